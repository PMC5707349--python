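"""Enrichment machinery: hypergeometric oracle, GSEA running sums,
activation calls and permutation interaction tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import kstest

from popclock.enrich import (
    GeneSetCollection,
    fisher_enrichment,
    fold_enrichment,
    gsea,
    pathway_activation,
    permutation_interaction_test,
    read_gmt,
)


def hypergeom_tail_oracle(k, K, n, N):
    """Exact rational upper hypergeometric tail via binomial coefficients."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


# ---------------------------------------------------------------- fisher
def make_collection(K, N, name="term"):
    universe = {f"g{i}" for i in range(N)}
    return GeneSetCollection({name: {f"g{i}" for i in range(K)}}, universe)


def test_fisher_matches_exact_tail_example():
    coll = make_collection(K=10, N=100)
    query = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 65)}  # k=5, n=20
    (res,) = fisher_enrichment(query, coll)
    assert res.k == 5 and res.n == 20
    assert res.p_raw == pytest.approx(hypergeom_tail_oracle(5, 10, 20, 100), abs=1e-12)


def test_fisher_exhaustive_small_grid():
    N = 20
    for K in range(1, N + 1, 4):
        for n in range(1, N + 1, 4):
            coll = make_collection(K, N)
            for k in range(max(0, K + n - N), min(K, n) + 1, 2):
                query = ({f"g{i}" for i in range(k)}
                         | {f"g{i}" for i in range(K, K + n - k)})
                (res,) = fisher_enrichment(query, coll)
                assert res.p_raw == pytest.approx(
                    hypergeom_tail_oracle(k, K, n, N), abs=1e-10
                )


def test_fisher_zero_overlap_and_bonferroni_cap():
    universe = {f"g{i}" for i in range(50)}
    coll = GeneSetCollection(
        {f"t{j}": {f"g{i}" for i in range(5 * j, 5 * j + 5)} for j in range(4)},
        universe,
    )
    res = fisher_enrichment({f"g{i}" for i in range(45, 50)}, coll)
    by_term = {r.term: r for r in res}
    assert by_term["t0"].k == 0
    assert by_term["t0"].p_raw > 0.4
    assert all(r.p_bonferroni <= 1.0 for r in res)
    assert all(r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 4)) for r in res)


def test_fisher_empty_query_errors():
    coll = make_collection(5, 20)
    with pytest.raises(ValueError, match="empty"):
        fisher_enrichment(set(), coll)


# ---------------------------------------------------------------- gsea
def running_sum_oracle(genes, scores, gene_set, weight):
    """Hand enumeration of the weighted KS walk and its extreme."""
    hits = [g in gene_set for g in genes]
    w = [abs(s) ** weight for s in scores]
    tot_hit = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = len(genes) - sum(hits)
    walk, cur = [], 0.0
    for wi, h in zip(w, hits):
        cur += wi / tot_hit if h else -1.0 / n_miss
        walk.append(cur)
    extreme = max(walk, key=abs)
    return walk, extreme


def test_gsea_toy_running_sum_matches_hand_oracle():
    genes = [f"g{i}" for i in range(10)]
    scores = [9.0, 8.0, 6.0, 5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0]
    gene_set = {"g1", "g4", "g7"}
    res = gsea(genes, scores, gene_set, n_perm=200, seed=0)
    _, extreme = running_sum_oracle(genes, scores, gene_set, weight=1.0)
    assert res.es == pytest.approx(extreme, abs=1e-12)


def test_gsea_top_loaded_set_is_maximal_over_contiguous_placements():
    genes = [f"g{i}" for i in range(30)]
    scores = list(np.linspace(10, 1, 30))
    top = {"g0", "g1", "g2"}
    es_top = gsea(genes, scores, top, n_perm=100, seed=0).es
    assert es_top > 0
    for start in range(1, 27):
        placed = {f"g{start}", f"g{start + 1}", f"g{start + 2}"}
        es = gsea(genes, scores, placed, n_perm=100, seed=0).es
        assert es_top >= es - 1e-12


def test_gsea_weight_zero_invariant_to_monotone_score_transform():
    genes = [f"g{i}" for i in range(20)]
    scores = np.linspace(5, 0.5, 20)
    gene_set = {"g2", "g5", "g11"}
    es1 = gsea(genes, scores, gene_set, n_perm=50, seed=0, weight=0.0).es
    es2 = gsea(genes, np.exp(scores), gene_set, n_perm=50, seed=0, weight=0.0).es
    assert es1 == pytest.approx(es2, abs=1e-12)


def test_gsea_rejects_disjoint_set():
    with pytest.raises(ValueError, match="no genes"):
        gsea(["a", "b"], [2.0, 1.0], {"zzz"}, n_perm=10, seed=0)


# ---------------------------------------------------------------- activation
def test_pathway_activation_conjunction_and_untestable():
    universe = {f"g{i}" for i in range(200)}
    members = GeneSetCollection(
        {"pw_active": {f"g{i}" for i in range(20)},
         "pw_silent": {f"g{i}" for i in range(100, 120)},
         "pw_notargets": {f"g{i}" for i in range(140, 160)}},
        universe,
    )
    targets = GeneSetCollection(
        {"pw_active": {f"g{i}" for i in range(20, 40)},
         "pw_silent": {f"g{i}" for i in range(120, 140)}},
    )
    # stage gene set: the active pathway's members; ranking: its targets on top
    stage_genes = {"S1": {f"g{i}" for i in range(25)}}
    order = ([f"g{i}" for i in range(20, 40)]
             + [f"g{i}" for i in range(20)]
             + [f"g{i}" for i in range(40, 200)])
    scores = np.linspace(10, 0.1, 200)
    ranks = {"S1": (order, scores)}
    out = pathway_activation(stage_genes, members, targets, ranks,
                             n_perm=300, seed=0)
    got = out.set_index("pathway")["status"]
    assert got["pw_active"] == "active"
    assert got["pw_silent"] == "inactive"
    assert got["pw_notargets"] == "untestable"


# ---------------------------------------------------------------- interaction
def grid_graph_edges(n):
    rng = np.random.default_rng(n)
    nodes = [f"v{i}" for i in range(60)]
    edges = set()
    while len(edges) < 80:
        a, b = rng.choice(60, 2, replace=False)
        edges.add((nodes[min(a, b)], nodes[max(a, b)]))
    return nodes, sorted(edges)


def test_interaction_zero_edges_gives_p_near_one():
    nodes, edges = grid_graph_edges(1)
    # two sets with no connecting edges: pick isolated-ish singletons
    p, obs = permutation_interaction_test(
        [("a", "b"), ("c", "d")], {"a"}, {"d"},
        universe=["a", "b", "c", "d", "e", "f"], n_perm=200, seed=0,
    )
    assert obs == 0
    assert p > 0.5


def test_interaction_planted_bipartite_hits_floor():
    x = [f"x{i}" for i in range(4)]
    y = [f"y{i}" for i in range(4)]
    others = [f"o{i}" for i in range(40)]
    edges = [(a, b) for a in x for b in y]  # complete bipartite
    edges += [("o0", "o1"), ("o2", "o3")]
    p, obs = permutation_interaction_test(edges, x, y,
                                          universe=x + y + others,
                                          n_perm=999, seed=0)
    assert obs == 16
    assert p == pytest.approx(1 / 1000)


def test_interaction_pvalues_uniform_under_null():
    nodes, edges = grid_graph_edges(2)
    rng = np.random.default_rng(5)
    pvals = []
    for i in range(500):
        x = rng.choice(nodes, 6, replace=False)
        y = rng.choice(nodes, 6, replace=False)
        p, _ = permutation_interaction_test(edges, set(x) - set(y), set(y) - set(x),
                                            universe=nodes, n_perm=99,
                                            seed=int(rng.integers(2**31)),
                                            randomized=True)
        pvals.append(p)
    # randomized tie-breaking removes the discreteness of the edge-count
    # statistic, so the null p-values are exactly uniform
    assert kstest(pvals, "uniform").pvalue > 0.01
    # the default (conservative) p-value must still be valid: P(p<=a) <= ~a
    pvals_cons = []
    for i in range(300):
        x = rng.choice(nodes, 6, replace=False)
        y = rng.choice(nodes, 6, replace=False)
        p, _ = permutation_interaction_test(edges, set(x) - set(y), set(y) - set(x),
                                            universe=nodes, n_perm=99,
                                            seed=int(rng.integers(2**31)))
        pvals_cons.append(p)
    for alpha in (0.05, 0.1, 0.25):
        assert np.mean(np.asarray(pvals_cons) <= alpha) <= alpha + 3 * np.sqrt(
            alpha * (1 - alpha) / 300
        )


# ---------------------------------------------------------------- fold
def test_fold_enrichment_hand_counts():
    bg = {f"g{i}" for i in range(500)}
    feature = {f"g{i}" for i in range(20)}  # 20/500 in background
    query = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(100, 140)}  # 10/50
    assert fold_enrichment(query, feature, bg) == pytest.approx(5.0)
    assert fold_enrichment(bg, feature, bg) == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="zero"):
        out = fold_enrichment(query, {"nothere"}, bg)
    assert np.isnan(out)


# ---------------------------------------------------------------- gmt
def test_read_gmt_and_harmonization(tmp_path):
    f = tmp_path / "sets.gmt"
    f.write_text("setA\tdesc\tg1\tg2\tg99\nsetB\tdesc\tg3\n")
    with pytest.warns(UserWarning, match="empty"):
        coll = read_gmt(f, universe=["g1", "g2", "g4"])
    assert coll["setA"] == {"g1", "g2"}
    assert coll["setB"] == set()
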