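"""Enrichment machinery: overlap tests, GSEA, pathway activation calls,
and network permutation tests.

* :func:`fisher_enrichment` — one-sided hypergeometric overlap tests
  with Bonferroni correction across the terms tested in a call.
* :func:`gsea` — weighted Kolmogorov–Smirnov running-sum enrichment
  score with a gene-set permutation null (NES, FDR q).
* :func:`pathway_activation` — a pathway is called active in a stage iff
  its member genes are Fisher-enriched in the stage-specific gene set
  AND its upregulated targets are GSEA-enriched in the stage's
  expression ranking (conjunction rule).
* :func:`permutation_interaction_test` — are two gene sets more
  connected in a network than same-size random sets?
* :func:`fold_enrichment` — simple rate ratio against a background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "fisher_enrichment",
    "gsea",
    "pathway_activation",
    "permutation_interaction_test",
    "fold_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            clipped = {}
            for name, s in self.sets.items():
                inter = set(s) & self.universe
                if not inter:
                    warnings.warn(f"gene set {name!r} is empty after harmonization")
                clipped[name] = inter
            self.sets = clipped
        else:
            self.sets = {k: set(v) for k, v in self.sets.items()}

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...; tab-separated)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets, set(universe) if universe is not None else None)


@dataclass
class EnrichmentResult:
    term: str
    k: int              # overlap count
    K: int              # set size (in universe)
    n: int              # query size
    N: int              # universe size
    odds_ratio: float
    p_raw: float
    p_bonferroni: float
    es: float | None = None
    nes: float | None = None
    fdr_q: float | None = None


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
) -> list[EnrichmentResult]:
    """One-sided (enrichment) hypergeometric test per term, Bonferroni
    corrected across the terms tested in this call."""
    if collection.universe is None:
        raise ValueError("collection must define a universe")
    universe = collection.universe
    query = set(query) & universe
    if not query:
        raise ValueError("query is empty (after universe harmonization)")
    N, n = len(universe), len(query)
    n_terms = len(collection.sets)
    out = []
    for term, s in collection.sets.items():
        K = len(s)
        k = len(query & s)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b_ = k, n - k
        c_, d = K - k, N - K - (n - k)
        odds = (a * d) / (b_ * c_) if b_ * c_ > 0 else float("inf") if a * d > 0 else float("nan")
        out.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                odds_ratio=float(odds),
                p_raw=p,
                p_bonferroni=float(min(1.0, p * n_terms)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _running_es(
    hits: np.ndarray, scores: np.ndarray, weight: float
) -> float:
    """Signed enrichment score: max deviation of the weighted KS walk."""
    n = hits.size
    w = np.abs(scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = n - int(hits.sum())
    if total_hit == 0 or n_miss == 0:
        raise ValueError("gene set covers none or all of the ranking")
    walk = np.cumsum(hit_w / total_hit - (~hits) / n_miss)
    i_max = int(np.argmax(np.abs(walk)))
    return float(walk[i_max])


def gsea(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    term: str = "gene_set",
) -> EnrichmentResult:
    """Weighted KS enrichment of a gene set in a ranked list.

    ``ranked_genes`` must be ordered by decreasing ``scores``.  Hit steps
    increment proportionally to |score|^weight, miss steps decrement
    uniformly.  The null is gene-set permutation: ``n_perm`` random
    same-size sets drawn from the ranking.  NES divides the ES by the
    mean |null ES| of matching sign; FDR q is the fraction of same-sign
    null NES at least as extreme.
    """
    genes = list(ranked_genes)
    sc = np.asarray(scores, dtype=float)
    if len(genes) != sc.size:
        raise ValueError("ranked_genes and scores length mismatch")
    gene_set = set(gene_set)
    hits = np.fromiter((g in gene_set for g in genes), dtype=bool, count=len(genes))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set has no genes in the ranking")
    es = _running_es(hits, sc, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(genes))
    for i in range(n_perm):
        pick = rng.choice(idx, size=n_hit, replace=False)
        h = np.zeros(len(genes), dtype=bool)
        h[pick] = True
        null[i] = _running_es(h, sc, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        nes = float("inf") if es > 0 else float("-inf")
        fdr = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        null_nes = same_sign / np.mean(np.abs(same_sign))
        fdr = (1 + int((np.abs(null_nes) >= abs(nes)).sum())) / (same_sign.size + 1)
    return EnrichmentResult(
        term=term, k=n_hit, K=len(gene_set), n=len(genes), N=len(genes),
        odds_ratio=float("nan"), p_raw=float("nan"), p_bonferroni=float("nan"),
        es=float(es), nes=float(nes), fdr_q=float(fdr),
    )


# ---------------------------------------------------------------------------
# pathway activation and interaction tests
# ---------------------------------------------------------------------------

def pathway_activation(
    stage_genes: Mapping[str, set[str]],
    pathway_members: GeneSetCollection,
    pathway_up_targets: GeneSetCollection,
    stage_expression_rank: Mapping[str, tuple[Sequence[str], Sequence[float]]],
    fisher_p: float = 0.05,
    gsea_fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Call pathways active per stage by the member-AND-target rule.

    A pathway is active in a stage iff its members are Fisher-enriched
    in the stage-specific gene set (Bonferroni p < ``fisher_p``) AND its
    upregulated targets are positively GSEA-enriched in the stage's
    expression-ranked gene list (FDR < ``gsea_fdr``).  Pathways without
    a target set are reported untestable, not inactive.
    """
    rows = []
    for stage, genes in stage_genes.items():
        member_res = {r.term: r for r in fisher_enrichment(genes, pathway_members)}
        ranked, scores = stage_expression_rank[stage]
        for pw in pathway_members.names():
            targets = pathway_up_targets.sets.get(pw, set())
            if not targets:
                rows.append((stage, pw, member_res[pw].p_bonferroni, np.nan,
                             "untestable"))
                continue
            try:
                g = gsea(ranked, scores, targets, n_perm=n_perm, seed=seed, term=pw)
                target_ok = g.es is not None and g.es > 0 and g.fdr_q < gsea_fdr
                fdr_q = g.fdr_q
            except ValueError:
                rows.append((stage, pw, member_res[pw].p_bonferroni, np.nan,
                             "untestable"))
                continue
            member_ok = member_res[pw].p_bonferroni < fisher_p
            status = "active" if (member_ok and target_ok) else "inactive"
            rows.append((stage, pw, member_res[pw].p_bonferroni, fdr_q, status))
    return pd.DataFrame(
        rows, columns=["stage", "pathway", "member_p_bonferroni", "target_fdr_q", "status"]
    )


def permutation_interaction_test(
    edges: Iterable[tuple[str, str]],
    set_x: Iterable[str],
    set_y: Iterable[str],
    universe: Iterable[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    randomized: bool = False,
) -> tuple[float, int]:
    """Permutation p-value for cross-connectivity of two gene sets.

    Statistic: number of network edges with one endpoint in X and the
    other in Y.  Null: redraw same-size node sets uniformly from the
    universe (default: all network nodes).  Returns (p, observed count)
    with p = (1 + #{perm >= observed}) / (n_perm + 1).

    The edge count is discrete, so the default p-value is conservative
    (super-uniform) under the null.  With ``randomized=True`` ties with
    the observed statistic are broken by an auxiliary uniform draw,
    p = (#{perm > obs} + U·(1 + #{perm = obs})) / (n_perm + 1),
    which is exactly uniform under the null (useful for calibration
    studies; the conservative default is the right choice for claims).
    """
    edge_list = [(a, b) for a, b in edges]
    nodes = sorted({v for e in edge_list for v in e})
    uni = sorted(set(universe)) if universe is not None else nodes
    set_x, set_y = set(set_x), set(set_y)
    bad = (set_x | set_y) - set(uni)
    if bad:
        raise ValueError(f"genes outside universe: {sorted(bad)[:5]}")

    def count_between(x: set[str], y: set[str]) -> int:
        return sum(1 for a, b in edge_list
                   if (a in x and b in y) or (a in y and b in x))

    observed = count_between(set_x, set_y)
    rng = np.random.default_rng(seed)
    uni_arr = np.array(uni)
    gt = eq = 0
    for _ in range(n_perm):
        px = set(rng.choice(uni_arr, size=len(set_x), replace=False))
        py = set(rng.choice(uni_arr, size=len(set_y), replace=False))
        stat = count_between(px, py)
        if stat > observed:
            gt += 1
        elif stat == observed:
            eq += 1
    if randomized:
        u = rng.random()
        return (gt + u * (1 + eq)) / (n_perm + 1), observed
    return (1 + gt + eq) / (n_perm + 1), observed


def fold_enrichment(
    query: Iterable[str],
    feature_set: Iterable[str],
    background: Iterable[str],
) -> float:
    """Rate ratio: (|query ∩ feature| / |query|) / (|bg ∩ feature| / |bg|)."""
    query, feature, bg = set(query), set(feature_set), set(background)
    if not bg or not query:
        raise ValueError("query and background must be non-empty")
    if not query <= bg:
        raise ValueError("query must be contained in background")
    bg_rate = len(bg & feature) / len(bg)
    if bg_rate == 0:
        warnings.warn("background feature rate is zero; fold undefined")
        return float("nan")
    return (len(query & feature) / len(query)) / bg_rate
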