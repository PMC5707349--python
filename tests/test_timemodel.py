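"""PLS time model: fitting, single-cell transfer, timer genes, branches."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata, spearmanr

from popclock import exprio, timemodel
from popclock.simulate import TrajectorySimSpec, simulate_trajectory
from popclock.timemodel import (
    ScTimePrediction,
    TimeModel,
    compare_orderings,
    detect_branches,
    fit_pls_time,
    predict_sc_time,
    randomization_pvalue,
    timer_genes,
)

from conftest import make_matrix


def affine_bulk(n_genes=20, times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0), seed=0):
    """Every gene an exact affine function of time, no noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times)
    slopes = rng.normal(1.0, 0.5, n_genes)
    inters = rng.uniform(5.0, 10.0, n_genes)
    vals = inters[:, None] + slopes[:, None] * t[None, :]
    vals = np.maximum(vals, 0.0)
    return make_matrix(vals, times=t, modality="bulk")


# ---------------------------------------------------------------- fitting
def test_exact_affine_limit_recovers_time():
    X = affine_bulk()
    model = fit_pls_time(X)
    assert model.diag_pcc > 1 - 1e-9
    np.testing.assert_allclose(model.fitted_T, X.times(), atol=1e-6)


def test_first_weight_matches_eigen_oracle():
    # toy 4-sample x 3-gene: dominant eigenvector of X'yy'X is the PLS1
    # weight direction (X centred/scaled, y centred)
    rng = np.random.default_rng(1)
    vals = rng.gamma(2.0, 2.0, size=(3, 4))
    t = np.array([0.0, 1.0, 2.0, 3.0])
    X = make_matrix(vals, times=t, modality="bulk")
    model = fit_pls_time(X)

    arr = vals - vals.mean(axis=1, keepdims=True)
    arr = arr / arr.std(axis=1, ddof=1, keepdims=True)
    Xc = arr.T
    yc = (t - t.mean())[:, None]
    M = Xc.T @ yc @ yc.T @ Xc
    eigvals, eigvecs = np.linalg.eigh(M)
    dominant = eigvecs[:, -1]
    cos = abs(dominant @ model.W1) / np.linalg.norm(model.W1)
    assert cos > 1 - 1e-9


def test_fit_validations():
    X = affine_bulk(times=(0.0, 1.0))
    with pytest.raises(ValueError, match="samples"):
        fit_pls_time(X)
    Xc = affine_bulk()
    with pytest.raises(ValueError, match="intersection"):
        fit_pls_time(Xc, sc_expressed_genes=["nope"])
    flat = make_matrix(np.random.default_rng(0).gamma(2, 2, (5, 4)),
                       times=[1.0, 1.0, 1.0, 1.0], modality="bulk")
    with pytest.raises(ValueError, match="zero-variance"):
        fit_pls_time(flat)


# ---------------------------------------------------------------- prediction
def test_bulk_through_sc_path_reproduces_fitted_T():
    X = affine_bulk()
    model = fit_pls_time(X)
    preds = predict_sc_time(model, X, calibrate=False)
    np.testing.assert_allclose([p.raw_T for p in preds], model.fitted_T, atol=1e-9)
    np.testing.assert_allclose([p.t for p in preds], model.fitted_T, atol=1e-9)
    assert all(p.a == 1.0 and p.b == 0.0 for p in preds)


def test_prediction_invariant_to_gene_order():
    res = simulate_trajectory(TrajectorySimSpec(n_genes=200, n_timer_genes=40, seed=3))
    model = fit_pls_time(res.bulk)
    preds = predict_sc_time(model, res.sc)
    shuffled = res.sc.values.sample(frac=1.0, random_state=9)
    sc_shuf = exprio.ExpressionMatrix(shuffled, res.sc.sample_meta)
    preds2 = predict_sc_time(model, sc_shuf)
    np.testing.assert_allclose([p.t for p in preds], [p.t for p in preds2], atol=1e-9)


def test_model_serialization_round_trips_bit_identically(tmp_path):
    res = simulate_trajectory(TrajectorySimSpec(n_genes=200, n_timer_genes=40, seed=3))
    model = fit_pls_time(res.bulk)
    model.to_json(tmp_path / "model.json")
    back = TimeModel.from_json(tmp_path / "model.json")
    p1 = predict_sc_time(model, res.sc)
    p2 = predict_sc_time(back, res.sc)
    assert [p.t for p in p1] == [p.t for p in p2]


def test_missing_genes_imputed_with_warning():
    res = simulate_trajectory(TrajectorySimSpec(n_genes=100, n_timer_genes=30, seed=4))
    model = fit_pls_time(res.bulk)
    dropped = res.sc.subset_genes(res.sc.gene_ids[:-10])
    with pytest.warns(UserWarning, match="missing"):
        predict_sc_time(model, dropped)


def test_constant_collection_times_skip_calibration():
    res = simulate_trajectory(TrajectorySimSpec(n_genes=100, n_timer_genes=30, seed=4))
    model = fit_pls_time(res.bulk)
    with pytest.warns(UserWarning, match="calibration skipped"):
        preds = predict_sc_time(model, res.sc, sc_collection_times=np.ones(64))
    assert all(p.a == 1.0 and p.b == 0.0 for p in preds)


def test_subsampling_robustness_of_time_recovery():
    # dropping half the cells per timepoint barely moves the agreement
    # between predicted time and collection time
    res = simulate_trajectory(TrajectorySimSpec(noise_sd=0.3, seed=11))
    model = fit_pls_time(res.bulk)
    rng = np.random.default_rng(0)
    rccs = []
    for _ in range(5):
        keep = []
        for tp in range(8):
            cells = [f"cell_t{tp}_c{c}" for c in rng.choice(8, 4, replace=False)]
            keep.extend(cells)
        sub = res.sc.subset_samples(keep)
        preds = predict_sc_time(model, sub)
        rccs.append(spearmanr([p.t for p in preds], sub.times()).statistic)
    assert np.std(rccs) < 0.1


# ---------------------------------------------------------------- randomization
def test_randomization_pvalue_lower_bound_and_exhaustive():
    rng = np.random.default_rng(2)
    # n = 8 samples, Monte Carlo: perfect correlation -> p = 1/1000
    y8 = np.arange(8.0)
    p = randomization_pvalue(1.0, y8, y8, n_perm=999, seed=0)
    assert p == pytest.approx(1 / 1000)
    # n = 4 -> exhaustive enumeration over 24 permutations, matches a
    # brute-force oracle built directly on pearsonr
    g = rng.normal(size=4)
    y = np.array([0.0, 1.0, 2.0, 3.0])
    obs = pearsonr(g, y).statistic
    count = sum(
        abs(pearsonr(g, np.array(perm)).statistic) >= abs(obs) - 1e-12
        for perm in itertools.permutations(y)
    )
    expected = count / 24
    assert randomization_pvalue(obs, g, y, n_perm=1000) == pytest.approx(expected)


def test_timer_genes_selects_perfect_correlate_and_calibrates():
    rng = np.random.default_rng(3)
    t = np.linspace(0, 10, 12)
    vals = rng.normal(size=(2000, 12))
    vals[0] = t  # gene exactly equal to the time vector
    vals = vals - vals.min() + 0.1
    X = make_matrix(vals, gene_ids=[f"g{i}" for i in range(2000)])
    res = timer_genes(X, t, pcc_cutoff=0.6, p_cutoff=0.003, n_perm=999, seed=0)
    assert "g0" in res.selected_genes
    row = res.table.set_index("gene_id").loc["g0"]
    assert row["pcc"] == pytest.approx(1.0)
    # null calibration: with pcc_cutoff 0 the selection rate tracks alpha
    null = timer_genes(X.subset_genes([f"g{i}" for i in range(1, 2000)]),
                       t, pcc_cutoff=0.0, p_cutoff=0.05, n_perm=999, seed=1)
    rate = null.table["selected"].mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1999) + 0.01


def test_timer_genes_drops_constant_rows():
    t = np.linspace(0, 5, 6)
    vals = np.vstack([np.linspace(1, 2, 6), np.full(6, 3.0)])
    X = make_matrix(vals, gene_ids=["lin", "const"])
    res = timer_genes(X, t, pcc_cutoff=0.5, p_cutoff=1.0, n_perm=100, seed=0)
    assert res.n_dropped_constant == 1
    assert res.table["gene_id"].tolist() == ["lin"]


# ---------------------------------------------------------------- branches
def make_preds(t, s2):
    return [
        ScTimePrediction(cell_id=f"c{i}", raw_T=ti, t=ti, a=1.0, b=0.0,
                         sc_scores=(0.0, si))
        for i, (ti, si) in enumerate(zip(t, s2))
    ]


def test_single_trajectory_yields_one_branch():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 10, 40)
    s2 = rng.normal(0, 0.2, 40)
    out = detect_branches(None, make_preds(t, s2), seed=0)
    assert (out["branch"] == 0).all()


def test_two_diverging_lineages_recovered():
    rng = np.random.default_rng(1)
    t = np.linspace(0, 10, 60)
    lineage = (np.arange(60) % 2)[t > 5]  # late cells alternate lineages
    s2 = rng.normal(0, 0.15, 60)
    late = t > 5
    s2[late] += np.where((np.arange(60) % 2)[late] == 1, 2.0, -2.0)
    out = detect_branches(None, make_preds(t, s2), seed=0)
    late_out = out[out["t"] >= np.median(t)]
    got = late_out["branch"].to_numpy()
    truth = (np.arange(60) % 2)[out["t"].to_numpy() >= np.median(t)] + 1
    agreement = max((got == truth).mean(), (got == (3 - truth)).mean())
    assert agreement >= 0.9


def test_too_few_cells_refuse_branching():
    with pytest.warns(UserWarning, match="fewer than 6"):
        out = detect_branches(None, make_preds([0, 1, 2], [0, 0, 0]))
    assert (out["branch"] == 0).all()


# ---------------------------------------------------------------- orderings
def test_compare_orderings_identity_reversal_and_oracle():
    v = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert compare_orderings(v, v)["spearman_rcc"] == pytest.approx(1.0)
    assert compare_orderings(v, v[::-1])["spearman_rcc"] == pytest.approx(-1.0)
    a = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    b = np.array([2.0, 7.0, 1.0, 8.0, 2.5])
    # brute-force rank correlation oracle
    ra, rb = rankdata(a), rankdata(b)
    oracle = np.corrcoef(ra, rb)[0, 1]
    assert compare_orderings(a, b)["spearman_rcc"] == pytest.approx(oracle)
    flagged = compare_orderings([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert flagged["degenerate"]
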