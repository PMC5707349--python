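"""Real-scale differentiation-time inference for single cells.

The model is fit on a bulk (cell-population) time course and transferred
to single cells:

1. restrict genes to the intersection of bulk differential genes and
   single-cell-expressed genes;
2. fit a two-component PLS1 regression of collection time on the
   (centred, optionally z-scored) expression matrix: scores
   PLSCn = X·Wn maximize covariance with time;
3. ordinary least squares of time on (PLSC1, PLSC2) gives the fitted
   bulk differentiation time T = q1·PLSC1 + q2·PLSC2 + e;
4. single cells are projected through the same weights and their raw
   model time is calibrated by a shared linear map t = a·T + b against
   the cells' collection times, yielding a real-scale time, not a
   pseudotime rank.

Timer genes are genes whose expression correlates with T (bulk) or t
(single cells) beyond an absolute-PCC cutoff with a sample-randomization
p-value below a class cutoff.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .exprio import ExpressionMatrix

__all__ = [
    "TimeModel",
    "ScTimePrediction",
    "fit_pls_time",
    "predict_sc_time",
    "timer_genes",
    "randomization_pvalue",
    "detect_branches",
    "compare_orderings",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class TimeModel:
    gene_list: list[str]
    W1: np.ndarray            # projection vector for component 1 (rotation)
    W2: np.ndarray
    scores: np.ndarray        # n_bulk_samples x 2 (PLSC1, PLSC2)
    q1: float
    q2: float
    e: float                  # intercept
    center: np.ndarray        # per-gene centering
    scale: np.ndarray         # per-gene scaling divisor
    train_time: np.ndarray
    fitted_T: np.ndarray
    diag_pcc: float
    scaled: bool = True

    # -- (de)serialization -------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "gene_list": self.gene_list,
            "W1": self.W1.tolist(),
            "W2": self.W2.tolist(),
            "scores": self.scores.tolist(),
            "q1": self.q1,
            "q2": self.q2,
            "e": self.e,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "train_time": self.train_time.tolist(),
            "fitted_T": self.fitted_T.tolist(),
            "diag_pcc": self.diag_pcc,
            "scaled": self.scaled,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TimeModel":
        payload = json.loads(Path(path).read_text())
        if payload.pop("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        for k in ("W1", "W2", "scores", "center", "scale", "train_time", "fitted_T"):
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


@dataclass
class ScTimePrediction:
    cell_id: str
    raw_T: float
    t: float
    a: float
    b: float
    sc_scores: tuple[float, float]  # (PLSC1, PLSC2)


def _center_scale(
    arr: np.ndarray, scaled: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = arr.mean(axis=1)
    if scaled:
        scale = arr.std(axis=1, ddof=1)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(arr.shape[0])
    return (arr - center[:, None]) / scale[:, None], center, scale


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS PLS1 (X deflated, y not): returns (weights W, loadings P).

    Xc: samples x genes, centred; yc: centred response.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Xd = Xc.copy()
    for k in range(n_components):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(f"component {k + 1}: response uncorrelated with residual X")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {k + 1}: degenerate score")
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        W[:, k] = w
        P[:, k] = p_load
    return W, P


def fit_pls_time(
    X_cp: ExpressionMatrix,
    sc_expressed_genes: Sequence[str] | None = None,
    cp_deg_genes: Sequence[str] | None = None,
    n_components: int = 2,
    scaled: bool = True,
) -> TimeModel:
    """Fit the bulk PLS differentiation-time model.

    Genes are restricted to ``cp_deg_genes`` ∩ ``sc_expressed_genes``
    (either may be None = all genes).  Components are sign-oriented so
    each score correlates non-negatively with time.
    """
    times = X_cp.times()
    n_samples = X_cp.shape[1]
    if n_samples < n_components + 1:
        raise ValueError(
            f"need >= {n_components + 1} bulk samples for {n_components} components"
        )
    if np.std(times) == 0:
        raise ValueError("zero-variance collection times")

    genes = list(X_cp.gene_ids)
    if cp_deg_genes is not None:
        keep = set(cp_deg_genes)
        genes = [g for g in genes if g in keep]
    if sc_expressed_genes is not None:
        keep = set(sc_expressed_genes)
        genes = [g for g in genes if g in keep]
    if not genes:
        raise ValueError("empty gene intersection for PLS fit")

    arr = X_cp.values.loc[genes].to_numpy(dtype=float)
    arr_cs, center, scale = _center_scale(arr, scaled)
    Xc = arr_cs.T  # samples x genes
    yc = times - times.mean()

    W, P = _nipals_pls1(Xc, yc, n_components)
    # rotation: scores linear in the ORIGINAL centred matrix, T = Xc @ R
    R = W @ np.linalg.inv(P.T @ W)
    scores = Xc @ R

    # orient each component to correlate non-negatively with time
    for k in range(n_components):
        s = scores[:, k]
        if s.std() > 0 and np.corrcoef(s, times)[0, 1] < 0:
            R[:, k] *= -1
            scores[:, k] *= -1

    design = np.column_stack([scores, np.ones(n_samples)])
    coef, *_ = np.linalg.lstsq(design, times, rcond=None)
    fitted_T = design @ coef
    diag = float(np.corrcoef(fitted_T, times)[0, 1])
    return TimeModel(
        gene_list=genes,
        W1=R[:, 0].copy(),
        W2=R[:, 1].copy() if n_components > 1 else np.zeros(len(genes)),
        scores=scores[:, :2] if n_components > 1 else np.column_stack([scores[:, 0], np.zeros(n_samples)]),
        q1=float(coef[0]),
        q2=float(coef[1]) if n_components > 1 else 0.0,
        e=float(coef[-1]),
        center=center,
        scale=scale,
        train_time=times,
        fitted_T=fitted_T,
        diag_pcc=diag,
        scaled=scaled,
    )


def _project(model: TimeModel, X: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Scores of samples in X through the model; missing genes imputed at
    the training centre (zero contribution).  Returns (scores, n_missing)."""
    idx = X.values.index
    present = [g for g in model.gene_list if g in idx]
    n_missing = len(model.gene_list) - len(present)
    arr = np.zeros((len(model.gene_list), X.shape[1]))
    pos = {g: i for i, g in enumerate(model.gene_list)}
    sub = X.values.loc[present].to_numpy(dtype=float)
    rows = [pos[g] for g in present]
    arr[rows, :] = sub
    # missing genes sit at the centre -> 0 after centring
    arr[[i for i in range(len(model.gene_list)) if i not in set(rows)], :] = np.nan
    centred = (arr - model.center[:, None]) / model.scale[:, None]
    centred = np.nan_to_num(centred, nan=0.0)
    scores = centred.T @ np.column_stack([model.W1, model.W2])
    return scores, n_missing


def predict_sc_time(
    model: TimeModel,
    X_sc: ExpressionMatrix,
    sc_collection_times: Sequence[float] | np.ndarray | None = None,
    calibrate: bool = True,
) -> list[ScTimePrediction]:
    """Predict calibrated real-scale times for single cells.

    raw_T = q1·PLSC1 + q2·PLSC2 + e on the cell's projected scores; the
    shared calibration t = a·raw_T + b comes from least squares of raw_T
    on the cells' collection times (fit raw_T = a'·time + b', inverted),
    correcting the bulk-to-single-cell batch offset.  With
    ``calibrate=False`` the identity map (a=1, b=0) is used and
    collection times are not required.
    """
    scores, n_missing = _project(model, X_sc)
    if n_missing:
        warnings.warn(f"{n_missing} model genes missing from single-cell matrix; "
                      "imputed at training centre")
    raw_T = model.q1 * scores[:, 0] + model.q2 * scores[:, 1] + model.e

    if not calibrate:
        coll = None
    elif sc_collection_times is None:
        coll = X_sc.times()
    else:
        coll = np.asarray(sc_collection_times, dtype=float)
    if coll is not None and coll.shape[0] != raw_T.shape[0]:
        raise ValueError("collection times length mismatch")

    if coll is None:
        a, b = 1.0, 0.0
    elif np.std(coll) == 0:
        warnings.warn("all cells share one collection time; calibration skipped")
        a, b = 1.0, 0.0
    else:
        # regress raw_T on actual time, then invert onto the time axis
        A = np.column_stack([coll, np.ones_like(coll)])
        (a_p, b_p), *_ = np.linalg.lstsq(A, raw_T, rcond=None)
        if abs(a_p) < 1e-12 * max(1.0, float(np.std(raw_T))):
            warnings.warn("degenerate calibration slope; using mean offset")
            a, b = 1.0, float(np.mean(coll) - np.mean(raw_T))
        else:
            a, b = 1.0 / a_p, -b_p / a_p
    t = a * raw_T + b
    return [
        ScTimePrediction(
            cell_id=cid,
            raw_T=float(raw_T[i]),
            t=float(t[i]),
            a=float(a),
            b=float(b),
            sc_scores=(float(scores[i, 0]), float(scores[i, 1])),
        )
        for i, cid in enumerate(X_sc.sample_ids)
    ]


# ---------------------------------------------------------------------------
# timer genes and randomization p-values
# ---------------------------------------------------------------------------

def _pcc_rows(arr: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation of arr (genes x samples) with y."""
    ac = arr - arr.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((ac ** 2).sum(axis=1) * float(yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, ac @ yc / denom, np.nan)


def randomization_pvalue(
    observed_pcc: float,
    gene_values: np.ndarray,
    time_vector: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided sample-randomization p-value for a correlation.

    Permutes the time vector; p = (1 + #{perm: |PCC| >= |observed|}) /
    (n_perm + 1).  When n! <= n_perm all permutations are enumerated and
    the p-value is the exact fraction (the identity permutation counts).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = np.asarray(gene_values, dtype=float)
    y = np.asarray(time_vector, dtype=float)
    n = y.size
    obs = abs(observed_pcc)
    if math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        # correlate g against each permuted time vector
        pool = np.abs(_pcc_rows(y[perms], g))
        count = int((pool >= obs - 1e-12).sum())
        return count / perms.shape[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    pool = np.abs(_pcc_rows(y[perms], g))
    count = int((pool >= obs - 1e-12).sum())
    return (1 + count) / (n_perm + 1)


@dataclass
class TimerGeneTable:
    table: pd.DataFrame  # gene_id, pcc, p_value, selected, class, threshold_used
    n_dropped_constant: int

    @property
    def selected_genes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene_id"].tolist()


def timer_genes(
    X: ExpressionMatrix,
    time_vector: Sequence[float] | np.ndarray,
    pcc_cutoff: float = 0.6,
    p_cutoff: float = 0.003,
    n_perm: int = 1000,
    seed: int = 0,
    class_label: str = "T-gene",
) -> TimerGeneTable:
    """Genes correlated with (predicted) time beyond |PCC| and p cutoffs.

    Default cutoffs (0.6 / 0.003) are the bulk T-gene thresholds; use
    0.4 / 0.001 for single-cell t-genes and p 0.05 for per-stage sets.
    Shared time permutations are used across genes for efficiency.
    """
    y = np.asarray(time_vector, dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 samples")
    if y.size != X.shape[1]:
        raise ValueError("time vector length mismatch")
    arr = X.values.to_numpy(dtype=float)
    const = arr.std(axis=1) == 0
    n_dropped = int(const.sum())
    arr, genes = arr[~const], [g for g, c in zip(X.gene_ids, const) if not c]

    pcc = _pcc_rows(arr, y)
    n = y.size
    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # null |PCC| per gene across shared permutations: genes x perms
    yc_perm = y[perms]  # n_perm x n
    ac = arr - arr.mean(axis=1, keepdims=True)
    yp = yc_perm - yc_perm.mean(axis=1, keepdims=True)
    num = ac @ yp.T
    denom = np.sqrt((ac ** 2).sum(axis=1, keepdims=True) * (yp ** 2).sum(axis=1)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        null_abs = np.abs(np.where(denom > 0, num / denom, 0.0))
    counts = (null_abs >= np.abs(pcc)[:, None] - 1e-12).sum(axis=1)
    if exhaustive:
        p = counts / perms.shape[0]
    else:
        p = (1 + counts) / (perms.shape[0] + 1)

    selected = (np.abs(pcc) >= pcc_cutoff) & (p <= p_cutoff)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "pcc": pcc,
            "p_value": p,
            "selected": selected,
            "class": np.where(selected, class_label, ""),
            "threshold_used": pcc_cutoff,
        }
    )
    return TimerGeneTable(table=table, n_dropped_constant=n_dropped)


# ---------------------------------------------------------------------------
# branches and ordering comparison
# ---------------------------------------------------------------------------

def detect_branches(
    model: TimeModel | None,
    predictions: list[ScTimePrediction] | None = None,
    X_sc: ExpressionMatrix | None = None,
    silhouette_floor: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Branch labels from clustering late cells in the second PLS score.

    Returns per-cell (t, scPLS2, branch); scPLS2 captures the largest
    expression variance not already aligned with predicted time, so
    diverging lineages separate along it.  The late-time half of cells
    is clustered in scPLS2 with k in {1, 2, 3} chosen by silhouette
    (k = 1 when no k > 1 reaches ``silhouette_floor``).  The floor
    defaults to 0.75 because one-dimensional k-means on unimodal noise
    already reaches silhouettes near 0.55; genuinely separated branches
    score well above 0.8.  ``model`` and
    ``X_sc`` are accepted for API symmetry; the coordinates come from
    the predictions alone.
    """
    if predictions is None:
        raise ValueError("predictions are required")
    t = np.array([p.t for p in predictions])
    s2 = np.array([p.sc_scores[1] for p in predictions])
    cells = [p.cell_id for p in predictions]
    out = pd.DataFrame({"cell_id": cells, "t": t, "scPLS2": s2, "branch": 0})
    if len(cells) < 6:
        warnings.warn("fewer than 6 cells; branch detection refused")
        return out

    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    late = t >= np.median(t)
    xs = s2[late].reshape(-1, 1)
    best_k, best_labels, best_sil = 1, np.zeros(late.sum(), dtype=int), -1.0
    for k in (2, 3):
        if late.sum() <= k:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(xs)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(xs, km.labels_)
        if sil >= silhouette_floor and sil > best_sil:
            best_k, best_labels, best_sil = k, km.labels_, sil
    if best_k > 1:
        # stable numbering: branches ordered by mean scPLS2
        order = np.argsort([xs[best_labels == c].mean() for c in range(best_k)])
        remap = {int(c): i + 1 for i, c in enumerate(order)}
        out.loc[late, "branch"] = [remap[int(c)] for c in best_labels]
    return out


def compare_orderings(t: Sequence[float], other: Sequence[float]) -> dict:
    """Rank (Spearman) and linear (Pearson) agreement of two orderings."""
    a = np.asarray(t, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if a.std() == 0 or b.std() == 0:
        return {"spearman_rcc": float("nan"), "pearson_pcc": float("nan"),
                "degenerate": True}
    rcc = float(spearmanr(a, b).statistic)
    pcc = float(pearsonr(a, b).statistic)
    return {"spearman_rcc": rcc, "pearson_pcc": pcc, "degenerate": False}
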