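"""Sampling-saturation analysis against a matched bulk reference.

How many single cells are enough?  For each subset size k the averaged
expression profile of k randomly chosen cells is correlated (Pearson,
on log10(x+1) values) with the matched cell-population reference; the
resulting curve saturates when adding cells no longer increases the
correlation, i.e. when intercellular heterogeneity is fully sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

__all__ = ["SaturationResult", "sampling_saturation", "saturation_point"]


@dataclass
class SaturationResult:
    reference_id: str
    subset_sizes: np.ndarray        # 1..n
    pcc_samples: list[np.ndarray]   # per size, one PCC per drawn subset
    mean_pcc: np.ndarray
    sd_pcc: np.ndarray
    genes_used: list[str] | None = None  # with gene_filter="union": union per draw -> None

    @property
    def n_cells(self) -> int:
        return int(self.subset_sizes[-1])


def _all_combinations(n: int, k: int, rng: np.random.Generator, max_combos: int) -> list[tuple[int, ...]]:
    """min(C(n,k), max_combos) distinct index subsets of size k."""
    total = math.comb(n, k)
    if total <= max_combos:
        import itertools

        return list(itertools.combinations(range(n), k))
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_combos:
        combo = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        seen.add(combo)
    return sorted(seen)


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return float("nan")
    return float(a @ b) / denom


def sampling_saturation(
    X_sc: ExpressionMatrix,
    reference: pd.Series | np.ndarray,
    max_combos: int = 30,
    min_level: float = 0.5,
    min_samples: int = 8,
    seed: int = 0,
    reference_id: str = "reference",
    reference_scale: float = 1.0,
    gene_filter: str = "union",
    log: bool = True,
) -> SaturationResult:
    """Saturation curve of averaged single-cell profiles vs a bulk reference.

    For each k in 1..n, min(C(n, k), ``max_combos``) distinct cell
    subsets are drawn (all combinations enumerated when few enough, which
    removes Monte-Carlo noise at the extremes); each subset's per-gene
    average is correlated with the reference on log10(x+1) values.

    Gene restriction per draw (``gene_filter``):

    * ``"union"`` (default): genes with averaged value > ``min_level`` OR
      reference value > ``min_level``;
    * ``"sc"``: genes expressed (> ``min_level``) in >= ``min_samples`` of
      the selected cells (the averaged-profile-side filter alone);
    * ``"none"``: all genes.

    ``reference_scale`` divides the reference before comparison: pass the
    total mixing weight (e.g. sum of the ratio vector) when the reference
    is a ratio-weighted SUM of cell profiles, so that it lands on the
    same per-cell scale as the subset averages and the full multiset
    reproduces PCC = 1 exactly under the log transform.
    """
    if max_combos < 1:
        raise ValueError("max_combos must be >= 1")
    n = X_sc.shape[1]
    if n < 1:
        raise ValueError("need at least one cell")
    if gene_filter not in ("union", "sc", "none"):
        raise ValueError("gene_filter must be 'union', 'sc' or 'none'")
    arr = X_sc.values.to_numpy(dtype=float)
    ref = np.asarray(reference, dtype=float) / float(reference_scale)
    if ref.shape[0] != arr.shape[0]:
        raise ValueError("reference must cover the gene universe of X_sc")

    rng = np.random.default_rng(seed)
    sizes = np.arange(1, n + 1)
    pcc_samples: list[np.ndarray] = []
    any_genes = False
    for k in sizes:
        combos = _all_combinations(n, int(k), rng, max_combos)
        pccs = np.empty(len(combos))
        for i, combo in enumerate(combos):
            avg = arr[:, list(combo)].mean(axis=1)
            if gene_filter == "union":
                mask = (avg > min_level) | (ref > min_level)
            elif gene_filter == "sc":
                ms = min(min_samples, int(k))
                mask = (arr[:, list(combo)] > min_level).sum(axis=1) >= ms
            else:
                mask = np.ones_like(avg, dtype=bool)
            if not mask.any():
                pccs[i] = np.nan
                continue
            any_genes = True
            a, r = avg[mask], ref[mask]
            if log:
                a, r = np.log10(a + 1.0), np.log10(r + 1.0)
            pccs[i] = _pcc(a, r)
        pcc_samples.append(pccs)
    if not any_genes:
        raise ValueError("no genes survive filtering in any subset")
    mean = np.array([np.nanmean(p) for p in pcc_samples])
    sd = np.array([np.nanstd(p, ddof=1) if p.size > 1 else 0.0 for p in pcc_samples])
    return SaturationResult(
        reference_id=reference_id,
        subset_sizes=sizes,
        pcc_samples=pcc_samples,
        mean_pcc=mean,
        sd_pcc=sd,
    )


def saturation_point(result: SaturationResult, epsilon: float = 0.01) -> int:
    """Smallest k whose mean PCC is within ``epsilon`` of the full-sample value."""
    plateau = result.mean_pcc[-1]
    for k, m in zip(result.subset_sizes, result.mean_pcc):
        if m >= plateau - epsilon:
            return int(k)
    return int(result.subset_sizes[-1])


def result_to_frame(result: SaturationResult) -> pd.DataFrame:
    """Tidy per-size summary: k, mean_pcc, sd_pcc, n_combos."""
    return pd.DataFrame(
        {
            "k": result.subset_sizes,
            "mean_pcc": result.mean_pcc,
            "sd_pcc": result.sd_pcc,
            "n_combos": [len(p) for p in result.pcc_samples],
        }
    )
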