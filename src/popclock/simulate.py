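"""Synthetic data generators for matched bulk / single-cell designs.

Four generators cover the study designs the package is tested on:

* :func:`simulate_cp_from_sc` — a simulated bulk (cell-population)
  profile as a ratio-weighted sum of single-cell RPKM profiles.
* :func:`downsample_reads` — read-depth downsampling of an RPKM profile
  by multinomial read resampling.
* :func:`simulate_subtypes` — discrete cell subtypes at specified
  proportions (including a rare type) from a hierarchical
  gamma-Poisson count model.
* :func:`simulate_expansion_timecourse` — a two-population time course
  in which one population expands (e.g. to 95% vs 5%) while both share
  a temporal expression signal.
* :func:`simulate_trajectory` — a multi-stage differentiation time
  course observed in both bulk replicates and single cells, with
  planted time-correlated ("timer") genes.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

__all__ = [
    "SubtypeSimSpec",
    "ExpansionSimSpec",
    "TrajectorySimSpec",
    "simulate_cp_from_sc",
    "downsample_reads",
    "simulate_subtypes",
    "simulate_expansion_timecourse",
    "simulate_trajectory",
    "largest_remainder_counts",
]


def largest_remainder_counts(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts at given proportions summing exactly to ``total``."""
    proportions = np.asarray(proportions, dtype=float)
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


# ---------------------------------------------------------------------------
# bulk-from-single-cell mixtures and read downsampling
# ---------------------------------------------------------------------------

def simulate_cp_from_sc(
    X_sc: ExpressionMatrix,
    cell_ids: Sequence[str],
    ratio: Sequence[int],
) -> tuple[pd.Series, list[str]]:
    """Simulated bulk profile: per-gene ratio-weighted sum of cell RPKMs.

    Returns the summed profile and the implied cell multiset (each cell
    repeated ``ratio`` times; e.g. 3 cells at 1:2:3 -> 6 cell slots).
    Divide the profile by ``sum(ratio)`` to obtain the matched per-cell
    (average) scale.
    """
    cell_ids, ratio = list(cell_ids), list(ratio)
    if len(cell_ids) != len(ratio):
        raise ValueError("cell_ids and ratio must have equal length")
    if any((not float(r).is_integer()) or r <= 0 for r in ratio):
        raise ValueError("ratio entries must be positive integers")
    missing = [c for c in cell_ids if c not in X_sc.values.columns]
    if missing:
        raise KeyError(f"cells not in matrix: {missing}")
    sub = X_sc.values[cell_ids].to_numpy(dtype=float)
    profile = sub @ np.asarray(ratio, dtype=float)
    multiset = [c for c, r in zip(cell_ids, ratio) for _ in range(int(r))]
    return pd.Series(profile, index=X_sc.gene_ids), multiset


def downsample_reads(
    profile: pd.Series | np.ndarray,
    gene_lengths_kb: pd.Series | np.ndarray | float,
    depth: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``depth`` reads from an RPKM profile and re-derive RPKM.

    Expected read mass per gene is proportional to RPKM x length; counts
    are multinomial with total ``depth``; RPKM is recomputed as
    count / (length_kb x depth / 1e6).  Returns (counts, rpkm).
    """
    prof = np.asarray(profile, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lengths = np.broadcast_to(np.asarray(gene_lengths_kb, dtype=float), prof.shape)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    mass = prof * lengths
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero profile cannot be downsampled")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), mass / total)
    rpkm = counts / (lengths * depth / 1e6)
    return counts, rpkm


# ---------------------------------------------------------------------------
# gamma-Poisson subtype populations
# ---------------------------------------------------------------------------

@dataclass
class SubtypeSimSpec:
    """Discrete subtypes at fixed proportions, gamma-Poisson counts.

    Per-gene baseline means are Gamma(``gene_mean_shape``,
    ``gene_mean_scale``); per-cell library-size factors are
    lognormal(0, ``libsize_sigma``); a ``de_fraction`` subset of genes
    carries subtype-specific multiplicative factors drawn
    lognormal(``de_loc``, ``de_scale``), sign-symmetric (factor or its
    reciprocal with equal probability).
    """

    n_cells_total: int
    proportions: Sequence[float]
    n_genes: int = 2000
    de_fraction: float = 0.20
    seed: int = 0
    gene_mean_shape: float = 0.6
    gene_mean_scale: float = 2.0
    libsize_sigma: float = 0.35
    de_loc: float = 0.1
    de_scale: float = 0.4

    def validate(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {p.sum()}, expected 1")
        if (p <= 0).any():
            raise ValueError("all proportions must be > 0")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")


def simulate_subtypes(spec: SubtypeSimSpec) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Simulate a mixed population of discrete subtypes.

    Returns (matrix, per-cell subtype labels, per-gene DE factor table
    with one column per subtype; 1.0 marks a non-DE gene).
    Subtype counts follow the largest-remainder rounding of the
    specified proportions so they sum exactly to ``n_cells_total``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_sub = len(spec.proportions)
    counts = largest_remainder_counts(np.asarray(spec.proportions, float), spec.n_cells_total)

    base_mean = rng.gamma(spec.gene_mean_shape, spec.gene_mean_scale, size=spec.n_genes)
    base_mean = np.maximum(base_mean, 1e-3)
    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_genes = rng.choice(spec.n_genes, size=n_de, replace=False)

    factors = np.ones((spec.n_genes, n_sub))
    for s in range(n_sub):
        f = rng.lognormal(spec.de_loc, spec.de_scale, size=n_de)
        flip = rng.random(n_de) < 0.5
        f[flip] = 1.0 / f[flip]
        factors[de_genes, s] = f

    libsize = rng.lognormal(0.0, spec.libsize_sigma, size=spec.n_cells_total)
    labels = np.repeat(np.arange(n_sub), counts)

    mean_matrix = base_mean[:, None] * factors[:, labels] * libsize[None, :]
    values = rng.poisson(mean_matrix).astype(float)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    cell_ids = [f"cell{i:05d}" for i in range(spec.n_cells_total)]
    meta = pd.DataFrame(
        {"time": 0.0, "stage": [f"sub{k}" for k in labels], "modality": "sc"},
        index=pd.Index(cell_ids, name="sample_id"),
    )
    X = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=cell_ids), meta)
    label_series = pd.Series(labels, index=cell_ids, name="subtype")
    factor_df = pd.DataFrame(factors, index=gene_ids,
                             columns=[f"sub{k}" for k in range(n_sub)])
    return X, label_series, factor_df


# ---------------------------------------------------------------------------
# expanding two-population time course
# ---------------------------------------------------------------------------

@dataclass
class ExpansionSimSpec:
    """Two subpopulations over a time course; one may expand.

    At t0 the populations differ in ``de_fraction`` of genes; at each
    subsequent timepoint an additional ``per_timepoint_change_fraction``
    of genes shift in BOTH populations (a shared temporal signal).  The
    expanding population's proportion interpolates geometrically from
    ``initial_composition[0]`` to ``final_composition[0]``.
    """

    n_timepoints: int = 5
    per_timepoint_change_fraction: float = 0.01
    initial_composition: tuple[float, float] = (0.5, 0.5)
    final_composition: tuple[float, float] = (0.95, 0.05)
    cells_per_timepoint: int = 40
    n_genes: int = 2000
    de_fraction: float = 0.20
    temporal_effect_scale: float = 1.5
    seed: int = 0
    gene_mean_shape: float = 0.6
    gene_mean_scale: float = 2.0
    libsize_sigma: float = 0.35
    de_loc: float = 0.1
    de_scale: float = 0.4

    def validate(self) -> None:
        for comp in (self.initial_composition, self.final_composition):
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError(f"composition {comp} does not sum to 1")
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 timepoints")


@dataclass
class ExpansionSimResult:
    sc: ExpressionMatrix                 # all cells, meta.time = timepoint index
    labels: pd.Series                    # per-cell population 0/1 (0 expands)
    bulk: ExpressionMatrix               # one composition-weighted bulk per timepoint
    compositions: np.ndarray             # n_timepoints x 2
    changed_genes: list[np.ndarray]      # planted temporal gene sets per transition


def _geometric_schedule(p0: float, p1: float, n: int) -> np.ndarray:
    """Geometric interpolation of a proportion between endpoints."""
    if p0 <= 0 or p1 <= 0:
        raise ValueError("geometric schedule needs positive endpoints")
    return p0 * (p1 / p0) ** (np.arange(n) / (n - 1))


def simulate_expansion_timecourse(spec: ExpansionSimSpec) -> ExpansionSimResult:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_tp, n_genes = spec.n_timepoints, spec.n_genes

    base_mean = np.maximum(
        rng.gamma(spec.gene_mean_shape, spec.gene_mean_scale, size=n_genes), 1e-3
    )
    # population identity: de_fraction genes differ between pop 0 and pop 1
    n_de = int(round(spec.de_fraction * n_genes))
    de_genes = rng.choice(n_genes, size=n_de, replace=False)
    pop_factor = np.ones((n_genes, 2))
    f = rng.lognormal(spec.de_loc, spec.de_scale, size=n_de)
    flip = rng.random(n_de) < 0.5
    f[flip] = 1.0 / f[flip]
    pop_factor[de_genes, 1] = f

    # shared temporal signal: disjoint changed-gene sets per transition,
    # each gene shifts monotonically (log-linear) from its transition onward
    n_change = int(round(spec.per_timepoint_change_fraction * n_genes))
    available = np.setdiff1d(np.arange(n_genes), de_genes)
    rng.shuffle(available)
    changed_sets = [available[i * n_change:(i + 1) * n_change] for i in range(n_tp - 1)]
    log_time_factor = np.zeros((n_genes, n_tp))
    for k, genes in enumerate(changed_sets):
        eff = rng.normal(0.0, spec.temporal_effect_scale, size=len(genes))
        eff += np.sign(eff) * 0.5 * spec.temporal_effect_scale  # keep shifts clear of 0
        for tp in range(k + 1, n_tp):
            log_time_factor[genes, tp] += eff * (tp - k) / (n_tp - 1 - k)

    p_expand = _geometric_schedule(
        spec.initial_composition[0], spec.final_composition[0], n_tp
    )
    compositions = np.stack([p_expand, 1.0 - p_expand], axis=1)

    all_values, cell_ids, labels, times = [], [], [], []
    bulk_cols = {}
    for tp in range(n_tp):
        counts = largest_remainder_counts(compositions[tp], spec.cells_per_timepoint)
        mean_pop = base_mean[:, None] * pop_factor * np.exp(log_time_factor[:, tp])[:, None]
        # composition-weighted simulated bulk at this timepoint
        bulk_cols[f"bulk_t{tp}"] = mean_pop @ compositions[tp]
        for pop in (0, 1):
            n_cells = counts[pop]
            if n_cells == 0:
                continue
            lib = rng.lognormal(0.0, spec.libsize_sigma, size=n_cells)
            vals = rng.poisson(mean_pop[:, pop][:, None] * lib[None, :]).astype(float)
            all_values.append(vals)
            for i in range(n_cells):
                cell_ids.append(f"t{tp}_p{pop}_c{i:03d}")
                labels.append(pop)
                times.append(float(tp))

    sc_values = np.concatenate(all_values, axis=1)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sc_meta = pd.DataFrame(
        {"time": times, "stage": [f"t{int(t)}" for t in times], "modality": "sc"},
        index=pd.Index(cell_ids, name="sample_id"),
    )
    sc = ExpressionMatrix(pd.DataFrame(sc_values, index=gene_ids, columns=cell_ids), sc_meta)

    bulk_df = pd.DataFrame(bulk_cols, index=gene_ids)
    bulk_meta = pd.DataFrame(
        {"time": np.arange(n_tp, dtype=float), "stage": [f"t{k}" for k in range(n_tp)],
         "modality": "bulk"},
        index=pd.Index(list(bulk_cols), name="sample_id"),
    )
    bulk = ExpressionMatrix(bulk_df, bulk_meta)
    return ExpansionSimResult(
        sc=sc,
        labels=pd.Series(labels, index=cell_ids, name="population"),
        bulk=bulk,
        compositions=compositions,
        changed_genes=changed_sets,
    )


# ---------------------------------------------------------------------------
# matched bulk / single-cell differentiation trajectory
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySimSpec:
    """Multi-stage differentiation time course with planted timer genes.

    Timer genes follow gene-specific monotone functions of time — affine
    by default, with an optional ``sigmoid_fraction`` of logistic-shaped
    genes — plus Gaussian noise with sd = ``noise_sd`` x the gene's
    signal sd.  Non-timer genes are time-independent noise around a
    lognormal baseline.  Each single cell draws a true latent time from
    a Gaussian jitter around its collection timepoint; dropout zeroes
    entries with probability decaying in expression magnitude.
    """

    n_stages: int = 4
    timepoints: Sequence[float] = tuple(float(x) for x in range(0, 16, 2))  # 8 points
    bulk_replicates_per_timepoint: int = 3
    cells_per_timepoint: int = 8
    n_genes: int = 2000
    n_timer_genes: int = 300
    noise_sd: float = 0.3
    dropout_rate: float = 0.0
    sigmoid_fraction: float = 0.0
    time_jitter_sd: float | None = None  # default: 0.25 x timepoint spacing
    seed: int = 0

    def validate(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if not (np.diff(tp) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if self.n_timer_genes > self.n_genes:
            raise ValueError("n_timer_genes exceeds n_genes")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrajectorySimResult:
    bulk: ExpressionMatrix         # meta.time = collection time
    sc: ExpressionMatrix           # meta.time = collection time
    true_cell_times: pd.Series     # latent per-cell time
    timer_genes: list[str]         # planted time-correlated genes


def _timer_signal(
    time: np.ndarray, kind: np.ndarray, slope: np.ndarray, mid: np.ndarray,
    steep: np.ndarray, base: np.ndarray, amp: np.ndarray,
) -> np.ndarray:
    """Noise-free timer-gene expression, genes x samples, non-negative."""
    t = time[None, :]
    lin = base[:, None] + slope[:, None] * t
    sig = base[:, None] + amp[:, None] / (1.0 + np.exp(-steep[:, None] * (t - mid[:, None])))
    out = np.where(kind[:, None] == 0, lin, sig)
    return np.maximum(out, 0.0)


def simulate_trajectory(spec: TrajectorySimSpec) -> TrajectorySimResult:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tp = np.asarray(spec.timepoints, dtype=float)
    n_tp = tp.size
    span = tp[-1] - tp[0]
    jitter_sd = (
        spec.time_jitter_sd
        if spec.time_jitter_sd is not None
        else 0.25 * span / max(n_tp - 1, 1)
    )

    # latent cell times may overshoot the course by up to 3 jitter sds;
    # expression must stay non-negative over that extended span
    ext_lo, ext_hi = tp[0] - 3 * jitter_sd, tp[-1] + 3 * jitter_sd

    n_timer = spec.n_timer_genes
    kind = (rng.random(n_timer) < spec.sigmoid_fraction).astype(int)
    base = rng.lognormal(1.0, 0.5, size=n_timer)
    amp = base * rng.uniform(0.8, 2.0, size=n_timer) * np.where(rng.random(n_timer) < 0.5, -1, 1)
    # affine genes: slope chosen so the full-course change equals amp
    slope = amp / span
    # keep affine genes non-negative across the extended span
    base = np.where((kind == 0) & (slope < 0), base - slope * (ext_hi - tp[0]), base)
    base = np.where((kind == 0) & (slope > 0), base + slope * (tp[0] - ext_lo), base)
    mid = rng.uniform(tp[0] + 0.25 * span, tp[-1] - 0.25 * span, size=n_timer)
    steep = rng.uniform(2.0, 6.0, size=n_timer) / span
    base = np.where((kind == 1) & (amp < 0), base - amp, base)

    non_timer_mean = np.maximum(rng.lognormal(1.0, 0.8, size=spec.n_genes - n_timer), 0.05)

    def expression_at(times: np.ndarray) -> np.ndarray:
        timer = _timer_signal(times, kind, slope, mid, steep, base, amp)
        flat = np.repeat(non_timer_mean[:, None], times.size, axis=1)
        signal = np.concatenate([timer, flat], axis=0)
        if spec.noise_sd > 0:
            grid = _timer_signal(tp, kind, slope, mid, steep, base, amp)
            sd_timer = grid.std(axis=1)
            sd_flat = 0.5 * non_timer_mean  # noise scale for flat genes
            sd = np.concatenate([sd_timer, sd_flat]) * spec.noise_sd
            signal = signal + rng.normal(0.0, 1.0, signal.shape) * sd[:, None]
        return np.maximum(signal, 0.0)

    # bulk: replicates at each collection time
    bulk_times = np.repeat(tp, spec.bulk_replicates_per_timepoint)
    bulk_vals = expression_at(bulk_times)
    bulk_ids = [
        f"bulk_t{i}_r{r}"
        for i in range(n_tp)
        for r in range(spec.bulk_replicates_per_timepoint)
    ]

    # single cells: latent times jitter around collection timepoints
    sc_coll = np.repeat(tp, spec.cells_per_timepoint)
    jitter = np.clip(rng.normal(0.0, jitter_sd, size=sc_coll.size),
                     -3 * jitter_sd, 3 * jitter_sd)
    latent = sc_coll + jitter
    sc_vals = expression_at(latent)
    if spec.dropout_rate > 0:
        scale = np.median(sc_vals[sc_vals > 0]) if (sc_vals > 0).any() else 1.0
        p_drop = spec.dropout_rate * np.exp(-sc_vals / max(scale, 1e-9))
        sc_vals = np.where(rng.random(sc_vals.shape) < p_drop, 0.0, sc_vals)
    sc_ids = [f"cell_t{i}_c{c}" for i in range(n_tp) for c in range(spec.cells_per_timepoint)]

    gene_ids = [f"timer{i:04d}" for i in range(n_timer)] + [
        f"flat{i:04d}" for i in range(spec.n_genes - n_timer)
    ]
    stage_of_tp = np.minimum(
        (np.arange(n_tp) * spec.n_stages) // n_tp, spec.n_stages - 1
    )
    bulk_meta = pd.DataFrame(
        {
            "time": bulk_times,
            "stage": [f"S{stage_of_tp[i] + 1}" for i in range(n_tp)
                      for _ in range(spec.bulk_replicates_per_timepoint)],
            "modality": "bulk",
        },
        index=pd.Index(bulk_ids, name="sample_id"),
    )
    sc_meta = pd.DataFrame(
        {
            "time": sc_coll,
            "stage": [f"S{stage_of_tp[i] + 1}" for i in range(n_tp)
                      for _ in range(spec.cells_per_timepoint)],
            "modality": "sc",
        },
        index=pd.Index(sc_ids, name="sample_id"),
    )
    bulk = ExpressionMatrix(pd.DataFrame(bulk_vals, index=gene_ids, columns=bulk_ids), bulk_meta)
    sc = ExpressionMatrix(pd.DataFrame(sc_vals, index=gene_ids, columns=sc_ids), sc_meta)
    return TrajectorySimResult(
        bulk=bulk,
        sc=sc,
        true_cell_times=pd.Series(latent, index=sc_ids, name="true_time"),
        timer_genes=gene_ids[:n_timer],
    )
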