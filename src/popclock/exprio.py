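"""Expression-matrix I/O, normalization, filtering and rank-product DE.

The central container is :class:`ExpressionMatrix`: a genes x samples
non-negative real matrix (RPKM or simulated counts) with per-sample
metadata (collection time, stage label, modality).  All downstream
analyses (saturation curves, the PLS time model, network weighting)
consume this type.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "RankProductResult",
    "read_matrix",
    "write_matrix",
    "read_sample_meta",
    "quantile_normalize",
    "filter_expressed",
    "log_transform",
    "drop_zero_variance",
    "rank_product_de",
]


class MatrixParseError(ValueError):
    """Raised when an expression file cannot be parsed or validated."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
        Values must be finite and non-negative.
    sample_meta
        Optional per-sample records, indexed by sample id, with columns
        ``time`` (collection time, one consistent unit), ``stage``
        (categorical label) and ``modality`` (``"bulk"`` or ``"sc"``).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise MatrixParseError("non-finite values in expression matrix")
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise MatrixParseError(
                f"negative expression value at gene {v.index[gi]!r}, "
                f"sample {v.columns[si]!r}"
            )
        if self.sample_meta is not None:
            missing = [s for s in v.columns if s not in self.sample_meta.index]
            if missing:
                raise MatrixParseError(f"samples missing from metadata: {missing[:5]}")

    # -- convenience -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def times(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Collection times for the given samples (default: all)."""
        if self.sample_meta is None or "time" not in self.sample_meta.columns:
            raise ValueError("no collection times in sample metadata")
        samples = list(samples) if samples is not None else self.sample_ids
        t = self.sample_meta.loc[samples, "time"].to_numpy(dtype=float)
        if np.isnan(t).any():
            bad = [s for s, x in zip(samples, t) if np.isnan(x)]
            raise ValueError(f"missing collection time for samples: {bad[:5]}")
        return t

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(samples)]
        return ExpressionMatrix(self.values[list(samples)], meta)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta)

    def copy_with(self, arr: np.ndarray) -> "ExpressionMatrix":
        df = pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(df, self.sample_meta)


def read_matrix(
    path: str | Path,
    fmt: str = "tsv",
    sample_meta: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket.

    TSV layout: first column gene id, header row of sample ids,
    tab-separated, '.' decimal.  MTX layout: coordinate real general
    with companion ``<prefix>.genes.txt`` / ``<prefix>.samples.txt``
    files, one name per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
        non_num = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if non_num:
            raise MatrixParseError(f"non-numeric columns in {path}: {non_num[:5]}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df = df.astype(float)
    elif fmt == "mtx":
        prefix = path.with_suffix("") if path.suffix == ".mtx" else path
        genes_f = Path(str(prefix) + ".genes.txt")
        samples_f = Path(str(prefix) + ".samples.txt")
        for f in (genes_f, samples_f):
            if not f.exists():
                raise FileNotFoundError(f"companion name file missing: {f}")
        raw = mmread(str(path))
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        genes = genes_f.read_text().split()
        samples = samples_f.read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise MatrixParseError(
                f"mtx shape {mat.shape} does not match name files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples, dtype=float)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'mtx')")
    meta = read_sample_meta(sample_meta) if sample_meta is not None else None
    return ExpressionMatrix(df, meta)


def write_matrix(X: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a matrix as TSV (default) or MatrixMarket + name files."""
    path = Path(path)
    if fmt == "tsv":
        X.values.to_csv(path, sep="\t", float_format="%.10g")
    elif fmt == "mtx":
        prefix = path.with_suffix("") if path.suffix == ".mtx" else path
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(X.values.to_numpy(dtype=float)))
        Path(str(prefix) + ".genes.txt").write_text("\n".join(X.gene_ids) + "\n")
        Path(str(prefix) + ".samples.txt").write_text("\n".join(X.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, time, stage, modality."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise MatrixParseError(f"sample metadata {path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    return meta


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so every column shares one value multiset.

    The reference distribution is the per-rank mean of column-wise order
    statistics; values are assigned back by within-column rank, with ties
    receiving the mean of their rank positions' reference values.
    """
    arr = X.values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return X.copy_with(arr.copy())
    ref = np.sort(arr, axis=0).mean(axis=1)  # per-rank reference values
    # cumulative means let tied entries take the mean reference over their span
    ref_csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(arr)
    for j in range(n_samples):
        r = rankdata(arr[:, j], method="average")  # 1-based average ranks
        rmin = rankdata(arr[:, j], method="min").astype(int)
        rmax = rankdata(arr[:, j], method="max").astype(int)
        out[:, j] = (ref_csum[rmax] - ref_csum[rmin - 1]) / (rmax - rmin + 1)
        del r
    return X.copy_with(out)


def filter_expressed(
    X: ExpressionMatrix, min_level: float = 0.5, min_samples: int = 8
) -> ExpressionMatrix:
    """Keep genes with value strictly > ``min_level`` in >= ``min_samples`` samples.

    Defaults reproduce the standard single-cell expression filter
    (RPKM > 0.5 in at least eight cells).
    """
    if min_samples > X.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {X.shape[1]}"
        )
    arr = X.values.to_numpy(dtype=float)
    keep = (arr > min_level).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "no genes pass the expression filter; relax min_level/min_samples"
        )
    return ExpressionMatrix(X.values.loc[keep], X.sample_meta)


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10(value + 1)."""
    return X.copy_with(np.log10(X.values.to_numpy(dtype=float) + 1.0))


def drop_zero_variance(X: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Drop constant gene rows; returns (filtered matrix, n_dropped)."""
    arr = X.values.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        X = ExpressionMatrix(X.values.loc[keep], X.sample_meta)
    return X, n_dropped


# ---------------------------------------------------------------------------
# rank-product differential expression
# ---------------------------------------------------------------------------

@dataclass
class RankProductResult:
    gene_id: str
    rp_statistic: float  # geometric mean of across-replicate ranks, >= 1
    pfp: float           # proportion of false positives (can exceed 1)
    p_value: float       # per-gene permutation p-value, uniform under the null
    direction: str       # 'up' (higher in group A) or 'down'


def _fold_change_ranks(
    arr_a: np.ndarray, arr_b: np.ndarray, direction: str, pairing: str
) -> np.ndarray:
    """Per-replicate-pair gene ranks of fold change A/B (1 = most extreme).

    ``pairing="all"`` uses every (a, b) sample pair; ``"paired"`` zips
    the two groups one-to-one (requires equal sizes).  Note the null
    model permutes ranks independently across replicates, which is exact
    for paired designs; all-pairs replicates share samples and make the
    permutation p-values conservative approximations.
    """
    n_genes = arr_a.shape[0]
    if pairing == "paired":
        if arr_a.shape[1] != arr_b.shape[1]:
            raise ValueError("paired design requires equal group sizes")
        pairs = list(zip(range(arr_a.shape[1]), range(arr_b.shape[1])))
    else:
        pairs = list(itertools.product(range(arr_a.shape[1]), range(arr_b.shape[1])))
    ranks = np.empty((n_genes, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        fc = np.log((arr_a[:, i] + 1e-9) / (arr_b[:, j] + 1e-9))
        if direction == "up":
            fc = -fc  # descending fold change -> rank 1 for largest
        ranks[:, k] = rankdata(fc, method="average")
    return ranks


def _null_rp_cdf_exact(n_genes: int, n_reps: int, rank_products: np.ndarray) -> np.ndarray:
    """Exact P(null product of ranks <= observed) with iid uniform ranks.

    Under within-gene permutation each replicate rank is uniform on
    {1..n_genes}, independent across replicates; enumerate the n^K grid.
    Comparison happens on the product scale, where (half-)integer rank
    products are exact floats, so ties are counted exactly.
    """
    grids = np.meshgrid(*[np.arange(1, n_genes + 1)] * n_reps, indexing="ij")
    prods = np.ones_like(grids[0], dtype=float)
    for g in grids:
        prods = prods * g
    null = np.sort(prods.ravel())
    return np.searchsorted(null, rank_products, side="right") / null.size


def rank_product_de(
    X: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 200,
    seed: int = 0,
    direction: str = "up",
    exhaustive: bool = False,
    pairing: str = "all",
) -> list[RankProductResult]:
    """Rank-product differential expression between two sample groups.

    For every (a, b) replicate pair the genes are ranked by fold change
    (rank 1 = most up- or down-regulated per ``direction``); the statistic
    is the geometric mean of a gene's ranks.  The pfp (proportion of
    false positives) is estimated by permuting values within genes:
    pfp(g) = E[#null rank products <= rp(g)] / rank(rp(g)).  With
    ``exhaustive=True`` the null is computed exactly from the iid-uniform
    rank distribution instead of Monte Carlo sampling.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    arr_a = X.values[group_a].to_numpy(dtype=float)
    arr_b = X.values[group_b].to_numpy(dtype=float)
    n_genes = X.shape[0]
    if pairing not in ("all", "paired"):
        raise ValueError("pairing must be 'all' or 'paired'")
    ranks = _fold_change_ranks(arr_a, arr_b, direction, pairing)
    n_reps = ranks.shape[1]
    # counting happens on the product-of-ranks scale, where values are
    # exact floats, so observed-vs-null ties resolve deterministically
    prod = np.prod(ranks, axis=1)
    rp = prod ** (1.0 / n_reps)
    order_rank = rankdata(rp, method="average")  # rank 1 = smallest rp

    if exhaustive:
        if n_genes ** n_reps > 5_000_000:
            raise ValueError("exhaustive null too large; use Monte Carlo")
        cdf = _null_rp_cdf_exact(n_genes, n_reps, prod)
        exp_fp = n_genes * cdf
        p_val = cdf
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(n_genes)
        for _ in range(n_perm):
            perm_ranks = np.empty((n_genes, n_reps))
            for k in range(n_reps):
                perm_ranks[:, k] = rng.permutation(n_genes) + 1
            prod_perm = np.sort(np.prod(perm_ranks, axis=1))
            counts += np.searchsorted(prod_perm, prod, side="right")
        exp_fp = counts / n_perm
        p_val = (1.0 + counts) / (n_perm * n_genes + 1.0)
    pfp = exp_fp / order_rank

    return [
        RankProductResult(
            gene_id=g,
            rp_statistic=float(rp[i]),
            pfp=float(pfp[i]),
            p_value=float(p_val[i]),
            direction=direction,
        )
        for i, g in enumerate(X.gene_ids)
    ]
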