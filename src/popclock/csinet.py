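"""Connection specificity index (CSI) co-expression networks.

CSI measures how specific a pairwise co-expression is: for a gene pair
(A, B) it is the fraction of third-party genes C that are LESS
correlated (by a margin) with both A and B than A and B are with each
other.  A pair with high absolute correlation that also stands out from
the background receives CSI near 1; promiscuous correlations are
penalized.  Networks keep pairs with CSI above a cutoff (default 0.6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

__all__ = ["CSIResult", "csi_from_expression", "csi_matrix", "merge_transition_networks"]


@dataclass
class CSIResult:
    genes: list[str]
    pcc_matrix: np.ndarray     # absolute correlations, |G| x |G|
    csi_matrix: np.ndarray     # in [0, 1]
    edges: pd.DataFrame        # gene_a, gene_b, pcc, csi (csi > cutoff)
    stage: str | None = None


def csi_matrix(abs_pcc: np.ndarray, margin: float = 0.05) -> np.ndarray:
    """CSI from an absolute-correlation matrix.

    CSI(A, B) = #{C not in {A, B}: |PCC|(A,C) < |PCC|(A,B) - margin
                                AND |PCC|(B,C) < |PCC|(A,B) - margin}
                / (|G| - 2).
    """
    P = np.asarray(abs_pcc, dtype=float)
    n = P.shape[0]
    if n < 3:
        raise ValueError("CSI needs >= 3 genes")
    thr = P[:, :, None] - margin                      # (A, B, 1)
    less_a = P[:, None, :] < thr                      # P[A, C] < P[A, B] - m
    less_b = P[None, :, :] < thr                      # P[B, C] < P[A, B] - m
    both = less_a & less_b                            # (A, B, C)
    idx = np.arange(n)
    both[idx, :, idx] = False                         # exclude C = A
    both[:, idx, idx] = False                         # exclude C = B
    out = both.sum(axis=2) / (n - 2)
    np.fill_diagonal(out, 0.0)                        # self-pairs undefined
    return out


def csi_from_expression(
    X_cp: ExpressionMatrix,
    genes: Sequence[str],
    window_samples: Sequence[str],
    margin: float = 0.05,
    cutoff: float = 0.6,
    stage: str | None = None,
) -> CSIResult:
    """CSI network among ``genes`` over a sample window.

    Constant genes in the window are dropped (warning with count); the
    diagonal is excluded from edges.
    """
    window_samples = list(window_samples)
    if len(window_samples) < 3:
        raise ValueError("window needs >= 3 samples")
    genes = [g for g in genes if g in X_cp.values.index]
    arr = X_cp.values.loc[genes, window_samples].to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropped {int((sd == 0).sum())} constant genes in window")
        genes = [g for g, s in zip(genes, sd) if s > 0]
        arr = arr[sd > 0]
    if len(genes) < 3:
        raise ValueError("fewer than 3 usable genes")

    P = np.abs(np.corrcoef(arr))
    np.fill_diagonal(P, 1.0)
    C = csi_matrix(P, margin=margin)

    rows = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if C[i, j] > cutoff:
                rows.append((genes[i], genes[j], P[i, j], C[i, j]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "csi"])
    return CSIResult(genes=genes, pcc_matrix=P, csi_matrix=C, edges=edges, stage=stage)


def merge_transition_networks(
    results: Sequence[CSIResult],
    stage_labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union of per-transition CSI networks.

    Duplicate edges keep the maximum CSI.  Per-node stage annotation
    comes from ``stage_labels`` (gene -> stage of pathway activation)
    when given, else from the contributing result's stage tag.

    Returns (edge table, node table).
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    node_stage: dict[str, str] = {}
    for res in results:
        for _, row in res.edges.iterrows():
            key = tuple(sorted((row["gene_a"], row["gene_b"])))
            if key not in best or row["csi"] > best[key][1]:
                best[key] = (row["pcc"], row["csi"])
        if res.stage is not None:
            for g in res.genes:
                node_stage.setdefault(g, res.stage)
    if stage_labels:
        node_stage.update(stage_labels)

    edges = pd.DataFrame(
        [(a, b, p, c) for (a, b), (p, c) in sorted(best.items())],
        columns=["gene_a", "gene_b", "pcc", "csi"],
    )
    nodes_in_edges = sorted(set(edges["gene_a"]) | set(edges["gene_b"])) if len(edges) else []
    nodes = pd.DataFrame(
        {
            "gene": nodes_in_edges,
            "stage": [node_stage.get(g, "") for g in nodes_in_edges],
        }
    )
    return edges, nodes
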