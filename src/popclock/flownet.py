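"""Minimum-cost-flow subnetwork inference over a protein-interaction template.

Links bulk-only source genes (expressed in the cell population but
undetected in single cells) to single-cell timer target genes through a
weighted interaction network.  A super-source S feeds all sources and
all targets drain into a super-sink K; the continuous linear program

    min  sum_e f_e * (-log w_e)  -  gamma * (total flow out of S)

subject to conservation and unit capacities selects the subnetwork that
carries the largest information flow for the least edge cost, where the
per-edge weight w is the absolute Pearson correlation of the two genes'
bulk expression over the transition window.  Larger gamma buys more
flow; the weight floor on selected edges arbitrates the trade-off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exprio import ExpressionMatrix

__all__ = [
    "TemplateNetwork",
    "FlowProblem",
    "FlowResult",
    "load_template",
    "weight_edges",
    "build_flow_problem",
    "solve_flow",
    "select_gamma",
    "call_hubs",
]

SOURCE_NODE = "__S__"
SINK_NODE = "__K__"
FLOW_TOL = 1e-6


@dataclass
class TemplateNetwork:
    """Undirected interaction template; duplicate edges keep max confidence."""

    graph: nx.Graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _parse_edge_file(path: Path) -> list[tuple[str, str, float | None]]:
    edges = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 3 and not _is_number(parts[2]):
            a, _, b = parts  # SIF: a <relation> b
            score = None
        elif len(parts) == 3:
            a, b, score = parts[0], parts[1], float(parts[2])
        elif len(parts) == 2:
            a, b = parts
            score = None
        else:
            raise ValueError(f"{path}:{ln}: cannot parse edge line {line!r}")
        edges.append((a, b, score))
    return edges


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_template(
    paths: Sequence[str | Path],
    min_confidence: float = 600.0,
    ortholog_map: dict[str, str] | str | Path | None = None,
) -> TemplateNetwork:
    """Union of edge files (SIF or 2/3-column TSV) into one template.

    Score-bearing edges are kept only when score > ``min_confidence``
    (strict); unscored edges pass.  With an ortholog map (2-column TSV
    or dict), ids are translated before the union and edges touching an
    untranslatable id are dropped (count logged via warning).
    """
    if ortholog_map is not None and not isinstance(ortholog_map, dict):
        df = pd.read_csv(ortholog_map, sep="\t", header=None, dtype=str)
        ortholog_map = dict(zip(df[0], df[1]))

    g = nx.Graph()
    n_untranslated = 0
    for path in paths:
        for a, b, score in _parse_edge_file(Path(path)):
            if score is not None and not score > min_confidence:
                continue
            if ortholog_map is not None:
                if a not in ortholog_map or b not in ortholog_map:
                    n_untranslated += 1
                    continue
                a, b = ortholog_map[a], ortholog_map[b]
            if a == b:
                continue
            conf = score if score is not None else np.inf
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
    if n_untranslated:
        warnings.warn(f"dropped {n_untranslated} edges with untranslatable ids")
    if g.number_of_edges() == 0:
        raise ValueError("template union is empty")
    return TemplateNetwork(graph=g)


def weight_edges(
    template: TemplateNetwork,
    X_cp: ExpressionMatrix,
    window_samples: Sequence[str],
) -> nx.Graph:
    """Weight template edges by |PCC| over the transition window.

    Edges with either gene absent or constant in the window, or with
    zero correlation, are dropped.
    """
    window_samples = list(window_samples)
    if len(window_samples) < 3:
        raise ValueError("transition window needs >= 3 samples")
    sub = X_cp.values[window_samples]
    present = set(sub.index)
    arr = sub.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(sub.index)}
    sd = arr.std(axis=1)

    out = nx.Graph()
    for a, b in template.graph.edges():
        if a not in present or b not in present:
            continue
        ia, ib = pos[a], pos[b]
        if sd[ia] == 0 or sd[ib] == 0:
            continue
        w = abs(float(np.corrcoef(arr[ia], arr[ib])[0, 1]))
        if w == 0:
            continue
        out.add_edge(a, b, weight=min(w, 1.0))
    return out


@dataclass
class FlowProblem:
    graph: nx.DiGraph        # arcs with 'cost' and 'capacity'; includes S, K
    sources: list[str]
    targets: list[str]
    gamma: float = 1.0


@dataclass
class FlowResult:
    flows: dict[tuple[str, str], float]
    subnetwork: nx.Graph          # undirected positive-flow gene subnetwork
    node_roles: dict[str, str]    # source | mediator | target
    objective: float
    total_flow: float
    hubs: set[str] = field(default_factory=set)


def build_flow_problem(
    weighted: nx.Graph,
    sources: Sequence[str],
    targets: Sequence[str],
    gamma: float = 1.0,
) -> FlowProblem:
    """Expand an undirected weighted network into the directed flow problem.

    Gene-gene edges become two antiparallel unit-capacity arcs with cost
    -log w; S->source and target->K arcs are free unit-capacity arcs.
    Sources that also appear among targets are removed from the sources
    (an overlap signals an upstream labeling error) with a warning.
    """
    sources = [s for s in dict.fromkeys(sources) if s in weighted]
    targets = [t for t in dict.fromkeys(targets) if t in weighted]
    overlap = set(sources) & set(targets)
    if overlap:
        warnings.warn(f"{len(overlap)} genes in both sources and targets; "
                      "removed from sources")
        sources = [s for s in sources if s not in overlap]
    if not sources or not targets:
        raise ValueError("need at least one source and one target present in network")

    g = nx.DiGraph()
    for a, b, data in weighted.edges(data=True):
        w = data["weight"]
        if not 0 < w <= 1:
            raise ValueError(f"edge weight {w} outside (0, 1] for ({a}, {b})")
        cost = -math.log(w)
        g.add_edge(a, b, cost=cost, capacity=1.0)
        g.add_edge(b, a, cost=cost, capacity=1.0)
    for s in sources:
        g.add_edge(SOURCE_NODE, s, cost=0.0, capacity=1.0)
    for t in targets:
        g.add_edge(t, SINK_NODE, cost=0.0, capacity=1.0)
    return FlowProblem(graph=g, sources=sources, targets=targets, gamma=gamma)


def solve_flow(problem: FlowProblem) -> FlowResult:
    """Solve the continuous min-cost / max-flow trade-off LP.

    Unreached targets (zero incoming flow) are reported via warning.
    """
    g = problem.graph
    arcs = list(g.edges())
    arc_idx = {e: i for i, e in enumerate(arcs)}
    n_arcs = len(arcs)
    nodes = [v for v in g.nodes() if v not in (SOURCE_NODE, SINK_NODE)]

    c = np.zeros(n_arcs)
    for (u, v), i in arc_idx.items():
        if u == SOURCE_NODE:
            c[i] = -problem.gamma
        else:
            c[i] = g[u][v]["cost"]
    # conservation at every gene node
    A_eq = np.zeros((len(nodes), n_arcs))
    for r, v in enumerate(nodes):
        for u in g.predecessors(v):
            A_eq[r, arc_idx[(u, v)]] = 1.0
        for w_ in g.successors(v):
            A_eq[r, arc_idx[(v, w_)]] = -1.0
    bounds = [(0.0, g[u][v]["capacity"]) for (u, v) in arcs]

    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(len(nodes)), bounds=bounds,
                  method="highs")
    if not res.success:
        raise RuntimeError(
            f"flow LP failed ({res.status}): {res.message}; "
            "an unbounded problem means gamma exceeds the cost floor"
        )
    flows = {e: float(res.x[i]) for e, i in arc_idx.items()}
    total = sum(f for (u, _), f in flows.items() if u == SOURCE_NODE)

    sub = nx.Graph()
    for (u, v), f in flows.items():
        if u in (SOURCE_NODE,) or v in (SINK_NODE,):
            continue
        if f > FLOW_TOL:
            w = math.exp(-g[u][v]["cost"])
            if sub.has_edge(u, v):
                sub[u][v]["flow"] += f
            else:
                sub.add_edge(u, v, flow=f, weight=w)
    roles = {}
    for v in sub.nodes():
        if v in problem.sources:
            roles[v] = "source"
        elif v in problem.targets:
            roles[v] = "target"
        else:
            roles[v] = "mediator"
    unreached = [t for t in problem.targets
                 if flows.get((t, SINK_NODE), 0.0) <= FLOW_TOL]
    if unreached:
        warnings.warn(f"targets receive no flow: {unreached[:10]}")
    return FlowResult(
        flows=flows,
        subnetwork=sub,
        node_roles=roles,
        objective=float(res.fun),
        total_flow=float(total),
    )


def select_gamma(
    weighted: nx.Graph,
    sources: Sequence[str],
    targets: Sequence[str],
    gamma_grid: Sequence[float],
    scorer: Callable[[FlowResult], float] | None = None,
    min_edge_weight: float = 0.6,
) -> tuple[float, FlowResult]:
    """Pick gamma over a grid; default scorer prefers the largest network
    whose minimum positive-flow edge weight exceeds ``min_edge_weight``.

    A literature-based scorer (e.g. co-citation) can be injected as
    ``scorer``: a callable mapping a FlowResult to a real score (higher
    is better); it then replaces the default rule entirely.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma grid is empty")
    results = []
    for gamma in gamma_grid:
        problem = build_flow_problem(weighted, sources, targets, gamma=gamma)
        results.append((gamma, solve_flow(problem)))
    if scorer is not None:
        best = max(results, key=lambda gr: scorer(gr[1]))
        return best
    admissible = []
    for gamma, res in results:
        weights = [d["weight"] for _, _, d in res.subnetwork.edges(data=True)]
        if weights and min(weights) > min_edge_weight:
            admissible.append((gamma, res))
    if admissible:
        return max(admissible, key=lambda gr: gr[1].subnetwork.number_of_edges())
    warnings.warn("no gamma satisfies the edge-weight floor; "
                  "returning the smallest-network gamma")
    return min(results, key=lambda gr: gr[1].subnetwork.number_of_edges())


def call_hubs(
    result: FlowResult | nx.Graph,
    min_degree: int = 4,
    top_fraction: float = 0.05,
) -> set[str]:
    """Hubs: degree strictly > ``min_degree`` in the selected subnetwork,
    capped to the ``top_fraction`` highest-degree nodes when that cap is
    smaller; boundary ties are all included."""
    sub = result.subnetwork if isinstance(result, FlowResult) else result
    if sub.number_of_nodes() == 0:
        raise ValueError("empty subnetwork")
    deg = dict(sub.degree())
    above = {v for v, d in deg.items() if d > min_degree}
    if not above:
        return set()
    cap = max(1, math.ceil(top_fraction * sub.number_of_nodes()))
    if len(above) <= cap:
        return above
    ranked = sorted(above, key=lambda v: -deg[v])
    cutoff_degree = deg[ranked[cap - 1]]
    return {v for v in above if deg[v] >= cutoff_degree}
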