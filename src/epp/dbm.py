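"""Density-based merging: statistical validation of cluster-graph edges.

Every edge of the cluster graph carries a saddle — its highest-density
point.  An edge is a real separation only if both modes it separates are
significantly denser than the saddle.  The pointwise variance of the KDE is
estimated by a second smoothing pass with the squared kernel (for a sqrt(2)
widening sequence that pass equals the previous density estimate, which is
why widening is cheap), and each mode-minus-saddle difference is tested
with a one-sided z test, Bonferroni-corrected over the current edge count.
Insignificant edges are removed highest-saddle-first, their faces merged
and parallel chains spliced, until every surviving edge is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .density import GRID, smooth_grid, squared_kernel_eigenvalues
from .modal import ClusterGraph, Edge

__all__ = ["DbmConfig", "DipTestResult", "variance_grid", "edge_saddle",
           "dip_significant", "merge_insignificant"]


@dataclass(frozen=True)
class DbmConfig:
    alpha: float = 0.05
    multiplicity_correction: str = "bonferroni"   # or "none"


@dataclass(frozen=True)
class DipTestResult:
    edge_id: int
    saddle_density: float
    mode_densities: tuple
    statistic: float
    significant: bool


def variance_grid(weights: np.ndarray, kernel_sd: float, n_events: int,
                  scale: float) -> np.ndarray:
    """Pointwise variance of the (integral-one) density estimate.

    density = scale * (K * w); independent events give
    Var(K * w) ~= (K^2 * w), hence Var(density) = scale^2 * (K^2 * w).
    """
    v = smooth_grid(weights, squared_kernel_eigenvalues(kernel_sd))
    return (scale * scale) * v


def edge_saddle(density: np.ndarray, edge_points: np.ndarray
                ) -> tuple[tuple, float]:
    """Highest-density point along an edge; ties break row-major."""
    d = density[edge_points[:, 0], edge_points[:, 1]]
    flat = edge_points[:, 0] * GRID + edge_points[:, 1]
    order = np.lexsort((flat, -d))
    k = order[0]
    return (int(edge_points[k, 0]), int(edge_points[k, 1])), float(d[k])


def dip_significant(mode_densities: tuple, mode_points: tuple,
                    saddle_density: float, saddle_point: tuple,
                    var: np.ndarray, alpha: float, n_edges: int,
                    correction: str = "bonferroni") -> tuple[bool, float]:
    """One-sided z test that *both* modes rise significantly above the
    saddle.  Returns (significant, min z statistic)."""
    a = alpha / max(n_edges, 1) if correction == "bonferroni" else alpha
    z_crit = stats.norm.isf(a)
    v_s = var[saddle_point]
    zs = []
    for md, mp in zip(mode_densities, mode_points):
        se = np.sqrt(var[mp] + v_s)
        if se <= 0:
            zs.append(np.inf if md > saddle_density else 0.0)
        else:
            zs.append((md - saddle_density) / se)
    stat = float(min(zs))
    return stat > z_crit, stat


def _splice_degree_two(graph: ClusterGraph) -> None:
    """Join pairs of edges meeting at a now-degree-2 interior vertex."""
    changed = True
    while changed:
        changed = False
        incidence = {}
        for e in graph.edges:
            for t in set(e.terminals):
                incidence.setdefault(t, []).append(e)
        for t, inc in incidence.items():
            info = graph.vertices.get(t, {})
            if info.get("border_terminal"):
                continue
            if len(inc) == 1 and inc[0].terminals == (t, t):
                # both ends at a free vertex: close into a loop
                e = inc[0]
                graph.edges[graph.edges.index(e)] = replace(
                    e, points=_merge_points(e.points,
                                            info.get("pixels")),
                    terminals=())
                graph.vertices.pop(t, None)
                changed = True
                break
            if len(inc) != 2 or inc[0] is inc[1]:
                continue
            e1, e2 = inc
            if e1.faces != e2.faces:
                continue
            other1 = [x for x in e1.terminals if x != t]
            other2 = [x for x in e2.terminals if x != t]
            terms = tuple(sorted(other1 + other2, key=str))
            merged = Edge(id=min(e1.id, e2.id), faces=e1.faces,
                          points=_merge_points(e1.points, e2.points,
                                               info.get("pixels")),
                          terminals=terms)
            graph.edges.remove(e1)
            graph.edges.remove(e2)
            graph.edges.append(merged)
            graph.vertices.pop(t, None)
            changed = True
            break


def _merge_points(*arrs) -> np.ndarray:
    parts = [np.asarray(a).reshape(-1, 2) for a in arrs if a is not None]
    return np.vstack(parts) if parts else np.empty((0, 2), dtype=int)


def merge_insignificant(graph: ClusterGraph, density: np.ndarray,
                        var: np.ndarray, config: DbmConfig | None = None
                        ) -> tuple[ClusterGraph, list]:
    """Prune the cluster graph to edges with significant dips.

    Edges are tested in descending saddle order; on the first insignificant
    edge, that edge is removed, its faces merged (the merged face keeps the
    higher mode), parallel edges spliced, and the scan restarts.  Returns
    the pruned graph and the final per-edge test results.
    """
    if config is None:
        config = DbmConfig()
    graph = ClusterGraph(faces=dict(graph.faces), edges=list(graph.edges),
                         vertices=dict(graph.vertices), labels=graph.labels)
    results: list = []
    while True:
        results = []
        edges = sorted(graph.edges,
                       key=lambda e: -edge_saddle(density, e.points)[1])
        n_edges = len(edges)
        if n_edges == 0:
            break
        removed = None
        for e in edges:
            spt, sd = edge_saddle(density, e.points)
            e.saddle = (spt, sd)
            fa, fb = graph.faces[e.faces[0]], graph.faces[e.faces[1]]
            sig, stat = dip_significant(
                (fa.mode_density, fb.mode_density),
                (fa.mode, fb.mode), sd, spt, var,
                config.alpha, n_edges, config.multiplicity_correction)
            results.append(DipTestResult(e.id, sd,
                                         (fa.mode_density, fb.mode_density),
                                         stat, sig))
            if not sig:
                removed = e
                break
        if removed is None:
            break
        _merge_faces(graph, removed)
    return graph, results


def _merge_faces(graph: ClusterGraph, edge) -> None:
    a, b = edge.faces
    fa, fb = graph.faces[a], graph.faces[b]
    keep, drop = (fa, fb) if fa.mode_density >= fb.mode_density else (fb, fa)
    merged = replace(keep, id=min(a, b),
                     weight=fa.weight + fb.weight,
                     members=fa.members | fb.members)
    graph.faces.pop(a)
    graph.faces.pop(b)
    graph.faces[merged.id] = merged
    new_edges = []
    for e in graph.edges:
        if e is edge:
            continue
        faces = tuple(sorted(merged.id if f in (a, b) else f
                             for f in e.faces))
        if faces[0] == faces[1]:
            continue        # became internal to the merged face
        new_edges.append(replace(e, faces=faces))
    graph.edges[:] = new_edges
    _splice_degree_two(graph)
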