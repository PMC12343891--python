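"""Boundary scoring, best-split selection and the recursive gating engine.

Misallocation at a split scales with the number of events close to the
boundary, so each candidate is scored by the estimated event count in a
strip +/- W wide along its curve (smaller is better).  In best-balance mode
the score is divided by 4 P (1 - P), P being the event fraction on one
side, which penalises unbalanced splits.  The engine recurses depth-first:
qualify dimensions, analyse every qualified pair (widening the kernel on
complexity signals), prune insignificant dips, enumerate and score
candidates, take the global best, partition the events by cluster side and
repeat on both children until no statistically supported split remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import STEP, density_grid, widen_kernel
from .dbm import DbmConfig, merge_insignificant, variance_grid
from .dual import CandidateBoundary, enumerate_candidates
from .errors import ConfigurationError, WidenKernel
from .io import EventMatrix
from .modal import (ClusterConfig, GridLabels, assign_events,
                    build_cluster_graph, cluster_grid, noise_floor,
                    resolve_boundary_labels)
from .qualification import QualificationConfig, qualify_and_pair

__all__ = ["RunConfig", "SplitCandidate", "GatingNode", "GatingTree",
           "score_boundary", "balance_adjust", "select_best_split",
           "analyze_pair", "epp_recurse"]


@dataclass(frozen=True)
class RunConfig:
    mode: str = "best_balance"            # or "best_separation"
    initial_kernel_sd: float = 0.01       # 0.025 recommended for mass data
    min_events_absolute: int = 0
    min_events_relative: float = 0.0
    min_population: int = 50
    rdp_tolerance: float = 0.01
    qualification: QualificationConfig = field(
        default_factory=QualificationConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    dbm: DbmConfig = field(default_factory=DbmConfig)

    def __post_init__(self):
        if self.mode not in ("best_balance", "best_separation"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class SplitCandidate:
    pair: tuple                    # (dim_i, dim_j) original column indices
    boundary: CandidateBoundary
    raw_score: float
    P: float                       # event fraction on the smaller-indexed side
    balance_factor: float
    adjusted_score: float
    labels: GridLabels
    kernel_sd: float
    pass_count: int
    boundary_points: np.ndarray    # grid points of the cut, for reporting
    side_a_clusters: frozenset = frozenset()   # original cluster ids, side a
    side_b_clusters: frozenset = frozenset()


def score_boundary(density: np.ndarray, n_events: int,
                   boundary_points: np.ndarray, kernel_sd: float) -> float:
    """Estimated number of events within +/- W of the boundary:
    n * sum over boundary grid points of density * (2 W * grid step).
    The absolute scaling is approximate; only the ordering is used."""
    if boundary_points.size == 0:
        return 0.0
    d = density[boundary_points[:, 0], boundary_points[:, 1]]
    return float(n_events * d.sum() * (2.0 * kernel_sd * STEP))


def balance_adjust(raw_score: float, P: float, mode: str) -> float:
    """best_separation keeps the raw score; best_balance divides by
    4 P (1 - P)."""
    if mode == "best_separation":
        return raw_score
    if not 0.0 < P < 1.0:
        raise ValueError("degenerate split: P must be in (0, 1)")
    return raw_score / (4.0 * P * (1.0 - P))


def select_best_split(candidates: list) -> SplitCandidate | None:
    """Minimum adjusted score; ties break on (pair, edge mask)."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c.adjusted_score, c.pair,
                                          c.boundary.edge_mask))


def analyze_pair(coords: np.ndarray, pair: tuple, config: RunConfig
                 ) -> list:
    """Full single-pair analysis: density -> modal clustering -> dip
    pruning -> candidate enumeration -> scoring.  Returns scored
    candidates; empty when the pair yields no valid separation."""
    n = coords.shape[0]
    grid = density_grid(coords, config.initial_kernel_sd)
    while True:
        try:
            thr = noise_floor(grid.density, grid.weights, grid.kernel_sd,
                              config.cluster)
            if not np.isfinite(thr):
                return []
            labels = cluster_grid(grid.density, thr, config.cluster)
            if labels.n_clusters < 2:
                return []
            graph = build_cluster_graph(labels, grid.density, grid.weights,
                                        config.cluster)
            var = variance_grid(grid.weights, grid.kernel_sd, n, grid.scale)
            graph, _ = merge_insignificant(graph, grid.density, var,
                                           config.dbm)
            if graph.n_faces < 2 or not graph.edges:
                return []
            raw_candidates = enumerate_candidates(graph)
            break
        except WidenKernel:
            try:
                grid = widen_kernel(grid, config.cluster.max_widening_passes)
            except RuntimeError:
                return []

    assignment = assign_events(coords, labels)
    counts = np.bincount(assignment, minlength=labels.n_clusters + 1)
    # DBM may have merged faces: map each original cluster to its surviving
    # face through the resolved grid (faces partition the original ids)
    face_of = _face_membership(graph, labels)
    out = []
    for cand in raw_candidates:
        pts = _cut_points(graph, cand.edge_mask)
        raw = score_boundary(grid.density, n, pts, grid.kernel_sd)
        side_a = frozenset(c for c, f in face_of.items()
                           if f in cand.faces_a)
        side_b = frozenset(face_of) - side_a
        n_a = int(counts[sorted(side_a)].sum())
        if min(cand.faces_a) > min(cand.faces_b):
            P = (n - n_a) / n  # P is the fraction on the smaller-indexed side
        else:
            P = n_a / n
        if not 0.0 < n_a / n < 1.0:
            continue
        bf = 4.0 * P * (1.0 - P)
        out.append(SplitCandidate(
            pair=pair, boundary=cand, raw_score=raw, P=P,
            balance_factor=bf,
            adjusted_score=balance_adjust(raw, P, config.mode),
            labels=labels, kernel_sd=grid.kernel_sd,
            pass_count=grid.pass_count, boundary_points=pts,
            side_a_clusters=side_a, side_b_clusters=side_b))
    return out


def _cut_points(graph, edge_mask: int) -> np.ndarray:
    parts = [e.points for i, e in enumerate(graph.edges)
             if edge_mask >> i & 1]
    if not parts:
        return np.empty((0, 2), dtype=int)
    pts = np.vstack(parts)
    return np.unique(pts, axis=0)


def _face_membership(graph, labels: GridLabels) -> dict:
    """original cluster id -> surviving face id after dip merging."""
    face_of = {}
    for f in graph.faces.values():
        for c in (f.members or {f.id}):
            face_of[c] = f.id
    for c in range(1, labels.n_clusters + 1):
        face_of.setdefault(c, min(graph.faces))
    return face_of


# --- recursion --------------------------------------------------------------

@dataclass
class GatingNode:
    node_id: int
    n_events: int
    dims: tuple | None = None          # split pair (column indices)
    dim_names: tuple | None = None
    score: float | None = None
    adjusted_score: float | None = None
    P: float | None = None
    kernel_sd: float | None = None
    pass_count: int | None = None
    polygon: list | None = None        # this node's own gate, parent's pair
    children: list | None = None
    leaf_id: int | None = None
    label: str | None = None


@dataclass
class GatingTree:
    root: GatingNode
    n_leaves: int
    event_rows: dict                   # leaf_id -> event row indices

    def leaves(self) -> list:
        out = []

        def walk(node):
            if node.children is None:
                out.append(node)
            else:
                for ch in node.children:
                    walk(ch)
        walk(self.root)
        return out

    def leaf_assignment(self, n_events: int) -> np.ndarray:
        leaf = np.zeros(n_events, dtype=int)
        for lid, rows in self.event_rows.items():
            leaf[rows] = lid
        return leaf


def epp_recurse(events: EventMatrix, config: RunConfig | None = None
                ) -> GatingTree:
    """Run the full recursive analysis and return the gating tree.

    Deterministic: identical input and configuration give an identical
    tree.  Leaves are numbered in depth-first discovery order with the
    lower-weight child explored first.
    """
    from .outputs import build_gate_polygons, heuristic_label

    if config is None:
        config = RunConfig()
    if events.phenotyping_indices.size < 2:
        raise ConfigurationError("need at least 2 phenotyping dimensions")
    root_n = events.n_events
    counter = {"node": 0, "leaf": 0}
    event_rows: dict = {}

    def make_node(n):
        counter["node"] += 1
        return GatingNode(node_id=counter["node"], n_events=n)

    def recurse(rows: np.ndarray, node: GatingNode) -> None:
        n = rows.size
        stop = n < config.min_population
        if config.min_events_absolute:
            stop = stop or n < config.min_events_absolute
        if config.min_events_relative:
            stop = stop or n < config.min_events_relative * root_n
        best = None
        if not stop:
            sub = events.values[rows]
            sub_em = EventMatrix(sub, events.dim_names,
                                 events.phenotyping_flags)
            _, pairs = qualify_and_pair(sub_em, config.qualification)
            candidates = []
            for pair in pairs:
                coords = sub[:, list(pair)]
                candidates.extend(analyze_pair(coords, pair, config))
            best = select_best_split(candidates)
        if best is None:
            counter["leaf"] += 1
            node.leaf_id = counter["leaf"]
            event_rows[node.leaf_id] = rows
            return
        pair = best.pair
        coords = events.values[rows][:, list(pair)]
        assignment = assign_events(coords, best.labels)
        in_a = np.isin(assignment, sorted(best.side_a_clusters))
        rows_a, rows_b = rows[in_a], rows[~in_a]
        if rows_a.size == 0 or rows_b.size == 0:
            counter["leaf"] += 1
            node.leaf_id = counter["leaf"]
            event_rows[node.leaf_id] = rows
            return
        node.dims = pair
        node.dim_names = (events.dim_names[pair[0]], events.dim_names[pair[1]])
        node.score = best.raw_score
        node.adjusted_score = best.adjusted_score
        node.P = best.P
        node.kernel_sd = best.kernel_sd
        node.pass_count = best.pass_count
        polys = build_gate_polygons(best, config.rdp_tolerance)
        # lower-weight child first (stable when equal)
        if rows_b.size < rows_a.size:
            sides = [(rows_b, polys[1]), (rows_a, polys[0])]
        else:
            sides = [(rows_a, polys[0]), (rows_b, polys[1])]
        node.children = []
        parent_vals = events.values[rows]
        for child_rows, poly in sides:
            child = make_node(child_rows.size)
            child.polygon = poly
            child.label = heuristic_label(events, parent_vals,
                                          events.values[child_rows])
            node.children.append(child)
            recurse(child_rows, child)

    root = make_node(root_n)
    recurse(np.arange(root_n), root)
    return GatingTree(root=root, n_leaves=counter["leaf"],
                      event_rows=event_rows)
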