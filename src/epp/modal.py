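"""Modal clustering of the density grid and cluster-graph construction.

Grid points are classified in descending density order: a point none of
whose 4-neighbours belongs to a cluster founds a new cluster (a mode); a
point whose 4-neighbours span two distinct clusters becomes a boundary
point; otherwise it joins its neighbour's cluster.  New clusters may only
be founded above a counting-noise floor, chosen so that a window of grid
points the size of the kernel spot (side 4W) holds at least sigma^2 events.
As each point is classified, seven of its eight surrounding points are
marked contiguous with the classified set — one diagonal, rotated by a
counter modulo 4, is skipped to keep the growth radially symmetric — and
below-floor points are then absorbed sweep by sweep through that marking.

The labelled grid is condensed into a planar cluster graph: faces are
clusters, edges are chains of boundary points separating exactly two
clusters, vertices are the meeting points of three or more clusters (chains
may also terminate on the grid border).  Too many clusters or edges, or a
partition whose graph violates the Euler relation, raises ``WidenKernel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .density import GRID
from .errors import WidenKernel

__all__ = ["ClusterConfig", "GridLabels", "Face", "Edge", "ClusterGraph",
           "noise_floor", "cluster_grid", "build_cluster_graph",
           "assign_events", "resolve_boundary_labels"]


@dataclass(frozen=True)
class ClusterConfig:
    sigma_noise: float = 3.0     # window must hold sigma^2 = 9 events
    max_clusters: int = 12
    max_edges: int = 32
    max_widening_passes: int = 8

    def __post_init__(self):
        if self.max_edges < self.max_clusters:
            raise ValueError("max_edges must be >= max_clusters")


@dataclass
class GridLabels:
    """label[i, j]: cluster id >= 1, or 0 for a boundary point."""
    label: np.ndarray
    modes: list                       # (i, j, density) per cluster, id order
    noise_floor: float

    @property
    def n_clusters(self) -> int:
        return len(self.modes)


def noise_floor(density: np.ndarray, weights: np.ndarray, kernel_sd: float,
                config: ClusterConfig) -> float:
    """Density below which a local maximum is treated as counting noise.

    Slides a window of L grid points — L being the number of grid cells in a
    square of side 4W (the kernel spot +/- 2W), at least 1 — along the
    points sorted ascending by density; the floor is the top density of the
    first window holding more than sigma^2 events.  +inf when no window
    qualifies (then no cluster can be founded).
    """
    L = max(1, round((4.0 * kernel_sd * (GRID - 1)) ** 2))
    flat_d = density.ravel()
    order = np.argsort(flat_d, kind="stable")
    w_sorted = weights.ravel()[order]
    need = config.sigma_noise ** 2
    L = min(L, order.size)
    csum = np.concatenate(([0.0], np.cumsum(w_sorted)))
    win = csum[L:] - csum[:-L]          # win[k]: window ending at k + L - 1
    hits = np.flatnonzero(win > need)
    if hits.size == 0:
        return np.inf
    return float(flat_d[order[hits[0] + L - 1]])


# --- numba scan -------------------------------------------------------------

_NEW, _BOUNDARY, _INHERIT, _DEFER = 0, 1, 2, 3
# diagonal skipped by the modulo-4 counter, cycling NE, SE, SW, NW
_DIAG = np.array([[-1, 1], [1, 1], [1, -1], [-1, -1]], dtype=np.int64)


@njit(cache=True)
def _classify(p, label, allow_new):
    n = GRID
    i, j = p // n, p % n
    first = -1
    second = -1
    has_labeled = False
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ii, jj = i + di, j + dj
        if ii < 0 or ii >= n or jj < 0 or jj >= n:
            continue
        l = label[ii * n + jj]
        if l >= 0:
            has_labeled = True
        if l > 0:
            if first < 0:
                first = l
            elif l != first:
                second = l
    if second > 0:
        return _BOUNDARY, 0
    if first > 0:
        return _INHERIT, first
    if has_labeled:
        # adjoins only boundary points: extend the boundary
        return _BOUNDARY, 0
    if allow_new:
        return _NEW, 0
    return _DEFER, 0


@njit(cache=True)
def _mark_contiguous(p, contig, counter):
    n = GRID
    i, j = p // n, p % n
    skip_di = _DIAG[counter % 4, 0]
    skip_dj = _DIAG[counter % 4, 1]
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            if di == skip_di and dj == skip_dj:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < n and 0 <= jj < n:
                contig[ii * n + jj] = 1


@njit(cache=True)
def _scan(order, dens, threshold, max_clusters):
    """Returns (label_flat, mode_points, n_clusters); n_clusters of
    max_clusters + 1 signals too many clusters."""
    nn = GRID * GRID
    label = np.full(nn, -1, dtype=np.int32)
    contig = np.zeros(nn, dtype=np.uint8)
    modes = np.full(max_clusters, -1, dtype=np.int64)
    n_clusters = 0
    counter = 0
    split_k = order.size
    for k in range(order.size):
        p = order[k]
        if dens[p] < threshold:
            split_k = k
            break
        action, lab = _classify(p, label, True)
        if action == _NEW:
            if n_clusters == max_clusters:
                return label, modes, max_clusters + 1
            n_clusters += 1
            label[p] = n_clusters
            modes[n_clusters - 1] = p
        elif action == _BOUNDARY:
            label[p] = 0
        else:
            label[p] = lab
        _mark_contiguous(p, contig, counter)
        counter += 1
    if n_clusters == 0:
        return label, modes, 0
    # absorb below-floor points, sweeping in density order over those marked
    # contiguous with the classified set
    m = order.size - split_k
    done = np.zeros(m, dtype=np.uint8)
    frontier = np.zeros(m, dtype=np.uint8)
    n_left = m
    while n_left > 0:
        # snapshot the frontier so absorption grows in equidistant layers
        for k in range(m):
            frontier[k] = 1 if (done[k] == 0
                                and contig[order[split_k + k]] == 1) else 0
        progressed = False
        for k in range(m):
            if frontier[k] == 0:
                continue
            p = order[split_k + k]
            action, lab = _classify(p, label, False)
            if action == _DEFER:
                continue
            label[p] = 0 if action == _BOUNDARY else lab
            _mark_contiguous(p, contig, counter)
            counter += 1
            done[k] = 1
            n_left -= 1
            progressed = True
        if not progressed:
            # unstick: join the densest stuck point to its nearest labelled
            # 8-neighbour (lowest id for determinism)
            forced = False
            for k in range(m):
                if done[k]:
                    continue
                p = order[split_k + k]
                i, j = p // GRID, p % GRID
                best = -1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < GRID and 0 <= jj < GRID:
                            l = label[ii * GRID + jj]
                            if l > 0 and (best < 0 or l < best):
                                best = l
                if best > 0:
                    label[p] = best
                    _mark_contiguous(p, contig, counter)
                    counter += 1
                    done[k] = 1
                    n_left -= 1
                    forced = True
                    break
            if not forced:
                break
    return label, modes, n_clusters


def cluster_grid(density: np.ndarray, threshold: float,
                 config: ClusterConfig) -> GridLabels:
    """Partition the grid into modal clusters above the noise floor.

    Deterministic: the scan order is density descending with row-major
    tie-break.  Raises ``WidenKernel`` when more than ``max_clusters``
    clusters are founded.
    """
    flat = density.ravel()
    order = np.argsort(-flat, kind="stable")
    label, mode_pts, n_clusters = _scan(order, flat, threshold,
                                        config.max_clusters)
    if n_clusters > config.max_clusters:
        raise WidenKernel(f"more than {config.max_clusters} clusters")
    modes = [(int(p // GRID), int(p % GRID), float(flat[p]))
             for p in mode_pts[:n_clusters]]
    return GridLabels(label=label.reshape(GRID, GRID), modes=modes,
                      noise_floor=float(threshold))


# --- graph construction -----------------------------------------------------

@dataclass
class Face:
    id: int
    mode: tuple                 # (i, j)
    mode_density: float
    weight: float               # event mass in the face
    members: frozenset = frozenset()   # original cluster ids merged in


@dataclass
class Edge:
    id: int
    faces: tuple                # (a, b), a < b
    points: np.ndarray          # (k, 2) grid indices of the boundary chain
    terminals: tuple            # 0-2 vertex keys; () for a closed loop
    saddle: tuple | None = None  # ((i, j), density) filled by the dip test


@dataclass
class ClusterGraph:
    faces: dict
    edges: list
    vertices: dict = field(default_factory=dict)  # key -> {"on_border": bool}
    labels: GridLabels | None = None

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def adjacency(self) -> dict:
        adj = {f: set() for f in self.faces}
        for e in self.edges:
            a, b = e.faces
            adj[a].add(b)
            adj[b].add(a)
        return adj


_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_S8 = np.ones((3, 3), dtype=int)


def _neighbor_label_sets(label: np.ndarray, pts: np.ndarray) -> list:
    padded = np.full((GRID + 2, GRID + 2), -1, dtype=label.dtype)
    padded[1:-1, 1:-1] = label
    sets = []
    for i, j in pts:
        s = set()
        for di, dj in _EIGHT:
            l = padded[i + 1 + di, j + 1 + dj]
            if l > 0:
                s.add(int(l))
        sets.append(s)
    return sets


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self) -> int:
        return len({self.find(x) for x in self.parent})


def _check_euler(graph: ClusterGraph) -> bool:
    """Generalised Euler relation V - E + F = 1 + C for the planar
    subdivision, counting the exterior face, border arcs between border
    terminals, and a phantom vertex per closed curve."""
    uf = _UnionFind()
    V = E = 0
    border_terms = []
    for key, info in graph.vertices.items():
        uf.add(("v", key))
        V += 1
    for e in graph.edges:
        E += 1
        terms = e.terminals
        if len(terms) == 0:
            uf.add(("loop", e.id))
            V += 1
            continue
        for t in terms:
            uf.add(("v", t))
        if len(terms) == 2:
            uf.union(("v", terms[0]), ("v", terms[1]))
    for key, info in graph.vertices.items():
        if info.get("border_terminal") or info.get("on_border"):
            border_terms.append(key)
    if border_terms:
        E += len(border_terms)      # border arcs
        for t in border_terms[1:]:
            uf.union(("v", border_terms[0]), ("v", t))
    else:
        uf.add(("border",))
        V += 1
        E += 1
    F = graph.n_faces + 1
    C = uf.n_components()
    return V - E + F == 1 + C


def build_cluster_graph(labels: GridLabels, density: np.ndarray,
                        weights: np.ndarray,
                        config: ClusterConfig | None = None) -> ClusterGraph:
    """Group boundary points into edges and assemble the planar graph.

    Raises ``WidenKernel`` for graphs with more than ``max_edges`` edges,
    edges touching more than two vertices, or an Euler-relation violation
    (the rare pathological partitions).
    """
    if config is None:
        config = ClusterConfig()
    lab = labels.label
    k = labels.n_clusters
    if k < 2:
        raise ValueError("cluster graph requires >= 2 clusters")

    resolved = resolve_boundary_labels(lab)
    face_weights = ndimage.sum_labels(weights, resolved,
                                      index=np.arange(1, k + 1))
    faces = {c + 1: Face(id=c + 1, mode=(labels.modes[c][0],
                                         labels.modes[c][1]),
                         mode_density=labels.modes[c][2],
                         weight=float(face_weights[c]),
                         members=frozenset({c + 1}))
             for c in range(k)}

    bpts = np.argwhere(lab == 0)
    nsets = _neighbor_label_sets(lab, bpts)

    vertex_mask = np.zeros_like(lab, dtype=bool)
    pair_of = {}
    for (pt, s) in zip(bpts, nsets):
        if len(s) >= 3:
            vertex_mask[pt[0], pt[1]] = True
        elif len(s) == 2:
            pair_of[(int(pt[0]), int(pt[1]))] = tuple(sorted(s))

    vcomp, n_v = ndimage.label(vertex_mask, structure=_S8)
    vertices = {}
    for vid in range(1, n_v + 1):
        pts = np.argwhere(vcomp == vid)
        on_border = bool(((pts == 0) | (pts == GRID - 1)).any())
        vertices[vid] = {"on_border": on_border,
                         "pixels": pts}

    vpad = np.zeros((GRID + 2, GRID + 2), dtype=vcomp.dtype)
    vpad[1:-1, 1:-1] = vcomp

    edges = []
    eid = 0
    pairs = sorted(set(pair_of.values()))
    border_vertex_count = 0
    for pair in pairs:
        mask = np.zeros_like(lab, dtype=bool)
        for (pt, p) in pair_of.items():
            if p == pair:
                mask[pt[0], pt[1]] = True
        comp, n_c = ndimage.label(mask, structure=_S8)
        for cid in range(1, n_c + 1):
            pts = np.argwhere(comp == cid)
            # adjacent interior vertices
            terms = set()
            for i, j in pts:
                win = vpad[i:i + 3, j:j + 3]
                for v in np.unique(win):
                    if v > 0:
                        terms.add(int(v))
            # border terminations: connected runs of this chain's border pixels
            on_border = (pts == 0) | (pts == GRID - 1)
            if on_border.any():
                bmask = np.zeros_like(mask)
                for (i, j), ob in zip(pts, on_border):
                    if ob.any():
                        bmask[i, j] = True
                runs, n_runs = ndimage.label(bmask, structure=_S8)
                for r in range(1, n_runs + 1):
                    border_vertex_count += 1
                    key = ("b", eid, r)
                    vertices[key] = {"on_border": True,
                                     "border_terminal": True}
                    terms.add(key)
            if len(terms) > 2:
                raise WidenKernel("edge touches more than two vertices")
            terms = tuple(sorted(terms, key=str))
            if len(terms) == 1:
                terms = (terms[0], terms[0])
            edges.append(Edge(id=eid, faces=pair, points=pts,
                              terminals=terms))
            eid += 1

    if len(edges) > config.max_edges:
        raise WidenKernel(f"more than {config.max_edges} edges")

    graph = ClusterGraph(faces=faces, edges=edges, vertices=vertices,
                         labels=labels)
    if not _check_euler(graph):
        raise WidenKernel("Euler relation violated (pathological partition)")
    return graph


def resolve_boundary_labels(label: np.ndarray) -> np.ndarray:
    """Replace boundary points (0) by the lowest-numbered adjacent cluster,
    iterating for boundary bands wider than one point."""
    resolved = label.copy()
    for _ in range(GRID):
        bound = resolved == 0
        if not bound.any():
            break
        padded = np.full((GRID + 2, GRID + 2), np.iinfo(np.int32).max,
                         dtype=np.int64)
        inner = resolved.astype(np.int64)
        inner[inner == 0] = np.iinfo(np.int32).max
        padded[1:-1, 1:-1] = inner
        best = np.full_like(inner, np.iinfo(np.int32).max)
        for di, dj in _EIGHT:
            np.minimum(best, padded[1 + di:GRID + 1 + di,
                                    1 + dj:GRID + 1 + dj], out=best)
        take = bound & (best < np.iinfo(np.int32).max)
        resolved[take] = best[take]
    return resolved


def assign_events(coords: np.ndarray, labels: GridLabels) -> np.ndarray:
    """Cluster id per event: the label of the nearest grid node, boundary
    nodes resolved to the lowest-numbered adjacent cluster."""
    resolved = resolve_boundary_labels(labels.label)
    i = np.clip(np.rint(coords[:, 0] * (GRID - 1)).astype(np.int64),
                0, GRID - 1)
    j = np.clip(np.rint(coords[:, 1] * (GRID - 1)).astype(np.int64),
                0, GRID - 1)
    return resolved[i, j]
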