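"""Candidate-separation enumeration via dual-graph simplification.

A candidate separation is a subset of cluster-graph edges forming a single
continuous curve (the grid border closes curves that terminate on it) and
dividing the faces into exactly two contiguous groups.  The dual graph —
one node per face, one dual edge per cluster edge — is simplified by
repeatedly removing one dual edge and merging its endpoint nodes; dual
edges that then join the same node pair merge by OR-ing their bitmasks
(splicing the corresponding cluster edges).  Every simplification path
ending in a two-node, one-edge dual yields a candidate.

Nodes and edges are bit vectors (32 original edges at most), and a
depth-first stack search removes edge units in increasing order of their
lowest original-edge bit, which visits each reachable simplified dual
exactly once instead of O(n!) times.  Emitted candidates are re-verified
geometrically; defensive deduplication keeps the output a set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .modal import ClusterGraph

__all__ = ["DualGraph", "CandidateBoundary", "dualize", "simplify_step",
           "enumerate_candidates", "boundary_is_continuous"]

_MAX_POPS = 1_000_000


@dataclass(frozen=True)
class DualGraph:
    """Immutable dual-graph snapshot on a simplification path.

    nodes: per merged node, bitmask over original faces.
    edges: (node_index_a, node_index_b, bitmask over original cluster edges).
    removed_min_bit: lowest original bit of the last removed edge unit
    (removal units are taken in increasing low-bit order).
    """

    nodes: tuple
    edges: tuple
    removed_min_bit: int = -1


def _low_bit(mask: int) -> int:
    return (mask & -mask).bit_length() - 1


def dualize(graph: ClusterGraph) -> DualGraph:
    """One dual node per face (bit = rank of sorted face id), one singleton
    dual edge per cluster edge (bit = position in graph.edges)."""
    face_ids = sorted(graph.faces)
    bit_of = {f: i for i, f in enumerate(face_ids)}
    nodes = tuple(1 << i for i in range(len(face_ids)))
    edges = tuple((bit_of[e.faces[0]], bit_of[e.faces[1]], 1 << i)
                  for i, e in enumerate(graph.edges))
    return DualGraph(nodes=nodes, edges=edges)


def simplify_step(dual: DualGraph, edge_index: int) -> DualGraph:
    """Remove one dual edge: merge its endpoints, OR together dual edges now
    joining the same node pair, drop edges collapsing to self-loops."""
    ia, ib, removed_mask = dual.edges[edge_index]
    if ia == ib:
        raise ValueError("cannot remove a self-loop")
    keep, gone = min(ia, ib), max(ia, ib)
    nodes = list(dual.nodes)
    nodes[keep] |= nodes[gone]
    del nodes[gone]

    def remap(i: int) -> int:
        if i == gone:
            return keep
        return i - 1 if i > gone else i

    merged: dict = {}
    for k, (a, b, m) in enumerate(dual.edges):
        if k == edge_index:
            continue
        a, b = remap(a), remap(b)
        if a == b:
            continue                      # self-loop: spliced closed curve
        key = (min(a, b), max(a, b))
        merged[key] = merged.get(key, 0) | m
    edges = tuple((a, b, m) for (a, b), m in sorted(merged.items()))
    return DualGraph(nodes=tuple(nodes), edges=edges,
                     removed_min_bit=_low_bit(removed_mask))


@dataclass(frozen=True)
class CandidateBoundary:
    edge_mask: int
    faces_a: frozenset
    faces_b: frozenset


def _faces_from_mask(mask: int, face_ids: list) -> frozenset:
    return frozenset(f for i, f in enumerate(face_ids) if mask >> i & 1)


def _connected(faces: frozenset, adjacency: dict) -> bool:
    if not faces:
        return False
    seen = {next(iter(faces))}
    stack = list(seen)
    while stack:
        f = stack.pop()
        for g in adjacency[f]:
            if g in faces and g not in seen:
                seen.add(g)
                stack.append(g)
    return seen == faces


def boundary_is_continuous(graph: ClusterGraph, edge_mask: int) -> bool:
    """True when the masked edges form one continuous curve: every interior
    vertex they touch has exactly two incident cut edges (vertices on the
    grid border may terminate the curve) and the cut edges are connected,
    counting the border as a single closing node."""
    cut = [e for i, e in enumerate(graph.edges) if edge_mask >> i & 1]
    if not cut:
        return False

    def node_of(term):
        info = graph.vertices.get(term, {})
        if info.get("border_terminal"):
            return "BORDER"
        return term

    degree: dict = {}
    for e in cut:
        for t in e.terminals:
            n = node_of(t)
            degree[n] = degree.get(n, 0) + 1
    for n, d in degree.items():
        if n == "BORDER":
            continue
        if graph.vertices.get(n, {}).get("on_border"):
            continue
        if d != 2:
            return False
    # connectivity over shared terminals / border
    idx = {id(e): i for i, e in enumerate(cut)}
    parent = list(range(len(cut)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_node: dict = {}
    for e in cut:
        for t in e.terminals:
            by_node.setdefault(node_of(t), []).append(idx[id(e)])
    for members in by_node.values():
        for m in members[1:]:
            ra, rb = find(members[0]), find(m)
            if ra != rb:
                parent[ra] = rb
    return len({find(i) for i in range(len(cut))}) == 1


def enumerate_candidates(graph: ClusterGraph) -> list:
    """All candidate separations of a DBM-pruned cluster graph.

    Depth-first search over ordered simplification paths of the dual;
    every one-edge simplified dual yields a candidate, deduplicated by
    edge mask and verified: both face groups contiguous, the cut equal to
    the full set of edges between the groups, and the curve continuous.
    Candidates are returned sorted by edge mask.
    """
    dual = dualize(graph)
    face_ids = sorted(graph.faces)
    adjacency = graph.adjacency()
    seen_masks = set()
    out = []
    stack = [dual]
    pops = 0
    while stack:
        pops += 1
        if pops > _MAX_POPS:
            raise RuntimeError("dual-graph search exploded")
        g = stack.pop()
        if len(g.edges) == 1:
            a, b, mask = g.edges[0]
            if mask in seen_masks:
                continue
            seen_masks.add(mask)
            fa = _faces_from_mask(g.nodes[a], face_ids)
            fb = _faces_from_mask(g.nodes[b], face_ids)
            if not (_connected(fa, adjacency) and _connected(fb, adjacency)):
                continue
            between = 0
            for i, e in enumerate(graph.edges):
                if (e.faces[0] in fa) != (e.faces[1] in fa):
                    between |= 1 << i
            if between != mask:
                continue
            if not boundary_is_continuous(graph, mask):
                continue
            out.append(CandidateBoundary(edge_mask=mask,
                                         faces_a=fa, faces_b=fb))
            continue
        for k, (_, _, m) in enumerate(g.edges):
            if _low_bit(m) > g.removed_min_bit:
                stack.append(simplify_step(g, k))
    return sorted(out, key=lambda c: c.edge_mask)
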