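"""Serialisation and comparison utilities.

The gating tree is written as JSON (this package's own documented schema,
see README) with per-boundary scores and Ramer-Douglas-Peucker-simplified
gate polygons; per-event output is a CSV with the leaf (cluster) identifier
and the Mahalanobis distance from the leaf centre.  Partition-comparison
helpers build shared-event match tables and the Jaccard and Central
Similarity coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from skimage import measure

from .density import GRID
from .io import EventMatrix
from .modal import resolve_boundary_labels
from .split import GatingNode, GatingTree, SplitCandidate

__all__ = ["simplify_polygon", "build_gate_polygons", "heuristic_label",
           "PhenotypeAssignment", "phenotype_assignment", "write_outputs",
           "tree_to_dict", "tree_from_dict", "match_table", "jaccard",
           "central_similarity", "mahalanobis_distances"]


def simplify_polygon(points, tolerance: float = 0.01) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification of a polyline/polygon.

    Every removed vertex lies within ``tolerance`` (fraction of full scale)
    of the simplified polyline; endpoints are preserved.  Fewer than three
    distinct vertices are returned unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if len(np.unique(pts, axis=0)) < 3:
        return pts
    line = LineString(pts)
    simp = line.simplify(tolerance, preserve_topology=False)
    return np.asarray(simp.coords)


def build_gate_polygons(cand: SplitCandidate, tolerance: float = 0.01
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Gate polygon per child: the outline of each side's grid region
    (closed along the grid border where needed), in unit coordinates,
    RDP-simplified."""
    resolved = resolve_boundary_labels(cand.labels.label)
    polys = []
    for side in (cand.side_a_clusters, cand.side_b_clusters):
        mask = np.isin(resolved, sorted(side)).astype(float)
        padded = np.zeros((GRID + 2, GRID + 2))
        padded[1:-1, 1:-1] = mask
        contours = measure.find_contours(padded, 0.5)
        contour = max(contours, key=len)
        coords = np.clip((contour - 1.0) / (GRID - 1), 0.0, 1.0)
        polys.append(simplify_polygon(coords, tolerance))
    return polys[0], polys[1]


def heuristic_label(events: EventMatrix, parent_values: np.ndarray,
                    child_values: np.ndarray) -> str:
    """Crude +/- calls per phenotyping dimension: child median above the
    parent median reads '+', below reads '-'.  Non-normative, for display
    only."""
    parts = []
    for d in events.phenotyping_indices:
        name = events.dim_names[d]
        sign = "+" if (np.median(child_values[:, d])
                       >= np.median(parent_values[:, d])) else "-"
        parts.append(f"{name}{sign}")
    return "".join(parts)


# --- per-event output -------------------------------------------------------

@dataclass
class PhenotypeAssignment:
    leaf_id: np.ndarray          # int per event
    mahalanobis: np.ndarray      # >= 0 per event


def mahalanobis_distances(values: np.ndarray) -> np.ndarray:
    """Mahalanobis distance of each row from the sample mean; singular
    covariances are ridge-regularised by 1e-6 x trace."""
    mu = values.mean(axis=0)
    centred = values - mu
    if values.shape[0] < 2:
        return np.zeros(values.shape[0])
    cov = np.cov(centred, rowvar=False)
    cov = np.atleast_2d(cov)
    d = cov.shape[0]
    try:
        inv = np.linalg.inv(cov)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = cov + np.eye(d) * 1e-6 * max(np.trace(cov), 1e-300)
        inv = np.linalg.inv(cov)
    return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", centred, inv,
                                        centred), 0.0))


def phenotype_assignment(events: EventMatrix, tree: GatingTree
                         ) -> PhenotypeAssignment:
    dims = events.phenotyping_indices
    leaf = tree.leaf_assignment(events.n_events)
    maha = np.zeros(events.n_events)
    for lid, rows in tree.event_rows.items():
        vals = events.values[rows][:, dims]
        maha[rows] = mahalanobis_distances(vals)
    return PhenotypeAssignment(leaf_id=leaf, mahalanobis=maha)


# --- JSON tree --------------------------------------------------------------

def _node_dict(node: GatingNode) -> dict:
    d = {"node_id": node.node_id, "n_events": node.n_events}
    if node.polygon is not None:
        d["gate_polygon"] = [[round(float(x), 10), round(float(y), 10)]
                             for x, y in node.polygon]
    if node.label is not None:
        d["label"] = node.label
    if node.children is None:
        d["leaf_id"] = node.leaf_id
    else:
        d.update({
            "split_dims": list(node.dims),
            "split_dim_names": list(node.dim_names),
            "boundary_score": round(float(node.score), 10),
            "adjusted_score": round(float(node.adjusted_score), 10),
            "P": round(float(node.P), 10),
            "kernel_sd": round(float(node.kernel_sd), 12),
            "widening_passes": node.pass_count,
            "children": [_node_dict(ch) for ch in node.children],
        })
    return d


def tree_to_dict(tree: GatingTree) -> dict:
    return {"n_leaves": tree.n_leaves, "root": _node_dict(tree.root)}


def _node_from_dict(d: dict) -> GatingNode:
    node = GatingNode(node_id=d["node_id"], n_events=d["n_events"])
    if "gate_polygon" in d:
        node.polygon = [tuple(p) for p in d["gate_polygon"]]
    node.label = d.get("label")
    if "children" in d:
        node.dims = tuple(d["split_dims"])
        node.dim_names = tuple(d["split_dim_names"])
        node.score = d["boundary_score"]
        node.adjusted_score = d["adjusted_score"]
        node.P = d["P"]
        node.kernel_sd = d["kernel_sd"]
        node.pass_count = d["widening_passes"]
        node.children = [_node_from_dict(c) for c in d["children"]]
    else:
        node.leaf_id = d["leaf_id"]
    return node


def tree_from_dict(d: dict) -> GatingTree:
    root = _node_from_dict(d["root"])
    return GatingTree(root=root, n_leaves=d["n_leaves"], event_rows={})


def write_outputs(tree: GatingTree, assignment: PhenotypeAssignment,
                  out_dir) -> tuple[Path, Path]:
    """Write gating_tree.json and events.csv; both byte-stable across
    reruns on identical input."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree_path = out / "gating_tree.json"
    with open(tree_path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1, sort_keys=True)
        fh.write("\n")
    csv_path = out / "events.csv"
    frame = pd.DataFrame({
        "event_index": np.arange(assignment.leaf_id.size),
        "cluster_id": assignment.leaf_id,
        "mahalanobis": np.round(assignment.mahalanobis, 9),
    })
    frame.to_csv(csv_path, index=False)
    return tree_path, csv_path


# --- comparison -------------------------------------------------------------

def match_table(labels_a, labels_b) -> pd.DataFrame:
    """Shared-event counts per (population a, population b) pair."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions cover different event universes")
    return pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))


def jaccard(a, b) -> float:
    """|A intersect B| / |A union B| over event-index sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def central_similarity(a, b, events: EventMatrix,
                       central_fraction: float = 0.8) -> float:
    """Jaccard restricted to the central fraction of A union B by
    Mahalanobis distance from the mean of A union B (over the phenotyping
    dimensions)."""
    a, b = set(a), set(b)
    union = sorted(a | b)
    if not union:
        raise ValueError("undefined for two empty sets")
    if central_fraction >= 1.0:
        return jaccard(a, b)
    dims = events.phenotyping_indices
    vals = events.values[np.asarray(union)][:, dims]
    dist = mahalanobis_distances(vals)
    cutoff = np.quantile(dist, central_fraction)
    core = {u for u, d in zip(union, dist) if d <= cutoff}
    return jaccard(a & core, b & core)
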