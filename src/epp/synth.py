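"""Seeded synthetic event matrices and planar-partition fixtures.

The mixture generator emulates the data model the gating engine assumes:
unit-scaled events whose positive populations are near-normal in each
dimension and whose mass-cytometry negatives are zero-inflated exponential.
Draws falling outside the unit cube are resampled rather than clipped —
clipping would pile mass on the cube walls and create spurious modes that
the clustering would legitimately detect, confounding null tests.

The planar-partition generator builds random Voronoi tessellations of the
density grid and converts them into cluster graphs; these exercise the
boundary-enumeration stage against brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import GRID
from .errors import ConfigurationError
from .io import EventMatrix
from .modal import ClusterConfig, ClusterGraph, GridLabels, build_cluster_graph

__all__ = ["MixtureSpec", "generate_mixture", "generate_planar_partition",
           "two_component_spec", "five_component_spec"]


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture on the unit cube with ground-truth labels.

    ``negative_dims`` lists, per component, dimensions drawn as
    zero-inflated exponentials (mass-cytometry negatives) instead of
    normals; the exponential scale is that dimension's mean entry.
    """

    dimensions: int
    components: tuple     # ((weight, mean tuple, cov matrix tuple), ...)
    n_events: int
    seed: int = 0
    mass_mode: bool = False
    negative_dims: tuple = ()          # per component, tuple of dim indices
    zero_inflation: float = 0.4

    def __post_init__(self):
        w = np.array([c[0] for c in self.components], dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("component weights must sum to 1")
        for _, mean, cov in self.components:
            m = np.asarray(mean, dtype=float)
            if m.size != self.dimensions:
                raise ConfigurationError("mean dimension mismatch")
            if (m <= 0).any() or (m >= 1).any():
                raise ConfigurationError("means must lie in the open cube")
            c = np.asarray(cov, dtype=float)
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ConfigurationError("covariances must be positive definite")


def generate_mixture(spec: MixtureSpec) -> tuple[EventMatrix, np.ndarray]:
    """Draw a seeded event matrix; returns (events, true component label)."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[0] for c in spec.components])
    counts = rng.multinomial(spec.n_events, weights)
    blocks, labels = [], []
    total_resampled = 0
    for k, ((_, mean, cov), n_k) in enumerate(zip(spec.components, counts)):
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        neg = (spec.negative_dims[k] if spec.mass_mode
               and k < len(spec.negative_dims) else ())
        draws = rng.multivariate_normal(mean, cov, size=n_k,
                                        method="cholesky")
        for d in neg:
            zero = rng.random(n_k) < spec.zero_inflation
            vals = rng.exponential(scale=mean[d], size=n_k)
            vals[zero] = 0.0
            draws[:, d] = vals
        bad = ((draws < 0) | (draws > 1)).any(axis=1)
        tries = 0
        while bad.any() and tries < 100:
            n_bad = int(bad.sum())
            total_resampled += n_bad
            redraw = rng.multivariate_normal(mean, cov, size=n_bad,
                                             method="cholesky")
            for d in neg:
                zero = rng.random(n_bad) < spec.zero_inflation
                vals = rng.exponential(scale=mean[d], size=n_bad)
                vals[zero] = 0.0
                redraw[:, d] = vals
            draws[bad] = redraw
            bad = ((draws < 0) | (draws > 1)).any(axis=1)
            tries += 1
        blocks.append(draws)
        labels.append(np.full(n_k, k, dtype=int))
    values = np.vstack(blocks)
    truth = np.concatenate(labels)
    # deterministic shuffle so component order carries no information
    perm = rng.permutation(spec.n_events)
    values, truth = values[perm], truth[perm]
    if total_resampled > 0.1 * spec.n_events:
        warnings.warn("more than 10% of draws resampled; component too "
                      "close to the cube wall", stacklevel=2)
    em = EventMatrix(values=values,
                     dim_names=[f"M{i+1}" for i in range(spec.dimensions)],
                     phenotyping_flags=np.ones(spec.dimensions, dtype=bool),
                     provenance={"synthetic": True, "seed": spec.seed})
    return em, truth


def two_component_spec(n_events: int = 50_000, seed: int = 0,
                       sd: float = 0.03) -> MixtureSpec:
    """Two well-separated components in 2-D (>= 8 kernel widths apart)."""
    cov = (np.eye(2) * sd * sd).tolist()
    return MixtureSpec(
        dimensions=2,
        components=((0.5, (0.3, 0.35), cov), (0.5, (0.7, 0.65), cov)),
        n_events=n_events, seed=seed)


def five_component_spec(n_events: int = 50_000, seed: int = 0,
                        sd: float = 0.03) -> MixtureSpec:
    """Five components in 3-D, pairwise >= 8 kernel widths apart in the
    first 2-D projection."""
    cov = (np.eye(3) * sd * sd).tolist()
    means = ((0.2, 0.2, 0.3), (0.5, 0.25, 0.7), (0.8, 0.3, 0.3),
             (0.35, 0.7, 0.5), (0.7, 0.75, 0.75))
    return MixtureSpec(
        dimensions=3,
        components=tuple((0.2, m, cov) for m in means),
        n_events=n_events, seed=seed)


def generate_planar_partition(n_faces: int, seed: int = 0
                              ) -> tuple[GridLabels, ClusterGraph]:
    """Random Voronoi partition of the grid as a cluster-graph fixture."""
    if not 2 <= n_faces <= 6:
        raise ConfigurationError("n_faces must be between 2 and 6")
    rng = np.random.default_rng(seed)
    cfg = ClusterConfig()
    for _ in range(50):
        sites = rng.uniform(0.1, 0.9, size=(n_faces, 2))
        xs = np.arange(GRID) / (GRID - 1)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        d2 = ((gx[..., None] - sites[:, 0]) ** 2
              + (gy[..., None] - sites[:, 1]) ** 2)
        nearest = d2.argmin(axis=2) + 1
        label = nearest.copy()
        # one-pixel boundary on the higher-label side of each divide
        diff = np.zeros_like(label, dtype=bool)
        diff[1:, :] |= (nearest[1:, :] != nearest[:-1, :]) \
            & (nearest[1:, :] > nearest[:-1, :])
        diff[:-1, :] |= (nearest[:-1, :] != nearest[1:, :]) \
            & (nearest[:-1, :] > nearest[1:, :])
        diff[:, 1:] |= (nearest[:, 1:] != nearest[:, :-1]) \
            & (nearest[:, 1:] > nearest[:, :-1])
        diff[:, :-1] |= (nearest[:, :-1] != nearest[:, 1:]) \
            & (nearest[:, :-1] > nearest[:, 1:])
        label[diff] = 0
        if len(np.unique(label[label > 0])) != n_faces:
            continue
        modes = []
        ok = True
        for f in range(1, n_faces + 1):
            i = np.clip(int(round(sites[f - 1, 0] * (GRID - 1))), 0, GRID - 1)
            j = np.clip(int(round(sites[f - 1, 1] * (GRID - 1))), 0, GRID - 1)
            if label[i, j] != f:
                pts = np.argwhere(label == f)
                if pts.size == 0:
                    ok = False
                    break
                i, j = pts[len(pts) // 2]
            modes.append((int(i), int(j), 1.0))
        if not ok:
            continue
        labels = GridLabels(label=label, modes=modes, noise_floor=0.0)
        weights = np.ones((GRID, GRID))
        density = np.ones((GRID, GRID))
        try:
            graph = build_cluster_graph(labels, density, weights, cfg)
        except Exception:
            continue
        return labels, graph
    raise RuntimeError("could not draw a non-degenerate partition")
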