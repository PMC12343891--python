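"""2-D kernel density estimation on a fixed 257 x 257 grid via DCT.

Each event deposits unit mass onto the four grid nodes of its enclosing
cell by bilinear (linear-binning) weights; the weight array is then smoothed
with a discretely sampled Gaussian kernel under reflective (even) boundary
conditions.  Whole-sample symmetric reflection is diagonalised by the
type-I DCT, so the smooth is an exact circular convolution of the
symmetric extension — identical to direct convolution with reflected
padding, but O(grid log grid) and independent of the event count.

When downstream stages find the partition too complex the kernel standard
deviation is widened by sqrt(2) and the estimate recomputed from the same
weights; the previous pass's density is retained because the squared-kernel
smooth needed by the dip test at sd W equals the plain smooth at W/sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

__all__ = ["GRID", "STEP", "DensityGrid", "compute_weights", "kde_dct",
           "widen_kernel", "density_grid", "kernel_eigenvalues",
           "squared_kernel_eigenvalues", "smooth_grid", "grid_integral"]

GRID = 257            # grid nodes per axis; node i sits at i/256
STEP = 1.0 / (GRID - 1)
MIN_KERNEL_SD = STEP  # below one grid step the 257 grid cannot resolve it


def compute_weights(coords: np.ndarray) -> np.ndarray:
    """Bilinear-bin events (n, 2 coordinates in [0,1]) onto the grid.

    Total deposited mass equals the event count exactly; an event sitting on
    a node puts its whole mass there.
    """
    coords = np.asarray(coords, dtype=float)
    x = coords[:, 0] * (GRID - 1)
    y = coords[:, 1] * (GRID - 1)
    i0 = np.minimum(x.astype(np.int64), GRID - 2)
    j0 = np.minimum(y.astype(np.int64), GRID - 2)
    fx = x - i0
    fy = y - j0
    w = np.zeros((GRID, GRID))
    np.add.at(w, (i0, j0), (1 - fx) * (1 - fy))
    np.add.at(w, (i0, j0 + 1), (1 - fx) * fy)
    np.add.at(w, (i0 + 1, j0), fx * (1 - fy))
    np.add.at(w, (i0 + 1, j0 + 1), fx * fy)
    return w


def _kernel_profile(kernel_sd: float) -> np.ndarray:
    """1-D discrete Gaussian taps g[0..256], normalised so the full
    periodised (length 512) kernel sums to 1."""
    m = np.arange(GRID)
    g = np.exp(-((m * STEP) ** 2) / (2.0 * kernel_sd ** 2))
    total = g[0] + 2.0 * g[1:-1].sum() + g[-1]
    return g / total


def kernel_eigenvalues(kernel_sd: float) -> np.ndarray:
    """DCT-I eigenvalues of symmetric convolution with the sampled kernel."""
    return sp_fft.dct(_kernel_profile(kernel_sd), type=1)


def squared_kernel_eigenvalues(kernel_sd: float) -> np.ndarray:
    """Eigenvalues of convolution with the *squared* kernel taps (used for
    the pointwise variance of the density estimate)."""
    return sp_fft.dct(_kernel_profile(kernel_sd) ** 2, type=1)


def smooth_grid(arr: np.ndarray, eig: np.ndarray) -> np.ndarray:
    """Apply the separable symmetric convolution with given 1-D eigenvalues."""
    spec = sp_fft.dctn(arr, type=1)
    spec *= np.outer(eig, eig)
    out = sp_fft.idctn(spec, type=1)
    np.maximum(out, 0.0, out=out)   # clip DCT round-off
    return out


def grid_integral(arr: np.ndarray) -> float:
    """Trapezoidal integral of a grid function over the unit square."""
    xs = np.arange(GRID) * STEP
    return float(np.trapezoid(np.trapezoid(arr, xs, axis=1), xs))


def kde_dct(weights: np.ndarray, kernel_sd: float) -> np.ndarray:
    """Gaussian KDE of a weight array, normalised to integrate to 1."""
    density, _ = _kde_with_scale(weights, kernel_sd)
    return density


def _kde_with_scale(weights: np.ndarray, kernel_sd: float
                    ) -> tuple[np.ndarray, float]:
    if kernel_sd < MIN_KERNEL_SD:
        raise ValueError(
            f"kernel_sd {kernel_sd:g} below grid resolution {MIN_KERNEL_SD:g}")
    smoothed = smooth_grid(weights, kernel_eigenvalues(kernel_sd))
    integral = grid_integral(smoothed)
    if integral <= 0:
        return np.zeros_like(smoothed), 0.0
    scale = 1.0 / integral
    return smoothed * scale, scale


@dataclass
class DensityGrid:
    """Weight array and KDE for one dimension pair at the current bandwidth.

    ``scale`` converts the raw mass-conserving smooth into the
    integral-one density; the dip test scales its variance by ``scale**2``
    for consistency.
    """

    weights: np.ndarray
    density: np.ndarray
    kernel_sd: float
    n_events: int
    pass_count: int = 0
    scale: float = 1.0
    prev_density: np.ndarray | None = field(default=None, repr=False)


def density_grid(coords: np.ndarray, kernel_sd: float) -> DensityGrid:
    """Build the weight array and its KDE for a pair projection."""
    w = compute_weights(coords)
    density, scale = _kde_with_scale(w, kernel_sd)
    return DensityGrid(weights=w, density=density, kernel_sd=kernel_sd,
                       n_events=coords.shape[0], scale=scale)


def widen_kernel(grid: DensityGrid, max_passes: int = 8) -> DensityGrid:
    """Recompute the KDE at sd x sqrt(2); raises RuntimeError past the cap
    (the caller then declares the population a leaf for this pair)."""
    if grid.pass_count >= max_passes:
        raise RuntimeError("kernel widening cap exceeded")
    new_sd = grid.kernel_sd * np.sqrt(2.0)
    density, scale = _kde_with_scale(grid.weights, new_sd)
    return DensityGrid(weights=grid.weights, density=density,
                       kernel_sd=new_sd, n_events=grid.n_events,
                       pass_count=grid.pass_count + 1, scale=scale,
                       prev_density=grid.density)
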