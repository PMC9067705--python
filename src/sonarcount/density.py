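"""Ground-truth density maps from point annotations.

A density map is a nonnegative grid whose spatial integral equals the object
count: each annotated point contributes a unit-mass Gaussian bump, so summing
the grid recovers the number of fish. The network regresses images to such
maps and the predicted count is the integral of the predicted map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityMap",
    "gaussian_kernel",
    "points_to_density",
    "count_from_density",
    "downsample_density",
    "save_density",
    "load_density",
    "save_heatmap",
]


@dataclass
class DensityMap:
    """Nonnegative 2-D grid; ``resolution`` tags full vs downsampled maps."""

    grid: np.ndarray
    resolution: str = "full"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("density grid must be 2-D")

    @property
    def count(self) -> float:
        return float(self.grid.sum())


def gaussian_kernel(s: int = 4, sigma: float = 1.0) -> np.ndarray:
    """Normalized isotropic Gaussian stamp of size parameter ``s``.

    The support is an odd square of side ``2 * ceil(s / 2) + 1`` so the stamp
    has a centre pixel to align with the annotation; entries are proportional
    to ``exp(-(i^2 + j^2) / (2 sigma^2))`` and normalized to sum exactly 1.
    The defaults (s=4, sigma=1) give a 5x5 stamp.
    """
    if s < 1:
        raise ValueError(f"kernel size parameter must be >= 1; got {s}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0; got {sigma}")
    half = math.ceil(s / 2)
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g1, g1)
    return kernel / kernel.sum()


def points_to_density(
    points, shape: tuple[int, int], kernel: np.ndarray | None = None
) -> DensityMap:
    """Stamp a unit-mass kernel at every point.

    Near the frame border the in-bounds part of the stamp is renormalized to
    mass 1, so every point contributes exactly one unit to the integral and
    the map's sum equals the annotation count (the count label of Eq-style
    L1 training is the integral of this map).
    """
    if kernel is None:
        kernel = gaussian_kernel()
    rows, cols = shape
    grid = np.zeros((rows, cols), dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    half = kernel.shape[0] // 2
    for r, c in pts:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"point ({r}, {c}) outside {rows}x{cols} frame")
        ri, ci = int(round(r)), int(round(c))
        ri = min(ri, rows - 1)
        ci = min(ci, cols - 1)
        top, bottom = max(0, ri - half), min(rows, ri + half + 1)
        left, right = max(0, ci - half), min(cols, ci + half + 1)
        sub = kernel[
            top - (ri - half) : kernel.shape[0] - ((ri + half + 1) - bottom),
            left - (ci - half) : kernel.shape[1] - ((ci + half + 1) - right),
        ]
        grid[top:bottom, left:right] += sub / sub.sum()
    return DensityMap(grid=grid, resolution="full")


def count_from_density(density: DensityMap | np.ndarray) -> float:
    """Integrate a density map to a (real-valued) count estimate."""
    grid = density.grid if isinstance(density, DensityMap) else np.asarray(density)
    return float(grid.sum())


def downsample_density(density: DensityMap, factor: int) -> DensityMap:
    """Sum-pool by ``factor``; the integral is preserved exactly.

    Used to compare a full-resolution ground-truth map with the coarse
    (rows/d x cols/d) grid the network predicts.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    grid = density.grid
    rows, cols = grid.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"grid shape {grid.shape} not divisible by factor {factor}"
        )
    pooled = grid.reshape(rows // factor, factor, cols // factor, factor).sum(axis=(1, 3))
    return DensityMap(grid=pooled, resolution="downsampled" if factor > 1 else density.resolution)


def save_density(density: DensityMap, path) -> None:
    """Persist a density map as a 32-bit float NPY array."""
    np.save(path, density.grid.astype(np.float32))


def load_density(path, resolution: str = "full") -> DensityMap:
    return DensityMap(grid=np.load(path).astype(float), resolution=resolution)


def save_heatmap(density: DensityMap | np.ndarray, path) -> None:
    """Write a density map as a heat-map PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = density.grid if isinstance(density, DensityMap) else np.asarray(density)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid, cmap="jet")
    fig.colorbar(im, ax=ax, fraction=0.03)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
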