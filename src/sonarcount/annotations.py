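"""Core annotated-image containers shared by every pipeline stage.

Coordinate convention (used everywhere in this package): points are
``(row, col)``, 0-based, at the resolution of the pixel grid they annotate.
Boxes are axis-aligned ``(top, left, bottom, right)`` and *half-open*:
a point ``(r, c)`` is inside iff ``top <= r < bottom and left <= c < right``.
The only place the external x/y (col/row) convention appears is the VIA
reader/writer in :mod:`sonarcount.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnotatedImage", "PredictionRecord", "points_in_box"]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (N, 2) (row, col); got shape {pts.shape}")
    return pts


def _as_boxes(boxes) -> np.ndarray:
    arr = np.asarray(boxes, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 4)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"boxes must be (M, 4) (top, left, bottom, right); got {arr.shape}")
    return arr


def points_in_box(points: np.ndarray, box) -> np.ndarray:
    """Boolean mask of points inside a half-open (top, left, bottom, right) box."""
    pts = _as_points(points)
    top, left, bottom, right = box
    if pts.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    return (
        (pts[:, 0] >= top)
        & (pts[:, 0] < bottom)
        & (pts[:, 1] >= left)
        & (pts[:, 1] < right)
    )


@dataclass
class AnnotatedImage:
    """A raster frame with fish point annotations and noise bounding boxes.

    Parameters
    ----------
    image_id:
        Stable identifier (typically the file stem).
    pixels:
        ``(H, W, 3)`` uint8 array. Grayscale sources are replicated to three
        channels at read time (the backbone contract expects 3 channels).
    fish_points:
        ``(N, 2)`` float array of (row, col) fish centres.
    noise_boxes:
        ``(M, 4)`` float array of (top, left, bottom, right) half-open boxes
        around noise objects (dolphins, nets, ...).
    """

    image_id: str
    pixels: np.ndarray
    fish_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    noise_boxes: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = np.repeat(self.pixels[:, :, None], 3, axis=2)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be (H, W, 3); got shape {self.pixels.shape}"
            )
        self.fish_points = _as_points(self.fish_points)
        self.noise_boxes = _as_boxes(self.noise_boxes)
        h, w = self.shape
        pts = self.fish_points
        if pts.shape[0]:
            bad = ~points_in_box(pts, (0, 0, h, w))
            if bad.any():
                idx = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"fish point {tuple(pts[idx])} outside {h}x{w} frame "
                    f"of image {self.image_id!r}"
                )
        for box in self.noise_boxes:
            top, left, bottom, right = box
            if not (0 <= top <= bottom <= h and 0 <= left <= right <= w):
                raise ValueError(
                    f"noise box {tuple(box)} outside {h}x{w} frame "
                    f"of image {self.image_id!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.pixels.shape[0]), int(self.pixels.shape[1])

    @property
    def true_count(self) -> int:
        """Number of fish points. Always recomputed, never stored."""
        return int(self.fish_points.shape[0])

    def copy(self) -> "AnnotatedImage":
        return AnnotatedImage(
            image_id=self.image_id,
            pixels=self.pixels.copy(),
            fish_points=self.fish_points.copy(),
            noise_boxes=self.noise_boxes.copy(),
        )


@dataclass
class PredictionRecord:
    """One test-time prediction: true count, estimated count and log-variance."""

    image_id: str
    count_true: int
    count_pred: float
    log_sigma2: float
    subgroup: str = ""

    def __post_init__(self) -> None:
        self.count_true = int(self.count_true)
        if self.count_true < 0:
            raise ValueError("count_true must be >= 0")
        self.count_pred = float(self.count_pred)
        self.log_sigma2 = float(self.log_sigma2)
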