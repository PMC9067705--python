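"""Annotation and prediction I/O plus geometric preprocessing.

Reads/writes the VGG Image Annotator (VIA) JSON dialects (project export
with ``_via_img_metadata``, or the plain region-list export), converts the
external (x, y) = (col, row) convention to the package-internal (row, col),
applies the crop + bilinear-resize preprocessing through which annotation
coordinates are mapped by the same affine transform, and persists prediction
records as CSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .annotations import AnnotatedImage, PredictionRecord, points_in_box

__all__ = [
    "AnnotationStub",
    "read_via_annotations",
    "write_via_annotations",
    "load_annotated_images",
    "preprocess",
    "write_predictions",
    "read_predictions",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationStub:
    """Annotations for one file, before pixels are attached."""

    filename: str
    fish_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    noise_boxes: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))


def _parse_regions(filename: str, regions) -> AnnotationStub:
    points, boxes = [], []
    for region in regions:
        shape = region.get("shape_attributes", {})
        name = shape.get("name")
        if name == "point":
            # VIA stores (cx, cy) = (col, row)
            points.append((float(shape["cy"]), float(shape["cx"])))
        elif name == "rect":
            top, left = float(shape["y"]), float(shape["x"])
            boxes.append(
                (top, left, top + float(shape["height"]), left + float(shape["width"]))
            )
        else:
            msg = f"{filename}: skipping region of unknown shape {name!r}"
            warnings.warn(msg, stacklevel=3)
            logger.warning(msg)
    return AnnotationStub(
        filename=filename,
        fish_points=np.array(points, dtype=float).reshape(-1, 2),
        noise_boxes=np.array(boxes, dtype=float).reshape(-1, 4),
    )


def read_via_annotations(path: str | Path) -> list[AnnotationStub]:
    """Parse a VIA JSON export into per-file annotation stubs.

    Point regions become fish points, rect regions become noise boxes;
    unknown region shapes are skipped with a logged warning.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed VIA JSON in {path}: {exc}") from exc
    entries = payload.get("_via_img_metadata", payload)
    stubs = []
    for _, entry in sorted(entries.items()):
        if not isinstance(entry, dict) or "regions" not in entry:
            continue
        filename = entry.get("filename", "")
        stubs.append(_parse_regions(filename, entry["regions"]))
    return stubs


def write_via_annotations(images, path: str | Path) -> None:
    """Write annotations in the VIA project dialect (round-trips with the reader)."""
    metadata = {}
    for img in images:
        regions = [
            {
                "shape_attributes": {"name": "point", "cx": float(c), "cy": float(r)},
                "region_attributes": {},
            }
            for r, c in img.fish_points
        ]
        regions += [
            {
                "shape_attributes": {
                    "name": "rect",
                    "x": float(left),
                    "y": float(top),
                    "width": float(right - left),
                    "height": float(bottom - top),
                },
                "region_attributes": {},
            }
            for top, left, bottom, right in img.noise_boxes
        ]
        filename = f"{img.image_id}.png"
        metadata[filename] = {
            "filename": filename,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    with open(path, "w") as fh:
        json.dump({"_via_img_metadata": metadata}, fh)


def load_annotated_images(image_dir: str | Path, annotation_path: str | Path) -> list[AnnotatedImage]:
    """Attach pixels to annotation stubs; grayscale frames become 3-channel."""
    from PIL import Image

    image_dir = Path(image_dir)
    out = []
    for stub in read_via_annotations(annotation_path):
        img_path = image_dir / stub.filename
        pixels = np.asarray(Image.open(img_path))
        if pixels.ndim == 3 and pixels.shape[2] > 3:
            pixels = pixels[:, :, :3]
        out.append(
            AnnotatedImage(
                image_id=Path(stub.filename).stem,
                pixels=pixels,
                fish_points=stub.fish_points,
                noise_boxes=stub.noise_boxes,
            )
        )
    return out


def preprocess(
    image: AnnotatedImage,
    crop_box: tuple[int, int, int, int],
    target_shape: tuple[int, int] = (320, 576),
) -> AnnotatedImage:
    """Crop then bilinearly resize; map annotations through the same affine.

    Points on the leading (top/left) crop edge are kept, trailing edge
    dropped (half-open rule), so disjoint crops partition the points.
    """
    top, left, bottom, right = (int(v) for v in crop_box)
    h, w = image.shape
    if not (0 <= top < bottom <= h and 0 <= left < right <= w):
        raise ValueError(f"crop box {crop_box} invalid for {h}x{w} image")
    crop = image.pixels[top:bottom, left:right]
    tr, tc = target_shape
    scale_r = tr / (bottom - top)
    scale_c = tc / (right - left)
    if (tr, tc) == (bottom - top, right - left):
        resized = crop.copy()
    else:
        resized = _sk_resize(
            crop.astype(float), (tr, tc), order=1, anti_aliasing=False, preserve_range=True
        )
    resized = np.clip(resized, 0, 255).astype(np.uint8)

    keep = points_in_box(image.fish_points, (top, left, bottom, right))
    pts = image.fish_points[keep]
    pts = np.column_stack([(pts[:, 0] - top) * scale_r, (pts[:, 1] - left) * scale_c]) if pts.size else pts.reshape(0, 2)
    # transformed points can land exactly on the trailing edge; nudge inside
    if pts.size:
        pts[:, 0] = np.minimum(pts[:, 0], tr - 1e-9)
        pts[:, 1] = np.minimum(pts[:, 1], tc - 1e-9)

    boxes = []
    for btop, bleft, bbottom, bright in image.noise_boxes:
        ntop, nleft = max(btop, top), max(bleft, left)
        nbottom, nright = min(bbottom, bottom), min(bright, right)
        if ntop >= nbottom or nleft >= nright:
            continue
        boxes.append(
            (
                (ntop - top) * scale_r,
                (nleft - left) * scale_c,
                (nbottom - top) * scale_r,
                (nright - left) * scale_c,
            )
        )
    return AnnotatedImage(
        image_id=image.image_id,
        pixels=resized,
        fish_points=pts,
        noise_boxes=np.array(boxes, dtype=float).reshape(-1, 4),
    )


_PRED_COLUMNS = ["image_id", "count_true", "count_pred", "log_sigma2", "subgroup"]


def write_predictions(records: list[PredictionRecord], path: str | Path) -> None:
    """Persist prediction records as CSV (header always written)."""
    frame = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "count_true": r.count_true,
                "count_pred": r.count_pred,
                "log_sigma2": r.log_sigma2,
                "subgroup": r.subgroup,
            }
            for r in records
        ],
        columns=_PRED_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        PredictionRecord(
            image_id=str(row.image_id),
            count_true=int(row.count_true),
            count_pred=float(row.count_pred),
            log_sigma2=float(row.log_sigma2),
            subgroup=str(row.subgroup),
        )
        for row in frame.itertuples()
    ]
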