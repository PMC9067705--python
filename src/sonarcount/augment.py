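"""Annotation-consistent data augmentation.

Expands a small labelled set with crops (placed on a blank background at the
original frame size), translations, horizontal flips, small rotations, and
superimposed noise objects (e.g. a dolphin patch from one frame pasted onto
another). Every transform is applied identically to pixels and annotations;
points that leave the frame (or are occluded by a pasted patch) are dropped,
so augmentation can only ever reduce the fish count. Resizing/scale
augmentation is deliberately absent: the imaging geometry keeps fish size
constant across frames, so scale-awareness is not part of the task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import AnnotatedImage, points_in_box

__all__ = [
    "AugmentConfig",
    "augment_one",
    "superimpose_noise",
    "expand_dataset",
]

BLANK_LEVEL = 0  # background-removed frames are black


@dataclass(frozen=True)
class AugmentConfig:
    rotation_max_deg: float = 10.0
    crop_fraction_range: tuple[float, float] = (0.5, 0.9)
    translate_max_px: int = 24
    multiplier: int = 16
    superimpose_prob: float = 0.15


def _hflip(image: AnnotatedImage) -> AnnotatedImage:
    h, w = image.shape
    pts = image.fish_points.copy()
    if pts.size:
        # pixel-centre mirror; sub-pixel positions in the last pixel would
        # map slightly negative, so clamp them into their mirrored pixel
        pts[:, 1] = np.clip((w - 1) - pts[:, 1], 0.0, None)
    boxes = image.noise_boxes.copy()
    if boxes.size:
        boxes = np.column_stack(
            [boxes[:, 0], w - boxes[:, 3], boxes[:, 2], w - boxes[:, 1]]
        )
    return AnnotatedImage(image.image_id, image.pixels[:, ::-1].copy(), pts, boxes)


def _translate(image: AnnotatedImage, dr: int, dc: int) -> AnnotatedImage:
    h, w = image.shape
    out = np.full_like(image.pixels, BLANK_LEVEL)
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = image.pixels[src_r, src_c]
    pts = image.fish_points + np.array([dr, dc], dtype=float)
    keep = points_in_box(pts, (0, 0, h, w))
    boxes = []
    for top, left, bottom, right in image.noise_boxes:
        top, left, bottom, right = top + dr, left + dc, bottom + dr, right + dc
        top, left = max(0.0, top), max(0.0, left)
        bottom, right = min(float(h), bottom), min(float(w), right)
        if top < bottom and left < right:
            boxes.append((top, left, bottom, right))
    return AnnotatedImage(
        image.image_id, out, pts[keep], np.array(boxes).reshape(-1, 4)
    )


def _crop_to_blank(
    image: AnnotatedImage, crop_box, place_at: tuple[int, int]
) -> AnnotatedImage:
    """Cut a region and place it on a blank frame of the original size."""
    top, left, bottom, right = (int(v) for v in crop_box)
    h, w = image.shape
    ph, pw = bottom - top, right - left
    pr, pc = place_at
    if not (0 <= pr <= h - ph and 0 <= pc <= w - pw):
        raise ValueError("placement puts the crop outside the frame")
    out = np.full_like(image.pixels, BLANK_LEVEL)
    out[pr : pr + ph, pc : pc + pw] = image.pixels[top:bottom, left:right]
    keep = points_in_box(image.fish_points, (top, left, bottom, right))
    pts = image.fish_points[keep] - np.array([top, left]) + np.array([pr, pc], dtype=float)
    boxes = []
    for btop, bleft, bbottom, bright in image.noise_boxes:
        ntop, nleft = max(btop, top), max(bleft, left)
        nbottom, nright = min(bbottom, bottom), min(bright, right)
        if ntop < nbottom and nleft < nright:
            boxes.append(
                (ntop - top + pr, nleft - left + pc, nbottom - top + pr, nright - left + pc)
            )
    return AnnotatedImage(image.image_id, out, pts, np.array(boxes).reshape(-1, 4))


def _rotate(image: AnnotatedImage, angle_deg: float) -> AnnotatedImage:
    h, w = image.shape
    rotated = ndimage.rotate(
        image.pixels.astype(float),
        angle_deg,
        axes=(1, 0),
        reshape=False,
        order=1,
        mode="constant",
        cval=BLANK_LEVEL,
    )
    rotated = np.clip(rotated, 0, 255).astype(np.uint8)
    # ndimage.rotate by `angle` maps output coords through a rotation of the
    # input; forward-map annotation points with the matching rotation about
    # the frame centre.
    theta = np.deg2rad(angle_deg)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rel = image.fish_points - center
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = rel @ rot.T + center
    keep = points_in_box(pts, (0, 0, h, w))
    boxes = []
    for top, left, bottom, right in image.noise_boxes:
        corners = np.array(
            [[top, left], [top, right], [bottom, left], [bottom, right]], dtype=float
        )
        rc = (corners - center) @ rot.T + center
        ntop, nleft = rc[:, 0].min(), rc[:, 1].min()
        nbottom, nright = rc[:, 0].max(), rc[:, 1].max()
        ntop, nleft = max(0.0, ntop), max(0.0, nleft)
        nbottom, nright = min(float(h), nbottom), min(float(w), nright)
        if ntop < nbottom and nleft < nright:
            boxes.append((ntop, nleft, nbottom, nright))
    return AnnotatedImage(image.image_id, rotated, pts[keep], np.array(boxes).reshape(-1, 4))


def augment_one(
    image: AnnotatedImage,
    op_spec: dict,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> AnnotatedImage:
    """Apply one augmentation op; ``op_spec = {"kind": ..., **params}``.

    Kinds: ``hflip``; ``rotate`` (param ``angle_deg``, random within
    +/-rotation_max_deg if absent); ``translate`` (params ``dr, dc``);
    ``crop`` (params ``box``, ``place_at``; random if absent).
    """
    config = config or AugmentConfig()
    kind = op_spec["kind"]
    h, w = image.shape
    if kind == "hflip":
        return _hflip(image)
    if kind == "rotate":
        angle = op_spec.get("angle_deg")
        if angle is None:
            angle = float(rng.uniform(-config.rotation_max_deg, config.rotation_max_deg))
        if abs(angle) > config.rotation_max_deg:
            raise ValueError(
                f"rotation {angle} deg exceeds configured max {config.rotation_max_deg}"
            )
        if angle == 0.0:
            return image.copy()
        return _rotate(image, angle)
    if kind == "translate":
        dr = int(op_spec.get("dr", rng.integers(-config.translate_max_px, config.translate_max_px + 1)))
        dc = int(op_spec.get("dc", rng.integers(-config.translate_max_px, config.translate_max_px + 1)))
        return _translate(image, dr, dc)
    if kind == "crop":
        box = op_spec.get("box")
        if box is None:
            frac = rng.uniform(*config.crop_fraction_range)
            ch, cw = max(1, int(h * frac)), max(1, int(w * frac))
            top = int(rng.integers(0, h - ch + 1))
            left = int(rng.integers(0, w - cw + 1))
            box = (top, left, top + ch, left + cw)
        place_at = op_spec.get("place_at")
        if place_at is None:
            ph, pw = int(box[2]) - int(box[0]), int(box[3]) - int(box[1])
            place_at = (
                int(rng.integers(0, h - ph + 1)),
                int(rng.integers(0, w - pw + 1)),
            )
        return _crop_to_blank(image, box, place_at)
    raise ValueError(f"unknown augmentation kind {kind!r}")


def superimpose_noise(
    target: AnnotatedImage,
    donor_patch: np.ndarray,
    rng: np.random.Generator,
    place_at: tuple[int, int] | None = None,
) -> AnnotatedImage:
    """Paste an opaque noise patch; fish underneath are occluded (removed)."""
    h, w = target.shape
    ph, pw = donor_patch.shape[:2]
    if ph > h or pw > w:
        raise ValueError(f"patch {ph}x{pw} larger than target {h}x{w}")
    if place_at is None:
        place_at = (int(rng.integers(0, h - ph + 1)), int(rng.integers(0, w - pw + 1)))
    pr, pc = place_at
    if not (0 <= pr <= h - ph and 0 <= pc <= w - pw):
        raise ValueError("patch does not fit at the sampled location")
    pixels = target.pixels.copy()
    patch = donor_patch if donor_patch.ndim == 3 else np.repeat(donor_patch[:, :, None], 3, axis=2)
    pixels[pr : pr + ph, pc : pc + pw] = patch
    pasted_box = (float(pr), float(pc), float(pr + ph), float(pc + pw))
    covered = points_in_box(target.fish_points, pasted_box)
    boxes = np.vstack([target.noise_boxes, np.array(pasted_box).reshape(1, 4)])
    return AnnotatedImage(
        target.image_id, pixels, target.fish_points[~covered], boxes
    )


def _extract_noise_patches(images) -> list[np.ndarray]:
    patches = []
    for img in images:
        for top, left, bottom, right in img.noise_boxes.astype(int):
            if bottom > top and right > left:
                patches.append(img.pixels[top:bottom, left:right].copy())
    return patches


def expand_dataset(
    images: list[AnnotatedImage],
    multiplier: int,
    seed: int,
    config: AugmentConfig | None = None,
) -> list[AnnotatedImage]:
    """Originals plus ``(multiplier - 1) * len(images)`` augmented variants.

    Each variant applies one randomly chosen geometric op, optionally
    followed by a superimposed noise patch drawn from the pool's noise
    boxes. Deterministic under ``seed``; never resizes.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    out = [img.copy() for img in images]
    patches = _extract_noise_patches(images)
    kinds = ["crop", "translate", "hflip", "rotate"]
    for round_idx in range(multiplier - 1):
        for img in images:
            kind = kinds[int(rng.integers(0, len(kinds)))]
            aug = augment_one(img, {"kind": kind}, rng, config)
            if patches and rng.random() < config.superimpose_prob:
                patch = patches[int(rng.integers(0, len(patches)))]
                if patch.shape[0] <= aug.shape[0] and patch.shape[1] <= aug.shape[1]:
                    aug = superimpose_noise(aug, patch, rng)
            aug.image_id = f"{img.image_id}_aug{round_idx}"
            out.append(aug)
    return out
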