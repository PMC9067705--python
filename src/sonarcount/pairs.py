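"""Ranked image pairs for the self-supervised counting-order task.

A pair (first, second) is built so that ``second`` is (a crop of) a
subregion of ``first`` and therefore contains equal or fewer fish — an
ordering known *by construction*, without any labels. For each source image
a series ``S = [original, crop(f=0.25), crop(f=0.5), crop(f=0.75)]`` is
built; the crop for factor ``f`` of the (default full-frame) bounding box
``(x1, y1, x2, y2)`` is the region ``rows [y1 + f*h, y2), cols [x1, x2 -
f*w)``, randomly translated onto a blank frame of the original size and
randomly h-flipped. Crop regions are nested, so all ordered pairs
``(S[j], S[k]), j < k`` are correctly ranked; each image yields C(4,2) = 6
pairs at the default factors.

A weak-label variant pairs "fish"-labelled images (first) against
"no fish"-labelled images (second), for datasets that ship binary presence
labels instead of crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .annotations import AnnotatedImage
from .augment import _crop_to_blank

__all__ = [
    "RankedPair",
    "Batch",
    "SeriesElement",
    "subregion_series",
    "generate_pairs",
    "pairs_from_weak_labels",
    "assemble_batch",
    "iter_epoch_batches",
    "pair_manifest",
]

DEFAULT_CROP_FACTORS = (0.25, 0.5, 0.75)


@dataclass
class SeriesElement:
    """One element of a subregion series, with its source region recorded."""

    image: AnnotatedImage
    factor: float | None  # None for the original image
    source_region: tuple[float, float, float, float]  # (top, left, bottom, right) in source coords
    placement: tuple[int, int] = (0, 0)  # (u, l) top-left on the blank frame
    flipped: bool = False


@dataclass
class RankedPair:
    """Ordered pair: ``first`` contains >= fish than ``second`` by construction."""

    first: AnnotatedImage
    second: AnnotatedImage
    provenance: dict = field(default_factory=dict)


@dataclass
class Batch:
    """One training mini-batch: K labelled images and K ranked pairs."""

    labelled: list[AnnotatedImage]
    pairs: list[RankedPair]


def crop_region_for_factor(
    f: float, bbox: tuple[int, int, int, int], frame_shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """(top, left, bottom, right) of the factor-``f`` crop of ``bbox``."""
    if not (0.0 < f < 1.0):
        raise ValueError(f"crop factor must lie in (0, 1); got {f}")
    x1, y1, x2, y2 = bbox[1], bbox[0], bbox[3], bbox[2]
    h, w = frame_shape
    top = int(round(y1 + f * h))
    right = int(round(x2 - f * w))
    return (top, x1, y2, right)


def subregion_series(
    image: AnnotatedImage,
    rng: np.random.Generator,
    crop_factors: tuple[float, ...] = DEFAULT_CROP_FACTORS,
    bbox: tuple[int, int, int, int] | None = None,
) -> list[SeriesElement]:
    """Original image followed by one randomly-placed crop per factor.

    The crop for factor ``f`` is translated to a top-left ``(u, l)`` drawn
    uniformly with ``0 <= u <= f*h`` and ``0 <= l <= f*w``, h-flipped with
    probability 1/2, and placed on a blank frame of the original size.
    """
    h, w = image.shape
    if bbox is None:
        bbox = (0, 0, h, w)
    series = [
        SeriesElement(
            image=image.copy(), factor=None, source_region=(float(bbox[0]), float(bbox[1]), float(bbox[2]), float(bbox[3]))
        )
    ]
    for f in crop_factors:
        region = crop_region_for_factor(f, bbox, (h, w))
        u = int(rng.integers(0, int(f * h) + 1))
        l = int(rng.integers(0, int(f * w) + 1))
        flip = bool(rng.integers(0, 2))
        cropped = _crop_to_blank(image, region, (u, l))
        if flip:
            from .augment import _hflip

            cropped = _hflip(cropped)
        cropped.image_id = f"{image.image_id}_f{f}"
        series.append(
            SeriesElement(
                image=cropped,
                factor=f,
                source_region=tuple(float(v) for v in region),
                placement=(u, l),
                flipped=flip,
            )
        )
    return series


def generate_pairs(
    images: list[AnnotatedImage],
    rng: np.random.Generator,
    crop_factors: tuple[float, ...] = DEFAULT_CROP_FACTORS,
) -> list[RankedPair]:
    """All ordered pairs (S[j], S[k]) with j < k, for every image's series."""
    pairs: list[RankedPair] = []
    for image in images:
        series = subregion_series(image, rng, crop_factors)
        for j, k in combinations(range(len(series)), 2):
            first, second = series[j], series[k]
            pairs.append(
                RankedPair(
                    first=first.image,
                    second=second.image,
                    provenance={
                        "source_id": image.image_id,
                        "j": j,
                        "k": k,
                        "factor_j": first.factor,
                        "factor_k": second.factor,
                        "region_j": first.source_region,
                        "region_k": second.source_region,
                        "flip_j": first.flipped,
                        "flip_k": second.flipped,
                        "placement_j": first.placement,
                        "placement_k": second.placement,
                    },
                )
            )
    return pairs


def pairs_from_weak_labels(
    images_with_labels: list[tuple[AnnotatedImage, str]],
    rng: np.random.Generator,
    n_pairs: int,
) -> list[RankedPair]:
    """Pairs from binary presence labels: first has "fish", second "no_fish"."""
    fish = [img for img, lab in images_with_labels if lab == "fish"]
    empty = [img for img, lab in images_with_labels if lab == "no_fish"]
    if not fish or not empty:
        return []
    pairs = []
    for _ in range(n_pairs):
        a = fish[int(rng.integers(0, len(fish)))]
        b = empty[int(rng.integers(0, len(empty)))]
        pairs.append(
            RankedPair(
                first=a,
                second=b,
                provenance={"source_id": a.image_id, "weak_labels": ("fish", "no_fish")},
            )
        )
    return pairs


def assemble_batch(
    labelled_pool: list[AnnotatedImage],
    pair_pool: list[RankedPair],
    K: int,
    rng: np.random.Generator,
) -> Batch:
    """K labelled images without replacement, K pairs with replacement."""
    if K <= 0:
        raise ValueError("K must be positive")
    if not labelled_pool or not pair_pool:
        raise ValueError("labelled_pool and pair_pool must be non-empty")
    idx = rng.choice(len(labelled_pool), size=min(K, len(labelled_pool)), replace=False)
    labelled = [labelled_pool[i] for i in idx]
    pidx = rng.integers(0, len(pair_pool), size=K)
    return Batch(labelled=labelled, pairs=[pair_pool[i] for i in pidx])


def iter_epoch_batches(
    labelled: list[AnnotatedImage],
    pair_pool: list[RankedPair] | None,
    K: int,
    rng: np.random.Generator,
):
    """Yield batches covering each labelled image once per epoch.

    The labelled set is shuffled and walked without replacement; when a pair
    pool is supplied, K pairs are drawn with replacement for each batch.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    order = rng.permutation(len(labelled))
    for start in range(0, len(order), K):
        chunk = [labelled[i] for i in order[start : start + K]]
        if pair_pool:
            pidx = rng.integers(0, len(pair_pool), size=len(chunk))
            batch_pairs = [pair_pool[i] for i in pidx]
        else:
            batch_pairs = []
        yield Batch(labelled=chunk, pairs=batch_pairs)


def pair_manifest(pairs: list[RankedPair]) -> pd.DataFrame:
    """Tabular provenance of a pair pool (one row per pair)."""
    rows = []
    for i, p in enumerate(pairs):
        prov = p.provenance
        rows.append(
            {
                "pair_id": i,
                "source_id": prov.get("source_id", ""),
                "j": prov.get("j", -1),
                "k": prov.get("k", -1),
                "factor_j": prov.get("factor_j"),
                "factor_k": prov.get("factor_k"),
                "flip_j": prov.get("flip_j"),
                "flip_k": prov.get("flip_k"),
                "u_j": prov.get("placement_j", (None, None))[0],
                "l_j": prov.get("placement_j", (None, None))[1],
                "u_k": prov.get("placement_k", (None, None))[0],
                "l_k": prov.get("placement_k", (None, None))[1],
            }
        )
    return pd.DataFrame(rows)
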