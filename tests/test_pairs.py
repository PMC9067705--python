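"""Ranked-pair generation: crop arithmetic, nesting, ordering guarantee."""

import numpy as np
import pytest

from sonarcount.annotations import AnnotatedImage, points_in_box
from sonarcount.pairs import (
    assemble_batch,
    crop_region_for_factor,
    generate_pairs,
    iter_epoch_batches,
    pair_manifest,
    pairs_from_weak_labels,
    subregion_series,
)
from sonarcount.synthetic import desk_scale_config, generate_dataset


def make_image(points, h=64, w=112, image_id="u"):
    return AnnotatedImage(
        image_id,
        np.zeros((h, w, 3), dtype=np.uint8),
        fish_points=np.array(points, dtype=float).reshape(-1, 2),
    )


class TestCropRegions:
    def test_factor_half_on_full_frame(self):
        """320x576 frame, f=0.5: crop rows [160, 320), cols [0, 288)."""
        region = crop_region_for_factor(0.5, (0, 0, 320, 576), (320, 576))
        assert region == (160, 0, 320, 288)

    def test_regions_are_nested(self):
        frame = (320, 576)
        bbox = (0, 0, 320, 576)
        regions = [crop_region_for_factor(f, bbox, frame) for f in (0.25, 0.5, 0.75)]
        for inner, outer in zip(regions[1:], regions[:-1]):
            assert inner[0] >= outer[0] and inner[1] >= outer[1]
            assert inner[2] <= outer[2] and inner[3] <= outer[3]

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_factor(self, f):
        with pytest.raises(ValueError):
            crop_region_for_factor(f, (0, 0, 10, 10), (10, 10))


class TestSubregionSeries:
    def test_series_length(self, rng):
        img = make_image([(10, 10)])
        series = subregion_series(img, rng)
        assert len(series) == 4  # original + 3 crop factors

    def test_crops_stay_inside_frame(self, rng):
        img = make_image([(10, 10)], h=64, w=112)
        for _ in range(10):
            series = subregion_series(img, rng)
            for elem in series[1:]:
                f = elem.factor
                u, l = elem.placement
                crop_h = 64 - int(round(f * 64))
                crop_w = 112 - int(round(f * 112))
                assert 0 <= u <= f * 64 and 0 <= l <= f * 112
                assert u + crop_h <= 64 + 1 and l + crop_w <= 112 + 1

    def test_series_counts_decrease_with_factor(self, rng):
        pts = rng.uniform(0, (64, 112), size=(50, 2))
        img = make_image(pts)
        series = subregion_series(img, rng)
        counts = [e.image.true_count for e in series]
        assert counts[0] == 50
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGeneratePairs:
    def test_six_pairs_per_image(self, rng):
        imgs = [make_image([(5, 5)], image_id=f"i{k}") for k in range(3)]
        pairs = generate_pairs(imgs, rng)
        assert len(pairs) == 18

    def test_no_images_no_pairs(self, rng):
        assert generate_pairs([], rng) == []

    def test_ordering_guarantee_point_in_rectangle_oracle(self, rng):
        """count(second) <= count(first) for every pair, by region counting."""
        images, _ = generate_dataset(20, desk_scale_config(), seed=5)
        pairs = generate_pairs(images, rng)
        by_id = {img.image_id: img for img in images}
        for pair in pairs:
            src = by_id[pair.provenance["source_id"]]
            n_first = int(points_in_box(src.fish_points, pair.provenance["region_j"]).sum())
            n_second = int(points_in_box(src.fish_points, pair.provenance["region_k"]).sum())
            assert n_second <= n_first
            # the pair's own annotations agree with the oracle
            assert pair.first.true_count == n_first
            assert pair.second.true_count == n_second

    def test_manifest_rows(self, rng):
        imgs = [make_image([(5, 5)])]
        pairs = generate_pairs(imgs, rng)
        frame = pair_manifest(pairs)
        assert len(frame) == 6
        assert {"pair_id", "source_id", "j", "k"} <= set(frame.columns)


class TestWeakLabelPairs:
    def test_single_valid_pair(self, rng):
        data = [(make_image([], image_id="f"), "fish"), (make_image([], image_id="n"), "no_fish")]
        pairs = pairs_from_weak_labels(data, rng, 1)
        assert len(pairs) == 1
        assert pairs[0].first.image_id == "f"
        assert pairs[0].second.image_id == "n"

    def test_all_fish_gives_nothing(self, rng):
        data = [(make_image([], image_id=f"f{k}"), "fish") for k in range(3)]
        assert pairs_from_weak_labels(data, rng, 5) == []

    def test_pairs_drawn_from_product_set(self, rng):
        fish = [(make_image([], image_id=f"f{k}"), "fish") for k in range(3)]
        empty = [(make_image([], image_id=f"n{k}"), "no_fish") for k in range(2)]
        pairs = pairs_from_weak_labels(fish + empty, rng, 6)
        valid = {(f"f{i}", f"n{j}") for i in range(3) for j in range(2)}
        assert all((p.first.image_id, p.second.image_id) in valid for p in pairs)


class TestBatching:
    def test_batch_sizes(self, rng):
        pool = [make_image([(5, 5)], image_id=f"i{k}") for k in range(20)]
        pairs = generate_pairs(pool[:2], rng)
        batch = assemble_batch(pool, pairs, K=10, rng=rng)
        assert len(batch.labelled) == 10
        assert len(batch.pairs) == 10

    def test_epoch_covers_each_image_once(self, rng):
        pool = [make_image([(5, 5)], image_id=f"i{k}") for k in range(10)]
        batches = list(iter_epoch_batches(pool, None, K=10, rng=rng))
        assert len(batches) == 1
        assert sorted(img.image_id for img in batches[0].labelled) == sorted(
            img.image_id for img in pool
        )

    def test_deterministic_batch_sequence(self):
        pool = [make_image([(5, 5)], image_id=f"i{k}") for k in range(15)]
        pairs = generate_pairs(pool[:2], np.random.default_rng(0))
        seq_a = [
            [img.image_id for img in b.labelled]
            for b in iter_epoch_batches(pool, pairs, 5, np.random.default_rng(42))
        ]
        seq_b = [
            [img.image_id for img in b.labelled]
            for b in iter_epoch_batches(pool, pairs, 5, np.random.default_rng(42))
        ]
        assert seq_a == seq_b

    def test_invalid_K(self, rng):
        pool = [make_image([])]
        with pytest.raises(ValueError):
            assemble_batch(pool, [], K=0, rng=rng)
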