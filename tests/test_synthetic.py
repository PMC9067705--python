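"""Synthetic scene generator: distribution control, fidelity, determinism."""

import numpy as np
import pytest

from sonarcount.synthetic import (
    GeneratorConfig,
    _sample_count,
    desk_scale_config,
    generate_dataset,
    render_scene,
    sample_scene,
)


class TestCountDistribution:
    def test_degenerate_at_zero(self):
        config = GeneratorConfig(zero_inflation=1.0)
        scene = sample_scene(config, np.random.default_rng(0))
        assert scene.count == 0
        assert scene.fish_positions.shape == (0, 2)

    def test_fixed_count(self):
        config = GeneratorConfig(fixed_count=10, dolphin_prob=0.0, net_prob=0.0)
        scene = sample_scene(config, np.random.default_rng(0))
        assert scene.count == 10
        assert scene.noise_objects == []

    def test_default_moments_monte_carlo(self):
        """10,000 draws: mean within +/-3 of 42, support bounded by 450."""
        config = GeneratorConfig()
        rng = np.random.default_rng(99)
        counts = np.array([_sample_count(config, rng) for _ in range(10_000)])
        assert abs(counts.mean() - 42.0) < 3.0
        assert counts.max() <= 450
        assert counts.min() >= 0
        # skew: low counts dominate
        assert (counts < 50).mean() > 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"zero_inflation": 1.5},
            {"lognorm_sigma": -1.0},
            {"max_count": -5},
            {"fixed_count": -1},
        ],
    )
    def test_invalid_distribution_parameters(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs).validate()


class TestSceneInvariants:
    def test_positions_inside_frame(self):
        config = desk_scale_config()
        for seed in range(20):
            scene = sample_scene(config, np.random.default_rng(seed))
            h, w = scene.frame_shape
            if scene.count:
                assert (scene.fish_positions[:, 0] < h).all()
                assert (scene.fish_positions[:, 1] < w).all()
                assert (scene.fish_positions >= 0).all()

    def test_dolphin_cap(self):
        config = GeneratorConfig(dolphin_prob=1.0)
        for seed in range(20):
            scene = sample_scene(config, np.random.default_rng(seed))
            dolphins = [o for o in scene.noise_objects if o.kind == "dolphin"]
            assert 1 <= len(dolphins) <= 4


class TestRendering:
    def test_empty_scene_pure_background(self):
        config = GeneratorConfig(
            zero_inflation=1.0, dolphin_prob=0.0, net_prob=0.0, blur_sigma=(0, 0),
            brightness_jitter=0.0,
        )
        scene = sample_scene(config, np.random.default_rng(0))
        img = render_scene(scene)
        assert img.true_count == 0
        assert np.ptp(img.pixels) == 0  # constant background

    def test_single_fish_brightest_neighbourhood(self):
        config = GeneratorConfig(fixed_count=1, dolphin_prob=0.0, net_prob=0.0)
        scene = sample_scene(config, np.random.default_rng(5))
        img = render_scene(scene)
        gray = img.pixels[:, :, 0].astype(float)
        peak = np.unravel_index(gray.argmax(), gray.shape)
        dist = np.hypot(*(np.array(peak) - scene.fish_positions[0]))
        assert dist <= scene.render_params["blob_radius"]

    def test_noise_boxes_passed_through(self):
        config = GeneratorConfig(dolphin_prob=1.0, net_prob=0.0)
        scene = sample_scene(config, np.random.default_rng(3))
        img = render_scene(scene)
        assert img.noise_boxes.shape[0] == len(scene.noise_objects)

    def test_annotation_fidelity(self, small_dataset):
        images, manifest = small_dataset
        for img, n in zip(images, manifest["n_fish"]):
            assert img.true_count == n


class TestGenerateDataset:
    def test_empty_dataset(self, desk_config):
        images, manifest = generate_dataset(0, desk_config, seed=0)
        assert images == []
        assert len(manifest) == 0
        assert list(manifest.columns) == ["image_id", "n_fish", "n_noise", "seed"]

    def test_determinism(self, desk_config):
        _, m1 = generate_dataset(30, desk_config, seed=7)
        _, m2 = generate_dataset(30, desk_config, seed=7)
        assert m1.equals(m2)

    def test_manifest_counts_match_annotations(self, small_dataset):
        images, manifest = small_dataset
        assert manifest["n_fish"].sum() == sum(img.true_count for img in images)

    def test_negative_n_rejected(self, desk_config):
        with pytest.raises(ValueError):
            generate_dataset(-1, desk_config, seed=0)

    def test_persisted_dataset_roundtrip(self, desk_config, tmp_path):
        from sonarcount.io import load_annotated_images

        images, manifest = generate_dataset(4, desk_config, seed=3, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        loaded = load_annotated_images(tmp_path, tmp_path / "annotations.json")
        assert len(loaded) == 4
        by_id = {img.image_id: img for img in loaded}
        for img in images:
            assert by_id[img.image_id].true_count == img.true_count


class TestClutterRegime:
    def test_speckle_scales_with_count(self):
        base = desk_scale_config(clutter=True)
        quiet = GeneratorConfig(**{**vars(base), "fixed_count": 0, "dolphin_prob": 0, "net_prob": 0, "blur_sigma": (0, 0)})
        busy = GeneratorConfig(**{**vars(base), "fixed_count": 60, "dolphin_prob": 0, "net_prob": 0, "blur_sigma": (0, 0)})
        img_q = render_scene(sample_scene(quiet, np.random.default_rng(0)))
        img_b = render_scene(sample_scene(busy, np.random.default_rng(0)))
        # background variability must grow with fish count under clutter
        assert img_b.pixels[:, :, 0].astype(float).std() > img_q.pixels[:, :, 0].astype(float).std()
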