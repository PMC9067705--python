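"""sonarcount: multi-task density regression for counting fish in sonar imagery.

Counts animals in noisy low-resolution frames by regressing each image to a
density map whose integral is the count, regularized by (a) a heteroscedastic
aleatoric-uncertainty term that learns a per-image noise variance, (b) a
self-supervised Siamese ranking task over automatically generated crop pairs
of unlabelled images, and (c) optional entropy-based batch reweighting for
class imbalance. Ships a synthetic sonar-scene generator so the whole
pipeline is testable without any field data.
"""

from .annotations import AnnotatedImage, PredictionRecord
from .density import (
    DensityMap,
    count_from_density,
    downsample_density,
    gaussian_kernel,
    points_to_density,
)
from .losses import ABLATIONS, AblationSpec, LossParts
from .model import CountingNetwork, ModelOutput, NetworkSpec, build_network, forward, forward_pair
from .pairs import Batch, RankedPair, generate_pairs, pairs_from_weak_labels, subregion_series
from .synthetic import GeneratorConfig, desk_scale_config, generate_dataset, render_scene, sample_scene
from .train import TrainConfig, TrainData, split_dataset, train_model, run_ablation_suite
from .evaluate import EvalReport, build_report, mae, rmse, nmae_by_subgroup

__version__ = "0.1.0"

__all__ = [
    "AnnotatedImage",
    "PredictionRecord",
    "DensityMap",
    "gaussian_kernel",
    "points_to_density",
    "count_from_density",
    "downsample_density",
    "ABLATIONS",
    "AblationSpec",
    "LossParts",
    "CountingNetwork",
    "ModelOutput",
    "NetworkSpec",
    "build_network",
    "forward",
    "forward_pair",
    "Batch",
    "RankedPair",
    "generate_pairs",
    "pairs_from_weak_labels",
    "subregion_series",
    "GeneratorConfig",
    "desk_scale_config",
    "generate_dataset",
    "render_scene",
    "sample_scene",
    "TrainConfig",
    "TrainData",
    "split_dataset",
    "train_model",
    "run_ablation_suite",
    "EvalReport",
    "build_report",
    "mae",
    "rmse",
    "nmae_by_subgroup",
]
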