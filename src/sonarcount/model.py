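"""Counting-network definition and forward contracts.

Architecture: a convolutional backbone downsampling by a factor ``d``
followed by a 1x1 convolution with 2 output channels. Channel 1 is the
predicted density map (integral = predicted count); channel 2 holds the
per-unit contributions to the predicted log noise variance (their spatial
sum *is* log sigma^2, clamped for overflow safety). The same parameters
serve the supervised counting branch and both Siamese ranking branches, so
adding the ranking task adds no parameters, and the second head channel
only doubles the (tiny) head.

Backbones:

* ``resnet50`` — the standard bottleneck ResNet-50 trunk (d=32, final
  width 2048), batch norm applied with frozen statistics. Optionally
  initialized from a local weights archive; random (Xavier) init otherwise.
* ``tiny`` — four 3x3 conv blocks, three of them strided (d=8, ~50k
  parameters), so the full training loop runs on one CPU in minutes. It
  honours the same contract (downsample by d, 2-channel head, shared
  weights); tests and desk-scale experiments run on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .annotations import AnnotatedImage
from .pairs import RankedPair

__all__ = [
    "NetworkSpec",
    "ModelOutput",
    "CountingNetwork",
    "build_network",
    "forward",
    "forward_pair",
    "save_checkpoint",
    "load_checkpoint",
]

LOGVAR_CLAMP = 10.0  # |log sigma^2| bound on the aggregated channel-2 sum

_DOWNSAMPLE = {"resnet50": 32, "tiny": 8}
_BACKBONE_WIDTH = {"resnet50": 2048, "tiny": 48}


@dataclass(frozen=True)
class NetworkSpec:
    backbone: str = "tiny"
    init: str = "xavier"  # "xavier" | "imagenet+xavier" | "checkpoint"
    checkpoint: str | None = None
    weights_asset: str | None = None  # local backbone weights archive, optional
    softplus_density: bool = False

    @property
    def downsample_factor(self) -> int:
        try:
            return _DOWNSAMPLE[self.backbone]
        except KeyError:
            raise ValueError(f"unknown backbone {self.backbone!r}") from None


@dataclass
class ModelOutput:
    """The two predicted grids plus their scalar aggregates."""

    density_hat: np.ndarray  # (H', W')
    logvar_map: np.ndarray  # (H', W')
    count_hat: float = field(init=False)
    log_sigma2: float = field(init=False)
    gap_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.count_hat = float(self.density_hat.sum())
        self.log_sigma2 = float(
            np.clip(self.logvar_map.sum(), -LOGVAR_CLAMP, LOGVAR_CLAMP)
        )
        self.gap_score = float(self.density_hat.mean())


def _build_tiny(rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(3, 24, 3, stride=2, padding=1, rng=rng, name="tiny1"),
        nn.ReLU(),
        nn.Conv2d(24, 48, 3, stride=2, padding=1, rng=rng, name="tiny2"),
        nn.ReLU(),
        nn.Conv2d(48, 48, 3, stride=2, padding=1, rng=rng, name="tiny3"),
        nn.ReLU(),
        nn.Conv2d(48, 48, 3, stride=1, padding=1, rng=rng, name="tiny4"),
        nn.ReLU(),
    )


def _build_resnet50(rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng, name="stem"),
        nn.BatchNorm2d(64, name="stem.bn"),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    in_ch = 64
    for stage, (width, blocks, stride) in enumerate(
        [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]
    ):
        for b in range(blocks):
            layers.append(
                nn.Bottleneck(
                    in_ch,
                    width,
                    stride=stride if b == 0 else 1,
                    rng=rng,
                    name=f"layer{stage + 1}.{b}",
                )
            )
            in_ch = width * nn.Bottleneck.expansion
    return nn.Sequential(*layers)


class CountingNetwork:
    """Backbone + 1x1 two-channel head with Siamese (shared) application."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.backbone == "tiny":
            self.backbone = _build_tiny(rng)
        elif spec.backbone == "resnet50":
            self.backbone = _build_resnet50(rng)
        else:
            raise ValueError(f"unknown backbone {spec.backbone!r}")
        width = _BACKBONE_WIDTH[spec.backbone]
        self.head = nn.Conv2d(width, 2, 1, rng=rng, name="head")
        self.d = spec.downsample_factor

    # -- parameter bookkeeping -------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.backbone.params() + self.head.params()

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    @property
    def head_param_fraction(self) -> float:
        head = sum(p.size for p in self.head.params())
        return head / self.n_params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, network needs {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for parameter {i}: checkpoint {arr.shape} vs "
                    f"network {p.value.shape}"
                )
            p.value = arr.astype(float).copy()

    def clone_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def restore_state(self, snapshot: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), snapshot):
            p.value = v.copy()

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"input must be (N, 3, H, W); got {x.shape}")
        if x.shape[2] % self.d or x.shape[3] % self.d:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} not divisible by d={self.d}"
            )

    def forward_raw(self, x: np.ndarray):
        """Return the (N, 2, H', W') head output and the backprop cache."""
        self._check_input(x)
        feats, bb_cache = self.backbone.forward(x)
        z, head_cache = self.head.forward(feats)
        sp_cache = None
        if self.spec.softplus_density:
            raw = z[:, 0]
            z = z.copy()
            z[:, 0] = np.log1p(np.exp(-np.abs(raw))) + np.maximum(raw, 0.0)
            sp_cache = raw
        return z, (bb_cache, head_cache, sp_cache)

    def backward_raw(self, dz: np.ndarray, cache) -> None:
        bb_cache, head_cache, sp_cache = cache
        if sp_cache is not None:
            dz = dz.copy()
            dz[:, 0] *= 1.0 / (1.0 + np.exp(-sp_cache))
        dfeats = self.head.backward(dz, head_cache)
        self.backbone.backward(dfeats, bb_cache)


def image_to_tensor(image: AnnotatedImage | np.ndarray) -> np.ndarray:
    """uint8 (H, W, 3) frame -> float (1, 3, H, W) in [0, 1]."""
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    x = pixels.astype(float) / 255.0
    return x.transpose(2, 0, 1)[None]


def images_to_tensor(images) -> np.ndarray:
    return np.concatenate([image_to_tensor(img) for img in images], axis=0)


def build_network(spec: NetworkSpec, seed: int = 0) -> CountingNetwork:
    """Build (and initialize) a counting network from a spec.

    Xavier init everywhere by default; ``init="checkpoint"`` loads a saved
    state; ``init="imagenet+xavier"`` loads backbone weights from a local
    ``weights_asset`` archive (never downloaded) and Xavier-initializes the
    head.
    """
    net = CountingNetwork(spec, seed=seed)
    if spec.init == "checkpoint":
        if not spec.checkpoint:
            raise ValueError("init='checkpoint' requires a checkpoint path")
        load_checkpoint(net, spec.checkpoint)
    elif spec.init == "imagenet+xavier":
        if not spec.weights_asset or not Path(spec.weights_asset).exists():
            raise FileNotFoundError(
                "imagenet init requires a local backbone weights archive "
                "(spec.weights_asset); none found"
            )
        with np.load(spec.weights_asset) as archive:
            bb_params = net.backbone.params()
            for i, p in enumerate(bb_params):
                arr = archive[f"p{i}"]
                if arr.shape != p.value.shape:
                    raise ValueError(
                        f"backbone weights asset mismatch at parameter {i}: "
                        f"{arr.shape} vs {p.value.shape}"
                    )
                p.value = arr.astype(float)
    elif spec.init != "xavier":
        raise ValueError(f"unknown init {spec.init!r}")
    return net


def forward(network: CountingNetwork, image: AnnotatedImage | np.ndarray) -> ModelOutput:
    """Inference on one image; deterministic (no stochastic layers)."""
    z, _ = network.forward_raw(image_to_tensor(image))
    return ModelOutput(density_hat=z[0, 0], logvar_map=z[0, 1])


def forward_pair(network: CountingNetwork, pair: RankedPair) -> tuple[float, float]:
    """GAP scores (p, p') of both pair members through the shared weights."""
    p = forward(network, pair.first).gap_score
    p_prime = forward(network, pair.second).gap_score
    return p, p_prime


def save_checkpoint(network: CountingNetwork, path: str | Path, meta: dict | None = None) -> None:
    """Save parameters (npz) plus a framework-neutral JSON manifest."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    manifest = {
        "backbone": network.spec.backbone,
        "downsample_factor": network.d,
        "n_params": network.n_params,
    } | (meta or {})
    manifest_path = path.with_suffix(".json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(network: CountingNetwork, path: str | Path) -> None:
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    with np.load(path) as archive:
        network.load_state({k: archive[k] for k in archive.files})
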