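"""Pluggable probabilistic segmenters: the predictor contract, a small
reference U-Net, analytic mock predictors, and the test-time-augmentation
(TTA) baseline path.

The ensemble machinery is model-agnostic: anything satisfying
:class:`PredictorContract` — a deterministic map from a 2-channel 2D image
to a per-pixel probability map of the same spatial shape — can be plugged
in.  The reference U-Net is a deliberately small encoder-decoder
(ReLU double convolutions, 2x2 max pooling, skip concatenations, nearest
upsampling, final 1x1 convolution + sigmoid) implemented directly in NumPy
and trained with Adam on binary cross-entropy; it is sized for desk-scale
experiments, not clinical workloads.

Mock predictors return analytically known probability maps derived from an
attached ground truth, so the projection/uncertainty machinery can be tested
without any training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import nn
from .geometry import forward_project, ProjectionGeometry, ProjectionCenter
from .images import BinaryMask, PlanarImage, ProbabilityStack, SphericalImage

__all__ = [
    "PredictorContract",
    "TrainConfig",
    "AugmentationSet",
    "Transform",
    "UNetPredictor",
    "MockPredictor",
    "build_reference_unet",
    "train",
    "mock_predictor",
    "default_augmentations",
    "predict_tta",
]


@runtime_checkable
class PredictorContract(Protocol):
    """A per-slice probabilistic segmenter.

    ``predict`` maps an image (2D or (H, W, C) array, ``PlanarImage`` or
    ``SphericalImage``) to a probability map in [0, 1] of the same spatial
    shape.  Repeated calls on identical input must give identical output
    for a fixed seed.
    """

    input_size: int
    deterministic_given_seed: bool

    def predict(self, image) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainConfig:
    """Reference-U-Net configuration; defaults are sized for CPU training
    on small synthetic cohorts (loss is always binary cross-entropy)."""

    depth: int = 3
    base_channels: int = 16
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "binary_cross_entropy"

    def __post_init__(self) -> None:
        if min(self.depth, self.base_channels, self.epochs, self.batch_size) < 1:
            raise ValueError("depth, base_channels, epochs, batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "binary_cross_entropy":
            raise ValueError("only binary cross-entropy is supported")


# ---------------------------------------------------------------------------
# reference U-Net


class _UNet:
    """Encoder-decoder with ReLU double convs, max pooling and skip concats."""

    def __init__(self, in_channels: int, depth: int, base: int, rng: np.random.Generator):
        self.depth = depth
        self.enc: list[tuple] = []
        self.pools = [nn.MaxPool2() for _ in range(depth)]
        c = in_channels
        ch = base
        for _ in range(depth):
            self.enc.append(self._double(c, ch, rng))
            c, ch = ch, ch * 2
        self.enc[0][0].compute_input_grad = False  # image gradient is unused
        self.bottleneck = self._double(c, ch, rng)
        self.ups: list[tuple] = []
        self.dec: list[tuple] = []
        for _ in range(depth):
            skip = ch // 2
            self.ups.append((nn.Upsample2(), nn.Conv2d(ch, skip, 3, rng), nn.ReLU()))
            self.dec.append(self._double(skip * 2, skip, rng))
            ch = skip
        self.head = nn.Conv2d(ch, 1, 1, rng)

    @staticmethod
    def _double(cin: int, cout: int, rng) -> tuple:
        return (nn.Conv2d(cin, cout, 3, rng), nn.ReLU(), nn.Conv2d(cout, cout, 3, rng), nn.ReLU())

    def params(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            out += blk[0].params() + blk[2].params()
        for _, conv, _ in self.ups:
            out += conv.params()
        out += self.head.params()
        return out

    @staticmethod
    def _run_block(blk, x, train):
        c1, r1, c2, r2 = blk
        return r2.forward(c2.forward(r1.forward(c1.forward(x, train), train), train), train)

    @staticmethod
    def _back_block(blk, g):
        c1, r1, c2, r2 = blk
        return c1.backward(r1.backward(c2.backward(r2.backward(g))))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = self._run_block(blk, x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self._run_block(self.bottleneck, x, train)
        self._concat_channels = []
        for (up, conv, relu), blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = relu.forward(conv.forward(up.forward(x, train), train), train)
            self._concat_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = self._run_block(blk, x, train)
        return self.head.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = []
        for (up, conv, relu), blk, cs in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._concat_channels)
        ):
            g = self._back_block(blk, g)
            gs, g = g[:, :cs], g[:, cs:]
            skip_grads.append(gs)
            g = up.backward(conv.backward(relu.backward(g)))
        g = self._back_block(self.bottleneck, g)
        # skip_grads were collected shallow-to-deep; encoder unwinds deep first
        for blk, pool, gs in zip(reversed(self.enc), reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g) + gs
            g = self._back_block(blk, g)


def _as_array(image) -> np.ndarray:
    if isinstance(image, (PlanarImage, SphericalImage)):
        arr = image.pixels
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


@dataclass
class UNetPredictor:
    """Reference U-Net satisfying :class:`PredictorContract`."""

    net: _UNet
    config: TrainConfig
    input_size: int
    deterministic_given_seed: bool = True
    loss_history: list[float] = field(default_factory=list)

    def predict(self, image) -> np.ndarray:
        arr = _as_array(image)
        if arr.shape[0] != self.input_size or arr.shape[1] != self.input_size:
            raise ValueError(
                f"predictor expects {self.input_size}^2 input, got {arr.shape[:2]}"
            )
        x = arr.transpose(2, 0, 1)[None].astype(np.float32)
        z = self.net.forward(x, train=False)[0, 0].astype(np.float64)
        return expit(z)

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for p, _ in self.net.params():
            h.update(p.tobytes())
        return h.hexdigest()


def build_reference_unet(
    config: TrainConfig, input_size: int = 256, in_channels: int = 2
) -> UNetPredictor:
    """An untrained reference U-Net with deterministically seeded weights.

    ``input_size`` must be divisible by ``2**depth`` so pooled feature maps
    stay integral.
    """
    if input_size % (2**config.depth) != 0:
        raise ValueError(
            f"input_size {input_size} not divisible by 2^depth = {2**config.depth}"
        )
    rng = np.random.default_rng(config.seed)
    net = _UNet(in_channels, config.depth, config.base_channels, rng)
    return UNetPredictor(net=net, config=config, input_size=input_size)


def train(
    predictor: UNetPredictor,
    images: Sequence[PlanarImage | SphericalImage | np.ndarray],
    masks: Sequence[BinaryMask | np.ndarray],
    config: TrainConfig | None = None,
) -> UNetPredictor:
    """Train with Adam on binary cross-entropy; logs per-epoch mean loss in
    ``predictor.loss_history``.  Deterministic given the config seed."""
    if config is None:
        config = predictor.config
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(masks):
        raise ValueError("images and masks length mismatch")
    xs = np.stack([_as_array(im).transpose(2, 0, 1) for im in images]).astype(np.float32)
    ys = np.stack(
        [
            (m.pixels if isinstance(m, BinaryMask) else np.asarray(m)).astype(np.float32)
            for m in masks
        ]
    )[:, None]
    opt = nn.Adam(predictor.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(xs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            # divergence surfaces as a non-finite loss below; the transient
            # overflow warnings on the way there carry no extra information
            with np.errstate(over="ignore", invalid="ignore"):
                z = predictor.net.forward(xs[idx], train=True)
                loss, grad = nn.bce_with_logits(z, ys[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            with np.errstate(over="ignore", invalid="ignore"):
                predictor.net.backward(grad)
            opt.step()
            losses.append(loss)
        predictor.loss_history.append(float(np.mean(losses)))
    return predictor


# ---------------------------------------------------------------------------
# mock predictors


@dataclass
class MockPredictor:
    """Analytic predictor derived from an attached ground truth.

    * ``perfect`` — returns the ground truth as {0, 1} probabilities;
    * ``blurred`` — ground truth smoothed by a Gaussian of the stated width;
    * ``noisy`` — ground truth plus seeded Gaussian noise, clipped to [0, 1].

    When called on a :class:`SphericalImage` the attached planar ground
    truth is forward-projected with that image's own geometry and center
    (nearest neighbor), so the mock behaves like an oracle segmenter in
    projected space.
    """

    mode: str
    gt: Optional[BinaryMask] = None
    blur_sigma: float = 2.0
    noise_scale: float = 0.2
    seed: int = 0
    input_size: int = 0
    deterministic_given_seed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "blurred", "noisy"):
            raise ValueError("mode must be perfect, blurred or noisy")

    def _gt_for(self, image) -> np.ndarray:
        if self.gt is None:
            raise ValueError("mock predictor has no attached ground truth")
        if isinstance(image, SphericalImage):
            proj = forward_project(
                PlanarImage(self.gt.pixels.astype(np.float64)),
                image.geometry,
                image.center,
                order=0,
            )
            return proj.pixels
        return self.gt.pixels.astype(np.float64)

    def predict(self, image) -> np.ndarray:
        base = self._gt_for(image)
        if self.mode == "perfect":
            return base
        if self.mode == "blurred":
            return np.clip(gaussian_filter(base, self.blur_sigma), 0.0, 1.0)
        # noisy: reproducible given (seed, image content)
        digest = hashlib.sha256(np.ascontiguousarray(base).tobytes()).digest()
        sub = int.from_bytes(digest[:4], "little")
        rng = np.random.default_rng((self.seed, sub))
        return np.clip(base + rng.normal(scale=self.noise_scale, size=base.shape), 0.0, 1.0)


def mock_predictor(
    mode: str,
    gt: BinaryMask | np.ndarray | None = None,
    blur_sigma: float = 2.0,
    noise_scale: float = 0.2,
    seed: int = 0,
    input_size: int = 0,
) -> MockPredictor:
    if gt is not None and not isinstance(gt, BinaryMask):
        gt = BinaryMask(np.asarray(gt))
    return MockPredictor(
        mode=mode,
        gt=gt,
        blur_sigma=blur_sigma,
        noise_scale=noise_scale,
        seed=seed,
        input_size=input_size,
    )


# ---------------------------------------------------------------------------
# test-time augmentation baseline


@dataclass(frozen=True)
class Transform:
    """An invertible grid transform (exact inverse on the pixel lattice)."""

    name: str
    apply: Callable[[np.ndarray], np.ndarray]
    invert: Callable[[np.ndarray], np.ndarray]


def _rot(k: int) -> Transform:
    return Transform(
        name=f"rot{90*k}",
        apply=lambda a, k=k: np.rot90(a, k, axes=(0, 1)).copy(),
        invert=lambda a, k=k: np.rot90(a, -k, axes=(0, 1)).copy(),
    )


def _shift(dr: int, dc: int) -> Transform:
    return Transform(
        name=f"shift({dr},{dc})",
        apply=lambda a: np.roll(a, (dr, dc), axis=(0, 1)),
        invert=lambda a: np.roll(a, (-dr, -dc), axis=(0, 1)),
    )


def default_augmentations() -> "AugmentationSet":
    """Identity, three rotations, two flips, two +/-8 px translations —
    eight invertible transforms in total."""
    t = [
        Transform("identity", lambda a: a, lambda a: a),
        _rot(1),
        _rot(2),
        _rot(3),
        Transform(
            "fliplr", lambda a: a[:, ::-1].copy(), lambda a: a[:, ::-1].copy()
        ),
        Transform(
            "flipud", lambda a: a[::-1].copy(), lambda a: a[::-1].copy()
        ),
        _shift(8, 0),
        _shift(0, -8),
    ]
    return AugmentationSet(transforms=tuple(t))


@dataclass(frozen=True)
class AugmentationSet:
    transforms: tuple[Transform, ...]

    def __post_init__(self) -> None:
        if not any(t.name == "identity" for t in self.transforms):
            raise ValueError("augmentation set must include the identity transform")

    @property
    def count(self) -> int:
        return len(self.transforms)


def predict_tta(
    predictor: PredictorContract,
    image: PlanarImage,
    augmentations: AugmentationSet | None = None,
) -> ProbabilityStack:
    """Baseline ensemble: transform -> predict -> inverse transform for each
    augmentation; the resulting stack feeds the identical aggregation and
    scoring path as the spherical-projection ensemble."""
    if augmentations is None:
        augmentations = default_augmentations()
    arr = _as_array(image)
    maps = []
    for t in augmentations.transforms:
        aug = t.apply(arr)
        prob = predictor.predict(aug)
        maps.append(t.invert(prob))
    return ProbabilityStack(maps=np.stack(maps), centers=None)
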