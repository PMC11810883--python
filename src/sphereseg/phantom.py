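"""Synthetic 2-channel MRI-like slice phantoms with ground truth.

Each phantom emulates the structure a contrast-enhancing extra-axial tumor
presents on co-registered T1 / T1ce slices:

* smooth background "anatomy" shared by both channels;
* one or more bright quasi-elliptical lesions, strongly enhanced on the
  T1ce-like channel and nearly iso-intense on the T1-like channel;
* optionally a thin curvilinear "dural tail" appendage attached to a lesion
  boundary — part of the ground truth, deliberately hard to delineate;
* vessel-like bright curvilinear distractors on the T1ce channel that are
  *not* part of the ground truth;
* mild smoothing of the lesion signal (boundary ambiguity) and additive
  Gaussian noise.

The ground truth is the union of lesion and tail supports.  Everything is
deterministic given the spec's seed.  The phantom is an explicit synthetic
stand-in: its realism extends only to the structural features the
segmentation/uncertainty machinery exercises, not to real brain anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .images import BinaryMask, PlanarImage

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "split_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice generator.

    Intensities are on a nominal [0, 1] dynamic range.  ``contrast_ratio``
    is the additive T1ce lesion enhancement relative to that range; the
    T1-like channel receives only a faint (0.1) lesion signal.
    """

    grid_size: int = 192
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (8.0, 24.0)
    tail_probability: float = 0.72
    tail_length_range: tuple[float, float] = (10.0, 28.0)
    tail_width: float = 2.0
    n_vessels: int = 3
    vessel_intensity: float = 0.8
    noise_sigma: float = 0.05
    contrast_ratio: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise ValueError("grid_size must be at least 32")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.lesion_radius_range[0] < 2:
            raise ValueError("lesion radii must be >= 2 px")
        if not (0 <= self.tail_probability <= 1):
            raise ValueError("tail_probability must lie in [0, 1]")


@dataclass
class PhantomCase:
    """A generated slice: 2-channel image, ground truth, and provenance."""

    image: PlanarImage
    gt: BinaryMask
    metadata: dict = field(default_factory=dict)


def _smooth_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Low-frequency anatomy-like background on roughly [0.15, 0.45]."""
    field_ = gaussian_filter(rng.normal(size=(n, n)), sigma=n / 10.0)
    lo, hi = field_.min(), field_.max()
    span = hi - lo if hi > lo else 1.0
    return 0.15 + 0.30 * (field_ - lo) / span


def _draw_tail(
    rng: np.random.Generator,
    lesion: np.ndarray,
    center: tuple[float, float],
    spec: PhantomSpec,
) -> np.ndarray:
    """A thin curved appendage starting on the lesion boundary, growing
    outward with a gentle random curvature; dilated to ``tail_width``."""
    n = spec.grid_size
    angle = rng.uniform(0, 2 * math.pi)
    length = rng.uniform(*spec.tail_length_range)
    # walk outward from the lesion boundary along `angle`, curving slowly
    r0 = 1.0
    cr, cc = center
    while True:
        rr = int(round(cr + r0 * math.sin(angle)))
        cc_ = int(round(cc + r0 * math.cos(angle)))
        if not (0 <= rr < n and 0 <= cc_ < n) or not lesion[rr, cc_]:
            break
        r0 += 1.0
    curvature = rng.uniform(-0.04, 0.04)
    pts = []
    a = angle
    # start a couple of pixels inside the lesion so the tail stays attached
    r0 = max(1.0, r0 - 2.0)
    r, c = cr + r0 * math.sin(a), cc + r0 * math.cos(a)
    pts.append((int(round(r)), int(round(c))))
    for _ in range(int(length) + 2):
        r += math.sin(a)
        c += math.cos(a)
        a += curvature
        if not (1 <= r < n - 1 and 1 <= c < n - 1):
            break
        pts.append((int(round(r)), int(round(c))))
    tail = np.zeros((n, n), dtype=bool)
    for rr, cc_ in pts:
        tail[rr, cc_] = True
    it = max(1, int(round(spec.tail_width / 2)))
    tail = binary_dilation(tail, iterations=it)
    return tail


def _draw_vessel(rng: np.random.Generator, n: int, avoid: np.ndarray) -> np.ndarray:
    """A bright curvilinear distractor (random smooth walk, width ~1-2 px)
    avoiding the ground-truth support."""
    vessel = np.zeros((n, n), dtype=bool)
    r = rng.uniform(0.15 * n, 0.85 * n)
    c = rng.uniform(0.15 * n, 0.85 * n)
    a = rng.uniform(0, 2 * math.pi)
    curvature = rng.uniform(-0.08, 0.08)
    length = int(rng.uniform(0.2 * n, 0.5 * n))
    for _ in range(length):
        r += math.sin(a)
        c += math.cos(a)
        a += curvature + rng.normal(0, 0.02)
        ri, ci = int(round(r)), int(round(c))
        if not (1 <= ri < n - 1 and 1 <= ci < n - 1):
            break
        vessel[ri, ci] = True
    vessel = binary_dilation(vessel) & ~avoid
    return vessel


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one 2-channel slice with ground truth, deterministically
    from ``spec.seed``.

    Raises ``RuntimeError`` naming the constraint if lesion placement fails
    after bounded retries (e.g. radii too large for the field of view).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    background = _smooth_background(rng, n)

    gt = np.zeros((n, n), dtype=bool)
    lesion_soft = np.zeros((n, n), dtype=np.float64)
    realized = []
    for li in range(spec.n_lesions):
        placed = False
        for _ in range(50):
            ra = rng.uniform(*spec.lesion_radius_range)
            rb = rng.uniform(*spec.lesion_radius_range)
            rot = rng.uniform(0, math.pi)
            margin = max(ra, rb) + max(spec.tail_length_range) + 2
            if 2 * margin >= n:
                continue
            cr = rng.uniform(margin, n - margin)
            cc = rng.uniform(margin, n - margin)
            rr, cc_ = draw_ellipse(cr, cc, ra, rb, shape=(n, n), rotation=rot)
            cand = np.zeros((n, n), dtype=bool)
            cand[rr, cc_] = True
            if (cand & gt).any():
                continue
            lesion = cand
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place lesion inside the field of view: "
                "lesion_radius_range + tail_length_range too large for grid_size"
            )
        tail = np.zeros((n, n), dtype=bool)
        has_tail = rng.uniform() < spec.tail_probability
        if has_tail:
            tail = _draw_tail(rng, lesion, (cr, cc), spec)
        gt |= lesion | tail
        lesion_soft += (lesion | tail).astype(np.float64)
        realized.append(
            {
                "center": (cr, cc),
                "radii": (ra, rb),
                "rotation": rot,
                "has_tail": bool(has_tail),
                "lesion_area_px": int(lesion.sum()),
                "tail_area_px": int(tail.sum()),
            }
        )

    vessels = np.zeros((n, n), dtype=bool)
    for _ in range(spec.n_vessels):
        vessels |= _draw_vessel(rng, n, avoid=gt)

    # Slight smoothing of the lesion signal creates boundary ambiguity.
    lesion_signal = gaussian_filter(np.clip(lesion_soft, 0, 1), sigma=1.0)
    t1 = background + 0.1 * lesion_signal
    t1ce = (
        background
        + spec.contrast_ratio * lesion_signal
        + spec.vessel_intensity * spec.contrast_ratio * gaussian_filter(vessels.astype(float), 0.5)
    )
    noise = rng.normal(scale=spec.noise_sigma, size=(2, n, n))
    t1 = t1 + noise[0]
    t1ce = t1ce + noise[1]
    image = np.stack([t1, t1ce], axis=-1)

    return PhantomCase(
        image=PlanarImage(pixels=image),
        gt=BinaryMask(gt.astype(np.uint8)),
        metadata={"spec": spec, "lesions": realized, "vessel_area_px": int(vessels.sum())},
    )


def generate_cohort(
    spec: PhantomSpec,
    n_cases: int,
    base_seed: int = 0,
    slices_per_subject: int = 3,
) -> tuple[list[PhantomCase], list[str]]:
    """A reproducible list of cases with subject IDs for grouped splitting.

    Per-case seeds derive from ``base_seed``; consecutive slices share a
    subject ID (``slices_per_subject`` each) so per-subject train/test
    splitting can be exercised.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    seed_rng = np.random.default_rng(base_seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_cases)
    cases = [generate_phantom(replace(spec, seed=int(s))) for s in seeds]
    subjects = [f"subj{(i // slices_per_subject):04d}" for i in range(n_cases)]
    for case, subj in zip(cases, subjects):
        case.metadata["subject_id"] = subj
    return cases, subjects


def split_cohort(
    cases: list[PhantomCase],
    subjects: list[str],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Per-subject randomized split: all slices of a subject land on the
    same side.  Returns (train_indices, test_indices)."""
    if len(cases) != len(subjects):
        raise ValueError("cases and subjects length mismatch")
    uniq = sorted(set(subjects))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    n_train_subj = int(round(train_fraction * len(uniq)))
    train_subj = {uniq[i] for i in order[:n_train_subj]}
    train_idx = [i for i, s in enumerate(subjects) if s in train_subj]
    test_idx = [i for i, s in enumerate(subjects) if s not in train_subj]
    return train_idx, test_idx
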