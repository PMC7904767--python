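"""Synthetic capsule-endoscopy frame and case generation with exact ground truth.

Small-bowel capsule frames show pink mucosa that may be partially obscured
by bubbles (bright foam), bile (yellow-green opaque fluid) or debris (dark
solid residue).  This module renders desk-scale synthetic frames in which
the obscured region is known exactly (a boolean mask), so every downstream
stage — per-frame scoring, tertile grading, adequacy ROC — can be checked
against ground truth.

The per-frame cleansing score is a 5-step scale on the fraction of visible
mucosa: 5 when more than 90% is visible, down to 1 when less than 25% is
visible.  Interior bins are equal-width quartiles of [0, 1) below 0.90
(see :func:`visible_fraction_to_score`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CATEGORIES",
    "FrameSpec",
    "SyntheticFrame",
    "CaseSpec",
    "SyntheticCase",
    "visible_fraction_to_score",
    "generate_frame",
    "generate_case",
]

CATEGORIES = ("clean", "bubble", "bile", "debris")

#: score thresholds on the visible-mucosa fraction: score = 1 + #{t : fraction >= t}
SCORE_THRESHOLDS = (0.25, 0.50, 0.75, 0.90)

# Default palette (RGB, 0-255).  Configurable via generate_frame(palette=...).
DEFAULT_PALETTE = {
    "mucosa": (196, 112, 96),
    "fold": (142, 66, 58),
    "bubble": (228, 224, 214),
    "bile": (176, 166, 52),
    "debris": (74, 48, 30),
}

MIN_IMAGE_SIZE = 16


def visible_fraction_to_score(fraction: float) -> int:
    """Map a visible-mucosa fraction in [0, 1] to the 5-step cleansing score.

    Score 5 requires more than 90% visible mucosa (>= 0.90 here, so that a
    fully clean frame scores 5); score 1 means less than 25% visible.  The
    interior bins are half-open and equal width: [0.25, 0.50) -> 2,
    [0.50, 0.75) -> 3, [0.75, 0.90) -> 4.
    """
    f = float(fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"visible fraction must lie in [0, 1], got {fraction!r}")
    return 1 + sum(f >= t for t in SCORE_THRESHOLDS)


@dataclass(frozen=True)
class FrameSpec:
    """Recipe for one synthetic frame.

    Parameters
    ----------
    image_size:
        Pixels per side of the square frame; at least 16.  Default 64.
    visible_fraction:
        Target fraction of mucosa left unobscured, in [0, 1].
    category:
        Obscuring material: ``clean``, ``bubble``, ``bile`` or ``debris``.
        A ``clean`` frame must request at least 0.90 visible.
    seed:
        Nonnegative integer seed; fixed seed gives bit-identical frames.
    """

    visible_fraction: float = 1.0
    category: str = "clean"
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < MIN_IMAGE_SIZE:
            raise ValueError(
                f"image_size must be >= {MIN_IMAGE_SIZE} px, got {self.image_size}"
            )
        if not 0.0 <= self.visible_fraction <= 1.0:
            raise ValueError(
                f"visible_fraction must lie in [0, 1], got {self.visible_fraction}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.category == "clean" and self.visible_fraction < 0.90:
            raise ValueError("a 'clean' frame must have visible_fraction >= 0.90")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass
class SyntheticFrame:
    """A rendered frame plus its exact ground truth."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, True where mucosa is visible
    true_visible_fraction: float
    true_score: int
    category: str
    timestamp_s: float = 0.0
    frame_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("pixels and mask must share spatial dimensions")


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Perlin-style value noise: white noise blurred to correlation length sigma."""
    z = gaussian_filter(rng.standard_normal((n, n)), sigma=sigma, mode="wrap")
    s = z.std()
    return z / s if s > 0 else z


def _render_mucosa(rng: np.random.Generator, n: int, palette: dict) -> np.ndarray:
    """Reddish-pink textured mucosa with darker fold lines."""
    base = np.asarray(palette["mucosa"], dtype=float)
    fold = np.asarray(palette["fold"], dtype=float)
    shade = _smooth_noise(rng, n, sigma=n / 12.0)  # broad illumination
    grain = _smooth_noise(rng, n, sigma=n / 48.0)  # fine texture
    img = base[None, None, :] * (1.0 + 0.10 * shade + 0.05 * grain)[:, :, None]
    # folds: thin level sets of an independent low-frequency field
    folds = _smooth_noise(rng, n, sigma=n / 8.0)
    for level in (-0.8, 0.0, 0.8):
        w = np.clip(1.0 - np.abs(folds - level) / 0.12, 0.0, 1.0)
        img = img * (1 - 0.6 * w[:, :, None]) + fold[None, None, :] * 0.6 * w[:, :, None]
    return img


def _obscuration_field(rng: np.random.Generator, n: int, category: str) -> np.ndarray:
    """Scalar field whose upper level sets shape the obscured region.

    The field's geometry mimics the material: bubbles cluster as circular
    bumps, bile pools as large smooth washes, debris scatters as irregular
    mid-scale blobs, and residue on a clean frame is fine specks.
    """
    if category == "bubble":
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        field = np.full((n, n), -np.inf)
        n_bub = max(6, n // 4)
        cx = rng.uniform(0, n, n_bub)
        cy = rng.uniform(0, n, n_bub)
        r = rng.uniform(n / 24.0, n / 6.0, n_bub)
        for k in range(n_bub):
            field = np.maximum(field, r[k] - np.hypot(xx - cx[k], yy - cy[k]))
        return field + 0.3 * _smooth_noise(rng, n, sigma=n / 16.0)
    if category == "bile":
        return _smooth_noise(rng, n, sigma=n / 5.0)
    if category == "debris":
        return _smooth_noise(rng, n, sigma=n / 14.0)
    # clean: rare fine specks
    return _smooth_noise(rng, n, sigma=n / 40.0)


def _render_obscuration(
    rng: np.random.Generator,
    img: np.ndarray,
    obscured: np.ndarray,
    field: np.ndarray,
    category: str,
    palette: dict,
) -> np.ndarray:
    """Paint the obscuring material over the obscured pixels of img."""
    out = img.copy()
    if not obscured.any():
        return out
    n = img.shape[0]
    depth = field - field[obscured].min()
    dmax = depth[obscured].max()
    rel = depth / dmax if dmax > 0 else np.zeros_like(depth)
    if category == "bubble":
        col = np.asarray(palette["bubble"], dtype=float)
        shine = 0.75 + 0.25 * rel  # brighter towards bubble centres
        out[obscured] = (col[None, :] * shine[obscured, None]).clip(0, 255)
    elif category == "bile":
        col = np.asarray(palette["bile"], dtype=float)
        # translucent wash: opaque enough to hide mucosal detail
        alpha = 0.72 + 0.18 * rel[obscured, None]
        out[obscured] = out[obscured] * (1 - alpha) + col[None, :] * alpha
    elif category == "debris":
        col = np.asarray(palette["debris"], dtype=float)
        speck = 1.0 + 0.25 * rng.standard_normal(img.shape[:2])
        out[obscured] = (col[None, :] * speck[obscured, None]).clip(0, 255)
    else:  # clean residue: faint pale specks
        col = np.asarray(palette["bubble"], dtype=float)
        out[obscured] = out[obscured] * 0.35 + col[None, :] * 0.65
    return out


def generate_frame(spec: FrameSpec) -> SyntheticFrame:
    """Render one synthetic frame deterministically from its spec.

    The obscured region is the set of pixels with the largest values of a
    category-shaped random field; its size is the rounded pixel count
    nearest ``(1 - visible_fraction) * n_pixels``, so the achieved visible
    fraction matches the request to within half a pixel (far inside the
    +/-0.02 contract) and ``mask.mean()`` equals ``true_visible_fraction``
    exactly by construction.
    """
    palette = DEFAULT_PALETTE
    n = spec.image_size
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    img = _render_mucosa(rng, n, palette)

    n_pix = n * n
    k = int(round((1.0 - spec.visible_fraction) * n_pix))
    field = _obscuration_field(rng, n, spec.category)
    obscured = np.zeros((n, n), dtype=bool)
    if k > 0:
        # stable ordering makes ties deterministic
        order = np.argsort(-field, axis=None, kind="stable")[:k]
        obscured.flat[order] = True
    img = _render_obscuration(rng, img, obscured, field, spec.category, palette)

    mask = ~obscured
    tvf = float(mask.mean())
    return SyntheticFrame(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        mask=mask,
        true_visible_fraction=tvf,
        true_score=visible_fraction_to_score(tvf),
        category=spec.category,
    )


@dataclass(frozen=True)
class CaseSpec:
    """Recipe for one synthetic examination (an ordered frame sequence).

    ``tertile_invisibility`` sets, per proximal/middle/distal tertile, the
    target fraction of frames whose visible mucosa falls below 0.5 (the
    frames a clinical grader counts as "invisible").  ``score_profile``
    gives the per-tertile sampling ranges for the visible fraction of
    visible and invisible frames.
    """

    n_frames: int = 30
    tertile_invisibility: tuple[float, float, float] = (0.0, 0.0, 0.0)
    score_profile: tuple[tuple[float, float], tuple[float, float]] = (
        (0.55, 1.0),  # visible frames: uniform range of visible_fraction
        (0.05, 0.45),  # invisible frames
    )
    image_size: int = 64
    frame_interval_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("a case needs at least 3 frames (one per tertile)")
        if len(self.tertile_invisibility) != 3:
            raise ValueError("tertile_invisibility must have exactly 3 entries")
        for v in self.tertile_invisibility:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"tertile invisibility must lie in [0, 1], got {v}")
        lo_v, hi_v = self.score_profile[0]
        lo_i, hi_i = self.score_profile[1]
        if not (0.5 <= lo_v <= hi_v <= 1.0 and 0.0 <= lo_i <= hi_i < 0.5):
            raise ValueError("score_profile ranges must respect the 0.5 visibility split")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


def tertile_sizes(n_frames: int) -> tuple[int, int, int]:
    """Split n frames into three contiguous tertiles; earlier tertiles take remainders."""
    base, rem = divmod(n_frames, 3)
    return tuple(base + (1 if t < rem else 0) for t in range(3))  # type: ignore[return-value]


@dataclass
class SyntheticCase:
    """An ordered synthetic examination with exact per-frame ground truth."""

    case_id: str
    frames: list[SyntheticFrame]
    tertile_of: list[int] = field(default_factory=list)  # 1, 2 or 3 per frame

    @property
    def visible_fractions(self) -> np.ndarray:
        return np.array([f.true_visible_fraction for f in self.frames])

    @property
    def true_scores(self) -> np.ndarray:
        return np.array([f.true_score for f in self.frames])


def generate_case(spec: CaseSpec, case_id: str = "case", render: bool = True) -> SyntheticCase:
    """Generate one examination's frame sequence with ground truth.

    Within each tertile, the number of invisible frames (visible fraction
    below 0.5) is the count nearest ``tertile_invisibility * tertile_size``
    and their positions within the tertile are shuffled; timestamps increase
    strictly.  With ``render=False`` only the ground truth is materialised
    (the pixel grids are empty), which makes large grading cohorts cheap.

    All randomness descends from ``spec.seed`` through a splittable seed
    tree, so per-frame streams are independent and the whole case is
    reproducible bit-for-bit.
    """
    root = np.random.SeedSequence(spec.seed)
    layout_ss, frames_ss = root.spawn(2)
    rng = np.random.default_rng(layout_ss)
    sizes = tertile_sizes(spec.n_frames)
    (lo_v, hi_v), (lo_i, hi_i) = spec.score_profile

    fractions: list[float] = []
    tertile_of: list[int] = []
    for t, size in enumerate(sizes):
        n_inv = int(round(spec.tertile_invisibility[t] * size))
        flags = np.zeros(size, dtype=bool)
        flags[:n_inv] = True
        rng.shuffle(flags)
        for inv in flags:
            if inv:
                fractions.append(float(rng.uniform(lo_i, hi_i)))
            else:
                fractions.append(float(rng.uniform(lo_v, hi_v)))
            tertile_of.append(t + 1)

    frame_seeds = frames_ss.generate_state(spec.n_frames, dtype=np.uint32)
    frames: list[SyntheticFrame] = []
    for i, vf in enumerate(fractions):
        if vf >= 0.95:
            category = "clean"
        else:
            category = CATEGORIES[1 + int(rng.integers(3))]
        ts = (i + 1) * spec.frame_interval_s + float(rng.uniform(0, 0.5 * spec.frame_interval_s))
        fid = f"{case_id}_f{i:05d}"
        if render:
            frame = generate_frame(
                FrameSpec(
                    visible_fraction=vf,
                    category=category,
                    image_size=spec.image_size,
                    seed=int(frame_seeds[i]),
                )
            )
        else:
            n = spec.image_size
            # ground-truth-only frame: uniform mask with the rounded pixel count
            k = int(round((1.0 - vf) * n * n))
            mask = np.ones(n * n, dtype=bool)
            mask[:k] = False
            mask = mask.reshape(n, n)
            tvf = float(mask.mean())
            frame = SyntheticFrame(
                pixels=np.zeros((n, n, 3), dtype=np.uint8),
                mask=mask,
                true_visible_fraction=tvf,
                true_score=visible_fraction_to_score(tvf),
                category=category,
            )
        frame.timestamp_s = ts
        frame.frame_id = fid
        frames.append(frame)

    # enforce strictly increasing timestamps (jitter cannot cross the next slot,
    # but guard against pathological float equality anyway)
    for i in range(1, len(frames)):
        if frames[i].timestamp_s <= frames[i - 1].timestamp_s:
            frames[i].timestamp_s = np.nextafter(frames[i - 1].timestamp_s, np.inf)

    return SyntheticCase(case_id=case_id, frames=frames, tertile_of=tertile_of)
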