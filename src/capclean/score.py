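"""Expected-value cleansing scores and their aggregation to segments and cases.

A frame classifier emits a softmax probability vector over the five
cleansing grades; the frame's cleansing score is the probability-weighted
mean of the grade indices,

    score(I) = sum_{i=1..5} i * p_i(I),

a real number in [1, 5] that preserves the classifier's uncertainty between
adjacent grades.  Case and segment scores are plain frame averages on the
same 1.0-5.0 scale (all frames pooled for the case average, with per-segment
means reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "validate_probability_vector",
    "frame_score",
    "split_tertiles",
    "average_score",
    "CaseScoreSummary",
    "score_case",
]

_GRADES = np.arange(1.0, 6.0)
_NORM_TOL = 1e-6


def validate_probability_vector(p: Sequence[float]) -> np.ndarray:
    """Check that p is 5 nonnegative probabilities summing to 1 within 1e-6."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"probability vector must have 5 entries, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("probability vector entries must be nonnegative")
    if abs(arr.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"probability vector must sum to 1 (got {arr.sum():.8f})")
    return arr


def frame_score(p: Sequence[float]) -> float:
    """Expected-value cleansing score sum(i * p_i) for one frame, in [1, 5]."""
    arr = validate_probability_vector(p)
    return float(arr @ _GRADES)


def split_tertiles(timestamps: Sequence[float]) -> np.ndarray:
    """Assign time-ordered frames to three contiguous, equal-count tertiles.

    Sizes differ by at most one; when the frame count is not divisible by 3
    the earlier tertiles take the extra frames.  Returns an array of tertile
    indices (1, 2 or 3), one per frame.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size < 3:
        raise ValueError(f"a case needs at least 3 frames to split, got {ts.size}")
    if not (np.diff(ts) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    base, rem = divmod(ts.size, 3)
    sizes = [base + (1 if t < rem else 0) for t in range(3)]
    return np.repeat([1, 2, 3], sizes)


def average_score(scores: Sequence[float]) -> float:
    """Mean cleansing score of a scope (segment or whole case), full precision."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty score list")
    return float(arr.mean())


@dataclass(frozen=True)
class CaseScoreSummary:
    """Per-segment and pooled average cleansing scores of one examination."""

    case_id: str
    per_segment_mean: tuple[float, float, float]
    case_mean: float
    n_frames_per_segment: tuple[int, int, int]
    n_frames: int


def score_case(
    case_id: str,
    frame_scores: Sequence[float],
    tertile_of: Sequence[int],
) -> CaseScoreSummary:
    """Aggregate per-frame scores into segment means and the pooled case mean."""
    scores = np.asarray(frame_scores, dtype=float)
    terts = np.asarray(tertile_of)
    if scores.size != terts.size:
        raise ValueError("frame_scores and tertile_of must have equal length")
    seg_means = []
    seg_n = []
    for t in (1, 2, 3):
        seg = scores[terts == t]
        if seg.size == 0:
            raise ValueError(f"tertile {t} of case {case_id!r} is empty")
        seg_means.append(float(seg.mean()))
        seg_n.append(int(seg.size))
    return CaseScoreSummary(
        case_id=case_id,
        per_segment_mean=tuple(seg_means),  # type: ignore[arg-type]
        case_mean=average_score(scores),
        n_frames_per_segment=tuple(seg_n),  # type: ignore[arg-type]
        n_frames=int(scores.size),
    )
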