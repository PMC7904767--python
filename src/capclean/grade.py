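"""The validated quantitative clinical grading scale for small-bowel preparation.

A frame counts as *invisible* when more than 50% of its mucosa is hidden by
bubbles, bile or debris.  Each of the three time-ordered tertile segments of
an examination receives a segmental grade 1-4 from its fraction of invisible
frames (grade 1 below 5%, grade 4 above 25%); the three grades sum to an
overall grade A (3-5), B (6-8) or C (9-12), and preparation is clinically
adequate for grades A and B only.

Bin boundaries at exactly 5%, 15% and 25% are resolved left-closed /
right-open (0.05 -> grade 2, 0.25 -> grade 4); a frame with exactly 50%
visible mucosa is *not* invisible (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GradingResult",
    "frame_invisible",
    "segmental_grade",
    "overall_grade",
    "adequacy",
    "grade_case",
]

#: segmental-grade thresholds on the invisible-frame fraction
_GRADE_EDGES = (0.05, 0.15, 0.25)


@dataclass(frozen=True)
class GradingResult:
    """Clinical grading of one examination, with all intermediate values."""

    invisibility_fraction: tuple[float, float, float]
    segmental_grade: tuple[int, int, int]
    overall_sum: int
    overall_grade: str  # "A", "B" or "C"
    adequate: bool


def frame_invisible(visible_fraction: float) -> bool:
    """True when more than 50% of the frame's mucosa is invisible."""
    f = float(visible_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"visible fraction must lie in [0, 1], got {visible_fraction!r}")
    return f < 0.5


def segmental_grade(invisibility_fraction: float) -> int:
    """Grade 1-4 from a segment's fraction of invisible frames."""
    f = float(invisibility_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(
            f"invisibility fraction must lie in [0, 1], got {invisibility_fraction!r}"
        )
    return 1 + sum(f >= e for e in _GRADE_EDGES)


def overall_grade(segmental_grades: Sequence[int]) -> str:
    """Overall grade A/B/C from the sum of the three segmental grades."""
    grades = tuple(int(g) for g in segmental_grades)
    if len(grades) != 3:
        raise ValueError(f"expected 3 segmental grades, got {len(grades)}")
    for g in grades:
        if not 1 <= g <= 4:
            raise ValueError(f"segmental grades must lie in 1..4, got {g}")
    total = sum(grades)
    if total <= 5:
        return "A"
    if total <= 8:
        return "B"
    return "C"


def adequacy(grade: str) -> bool:
    """Clinically adequate preparation means overall grade A or B."""
    if grade not in ("A", "B", "C"):
        raise ValueError(f"overall grade must be A, B or C, got {grade!r}")
    return grade in ("A", "B")


def grade_case(
    visible_fractions: Sequence[float],
    tertile_of: Sequence[int],
    frame_ids: Sequence[str] | None = None,
) -> GradingResult:
    """Grade one examination from per-frame visible-mucosa fractions.

    Parameters
    ----------
    visible_fractions:
        Per-frame visible fraction in [0, 1]; ``None``/NaN entries are
        rejected with the offending frame named.
    tertile_of:
        Per-frame tertile assignment (1, 2 or 3), a valid partition in which
        every tertile is nonempty.
    frame_ids:
        Optional identifiers used in error messages.
    """
    vf = list(visible_fractions)
    terts = list(tertile_of)
    if len(vf) != len(terts):
        raise ValueError("visible_fractions and tertile_of must have equal length")
    ids = list(frame_ids) if frame_ids is not None else [f"frame {i}" for i in range(len(vf))]
    for fid, v in zip(ids, vf):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing visible_fraction annotation for {fid}")

    inv_frac = []
    for t in (1, 2, 3):
        seg = [frame_invisible(v) for v, tt in zip(vf, terts) if tt == t]
        if not seg:
            raise ValueError(f"tertile {t} contains no frames")
        inv_frac.append(sum(seg) / len(seg))
    seg_grades = tuple(segmental_grade(f) for f in inv_frac)
    og = overall_grade(seg_grades)
    return GradingResult(
        invisibility_fraction=tuple(inv_frac),  # type: ignore[arg-type]
        segmental_grade=seg_grades,  # type: ignore[arg-type]
        overall_sum=sum(seg_grades),
        overall_grade=og,
        adequate=adequacy(og),
    )
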