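"""Frame-manifest reading and writing.

A manifest is a UTF-8 comma-separated table, one row per still frame, with
required columns ``case_id``, ``frame_id``, ``path``, ``timestamp_s``.
Synthetic manifests additionally carry the ground-truth columns
``visible_fraction``, ``true_score`` and ``category``.  Unknown extra
columns are preserved verbatim.  Frames are grouped by case and sorted by
timestamp, so row order in the file does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .score import split_tertiles
from .synth import SyntheticCase

__all__ = [
    "REQUIRED_COLUMNS",
    "GROUND_TRUTH_COLUMNS",
    "CaseRecord",
    "read_manifest",
    "write_manifest",
    "manifest_from_cases",
    "write_case_frames",
]

REQUIRED_COLUMNS = ("case_id", "frame_id", "path", "timestamp_s")
#: columns that, when present, carry simulator ground truth
GROUND_TRUTH_COLUMNS = ("visible_fraction", "true_score", "category")


@dataclass
class CaseRecord:
    """One examination: its frames (timestamp-sorted) and tertile assignment."""

    case_id: str
    frames: pd.DataFrame  # one row per frame, sorted by timestamp_s
    tertile_of: np.ndarray  # 1/2/3 per frame, contiguous in time order

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def load_pixels(self, root: Path | str | None = None) -> np.ndarray:
        """Load this case's frames from disk as an (N, H, W, 3) uint8 array."""
        root = Path(root) if root is not None else Path(".")
        imgs = []
        for p in self.frames["path"]:
            path = Path(p)
            if not path.is_absolute():
                path = root / path
            imgs.append(np.asarray(Image.open(path).convert("RGB")))
        return np.stack(imgs)


def read_manifest(path: Path | str) -> list[CaseRecord]:
    """Read a manifest CSV into per-case records.

    Raises a schema error naming any missing required column, and rejects
    duplicate frame ids within a case.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required column(s): {', '.join(missing)}")
    records = []
    for case_id, group in df.groupby("case_id", sort=True):
        dup = group["frame_id"][group["frame_id"].duplicated()]
        if not dup.empty:
            raise ValueError(
                f"case {case_id!r} has duplicate frame_id(s): {sorted(set(dup))}"
            )
        frames = group.sort_values("timestamp_s").reset_index(drop=True)
        tertile_of = split_tertiles(frames["timestamp_s"].to_numpy())
        records.append(CaseRecord(case_id=str(case_id), frames=frames, tertile_of=tertile_of))
    return records


def write_manifest(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_case_frames(case: SyntheticCase, outdir: Path | str) -> list[str]:
    """Write one synthetic case's frames as PNGs; returns relative paths."""
    outdir = Path(outdir)
    casedir = outdir / case.case_id
    casedir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in case.frames:
        rel = f"{case.case_id}/{frame.frame_id}.png"
        Image.fromarray(frame.pixels).save(outdir / rel)
        paths.append(rel)
    return paths


def manifest_from_cases(
    cases: Iterable[SyntheticCase], outdir: Path | str | None = None
) -> pd.DataFrame:
    """Build a manifest DataFrame from synthetic cases, with ground truth.

    When ``outdir`` is given the frame PNGs are written there and ``path``
    points at them; otherwise ``path`` is a placeholder (in-memory use).
    """
    rows = []
    for case in cases:
        paths = (
            write_case_frames(case, outdir)
            if outdir is not None
            else [f"<memory>/{f.frame_id}" for f in case.frames]
        )
        for frame, rel in zip(case.frames, paths):
            rows.append(
                {
                    "case_id": case.case_id,
                    "frame_id": frame.frame_id,
                    "path": rel,
                    "timestamp_s": frame.timestamp_s,
                    "visible_fraction": frame.true_visible_fraction,
                    "true_score": frame.true_score,
                    "category": frame.category,
                }
            )
    return pd.DataFrame(rows)
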