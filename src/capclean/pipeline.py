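"""End-to-end pipeline: simulate -> score -> grade -> evaluate -> report.

Wires the library modules together behind a single validated
:class:`RunConfig`.  Every stage is a plain function usable on its own;
``run_pipeline`` composes them and writes the machine-readable report
(schema version 1, validated by pydantic models shipped here).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import classify, evaluate, grade, score, synth
from .manifest import (
    GROUND_TRUTH_COLUMNS,
    CaseRecord,
    manifest_from_cases,
    read_manifest,
    write_manifest,
)

__all__ = [
    "RunConfig",
    "CaseReport",
    "RunReport",
    "generate_cohort",
    "score_cases",
    "grade_cases",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------- config


class RunConfig(BaseModel):
    """Validated parameters for a full pipeline run.

    The simulate defaults emulate the structure of a small-bowel validation
    cohort: mostly well-prepped cases plus a minority with heavy obscuration
    concentrated enough to grade C (inadequate).
    """

    n_cases: int = Field(20, ge=2)
    n_frames: int = Field(30, ge=3)
    image_size: int = Field(64, ge=16)
    inadequate_fraction: float = Field(1 / 12, ge=0.0, le=1.0)
    adequate_invisibility_max: float = Field(0.12, ge=0.0, le=1.0)
    inadequate_invisibility_range: tuple[float, float] = (0.30, 0.60)
    render: bool = False  # render pixels only when a CNN classifier needs them
    classifier: str = "oracle"  # "oracle" or a checkpoint path
    oracle_smoothing: float = Field(0.0, ge=0.0, lt=1.0)
    cutoff_method: Literal["youden", "min_distance"] = "youden"
    seed: int = Field(0, ge=0)
    output_dir: Optional[str] = None
    manifest: Optional[str] = None  # score an existing manifest instead of simulating

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))


# ---------------------------------------------------------------- report


class CaseReport(BaseModel):
    case_id: str
    n_frames: int
    per_segment_mean: list[float]
    case_mean: float
    invisibility_fraction: list[float]
    segmental_grade: list[int]
    overall_grade: Literal["A", "B", "C"]
    adequate: bool
    predicted_adequate: Optional[bool] = None


class EvaluationReport(BaseModel):
    auc: float
    cutoff_method: str
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    group_means: dict[str, float]


class RunReport(BaseModel):
    schema_version: Literal["1"]
    seed: int
    cases: list[CaseReport]
    evaluation: Optional[EvaluationReport] = None


# ---------------------------------------------------------------- stages


def generate_cohort(
    n_cases: int,
    n_frames: int = 30,
    inadequate_fraction: float = 1 / 12,
    adequate_invisibility_max: float = 0.12,
    inadequate_invisibility_range: tuple[float, float] = (0.30, 0.60),
    image_size: int = 64,
    render: bool = False,
    seed: int = 0,
) -> list[synth.SyntheticCase]:
    """Simulate a cohort of examinations with controlled adequacy mix.

    Adequate cases draw per-tertile invisible-frame rates uniformly below
    ``adequate_invisibility_max`` (segmental grades 1-2, overall A/B);
    inadequate cases draw from ``inadequate_invisibility_range`` (grade 4
    tertiles, overall C).
    """
    root = np.random.SeedSequence(seed)
    pick_ss, *case_ss = root.spawn(1 + n_cases)
    rng = np.random.default_rng(pick_ss)
    n_bad = int(round(inadequate_fraction * n_cases))
    bad = np.zeros(n_cases, dtype=bool)
    bad[rng.choice(n_cases, size=n_bad, replace=False)] = True
    lo, hi = inadequate_invisibility_range
    cases = []
    for i in range(n_cases):
        if bad[i]:
            inv = tuple(rng.uniform(lo, hi, 3))
        else:
            inv = tuple(rng.uniform(0.0, adequate_invisibility_max, 3))
        spec = synth.CaseSpec(
            n_frames=n_frames,
            tertile_invisibility=inv,  # type: ignore[arg-type]
            image_size=image_size,
            seed=int(case_ss[i].generate_state(1, dtype=np.uint32)[0]),
        )
        cases.append(synth.generate_case(spec, case_id=f"case{i:03d}", render=render))
    return cases


def _oracle_scores_from_truth(frames: pd.DataFrame, smoothing: float) -> np.ndarray:
    """Frame scores an oracle classifier would emit, read off true_score."""
    for col in GROUND_TRUTH_COLUMNS[:2]:
        if col not in frames.columns:
            raise ValueError(
                f"oracle scoring needs ground-truth column {col!r} in the manifest"
            )
    oracle = classify.OracleClassifier(smoothing=smoothing)
    out = []
    for ts in frames["true_score"].astype(int):
        p = np.zeros(5)
        i = ts - 1
        p[i] = 1.0 - oracle.smoothing
        nb = [j for j in (i - 1, i + 1) if 0 <= j < 5]
        for j in nb:
            p[j] = oracle.smoothing / len(nb)
        out.append(score.frame_score(p))
    return np.asarray(out)


def score_cases(
    records: Sequence[CaseRecord],
    classifier: str = "oracle",
    oracle_smoothing: float = 0.0,
    root: Path | str | None = None,
) -> tuple[pd.DataFrame, list[score.CaseScoreSummary]]:
    """Per-frame cleansing scores and per-case summaries for every record.

    ``classifier`` is ``"oracle"`` (ground-truth columns required) or a CNN
    checkpoint path (frame images loaded from disk).
    """
    cnn = None if classifier == "oracle" else classify.CNNClassifier.load(classifier)
    frame_rows = []
    summaries = []
    for rec in records:
        if cnn is None:
            fscores = _oracle_scores_from_truth(rec.frames, oracle_smoothing)
        else:
            pixels = rec.load_pixels(root=root)
            probs = cnn.predict_proba_batch(pixels)
            fscores = probs @ np.arange(1.0, 6.0)
        for fid, ts, t, fs in zip(
            rec.frames["frame_id"], rec.frames["timestamp_s"], rec.tertile_of, fscores
        ):
            frame_rows.append(
                {
                    "case_id": rec.case_id,
                    "frame_id": fid,
                    "timestamp_s": ts,
                    "tertile": int(t),
                    "score": float(fs),
                }
            )
        summaries.append(score.score_case(rec.case_id, fscores, rec.tertile_of))
    return pd.DataFrame(frame_rows), summaries


def grade_cases(records: Sequence[CaseRecord]) -> list[grade.GradingResult]:
    """Clinical grading of each record from its visible_fraction column."""
    results = []
    for rec in records:
        if "visible_fraction" not in rec.frames.columns:
            raise ValueError(
                f"case {rec.case_id!r} has no visible_fraction column for grading"
            )
        results.append(
            grade.grade_case(
                rec.frames["visible_fraction"].to_numpy(),
                rec.tertile_of,
                frame_ids=rec.frames["frame_id"],
            )
        )
    return results


# ---------------------------------------------------------------- composite


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute simulate (optional) -> score -> grade -> evaluate and report.

    Writes, under ``config.output_dir`` when given: the manifest (simulated
    runs), per-frame scores CSV, grading CSV, evaluation JSON and the full
    ``report.json``.  Deterministic for a fixed config and seed.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if config.manifest is not None:
        records = read_manifest(config.manifest)
        root = Path(config.manifest).parent
    else:
        needs_pixels = config.render or config.classifier != "oracle"
        cases = generate_cohort(
            n_cases=config.n_cases,
            n_frames=config.n_frames,
            inadequate_fraction=config.inadequate_fraction,
            adequate_invisibility_max=config.adequate_invisibility_max,
            inadequate_invisibility_range=config.inadequate_invisibility_range,
            image_size=config.image_size,
            render=needs_pixels,
            seed=config.seed,
        )
        frames_dir = outdir / "frames" if (outdir and needs_pixels) else None
        mdf = manifest_from_cases(cases, outdir=frames_dir)
        if outdir:
            write_manifest(mdf, outdir / "manifest.csv")
        records = []
        for case in cases:
            sub = mdf[mdf["case_id"] == case.case_id].reset_index(drop=True)
            records.append(
                CaseRecord(
                    case_id=case.case_id,
                    frames=sub,
                    tertile_of=np.asarray(case.tertile_of),
                )
            )
        root = frames_dir

    frame_scores, summaries = score_cases(
        records,
        classifier=config.classifier,
        oracle_smoothing=config.oracle_smoothing,
        root=root,
    )
    gradings = grade_cases(records)

    case_means = np.array([s.case_mean for s in summaries])
    adequate = np.array([g.adequate for g in gradings])
    evaluation = None
    cutoff = None
    if adequate.any() and (~adequate).any():
        roc = evaluate.select_cutoff(
            evaluate.roc_curve(case_means, adequate), method=config.cutoff_method
        )
        cutoff = roc.selected_cutoff
        groups: dict[str, float] = {}
        for letter in ("A", "B", "C"):
            sel = [s.case_mean for s, g in zip(summaries, gradings) if g.overall_grade == letter]
            if sel:
                groups[letter] = evaluate.group_summary(sel, letter).mean
        evaluation = EvaluationReport(
            auc=roc.auc,
            cutoff_method=config.cutoff_method,
            cutoff=roc.selected_cutoff,
            cutoff_sensitivity=roc.cutoff_sensitivity,
            cutoff_specificity=roc.cutoff_specificity,
            group_means=groups,
        )

    case_reports = [
        CaseReport(
            case_id=s.case_id,
            n_frames=s.n_frames,
            per_segment_mean=list(s.per_segment_mean),
            case_mean=s.case_mean,
            invisibility_fraction=list(g.invisibility_fraction),
            segmental_grade=list(g.segmental_grade),
            overall_grade=g.overall_grade,
            adequate=g.adequate,
            predicted_adequate=(s.case_mean >= cutoff) if cutoff is not None else None,
        )
        for s, g in zip(summaries, gradings)
    ]
    report = RunReport(
        schema_version=REPORT_SCHEMA_VERSION,
        seed=config.seed,
        cases=case_reports,
        evaluation=evaluation,
    )

    if outdir:
        frame_scores.to_csv(outdir / "frame_scores.csv", index=False)
        pd.DataFrame(
            [
                {
                    "case_id": c.case_id,
                    "invisibility_seg1": c.invisibility_fraction[0],
                    "invisibility_seg2": c.invisibility_fraction[1],
                    "invisibility_seg3": c.invisibility_fraction[2],
                    "grade_seg1": c.segmental_grade[0],
                    "grade_seg2": c.segmental_grade[1],
                    "grade_seg3": c.segmental_grade[2],
                    "overall_grade": c.overall_grade,
                    "adequate": c.adequate,
                }
                for c in case_reports
            ]
        ).to_csv(outdir / "grading.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
        )
        if evaluation is not None:
            (outdir / "evaluation.json").write_text(
                json.dumps(evaluation.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
            )
    return report
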