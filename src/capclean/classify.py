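"""Frame classifiers for the 5-step cleansing score, and their metrics.

Three pieces live here:

* the :class:`FrameClassifier` contract — anything that turns a frame into
  a softmax probability vector over scores 1..5 can drive the scoring
  pipeline;
* :class:`OracleClassifier`, a ground-truth-reading classifier for
  synthetic frames (optionally with probability mass smoothed onto the
  adjacent scores, mimicking inter-grade uncertainty);
* a trainable reference CNN (:func:`train_reference_classifier`) following
  the two-phase protocol — first the classification head alone on frozen
  features, then the full network at a lower learning rate — together with
  balanced dataset assembly and top-k accuracy.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cnn import SmallCNN
from .score import validate_probability_vector
from .synth import SyntheticFrame

__all__ = [
    "FrameClassifier",
    "OracleClassifier",
    "CNNClassifier",
    "TrainingPhase",
    "BalancedDataset",
    "predict",
    "build_balanced_dataset",
    "train_reference_classifier",
    "top_k_accuracy",
]


class FrameClassifier(abc.ABC):
    """Contract: map one frame to five class probabilities summing to one."""

    @abc.abstractmethod
    def predict_proba(self, frame) -> np.ndarray:
        """Return the (5,) probability vector for scores 1..5."""


def predict(classifier: FrameClassifier, frame) -> np.ndarray:
    """Classify one frame, validating the returned probability vector."""
    return validate_probability_vector(classifier.predict_proba(frame))


class OracleClassifier(FrameClassifier):
    """Reads the ground-truth score of a synthetic frame.

    With ``smoothing`` s in [0, 1), probability 1 - s goes to the true score
    and s is split over the adjacent scores (half each for interior scores;
    all of it to the single neighbour for scores 1 and 5).  s = 0 gives a
    one-hot vector.
    """

    def __init__(self, smoothing: float = 0.0) -> None:
        if not 0.0 <= smoothing < 1.0:
            raise ValueError(f"smoothing must lie in [0, 1), got {smoothing}")
        self.smoothing = float(smoothing)

    def predict_proba(self, frame) -> np.ndarray:
        if not isinstance(frame, SyntheticFrame):
            raise TypeError(
                "the oracle classifier requires a synthetic frame with ground truth "
                f"(got {type(frame).__name__})"
            )
        p = np.zeros(5)
        i = frame.true_score - 1
        p[i] = 1.0 - self.smoothing
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < 5]
        for j in neighbours:
            p[j] = self.smoothing / len(neighbours)
        return p


class CNNClassifier(FrameClassifier):
    """Wraps the reference CNN as a per-frame classifier."""

    def __init__(self, net: SmallCNN) -> None:
        self.net = net

    def predict_proba(self, frame) -> np.ndarray:
        pixels = frame.pixels if isinstance(frame, SyntheticFrame) else np.asarray(frame)
        return self.net.predict_proba(pixels)[0]

    def predict_proba_batch(self, pixels: np.ndarray, batch: int = 64) -> np.ndarray:
        """(N, H, W, 3) -> (N, 5), evaluated in chunks."""
        return np.concatenate(
            [self.net.predict_proba(pixels[i : i + batch]) for i in range(0, len(pixels), batch)]
        )

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        return cls(SmallCNN.load(path))


@dataclass(frozen=True)
class TrainingPhase:
    """One phase of the two-stage schedule.

    ``head_only`` freezes everything but the final classification layer;
    ``full_network`` trains all parameters.  Defaults mirror the desk-scale
    replica of the clinical training protocol (batch size 24; learning rate
    0.01 for the head phase, 0.0001 for the full phase).
    """

    scope: str
    n_steps: int
    batch_size: int = 24
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.scope not in ("head_only", "full_network"):
            raise ValueError(f"scope must be head_only or full_network, got {self.scope!r}")
        if self.n_steps < 1 or self.batch_size < 1:
            raise ValueError("n_steps and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


DEFAULT_PHASES = (
    TrainingPhase("head_only", n_steps=200, batch_size=24, learning_rate=0.01),
    TrainingPhase("full_network", n_steps=400, batch_size=24, learning_rate=0.0001),
)


@dataclass
class BalancedDataset:
    """Class-balanced image set: pixels (N, H, W, 3) uint8, labels 1..5."""

    pixels: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


def build_balanced_dataset(
    labeled_frames: Sequence, n_per_class: int, seed: int = 0
) -> BalancedDataset:
    """Sample exactly n_per_class frames per score class, without replacement.

    ``labeled_frames`` is a sequence of :class:`SyntheticFrame` (labels read
    from ``true_score``) or of ``(pixels, label)`` pairs.  A class with too
    few members raises an error naming it.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    items: list[tuple[np.ndarray, int]] = []
    for lf in labeled_frames:
        if isinstance(lf, SyntheticFrame):
            items.append((lf.pixels, lf.true_score))
        else:
            pixels, label = lf
            items.append((np.asarray(pixels), int(label)))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen_px: list[np.ndarray] = []
    chosen_y: list[int] = []
    for cls in range(1, 6):
        members = [i for i, (_, y) in enumerate(items) if y == cls]
        if len(members) < n_per_class:
            raise ValueError(
                f"class {cls} has only {len(members)} frames; {n_per_class} required"
            )
        for i in rng.choice(len(members), size=n_per_class, replace=False):
            chosen_px.append(items[members[i]][0])
            chosen_y.append(cls)
    return BalancedDataset(pixels=np.stack(chosen_px), labels=np.asarray(chosen_y))


def train_reference_classifier(
    dataset: BalancedDataset,
    phases: Sequence[TrainingPhase] = DEFAULT_PHASES,
    seed: int = 0,
    channels: Sequence[int] = (8, 16, 32),
    log_every: int = 50,
) -> tuple[CNNClassifier, list[dict]]:
    """Train the reference CNN through the given phases, in order.

    Returns the trained classifier and a per-phase log of (step, loss)
    samples.  Training is deterministic for a fixed seed under
    single-threaded execution: initialisation, batch sampling and updates
    all descend from ``seed``.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    if not phases:
        raise ValueError("at least one training phase is required")
    labels = np.asarray(dataset.labels)
    if not np.isin(labels, [1, 2, 3, 4, 5]).all():
        raise ValueError("labels must be cleansing scores 1..5")

    root = np.random.SeedSequence(seed)
    init_ss, *phase_ss = root.spawn(1 + len(phases))
    net = SmallCNN(
        input_size=dataset.pixels.shape[1],
        channels=channels,
        seed=int(init_ss.generate_state(1, dtype=np.uint32)[0]),
    )
    logs = []
    for phase, ss in zip(phases, phase_ss):
        rng = np.random.default_rng(ss)
        log = net.train_phase(
            dataset.pixels,
            labels - 1,
            scope=phase.scope,
            n_steps=phase.n_steps,
            batch_size=phase.batch_size,
            learning_rate=phase.learning_rate,
            rng=rng,
            log_every=log_every,
        )
        logs.append({"scope": phase.scope, "loss_curve": log})
    return CNNClassifier(net), logs


def top_k_accuracy(
    predictions: Sequence[Sequence[float]], labels: Sequence[int], k: int
) -> float:
    """Fraction of frames whose true score is among the k most probable classes.

    Ties in probability are broken toward the *lower* class index (a stable
    sort on descending probability), so e.g. a uniform prediction's top-2
    set is always {1, 2}.
    """
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    preds = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if preds.shape[0] != y.shape[0]:
        raise ValueError(
            f"predictions ({preds.shape[0]}) and labels ({y.shape[0]}) are misaligned"
        )
    if preds.shape[0] == 0:
        raise ValueError("cannot compute accuracy on an empty set")
    order = np.argsort(-preds, axis=1, kind="stable")  # stable -> lower index wins ties
    topk = order[:, :k] + 1  # class indices 1..5
    return float((topk == y[:, None]).any(axis=1).mean())
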