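"""A small convolutional network in plain numpy, with hand-written backprop.

Architecture: three 3x3 conv + ReLU + 2x2 maxpool blocks; the classifier
head reads a *multi-scale* global-average-pooled descriptor (the GAP of
every block's output, concatenated and standardized against statistics
frozen from the training set), followed by a linear 5-way softmax layer.
The shallow blocks contribute colour/brightness statistics and the deeper
blocks texture, which is what separates clean mucosa from bubbles, bile
and debris.

Everything is float32, single-threaded numpy, so a fixed seed reproduces
training bit-for-bit on the same platform.  Supports the two-phase
fine-tuning protocol: a *head-only* phase (conv stack frozen; features
precomputed once, making the phase cheap) followed by a *full-network*
phase that backpropagates through the conv stack at a lower learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SmallCNN", "CHECKPOINT_FORMAT"]

CHECKPOINT_FORMAT = "capclean-cnn-v1"
_K = 3  # conv kernel size, padding 1 throughout


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*9) patches for a 3x3 same-padding conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (_K, _K), axis=(2, 3))
    # win: (B, C, H, W, 3, 3) -> (B, H*W, C*9)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * _K * _K)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    b, c, h, w = shape
    d = dcols.reshape(b, h, w, c, _K, _K)
    dxp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
    for di in range(_K):
        for dj in range(_K):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


@dataclass
class _ConvLayer:
    w: np.ndarray  # (C_in*9, C_out)
    b: np.ndarray  # (C_out,)


class SmallCNN:
    """3-block CNN for 5-class frame classification on square RGB inputs."""

    def __init__(
        self,
        input_size: int = 64,
        channels: Sequence[int] = (8, 16, 32),
        n_classes: int = 5,
        seed: int = 0,
    ) -> None:
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError("input_size must be divisible by 2**n_blocks")
        self.input_size = int(input_size)
        self.channels = tuple(int(c) for c in channels)
        self.n_classes = int(n_classes)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.conv: list[_ConvLayer] = []
        c_in = 3
        for c_out in self.channels:
            fan_in = c_in * _K * _K
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(np.float32)
            self.conv.append(_ConvLayer(w=w, b=np.zeros(c_out, dtype=np.float32)))
            c_in = c_out
        self.n_features = sum(self.channels)
        self.head_w = rng.normal(
            0.0, np.sqrt(1.0 / self.n_features), (self.n_features, self.n_classes)
        ).astype(np.float32)
        self.head_b = np.zeros(self.n_classes, dtype=np.float32)
        # feature standardization, frozen from the training set at first fit
        self.feat_mu: np.ndarray | None = None
        self.feat_sigma: np.ndarray | None = None

    # ---- forward -----------------------------------------------------

    @staticmethod
    def _prepare(x: np.ndarray) -> np.ndarray:
        """(B, H, W, 3) uint8/float -> centred (B, 3, H, W) float32."""
        arr = np.asarray(x)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected (B, H, W, 3) images, got shape {arr.shape}")
        out = np.ascontiguousarray(arr.transpose(0, 3, 1, 2), dtype=np.float32)
        return (out / 255.0 - 0.5) / 0.25

    def _forward_conv(self, x: np.ndarray, keep_cache: bool = False):
        """Conv stack on prepared input -> per-block GAP list (+ caches)."""
        cache = []
        gaps = []
        h = x
        for layer in self.conv:
            b, c, hh, ww = h.shape
            cols = _im2col(h)
            z = cols @ layer.w + layer.b
            a = np.maximum(z, 0.0)
            a = a.reshape(b, hh, ww, -1).transpose(0, 3, 1, 2)
            # 2x2 maxpool; gradient is split evenly among tied maxima
            bo, co, ho, wo = a.shape
            ar = a.reshape(bo, co, ho // 2, 2, wo // 2, 2)
            pooled = ar.max(axis=(3, 5))
            gaps.append(pooled.mean(axis=(2, 3)))
            if keep_cache:
                cache.append((h.shape, cols, z, ar, pooled.shape))
            h = pooled
        return gaps, cache

    def _standardize(self, raw: np.ndarray) -> np.ndarray:
        if self.feat_mu is None:
            return raw
        return (raw - self.feat_mu) / self.feat_sigma

    def fit_feature_norm(self, x: np.ndarray, batch: int = 64) -> None:
        """Freeze feature mean/SD from a dataset (called once before training)."""
        raw = self._raw_features(self._prepare(x), batch=batch)
        self.feat_mu = raw.mean(axis=0).astype(np.float32)
        self.feat_sigma = (raw.std(axis=0) + 1e-6).astype(np.float32)

    def _raw_features(self, xs: np.ndarray, batch: int = 64) -> np.ndarray:
        chunks = []
        for i in range(0, xs.shape[0], batch):
            gaps, _ = self._forward_conv(xs[i : i + batch])
            chunks.append(np.concatenate(gaps, axis=1))
        return np.concatenate(chunks)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Standardized multi-scale GAP descriptor, shape (B, sum(channels))."""
        return self._standardize(self._raw_features(self._prepare(x)))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.features(x) @ self.head_w + self.head_b

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (B, 5)."""
        arr = np.asarray(x)
        spatial = arr.shape[-3:-1] if arr.ndim == 4 else arr.shape[:2]
        if spatial != (self.input_size, self.input_size):
            raise ValueError(
                f"classifier expects {self.input_size}x{self.input_size} frames, "
                f"got {spatial[0]}x{spatial[1]}"
            )
        return _softmax(self.logits(x))

    # ---- training ----------------------------------------------------

    def _head_step(self, feats: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step on the linear head given standardized features."""
        b = feats.shape[0]
        probs = _softmax(feats @ self.head_w + self.head_b)
        loss = float(-np.log(np.maximum(probs[np.arange(b), y], 1e-12)).mean())
        dlogits = probs
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        self.head_w -= (lr * (feats.T @ dlogits)).astype(np.float32)
        self.head_b -= (lr * dlogits.sum(axis=0)).astype(np.float32)
        return loss

    def _full_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        """One SGD step through the whole network; returns loss."""
        gaps, cache = self._forward_conv(x, keep_cache=True)
        raw = np.concatenate(gaps, axis=1)
        feats = self._standardize(raw)
        b = feats.shape[0]
        probs = _softmax(feats @ self.head_w + self.head_b)
        loss = float(-np.log(np.maximum(probs[np.arange(b), y], 1e-12)).mean())
        dlogits = probs
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        dhead_w = feats.T @ dlogits
        dhead_b = dlogits.sum(axis=0)
        draw = dlogits @ self.head_w.T
        if self.feat_mu is not None:
            draw = draw / self.feat_sigma
        # split the feature gradient back to each block's GAP
        dgaps = np.split(draw, np.cumsum(self.channels)[:-1], axis=1)

        grads: list[tuple[np.ndarray, np.ndarray]] = []
        dh: np.ndarray | None = None  # gradient w.r.t. the current block's pooled output
        for blk in range(len(self.conv) - 1, -1, -1):
            in_shape, cols, z, ar, pooled_shape = cache[blk]
            bo, co, ho2, wo2 = pooled_shape
            # GAP contribution spreads evenly over spatial positions
            dpooled = np.broadcast_to(
                (dgaps[blk] / (ho2 * wo2))[:, :, None, None], pooled_shape
            ).astype(np.float32)
            if dh is not None:
                dpooled = dpooled + dh
            m = ar.max(axis=(3, 5), keepdims=True)
            ties = ar == m
            dar = ties * (dpooled[:, :, :, None, :, None] / ties.sum(axis=(3, 5), keepdims=True))
            da = dar.reshape(bo, co, ho2 * 2, wo2 * 2)
            dz = da.transpose(0, 2, 3, 1).reshape(z.shape) * (z > 0)
            dw = np.einsum("bpk,bpf->kf", cols, dz)
            db = dz.sum(axis=(0, 1))
            grads.append((dw, db))
            if blk > 0:
                dh = _col2im(dz @ self.conv[blk].w.T, in_shape)

        for layer, (dw, db) in zip(reversed(self.conv), grads):
            layer.w -= (lr * dw).astype(np.float32)
            layer.b -= (lr * db).astype(np.float32)
        self.head_w -= (lr * dhead_w).astype(np.float32)
        self.head_b -= (lr * dhead_b).astype(np.float32)
        return loss

    def train_phase(
        self,
        x: np.ndarray,
        y: np.ndarray,
        scope: str,
        n_steps: int,
        batch_size: int,
        learning_rate: float,
        rng: np.random.Generator,
        log_every: int = 0,
    ) -> list[tuple[int, float]]:
        """Run one training phase; returns (step, loss) pairs at the log interval."""
        if scope not in ("head_only", "full_network"):
            raise ValueError(f"unknown phase scope {scope!r}")
        if self.feat_mu is None:
            self.fit_feature_norm(x)
        xs = self._prepare(x)
        ys = np.asarray(y, dtype=np.int64)
        n = xs.shape[0]
        bs = min(batch_size, n)
        log: list[tuple[int, float]] = []
        if scope == "head_only":
            feats = self._standardize(self._raw_features(xs))
            for step in range(n_steps):
                idx = rng.choice(n, size=bs, replace=False)
                loss = self._head_step(feats[idx], ys[idx], learning_rate)
                if log_every and (step + 1) % log_every == 0:
                    log.append((step + 1, loss))
        else:
            for step in range(n_steps):
                idx = rng.choice(n, size=bs, replace=False)
                loss = self._full_step(xs[idx], ys[idx], learning_rate)
                if log_every and (step + 1) % log_every == 0:
                    log.append((step + 1, loss))
        return log

    # ---- persistence -------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format": CHECKPOINT_FORMAT,
            "input_size": self.input_size,
            "channels": list(self.channels),
            "n_classes": self.n_classes,
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, layer in enumerate(self.conv):
            arrays[f"conv{i}_w"] = layer.w
            arrays[f"conv{i}_b"] = layer.b
        arrays["head_w"] = self.head_w
        arrays["head_b"] = self.head_b
        if self.feat_mu is not None:
            arrays["feat_mu"] = self.feat_mu
            arrays["feat_sigma"] = self.feat_sigma
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognised checkpoint format: {meta.get('format')!r}")
            net = cls(
                input_size=meta["input_size"],
                channels=meta["channels"],
                n_classes=meta["n_classes"],
            )
            for i in range(len(net.conv)):
                net.conv[i].w = data[f"conv{i}_w"]
                net.conv[i].b = data[f"conv{i}_b"]
            net.head_w = data["head_w"]
            net.head_b = data["head_b"]
            if "feat_mu" in data:
                net.feat_mu = data["feat_mu"]
                net.feat_sigma = data["feat_sigma"]
        return net
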