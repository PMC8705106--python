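"""Spatiotemporal identification: Manhattan-distance Siamese LSTM over joint tracks.

A gait cycle is encoded as a sequence of 18-component vectors — the x,y,z
positions of the six lower-body joints (left ankle 8, left knee 7, left hip
6, right ankle 3, right knee 2, right hip 1), root-centered per frame so
the arbitrary origin of unitless pose-estimator output drops out. Two such
sequences are scored by twin recurrent encoders with shared weights; the
similarity is ``exp(-||h_a - h_b||_1)`` on the twins' final hidden states,
which lies in (0, 1] and equals 1 for identical inputs.

The encoder is a compact single-layer LSTM (18-dimensional hidden state and
memory cell) written directly in numpy, with manual backpropagation through
time and an Adam optimizer; training minimizes the mean squared error
between the similarity and the pair label (same = 1, different = 0).
Everything is seeded and single-threaded, so training is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .cycles import GaitCycle
from .skeleton import h36m_column

__all__ = [
    "LAMBDA_JOINTS",
    "LambdaSequence",
    "PairSet",
    "SimilarityModel",
    "build_lambda",
    "make_pairs",
    "train_malstm",
    "similarity",
    "verification_accuracy",
    "identify",
    "DEFAULT_SEQUENCE_LENGTH",
]

#: H3.6M ids entering the spatiotemporal vector, in fixed order.
LAMBDA_JOINTS: tuple[int, ...] = (8, 7, 6, 3, 2, 1)

DEFAULT_SEQUENCE_LENGTH = 50

DEFAULT_TRAIN_CONFIG: dict[str, Any] = {
    "batch_size": 1024,
    "epochs": 10,
    "learning_rate": 0.02,
    "hidden_size": 18,
    "validation_fraction": 0.2,
}


@dataclass
class LambdaSequence:
    """Ordered 18-component joint vectors for one gait cycle."""

    steps: np.ndarray
    subject_id: str | None = None
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 2 or self.steps.shape[1] != 3 * len(LAMBDA_JOINTS):
            raise ValueError(f"steps must have shape (L, 18), got {self.steps.shape}")
        if not np.isfinite(self.steps).all():
            raise ValueError("steps contain non-finite values")

    def __len__(self) -> int:
        return self.steps.shape[0]


@dataclass
class PairSet:
    """Labelled sequence pairs for verification training; label 1 = same subject."""

    left: list[LambdaSequence]
    right: list[LambdaSequence]
    labels: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if not (len(self.left) == len(self.right) == len(self.labels)):
            raise ValueError("left, right and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def build_lambda(
    cycle: GaitCycle, length: int | None = DEFAULT_SEQUENCE_LENGTH
) -> LambdaSequence:
    """Encode a gait cycle as a root-centered 18-component vector sequence.

    One step per interpolated frame in [t_a, t_h], root-centered per frame;
    if ``length`` is given the sequence is linearly time-resampled to that
    fixed number of steps (uniform lengths allow batched training). Pass
    ``length=None`` to keep the native cycle length.
    """
    seq = cycle.source
    lo = int(math.ceil(cycle.ta))
    hi = int(math.floor(cycle.th))
    frames = seq.positions[lo : hi + 1]
    root = frames[:, h36m_column(0), :]
    cols = [h36m_column(j) for j in LAMBDA_JOINTS]
    centered = frames[:, cols, :] - root[:, None, :]
    steps = centered.reshape(len(frames), -1)
    if length is not None and len(steps) != length:
        if len(steps) < 2:
            raise ValueError("cycle spans fewer than two frames; cannot resample")
        t_old = np.linspace(0.0, 1.0, len(steps))
        t_new = np.linspace(0.0, 1.0, length)
        steps = np.stack([np.interp(t_new, t_old, steps[:, k]) for k in range(steps.shape[1])], axis=1)
    return LambdaSequence(
        steps=steps, subject_id=seq.subject_id, cycle_index=cycle.cycle_index
    )


def make_pairs(
    sequences: list[LambdaSequence], n_pairs: int, seed: int = 0
) -> PairSet:
    """Seeded uniform sampling of balanced same/different sequence pairs.

    Half the pairs share a subject (two distinct cycles), half do not. A
    cycle is never paired with itself. Requires at least two subjects and
    at least one subject with two cycles.
    """
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(sequences):
        by_subject.setdefault(str(s.subject_id), []).append(i)
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise ValueError("pair sampling needs at least 2 subjects")
    multi = [s for s in subjects if len(by_subject[s]) >= 2]
    if not multi:
        raise ValueError("no subject has two cycles; cannot form same-pairs")

    rng = np.random.default_rng(seed)
    n_same = n_pairs // 2
    left: list[LambdaSequence] = []
    right: list[LambdaSequence] = []
    labels: list[float] = []
    for _ in range(n_same):
        s = multi[rng.integers(len(multi))]
        i, j = rng.choice(by_subject[s], size=2, replace=False)
        left.append(sequences[i])
        right.append(sequences[j])
        labels.append(1.0)
    for _ in range(n_pairs - n_same):
        a, b = rng.choice(len(subjects), size=2, replace=False)
        i = int(rng.choice(by_subject[subjects[a]]))
        j = int(rng.choice(by_subject[subjects[b]]))
        left.append(sequences[i])
        right.append(sequences[j])
        labels.append(0.0)
    return PairSet(left=left, right=right, labels=np.array(labels), seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTM:
    """Single-layer LSTM with manual backpropagation through time.

    Gate order in the packed weight matrices is input, forget, cell, output.
    The forget-gate bias starts at 1 (standard remedy against early
    vanishing memory).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        k = 1.0 / math.sqrt(hidden_size)
        self.H = hidden_size
        self.Wx = rng.uniform(-k, k, size=(input_size, 4 * hidden_size))
        self.Wh = rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size))
        self.b = np.zeros(4 * hidden_size)
        self.b[hidden_size : 2 * hidden_size] = 1.0

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, X: np.ndarray, keep_cache: bool = False):
        """Run the batch (B, L, D); return final hidden state (B, H)."""
        B, L, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if keep_cache else None
        for t in range(L):
            x = X[:, t, :]
            z = x @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if keep_cache:
                cache.append((x, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        return (h, cache) if keep_cache else h

    def backward(self, cache, dh_final: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. parameters given d(loss)/d(final h)."""
        H = self.H
        grads = {"Wx": np.zeros_like(self.Wx), "Wh": np.zeros_like(self.Wh), "b": np.zeros_like(self.b)}
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for x, h_prev, c_prev, i, f, g, o, tc in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class SimilarityModel:
    """Trained Manhattan-similarity Siamese recurrent encoder.

    The twin branches are the same :class:`_LSTM` instance, so weight
    sharing is structural. ``threshold`` is the same/different decision
    boundary fitted on a validation split.
    """

    encoder: _LSTM
    config: dict[str, Any]
    seed: int
    threshold: float = 0.5
    history: pd.DataFrame | None = None

    def encode(self, seqs: list[LambdaSequence]) -> np.ndarray:
        X = np.stack([s.steps for s in seqs])
        return self.encoder.forward(X)

    def manifest(self) -> dict[str, Any]:
        return {
            "architecture": "siamese-lstm, shared single-layer encoder, exp(-L1) similarity",
            "input_size": int(self.encoder.Wx.shape[0]),
            "hidden_size": int(self.encoder.H),
            "config": self.config,
            "seed": self.seed,
            "threshold": self.threshold,
        }


def _pair_similarities(encoder: _LSTM, left, right) -> np.ndarray:
    hA = encoder.forward(np.stack([s.steps for s in left]))
    hB = encoder.forward(np.stack([s.steps for s in right]))
    return np.exp(-np.abs(hA - hB).sum(axis=1))


def _best_threshold(sims: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing verification accuracy; ties pick the smaller one."""
    order = np.argsort(sims, kind="stable")
    s = sims[order]
    cand = np.concatenate([[0.0], (s[:-1] + s[1:]) / 2.0, [1.0]])
    best_t, best_acc = 0.5, -1.0
    for t in cand:
        acc = float(((sims >= t) == (labels > 0.5)).mean())
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    return best_t, best_acc


def train_malstm(
    pairs: PairSet, config: dict[str, Any] | None = None, seed: int = 0
) -> SimilarityModel:
    """Train the Siamese LSTM on labelled pairs.

    Defaults: batch size 1024, 10 epochs, MSE loss on the exp(-L1)
    similarity against labels (same = 1, different = 0), Adam optimizer,
    18-dimensional hidden state. A validation split
    (``validation_fraction``) is held out to fit the verification
    threshold. The per-epoch training curve is stored on the model.
    """
    if len(pairs) == 0:
        raise ValueError("pair set is empty")
    cfg = dict(DEFAULT_TRAIN_CONFIG)
    if config:
        cfg.update(config)
    lengths = {len(s) for s in pairs.left} | {len(s) for s in pairs.right}
    if len(lengths) != 1:
        raise ValueError(
            "pairs mix sequence lengths; resample cycles to a fixed length for batched training"
        )

    rng = np.random.default_rng(seed)
    n = len(pairs)
    n_val = int(round(cfg["validation_fraction"] * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("no training pairs left after the validation split")

    XA = np.stack([s.steps for s in pairs.left])
    XB = np.stack([s.steps for s in pairs.right])
    y = pairs.labels

    encoder = _LSTM(input_size=XA.shape[2], hidden_size=int(cfg["hidden_size"]), rng=rng)
    opt = _Adam(encoder.params, lr=float(cfg["learning_rate"]))

    batch = int(cfg["batch_size"])
    hist: list[dict[str, float]] = []
    for epoch in range(int(cfg["epochs"])):
        order = rng.permutation(tr_idx)
        losses = []
        for k in range(0, len(order), batch):
            idx = order[k : k + batch]
            xa, xb, yy = XA[idx], XB[idx], y[idx]
            hA, cacheA = encoder.forward(xa, keep_cache=True)
            hB, cacheB = encoder.forward(xb, keep_cache=True)
            diff = hA - hB
            sims = np.exp(-np.abs(diff).sum(axis=1))
            err = sims - yy
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {k // batch}; "
                    "lower the learning rate"
                )
            losses.append(loss)
            dsim = 2.0 * err / len(idx)
            dhA = (dsim * sims)[:, None] * (-np.sign(diff))
            dhB = -dhA
            gA = encoder.backward(cacheA, dhA)
            gB = encoder.backward(cacheB, dhB)
            grads = {k2: gA[k2] + gB[k2] for k2 in gA}
            opt.step(encoder.params, grads)
        tr_sims = _pair_similarities(encoder, [pairs.left[i] for i in tr_idx], [pairs.right[i] for i in tr_idx])
        _, tr_acc = _best_threshold(tr_sims, y[tr_idx])
        hist.append({"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": tr_acc})

    if n_val > 0:
        val_sims = _pair_similarities(
            encoder, [pairs.left[i] for i in val_idx], [pairs.right[i] for i in val_idx]
        )
        threshold, _ = _best_threshold(val_sims, y[val_idx])
    else:
        tr_sims = _pair_similarities(encoder, [pairs.left[i] for i in tr_idx], [pairs.right[i] for i in tr_idx])
        threshold, _ = _best_threshold(tr_sims, y[tr_idx])

    return SimilarityModel(
        encoder=encoder,
        config=cfg,
        seed=seed,
        threshold=threshold,
        history=pd.DataFrame(hist),
    )


def similarity(model: SimilarityModel, a: LambdaSequence, b: LambdaSequence) -> float:
    """exp(-L1) similarity of two sequences under the trained encoder, in (0, 1]."""
    h = model.encode([a, b])
    return float(np.exp(-np.abs(h[0] - h[1]).sum()))


def verification_accuracy(model: SimilarityModel, pairs: PairSet) -> float:
    """Fraction of pairs whose same/different decision matches the label."""
    sims = _pair_similarities(model.encoder, pairs.left, pairs.right)
    return float(((sims >= model.threshold) == (pairs.labels > 0.5)).mean())


def identify(
    model: SimilarityModel, gallery: list[LambdaSequence], probe: LambdaSequence
) -> str:
    """Closed-set identification: subject with the highest mean similarity.

    Ties resolve to the lexicographically lowest subject id.
    """
    if not gallery:
        raise ValueError("gallery is empty")
    hG = model.encode(gallery)
    hP = model.encode([probe])[0]
    sims = np.exp(-np.abs(hG - hP).sum(axis=1))
    by_subject: dict[str, list[float]] = {}
    for s, v in zip(gallery, sims):
        by_subject.setdefault(str(s.subject_id), []).append(float(v))
    means = {k: float(np.mean(v)) for k, v in by_subject.items()}
    best = max(sorted(means), key=lambda k: means[k])
    return best
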