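"""The 4-4-1 tanh network and its residue-decoding rule.

Each length-16 window is classed from its gold residue labels as
completely-membrane (+1), completely-nonmembrane (-1) or mixed (0); mixed
windows are never presented for training because they straddle the
TM/non-TM boundary and live in the confusable region of feature space.

The network maps the 4-dim projected window feature through one hidden layer
of 4 tanh units to a single tanh output trained toward +1 (TM) / -1 (non-TM)
with squared error.  At prediction time, every window whose analog output
exceeds the firing threshold theta (default 0.4, deliberately biased toward
confident TM calls) marks a block of ``span`` residues (default 8, half the
window) starting at the window's first position as TM; blocks from
overlapping firing windows union, anything never marked is non-TM, and the
final block is clipped at the protein end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .property_features import FeatureSet
from .sequence_io import labels_to_segments

DEFAULT_THETA = 0.4
DEFAULT_SPAN = 8


def window_class(label_slice: np.ndarray) -> int:
    """Class of one window: +1 all-TM, -1 all-non-TM, 0 mixed."""
    s = np.asarray(label_slice)
    total = int(s.sum())
    if total == len(s):
        return 1
    if total == 0:
        return -1
    return 0


def window_classes(labels: np.ndarray, window_length: int) -> np.ndarray:
    """Vector of window classes for every window position of a protein."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) < window_length:
        raise ValueError("labels shorter than window length")
    csum = np.concatenate([[0], np.cumsum(labels)])
    sums = csum[window_length:] - csum[:-window_length]
    out = np.zeros(len(sums), dtype=np.int8)
    out[sums == window_length] = 1
    out[sums == 0] = -1
    return out


@dataclass
class NNModel:
    """Trained 4-4-1 network plus its input standardisation and decode rule."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    mean: np.ndarray  # input standardisation, from the labeled training windows
    std: np.ndarray
    theta: float = DEFAULT_THETA
    span: int = DEFAULT_SPAN
    seed: int | None = None
    degenerate: bool = False
    n_epochs: int = 0
    final_loss: float = float("nan")

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Analog output in (-1, 1) for each input row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mean) / self.std
        H = np.tanh(Z @ self.W1.T + self.b1)
        return np.tanh(H @ self.W2 + self.b2)

    def save(self, path: str | Path) -> None:
        payload = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "theta": self.theta,
            "span": self.span,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "n_epochs": self.n_epochs,
            "final_loss": self.final_loss,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NNModel":
        p = json.loads(Path(path).read_text())
        return cls(
            W1=np.asarray(p["W1"], dtype=float),
            b1=np.asarray(p["b1"], dtype=float),
            W2=np.asarray(p["W2"], dtype=float),
            b2=float(p["b2"]),
            mean=np.asarray(p["mean"], dtype=float),
            std=np.asarray(p["std"], dtype=float),
            theta=p["theta"],
            span=p["span"],
            seed=p["seed"],
            degenerate=p["degenerate"],
            n_epochs=p["n_epochs"],
            final_loss=p["final_loss"],
        )


def train_nn(
    X: np.ndarray,
    classes: np.ndarray,
    seed: int | None = None,
    hidden: int = 4,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    max_epochs: int = 500,
    batch_size: int = 32,
    tol: float = 1e-6,
    patience: int = 20,
    theta: float = DEFAULT_THETA,
    span: int = DEFAULT_SPAN,
) -> NNModel:
    """Back-propagation training on pure-class windows.

    ``classes`` may contain 0 (mixed) entries; they are dropped before
    training.  Inputs are standardised to zero mean / unit variance using the
    training windows' own statistics (tanh saturates on raw latent
    coordinates); the statistics are stored in the model and applied at
    prediction time.  Optimisation is mini-batch gradient descent with
    momentum on the squared error against +1/-1 targets, stopping early when
    the full-set loss stops improving by ``tol`` for ``patience`` consecutive
    epochs.  Deterministic given ``seed``.

    A single-class training set is fitted anyway but flagged
    ``degenerate=True`` with a warning.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    if X.shape[0] != classes.shape[0]:
        raise ValueError("X and classes length mismatch")
    keep = classes != 0
    X, y = X[keep], classes[keep].astype(float)
    if X.shape[0] == 0:
        raise ValueError("no pure-class windows to train on")
    present = np.unique(y)
    degenerate = len(present) < 2
    if degenerate:
        warnings.warn(
            f"training set contains a single class ({present[0]:+.0f}); "
            "fitting anyway, model flagged degenerate",
            stacklevel=2,
        )

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    rng = np.random.default_rng(seed)
    n_in = X.shape[1]
    W1 = rng.uniform(-0.5, 0.5, size=(hidden, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(n_in)
    W2 = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(hidden)
    b2 = rng.uniform(-0.5, 0.5) / np.sqrt(hidden)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = 0.0

    n = Z.shape[0]
    best = np.inf
    streak = 0
    epoch = 0
    loss = np.inf
    for epoch in range(1, max_epochs + 1):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            Xb, yb = Z[idx], y[idx]
            H = np.tanh(Xb @ W1.T + b1)
            out = np.tanh(H @ W2 + b2)
            # 0.5 * mean squared error gradients
            d_out = (out - yb) * (1.0 - out**2) / len(idx)
            gW2 = H.T @ d_out
            gb2 = d_out.sum()
            d_hid = np.outer(d_out, W2) * (1.0 - H**2)
            gW1 = d_hid.T @ Xb
            gb1 = d_hid.sum(axis=0)
            vW1 = momentum * vW1 - learning_rate * gW1
            vb1 = momentum * vb1 - learning_rate * gb1
            vW2 = momentum * vW2 - learning_rate * gW2
            vb2 = momentum * vb2 - learning_rate * gb2
            W1 += vW1
            b1 += vb1
            W2 += vW2
            b2 += vb2
        H = np.tanh(Z @ W1.T + b1)
        out = np.tanh(H @ W2 + b2)
        loss = float(0.5 * np.mean((out - y) ** 2))
        if loss < best - tol:
            best = loss
            streak = 0
        else:
            streak += 1
            if streak >= patience:
                break

    return NNModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        mean=mean,
        std=std,
        theta=theta,
        span=span,
        seed=seed,
        degenerate=degenerate,
        n_epochs=epoch,
        final_loss=loss,
    )


def predict_residues(features: FeatureSet, model: NNModel) -> np.ndarray:
    """Decode analog window outputs into a per-residue TM/non-TM vector.

    For each window with output strictly above ``model.theta``, the ``span``
    residues starting at the window's first position are marked TM (clipped
    at the protein end); residues never marked stay non-TM.
    """
    if features.projected is None:
        raise ValueError("features must be projected before prediction")
    L = features.sequence_length
    labels = np.zeros(L, dtype=np.int8)
    outputs = model.forward(features.projected)
    for s in features.window_starts[outputs > model.theta]:
        labels[s : s + model.span] = 1
    return labels


def predict_segments(
    features: FeatureSet, model: NNModel, min_len: int = 1
) -> list[tuple[int, int]]:
    """Predicted TM segments (1-based inclusive), shortest-first filtered.

    Maximal runs of decoded TM residues; runs shorter than ``min_len``
    residues are discarded (default 1 — no filtering).
    """
    labels = predict_residues(features, model)
    return [
        (s, e) for s, e in labels_to_segments(labels) if e - s + 1 >= min_len
    ]
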