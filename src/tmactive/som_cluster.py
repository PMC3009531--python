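"""Self-organizing map over the projected window features.

A 5x10 hexagonal SOM (50 nodes) is trained once on a random sample of the
unlabeled pool's projected windows and then frozen; assigning every window of
every protein to its nearest node (Euclidean distance) clusters the feature
space around the 50 node centroids.  Node identity is the currency of the
active-learning selectors: which nodes a protein's windows hit, and how
confused the labels within a node are.

Coordinate contract: grid node (r, c) in row-offset order (node index
r * cols + c) is converted to axial coordinates q = c - (r - (r & 1)) // 2,
then embedded in the plane as x = q + r/2, y = r * sqrt(3)/2.  Adjacent
hexagonal neighbours are at planar distance exactly 1; neighbourhood radii
and the Gaussian kernel are measured in this plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_ROWS = 5
DEFAULT_COLS = 10
DEFAULT_N_SAMPLES = 1000


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Planar (x, y) coordinates of each node of the hexagonal lattice."""
    r = np.repeat(np.arange(rows), cols)
    c = np.tile(np.arange(cols), rows)
    q = c - (r - (r & 1)) // 2
    x = q + r / 2.0
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])


@dataclass
class SOMModel:
    """A trained map: grid geometry, node weights and training provenance."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows*cols, k)
    seed: int | None = None
    n_samples: int = DEFAULT_N_SAMPLES
    radius: tuple[float, float] = (3.0, 1.0)
    learning_rate: tuple[float, float] = (0.5, 0.01)
    updates_per_sample: int = 10
    quantization_error_initial: float | None = None
    quantization_error_final: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def grid(self) -> np.ndarray:
        return hex_positions(self.rows, self.cols)

    def save(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "weights": self.weights.tolist(),
            "seed": self.seed,
            "n_samples": self.n_samples,
            "radius": list(self.radius),
            "learning_rate": list(self.learning_rate),
            "updates_per_sample": self.updates_per_sample,
            "quantization_error_initial": self.quantization_error_initial,
            "quantization_error_final": self.quantization_error_final,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        p = json.loads(Path(path).read_text())
        return cls(
            rows=p["rows"],
            cols=p["cols"],
            weights=np.asarray(p["weights"], dtype=float),
            seed=p["seed"],
            n_samples=p["n_samples"],
            radius=tuple(p["radius"]),
            learning_rate=tuple(p["learning_rate"]),
            updates_per_sample=p["updates_per_sample"],
            quantization_error_initial=p["quantization_error_initial"],
            quantization_error_final=p["quantization_error_final"],
        )


def quantization_error(data: np.ndarray, weights: np.ndarray) -> float:
    """Mean distance from each data point to its nearest node."""
    d = np.linalg.norm(data[:, None, :] - weights[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def train_som(
    data: np.ndarray,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
    radius: tuple[float, float] = (3.0, 1.0),
    learning_rate: tuple[float, float] = (0.5, 0.01),
    updates_per_sample: int = 10,
) -> SOMModel:
    """Train a hexagonal SOM with sequential (online) updates.

    A random sample of ``n_samples`` rows of ``data`` (all rows, with a
    warning, if fewer are available) is presented for a total of
    ``updates_per_sample * n_samples`` single-vector updates.  The
    neighbourhood is a Gaussian on planar hexagonal lattice distance whose
    radius decays linearly from ``radius[0]`` to ``radius[1]``; the learning
    rate decays linearly from ``learning_rate[0]`` to ``learning_rate[1]``.
    Weights are initialised by sampling data points with the run seed, so
    every weight stays inside the convex hull (hence the bounding box) of the
    training sample throughout.  Deterministic given ``seed``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("train_som: data must be a non-empty 2-D array")
    if rows <= 0 or cols <= 0:
        raise ValueError("train_som: grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    if data.shape[0] < n_samples:
        warnings.warn(
            f"pool has {data.shape[0]} windows < n_samples={n_samples}; using all",
            stacklevel=2,
        )
        sample = data
    else:
        sample = data[rng.choice(data.shape[0], size=n_samples, replace=False)]

    n_nodes = rows * cols
    init_idx = rng.choice(sample.shape[0], size=n_nodes, replace=sample.shape[0] < n_nodes)
    weights = sample[init_idx].copy()
    qe0 = quantization_error(sample, weights)

    grid = hex_positions(rows, cols)
    # pairwise lattice distances, precomputed once
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    total = updates_per_sample * sample.shape[0]
    order = rng.integers(0, sample.shape[0], size=total)
    denom = max(total - 1, 1)
    for t in range(total):
        frac = t / denom
        # the radius is the influence cutoff: the Gaussian falls to ~exp(-2)
        # at lattice distance `radius`, i.e. sigma = radius / 2
        sigma = 0.5 * (radius[0] + (radius[1] - radius[0]) * frac)
        lr = learning_rate[0] + (learning_rate[1] - learning_rate[0]) * frac
        x = sample[order[t]]
        bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
        weights += (lr * h)[:, None] * (x - weights)

    return SOMModel(
        rows=rows,
        cols=cols,
        weights=weights,
        seed=seed,
        n_samples=n_samples,
        radius=radius,
        learning_rate=learning_rate,
        updates_per_sample=updates_per_sample,
        quantization_error_initial=qe0,
        quantization_error_final=quantization_error(sample, weights),
    )


def assign(projected: np.ndarray, som: SOMModel) -> np.ndarray:
    """Nearest node (Euclidean) for each projected window row.

    Ties break toward the lowest node index.  Idempotent and independent of
    row order.
    """
    projected = np.atleast_2d(np.asarray(projected, dtype=float))
    if projected.shape[1] != som.weights.shape[1]:
        raise ValueError(
            f"dimension mismatch: windows have {projected.shape[1]} dims, "
            f"SOM weights have {som.weights.shape[1]}"
        )
    # direct differences (not the expanded dot-product form) so exact ties
    # stay exact and resolve to the lowest node index
    d2 = ((projected[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
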