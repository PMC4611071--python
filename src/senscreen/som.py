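"""Self-organizing-map clustering of fingerprint vectors.

A rectangular grid of prototype vectors (default 10 x 10) is trained
online with a Gaussian neighborhood whose radius and learning rate decay
linearly over the configured number of epochs. Binary fingerprints are
treated as points in Euclidean space, so neuron weights become fractional
bit prototypes. Reported per neuron: compound loadings (best-matching-unit
counts) and neighbor weight distances (the U-matrix) whose ridges mark
cluster boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("senscreen")


@dataclass
class SOMConfig:
    width: int = 10
    height: int = 10
    iterations: int = 200  # epochs over the data
    learning_rate: tuple[float, float] = (0.5, 0.01)  # linear initial -> final
    radius: tuple[float, float] | None = None  # default max(w,h)/2 -> 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.radius is None:
            self.radius = (max(self.width, self.height) / 2.0, 1.0)


@dataclass
class SOMGrid:
    config: SOMConfig
    weights: np.ndarray  # (height * width, dim), row-major neuron order
    qe_history: list[float] = field(default_factory=list)  # incl. initial

    def neuron_position(self, index: int) -> tuple[int, int]:
        return divmod(index, self.config.width)


def _bmu(weights: np.ndarray, x: np.ndarray) -> int:
    d2 = np.sum((weights - x) ** 2, axis=1)
    return int(np.argmin(d2))  # ties to the lowest neuron index


def quantization_error(weights: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance of each vector to its best-matching neuron."""
    d2 = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def train_som(data: np.ndarray, config: SOMConfig | None = None) -> SOMGrid:
    """Online SOM training, reproducible from the configured seed.

    Each epoch presents every vector once in a freshly shuffled order;
    every neuron moves toward the vector with a Gaussian weight in grid
    distance from the best-matching unit.
    """
    config = config or SOMConfig()
    X = np.atleast_2d(np.asarray(data, dtype=float))
    n, dim = X.shape
    if dim == 0:
        raise ValueError("zero-dimensional data")
    rng = np.random.default_rng(config.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    n_neurons = config.width * config.height
    weights = rng.uniform(size=(n_neurons, dim)) * (hi - lo) + lo

    rows, cols = np.divmod(np.arange(n_neurons), config.width)
    grid_d2 = (rows[:, None] - rows[None, :]) ** 2 + (cols[:, None] - cols[None, :]) ** 2

    lr0, lr1 = config.learning_rate
    r0, r1 = config.radius
    history = [quantization_error(weights, X)]
    T = config.iterations
    for t in range(T):
        frac = t / max(T - 1, 1)
        lr = lr0 + (lr1 - lr0) * frac
        radius = max(r0 + (r1 - r0) * frac, 1e-9)
        order = rng.permutation(n)
        denom = 2.0 * radius * radius
        for i in order:
            x = X[i]
            b = _bmu(weights, x)
            h = np.exp(-grid_d2[b] / denom)
            weights += (lr * h)[:, None] * (x - weights)
        history.append(quantization_error(weights, X))
    grid = SOMGrid(config=config, weights=weights, qe_history=history)
    logger.info("SOM trained: QE %.4f -> %.4f", history[0], history[-1])
    return grid


def neuron_loadings(
    grid: SOMGrid, data: np.ndarray, ids=None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Best-matching-unit counts per neuron; counts always sum to n.

    Returns (counts as a height x width array, long-format table with
    member ids per neuron).
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != grid.weights.shape[1]:
        raise ValueError("data dimension does not match neuron weights")
    ids = [str(i) for i in (ids if ids is not None else range(X.shape[0]))]
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    w, h = grid.config.width, grid.config.height
    counts = np.bincount(bmu, minlength=w * h).reshape(h, w)
    rows = []
    for neuron in range(w * h):
        members = [ids[i] for i in np.where(bmu == neuron)[0]]
        r, c = divmod(neuron, w)
        rows.append({"row": r, "col": c, "count": len(members), "members": ";".join(members)})
    return counts, pd.DataFrame(rows)


def neighbor_distances(grid: SOMGrid) -> pd.DataFrame:
    """U-matrix entries: weight distance for each adjacent neuron pair."""
    w, h = grid.config.width, grid.config.height
    rows = []
    for r in range(h):
        for c in range(w):
            i = r * w + c
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w:
                    j = r2 * w + c2
                    d = float(np.linalg.norm(grid.weights[i] - grid.weights[j]))
                    rows.append(
                        {"row1": r, "col1": c, "row2": r2, "col2": c2, "distance": d}
                    )
    return pd.DataFrame(rows)
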