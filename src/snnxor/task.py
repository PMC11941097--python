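"""Analog XOR ground truth, surface normalization, and boundary accuracy.

The analog XOR task labels an input pair (x0, x1) in [0, 1]^2 HIGH exactly
when one of the two inputs meets or exceeds the input boundary ``b``.  A
circuit's raw output statistic over an input grid (spike counts or ReLU
activations) is normalized by its grid maximum into [0, 1] and digitized
against the output threshold ``h``; accuracy is the fraction of grid points
where the digitized output matches the label.  Ties at either threshold
count as HIGH (the >= convention of the task's truth table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskBoundary",
    "AccuracySurface",
    "xor_label",
    "normalize_surface",
    "accuracy",
    "accuracy_grid",
]


@dataclass(frozen=True)
class TaskBoundary:
    """Decision boundary: input-side boundary b, output firing threshold h."""

    b: float
    h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if not 0.0 < self.h < 1.0:
            raise ValueError("h must lie in (0, 1)")


def xor_label(x0, x1, b: float):
    """HIGH (True) iff exactly one of x0, x1 is >= b.  Vectorized."""
    return np.logical_xor(np.asarray(x0) >= b, np.asarray(x1) >= b)


def normalize_surface(raw: np.ndarray) -> np.ndarray:
    """Scale a non-negative output surface by its maximum into [0, 1].

    An all-zero surface (degenerate circuit that never fires) is returned
    unchanged with a warning rather than dividing by zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("surface must be non-empty")
    if np.any(raw < 0):
        raise ValueError("raw surface values must be non-negative")
    m = raw.max()
    if m == 0:
        warnings.warn("all-zero output surface: circuit never responded", stacklevel=2)
        return raw.copy()
    return raw / m


@dataclass(frozen=True)
class AccuracySurface:
    """Normalized output statistic of one circuit over the input grid.

    ``raw[i, j]`` is the output statistic at (x0 = x0_values[i],
    x1 = x1_values[j]); ``normalized`` is ``raw`` scaled by its grid
    maximum.
    """

    x0_values: np.ndarray
    x1_values: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0_values, dtype=float)
        x1 = np.asarray(self.x1_values, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        if raw.shape != (x0.size, x1.size):
            raise ValueError("raw surface shape must match the input grid")
        object.__setattr__(self, "x0_values", x0)
        object.__setattr__(self, "x1_values", x1)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "normalized", normalize_surface(raw))

    def accuracy(self, boundary: TaskBoundary) -> float:
        return accuracy(self.normalized, self.x0_values, self.x1_values,
                        boundary.b, boundary.h)

    def accuracy_grid(self, b_values, h_values) -> np.ndarray:
        return accuracy_grid(self.normalized, self.x0_values, self.x1_values,
                             b_values, h_values)

    def best_boundary(self, b_values, h_values) -> tuple[TaskBoundary, float]:
        """Exhaustive argmax over the (b, h) grid; ties go to the smallest (b, h)."""
        acc = self.accuracy_grid(b_values, h_values)
        best = acc.max()
        bi, hi = np.argwhere(acc == best)[0]  # argwhere scans row-major: smallest (b, h)
        return TaskBoundary(float(np.asarray(b_values)[bi]),
                            float(np.asarray(h_values)[hi])), float(best)


def accuracy(normalized, x0_values, x1_values, b: float, h: float) -> float:
    """Fraction of grid points where the digitized output matches the XOR label."""
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size == 0:
        raise ValueError("empty grid")
    x0 = np.asarray(x0_values, dtype=float)[:, None]
    x1 = np.asarray(x1_values, dtype=float)[None, :]
    label = xor_label(x0, x1, b)
    pred = normalized >= h
    return float(np.mean(pred == label))


def accuracy_grid(normalized, x0_values, x1_values, b_values, h_values) -> np.ndarray:
    """Accuracy over a whole (b, h) candidate grid at once.

    Returns an array of shape (len(b_values), len(h_values)); equivalent to
    calling :func:`accuracy` per cell but evaluated with one matrix product
    over the flattened grid.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.size == 0:
        raise ValueError("empty grid")
    x0 = np.asarray(x0_values, dtype=float)
    x1 = np.asarray(x1_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    h_values = np.asarray(h_values, dtype=float)

    X0, X1 = np.meshgrid(x0, x1, indexing="ij")
    pts0, pts1 = X0.ravel(), X1.ravel()
    n = pts0.size
    # labels: (n_b, n) booleans; predictions: (n_h, n)
    labels = np.logical_xor(pts0[None, :] >= b_values[:, None],
                            pts1[None, :] >= b_values[:, None])
    preds = normalized.ravel()[None, :] >= h_values[:, None]
    L = labels.astype(np.float64)
    P = preds.astype(np.float64)
    # matches = L.P^T + (1-L).(1-P)^T
    agree = L @ P.T + (1.0 - L) @ (1.0 - P).T
    return agree / n
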