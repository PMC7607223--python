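"""Penalized fitting criteria for warp estimation.

Four criteria measure how well a warped response x*(t) matches a target y(t)
on the normalized window [0, 1]:

* ``psd``  — penalized squared difference: int |y - x*|^2 dt + lambda * pen
* ``psdd`` — the same on the curves' numeric derivatives
* ``pmc``  — penalized maximum correlation: -rho(y, x*) + lambda * pen
* ``pmcd`` — maximum correlation of the derivatives

where pen = int w'(t)^2 dt is the warping roughness penalty (the relative
curvature h''/h' of the warp) and lambda >= 0 the smoothing parameter.
Integrals use the left-endpoint rectangle rule over normalized time, so
lambda values are comparable across sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .warping import SplineBasis, roughness_penalty

CRITERIA = ("psd", "psdd", "pmc", "pmcd")
#: smoothing-parameter grid used throughout: no penalty plus four decade steps
LAMBDA_GRID = (0.0, 0.001, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class LossConfig:
    criterion: str = "psdd"
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}; choose from {CRITERIA}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def derivative_domain(self) -> bool:
        return self.criterion in ("psdd", "pmcd")

    @property
    def correlation_based(self) -> bool:
        return self.criterion in ("pmc", "pmcd")


def loss_grid(criteria=CRITERIA, lambdas=LAMBDA_GRID) -> list[LossConfig]:
    """Enumerate the full criterion x lambda grid (4 x 5 = 20 loss functions)."""
    return [LossConfig(c, l) for c in criteria for l in lambdas]


def rect_integral(f: np.ndarray, du: float) -> float:
    """Left-endpoint rectangle rule on an equally spaced grid."""
    return float(np.sum(f[:-1]) * du)


def numeric_derivative(x: np.ndarray, du: float | None = None) -> np.ndarray:
    """Forward difference quotient, same length as input (last value replicated).

    ``du`` is the grid step in normalized time; default assumes x spans [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if du is None:
        du = 1.0 / (x.size - 1)
    d = np.diff(x) / du
    return np.concatenate((d, d[-1:]))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors (rather than returning 0) on
    zero-variance input, since a silent 0 would corrupt correlation-based
    fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must share a length >= 3")
    da = a - a.mean()
    db = b - b.mean()
    va = np.dot(da, da)
    vb = np.dot(db, db)
    if va == 0.0 or vb == 0.0:
        raise ZeroDivisionError("correlation undefined for zero-variance input")
    return float(np.clip(np.dot(da, db) / np.sqrt(va * vb), -1.0, 1.0))


def loss(
    x_warped: np.ndarray,
    target: np.ndarray,
    coeffs: np.ndarray,
    config: LossConfig,
    basis: SplineBasis | None = None,
) -> float:
    """Evaluate the configured penalized criterion between x* and y."""
    x_warped = np.asarray(x_warped, dtype=float)
    target = np.asarray(target, dtype=float)
    if x_warped.shape != target.shape:
        raise ValueError("x_warped and target must share a grid")
    du = 1.0 / (x_warped.size - 1)
    if config.derivative_domain:
        x_warped = numeric_derivative(x_warped, du)
        target = numeric_derivative(target, du)
    pen = config.lam * roughness_penalty(coeffs, basis) if config.lam else 0.0
    if config.correlation_based:
        return -pearson(target, x_warped) + pen
    diff = target - x_warped
    return rect_integral(diff * diff, du) + pen
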