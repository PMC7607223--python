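"""Continuous monotone time-warping functions.

A warping function h(t) maps normalized structural time in [0, 1] to an
individual response's own normalized time axis.  Monotonicity is guaranteed
by construction: the natural logarithm of the derivative, w(t) = ln h'(t),
is modelled as a linear combination of 2nd-order (piecewise-linear) B-splines
on equally spaced knots,

    w(t) = sum_k c_k B_k(t),     h(t) = A + B * int_0^t exp{w(u)} du,

with A, B fixed by the endpoint constraints h(0) = 0, h(1) = 1 (hence A = 0
and B = 1 / int_0^1 exp{w}).  Since exp{w} > 0 for any finite coefficient
vector, h is strictly increasing whatever the optimizer proposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeWindow",
    "SplineBasis",
    "MonotoneMap",
    "WarpFunction",
    "bspline_basis",
    "eval_logderiv",
    "build_warp",
    "warp_response",
    "invert_warp",
    "compose_warps",
    "average_warps",
    "roughness_penalty",
]


@dataclass(frozen=True)
class TimeWindow:
    """Warping time range with its sampling grid.

    Normalized time is t = (time_ms - start_ms) / (end_ms - start_ms).
    """

    start_ms: float
    end_ms: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("end_ms must exceed start_ms")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")

    @classmethod
    def from_fs(cls, start_ms: float, end_ms: float, fs: float) -> "TimeWindow":
        """Window sampled at rate ``fs`` (Hz); sample count ceil(duration*fs)."""
        n = int(np.ceil((end_ms - start_ms) / 1000.0 * fs))
        return cls(start_ms, end_ms, n)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def grid(self) -> np.ndarray:
        """Normalized sample times on [0, 1]."""
        return np.linspace(0.0, 1.0, self.n_samples)

    @property
    def times_ms(self) -> np.ndarray:
        return self.start_ms + self.grid * self.duration_ms

    def to_norm(self, time_ms):
        return (np.asarray(time_ms, dtype=float) - self.start_ms) / self.duration_ms

    def to_ms(self, t):
        return self.start_ms + np.asarray(t, dtype=float) * self.duration_ms


@dataclass(frozen=True)
class SplineBasis:
    """K equally spaced knots t_k = (k-1)*dt on [0, 1], dt = 1/(K-1)."""

    K: int

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")

    @property
    def dt(self) -> float:
        return 1.0 / (self.K - 1)

    @property
    def knots(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.K)


def bspline_basis(t: float, k: int, basis: SplineBasis) -> float:
    """Evaluate the k-th (1-based) linear B-spline hat function at t.

    B_k is the triangular hat rising over [t_{k-1}, t_k] and falling over
    [t_k, t_{k+1}]; the boundary splines (k = 1 and k = K) omit the half that
    falls outside [0, 1].
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    if not 1 <= k <= basis.K:
        raise ValueError(f"knot index {k} outside 1..{basis.K}")
    knots = basis.knots
    dt = basis.dt
    tk = knots[k - 1]
    if k > 1 and knots[k - 2] <= t <= tk:
        return (t - knots[k - 2]) / dt
    if k < basis.K and tk <= t <= knots[k]:
        return (knots[k] - t) / dt
    if t == tk:  # boundary spline apex
        return 1.0
    return 0.0


def eval_logderiv(coeffs: np.ndarray, t, basis: SplineBasis):
    """w(t) = sum_k c_k B_k(t): the piecewise-linear interpolant of coeffs.

    For linear hat functions on the knot grid this is exactly linear
    interpolation of the coefficient values, with w(t_k) = c_k.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (basis.K,):
        raise ValueError(f"expected {basis.K} coefficients, got {coeffs.shape}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise ValueError("t outside [0, 1]")
    return np.interp(t, basis.knots, coeffs)


class MonotoneMap:
    """A strictly increasing, endpoint-pinned map of [0, 1] sampled on a grid.

    Base class for fitted warps, their compositions, pointwise averages and
    inverses; evaluation between grid points uses linear interpolation.
    """

    def __init__(self, grid: np.ndarray, values: np.ndarray):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.shape != values.shape or grid.ndim != 1:
            raise ValueError("grid/values shape mismatch")
        if np.any(np.diff(values) <= 0):
            raise ValueError("map values are not strictly increasing")
        self.grid = grid
        self.values = values

    def __call__(self, t):
        return np.interp(t, self.grid, self.values)

    @property
    def n_grid(self) -> int:
        return self.grid.size


class WarpFunction(MonotoneMap):
    """Monotone warp h(t) = A + B * int_0^t exp{w(u)} du built from B-spline
    coefficients of w = ln h'.  ``shift`` (A) and ``scale`` (B) pin h(0)=0,
    h(1)=1; the coefficients are the canonical representation."""

    def __init__(
        self,
        coeffs: np.ndarray,
        basis: SplineBasis,
        grid: np.ndarray,
        values: np.ndarray,
        shift: float,
        scale: float,
        window: TimeWindow | None = None,
    ):
        super().__init__(grid, values)
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.basis = basis
        self.shift = shift
        self.scale = scale
        self.window = window

    def to_json(self) -> str:
        if self.window is None:
            raise ValueError("window required for serialization")
        return json.dumps(
            {
                "K": self.basis.K,
                "window": {
                    "start_ms": self.window.start_ms,
                    "end_ms": self.window.end_ms,
                    "n_samples": self.window.n_samples,
                },
                "coeffs": self.coeffs.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str, n_grid: int | None = None) -> "WarpFunction":
        d = json.loads(text)
        window = TimeWindow(**d["window"])
        return build_warp(np.asarray(d["coeffs"]), window, n_grid or window.n_samples)


def build_warp(coeffs, window: TimeWindow, n_grid: int | None = None) -> WarpFunction:
    """Construct the monotone warp from log-derivative spline coefficients.

    Integration uses the left-endpoint rectangle rule on ``n_grid`` points
    (default: the window's own sample grid).  For any finite coefficient
    vector the result is strictly increasing with h(0)=0 and h(1)=1.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite warp coefficients")
    basis = SplineBasis(coeffs.size)
    if n_grid is None:
        n_grid = window.n_samples
    if n_grid < basis.K:
        raise ValueError("n_grid must be >= K")
    grid = np.linspace(0.0, 1.0, n_grid)
    w = np.interp(grid, basis.knots, coeffs)
    e = np.exp(w)
    du = grid[1] - grid[0]
    integral = np.concatenate(([0.0], np.cumsum(e[:-1]) * du))
    scale = 1.0 / integral[-1]
    values = integral * scale
    values[-1] = 1.0  # pin endpoint exactly
    return WarpFunction(coeffs, basis, grid, values, shift=0.0, scale=scale, window=window)


def identity_warp(window: TimeWindow, K: int = 13, n_grid: int | None = None) -> WarpFunction:
    return build_warp(np.zeros(K), window, n_grid)


def warp_response(x: np.ndarray, warp: MonotoneMap) -> np.ndarray:
    """Aligned response x*(t) = x{h(t)} by linear interpolation.

    ``x`` must be sampled on the same normalized grid as the warp; since
    h(0)=0 and h(1)=1 no extrapolation can occur.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != warp.grid.shape:
        raise ValueError(f"response shape {x.shape} != warp grid {warp.grid.shape}")
    return np.interp(warp.values, warp.grid, x)


def invert_warp(warp: MonotoneMap) -> MonotoneMap:
    """h^{-1} sampled on the same grid, by interpolating swapped (h(t), t) pairs."""
    values = np.interp(warp.grid, warp.values, warp.grid)
    return MonotoneMap(warp.grid, values)


def compose_warps(outer: MonotoneMap, inner: MonotoneMap) -> MonotoneMap:
    """(outer ∘ inner)(t) = outer(inner(t)) on the shared grid."""
    if outer.grid.shape != inner.grid.shape:
        raise ValueError("grid mismatch")
    return MonotoneMap(inner.grid, np.interp(inner.values, outer.grid, outer.values))


def average_warps(warps: list[MonotoneMap]) -> MonotoneMap:
    """Pointwise mean of warps on a shared grid.

    A mean of strictly increasing endpoint-pinned maps is itself strictly
    increasing and endpoint-pinned.
    """
    if not warps:
        raise ValueError("no warps to average")
    grid = warps[0].grid
    for w in warps[1:]:
        if w.grid.shape != grid.shape:
            raise ValueError("grid mismatch")
    return MonotoneMap(grid, np.mean([w.values for w in warps], axis=0))


def roughness_penalty(coeffs, basis: SplineBasis | None = None) -> float:
    """int_0^1 w'(t)^2 dt for the piecewise-linear w defined by ``coeffs``.

    w' is constant on each knot interval, so the integral has the closed form
    sum_k (c_{k+1} - c_k)^2 / dt.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if basis is None:
        basis = SplineBasis(coeffs.size)
    if coeffs.shape != (basis.K,):
        raise ValueError(f"expected {basis.K} coefficients")
    return float(np.sum(np.diff(coeffs) ** 2) / basis.dt)
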