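"""First-passage-time (Wiener) distribution of the constant-drift diffusion.

The two-boundary diffusion is the response-time kernel of the strategy model:
evidence X(t) starts at ``bias * alpha``, drifts at rate ``drift`` with unit
diffusion coefficient, and is absorbed at 0 (error) or ``alpha`` (correct).
The defective first-passage density at each boundary is evaluated with the
standard small-time / large-time series representations, switching adaptively
to whichever needs fewer terms for a requested absolute tolerance.

Conventions
-----------
* ``boundary="correct"`` is the upper boundary, ``"error"`` the lower one.
* Densities are per second and defective: the two boundary masses sum to 1.
* ``tau`` (non-decision time) shifts the density; density is 0 for rt <= tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "WienerParams",
    "wiener_logpdf",
    "wiener_pdf",
    "wiener_cdf",
    "boundary_mass",
    "simulate_first_passage",
]

#: absolute tolerance of the series truncation
SERIES_ATOL = 1e-10

# boundary codes
CORRECT, ERROR = 1, 0


@dataclass(frozen=True)
class WienerParams:
    """Four-parameter Wiener distribution (threshold, drift, non-decision, bias)."""

    alpha: float
    drift: float
    tau: float
    bias: float = 0.5

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.tau >= 0):
            raise ValueError(f"tau must be non-negative, got {self.tau}")
        if not (0.0 < self.bias < 1.0):
            raise ValueError(f"bias must lie in (0, 1), got {self.bias}")
        if not np.isfinite(self.drift):
            raise ValueError("drift must be finite")


@njit(cache=True)
def _fpt_lower_std(u: float, w: float, atol: float) -> float:
    """Density of first passage through the LOWER boundary for the unit problem
    (alpha=1, drift=0, start w), at normalized time u.  Series per the
    small-time/large-time dual representation with adaptive truncation."""
    if u <= 0.0:
        return 0.0
    # number of terms needed by each representation
    if math.pi * u * atol < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * atol) / (math.pi**2 * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if 2.0 * math.sqrt(2.0 * math.pi * u) * atol < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * atol * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if ks < kl:  # small-time representation
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-K, K + 1):
            z = w + 2.0 * k
            acc += z * math.exp(-z * z / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u**3)
    K = int(math.ceil(kl))  # large-time representation
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-(k**2) * math.pi**2 * u / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@njit(cache=True)
def _wiener_logpdf_scalar(
    rt: float, boundary: int, alpha: float, drift: float, tau: float, bias: float
) -> float:
    """Log defective density at the named boundary; -inf where density is 0."""
    t = rt - tau
    if t <= 0.0:
        return -np.inf
    if boundary == 1:  # upper boundary: reflect (drift -> -drift, w -> 1 - w)
        v = -drift
        w = 1.0 - bias
    else:
        v = drift
        w = bias
    u = t / (alpha * alpha)
    f = _fpt_lower_std(u, w, SERIES_ATOL)
    if f <= 0.0:
        return -np.inf
    return math.log(f) - 2.0 * math.log(alpha) - v * alpha * w - v * v * t / 2.0


def wiener_logpdf(rt, boundary, p: WienerParams):
    """Log first-passage density; `boundary` is "correct"/"error" or 1/0."""
    b = _boundary_code(boundary)
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    for i, t in enumerate(rt_arr):
        out[i] = _wiener_logpdf_scalar(t, b, p.alpha, p.drift, p.tau, p.bias)
    return out[0] if np.isscalar(rt) or np.asarray(rt).ndim == 0 else out


def wiener_pdf(rt, boundary, p: WienerParams):
    """Defective first-passage density (per second) at the named boundary."""
    return np.exp(wiener_logpdf(rt, boundary, p))


def _boundary_code(boundary) -> int:
    if boundary in ("correct", "upper", 1, True):
        return CORRECT
    if boundary in ("error", "lower", 0, False):
        return ERROR
    raise ValueError(f"unknown boundary {boundary!r}")


def boundary_mass(boundary, p: WienerParams) -> float:
    """Total probability of absorption at the named boundary (closed form)."""
    b = _boundary_code(boundary)
    v, a, w = p.drift, p.alpha, p.bias
    if abs(v) < 1e-12:
        p_upper = w
    else:
        # scale-function ratio for dX = v dt + dW on (0, a), start w*a
        p_upper = -math.expm1(-2.0 * v * w * a) / -math.expm1(-2.0 * v * a)
    return p_upper if b == CORRECT else 1.0 - p_upper


def wiener_cdf(rt, boundary, p: WienerParams, *, n_grid: int = 4096):
    """Defective CDF at the named boundary by adaptive trapezoid integration
    of the analytic density (vectorized over rt)."""
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    hi = max(rt_arr.max(), p.tau + 1e-3)
    # quadratic clustering near tau where the density peaks
    grid = p.tau + (hi - p.tau) * np.linspace(0.0, 1.0, n_grid) ** 2
    dens = wiener_pdf(grid, boundary, p)
    cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
    out = np.interp(rt_arr, grid, cum, left=0.0)
    return out[0] if np.isscalar(rt) or np.asarray(rt).ndim == 0 else out


@njit(cache=True)
def _simulate_em(
    n: int,
    alpha: float,
    drift: float,
    tau: float,
    bias: float,
    dt: float,
    correct_bounds: bool,
    t_max: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.zeros(n, dtype=np.bool_)
    # Broadie-Glasserman-Kou continuity correction for discrete boundary checks
    shift = 0.5826 * math.sqrt(dt) if correct_bounds else 0.0
    lo = 0.0 + shift
    hi = alpha - shift
    sdt = math.sqrt(dt)
    for i in range(n):
        x = bias * alpha
        t = 0.0
        while True:
            x += drift * dt + sdt * np.random.normal()
            t += dt
            if x >= hi:
                rts[i] = tau + t
                upper[i] = True
                break
            if x <= lo:
                rts[i] = tau + t
                upper[i] = False
                break
            if t > t_max:
                rts[i] = np.nan  # censored path
                break
    return rts, upper


def simulate_first_passage(
    n: int,
    p: WienerParams,
    *,
    dt: float = 1e-4,
    seed: int = 0,
    boundary_correction: bool = True,
    t_max: float = 60.0,
):
    """Euler–Maruyama simulation of the diffusion, independent of the series
    density.  Returns (rt array incl. tau, boolean upper/correct array); paths
    not absorbed by ``t_max`` decision-seconds come back as NaN.

    ``boundary_correction`` shrinks both boundaries by 0.5826*sqrt(dt) to
    remove the O(sqrt(dt)) discrete-monitoring bias of first-passage checks.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return _simulate_em(
        n, p.alpha, p.drift, p.tau, p.bias, dt, boundary_correction, t_max, seed
    )
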