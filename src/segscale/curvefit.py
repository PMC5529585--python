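"""Two-limbed fits of coherence threshold versus segment size.

Thresholds fall as a power law of segment size up to a knee-point k and are
flat beyond it:

    y(x) = t * (x / k)**s   for x <  k
    y(x) = t                for x >= k

with t the asymptotic threshold, s <= 0 the (descending-limb) exponent, and
the two limbs continuous at x = k. Fitting minimises summed squared
residuals in linear threshold space (a log-space option is exposed for
sensitivity analysis) via multi-start bounded local optimisation. When the
unconstrained knee estimate exceeds the largest tested segment size
(3.5 deg) the curve is conservatively re-fitted with the knee held fixed at
that value and flagged as clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ThresholdCurve",
    "CurveFit",
    "CurveFitError",
    "two_limb_value",
    "fit_two_limb",
    "r_squared",
    "fit_table",
]

#: Largest segment size tested; knees beyond it are clamped here.
KNEE_CLAMP = 3.5


class CurveFitError(ValueError):
    """Invalid input to the two-limbed fit, or a degenerate fit."""


@dataclass(frozen=True)
class ThresholdCurve:
    """Coherence thresholds (percent) at each tested segment size (deg)."""

    x: np.ndarray
    y: np.ndarray
    sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if len(self.x) != len(self.y):
            raise CurveFitError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise CurveFitError("segment sizes must be strictly increasing")
        if np.any(self.x <= 0):
            raise CurveFitError("segment sizes must be positive")
        if np.any(self.y <= 0) or np.any(self.y > 100.0):
            raise CurveFitError("thresholds must lie in (0, 100] percent")


@dataclass(frozen=True)
class CurveFit:
    """Fitted two-limbed parameters for one participant/condition."""

    k: float
    t: float
    s: float
    r2: float
    clamped: bool
    sse: float


def two_limb_value(x, k: float, t: float, s: float):
    """Evaluate the two-limbed function; continuous at x = k."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or k <= 0 or t <= 0:
        raise CurveFitError("x, k and t must be positive")
    out = np.where(x < k, t * (x / k) ** s, t)
    return float(out) if out.ndim == 0 else out


def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about the mean."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if len(observed) != len(fitted) or len(observed) < 2:
        raise CurveFitError("observed and fitted must share length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise CurveFitError("total variance is zero; R^2 undefined")
    ss_res = float(np.sum((observed - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _residual_factory(x, y, log_space):
    ly = np.log(y)

    def residuals(p):
        k, t, s = np.exp(p[0]), np.exp(p[1]), p[2]
        model = np.where(x < k, t * (x / k) ** s, t)
        if log_space:
            return np.log(model) - ly
        return model - y

    return residuals


def _fixed_k_residual_factory(x, y, k, log_space):
    ly = np.log(y)

    def residuals(p):
        t, s = np.exp(p[0]), p[1]
        model = np.where(x < k, t * (x / k) ** s, t)
        if log_space:
            return np.log(model) - ly
        return model - y

    return residuals


def fit_two_limb(
    curve,
    y: Optional[Sequence[float]] = None,
    *,
    clamp_max: float = KNEE_CLAMP,
    log_space: bool = False,
    s_bounds: tuple = (-8.0, 0.0),
) -> CurveFit:
    """Least-squares fit of the two-limbed function to a threshold curve.

    Accepts a :class:`ThresholdCurve` or separate ``x``/``y`` arrays (at
    least 4 points, non-constant). Optimisation runs from a grid of starts
    (knee over the x-range and beyond the clamp, slope over the permitted
    range) and keeps the best solution; ``s`` is constrained to
    ``s_bounds`` (non-positive, so the descending limb descends). If the
    best unconstrained knee exceeds ``clamp_max`` the fit is repeated with
    the knee fixed there and ``clamped=True``. ``r2`` is computed on the
    observed thresholds in linear space.
    """
    if y is not None:
        curve = ThresholdCurve(np.asarray(curve, dtype=float), np.asarray(y, dtype=float))
    elif not isinstance(curve, ThresholdCurve):
        raise CurveFitError("pass a ThresholdCurve or x and y arrays")
    x, yv = curve.x, curve.y
    if len(x) < 4:
        raise CurveFitError(f"need >= 4 points to fit, got {len(x)}")
    if np.allclose(yv, yv[0]):
        raise CurveFitError("constant thresholds: two-limbed fit is degenerate")

    res_fn = _residual_factory(x, yv, log_space)
    k_hi = 4.0 * clamp_max
    bounds_lo = [np.log(0.5 * x.min()), np.log(1e-6), s_bounds[0]]
    bounds_hi = [np.log(k_hi), np.log(1e4), s_bounds[1]]

    k_starts = list(x[1::2]) + [x.min(), clamp_max * 1.5]
    s_starts = (-0.5, -2.0)
    best = None
    for k0 in k_starts:
        flat = yv[x >= k0]
        t0 = float(flat.mean()) if len(flat) else float(yv[-1])
        t0 = min(max(t0, 1e-5), 9e3)
        for s0 in s_starts:
            p0 = np.array([np.log(k0), np.log(t0), s0])
            p0 = np.clip(p0, bounds_lo, bounds_hi)
            sol = least_squares(res_fn, p0, bounds=(bounds_lo, bounds_hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol

    k_fit = float(np.exp(best.x[0]))
    clamped = k_fit > clamp_max * (1.0 + 1e-9)
    if clamped:
        res_fixed = _fixed_k_residual_factory(x, yv, clamp_max, log_space)
        best_f = None
        for s0 in (-0.25, -1.0, -3.0):
            p0 = np.array([np.log(min(max(float(yv[-1]), 1e-5), 9e3)), s0])
            sol = least_squares(
                res_fixed, p0,
                bounds=([np.log(1e-6), s_bounds[0]], [np.log(1e4), s_bounds[1]]),
                method="trf",
            )
            if best_f is None or sol.cost < best_f.cost:
                best_f = sol
        k_fit = float(clamp_max)
        t_fit, s_fit = float(np.exp(best_f.x[0])), float(best_f.x[1])
    else:
        t_fit, s_fit = float(np.exp(best.x[1])), float(best.x[2])

    fitted = two_limb_value(x, k_fit, t_fit, s_fit)
    return CurveFit(
        k=k_fit,
        t=t_fit,
        s=s_fit,
        r2=r_squared(yv, fitted),
        clamped=clamped,
        sse=float(np.sum((yv - fitted) ** 2)),
    )


def fit_table(frame: pd.DataFrame, *, log_space: bool = False) -> pd.DataFrame:
    """Batch-fit a long table of threshold curves.

    Input columns: participant, task, segment_size, threshold. Returns one
    row per (participant, task) with columns k, t, s, r2, clamped; groups
    whose fit fails are reported with NaN parameters and the error message.
    """
    rows = []
    for (pid, task), grp in frame.groupby(["participant", "task"], sort=True):
        grp = grp.sort_values("segment_size")
        try:
            fit = fit_two_limb(grp["segment_size"].to_numpy(), grp["threshold"].to_numpy(),
                               log_space=log_space)
            rows.append(dict(participant=pid, task=task, k=fit.k, t=fit.t, s=fit.s,
                             r2=fit.r2, clamped=fit.clamped, error=""))
        except CurveFitError as exc:
            rows.append(dict(participant=pid, task=task, k=np.nan, t=np.nan, s=np.nan,
                             r2=np.nan, clamped=False, error=str(exc)))
    return pd.DataFrame(rows)
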