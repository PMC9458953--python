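"""Arrhenius analysis of rate-temperature data with breakpoint detection.

Rates are regressed as ln(k) on 1/T (kelvin); the activation energy is
-slope * R.  Mesophilic communities typically show a linear optimal range
and a steeper deviation below a critical temperature, so the model supports
one segment, a fixed two-segment split at a stated boundary temperature
(the boundary point belongs to both segments), or an exhaustive search over
boundary positions minimising the pooled residual sum of squares.  The
critical temperature is the intersection of the two fitted lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import CELSIUS_OFFSET, R_GAS


class InsufficientDataError(ValueError):
    """Fewer than two usable (positive-rate) points for a fit."""


class ParallelSegmentsError(ValueError):
    """Segment slopes too close for a meaningful intersection."""


#: Relative slope-difference threshold below which segments count as parallel.
PARALLEL_TOL = 1e-9


@dataclass(frozen=True)
class RatePoint:
    """One (temperature, volumetric rate) observation."""

    temperature_c: float
    rate: float  # mmol/L.h

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + CELSIUS_OFFSET


@dataclass(frozen=True)
class ArrheniusSegment:
    """One fitted ln(k) = intercept + slope * (1/T) line."""

    slope: float          # kelvin (on the 1/T axis)
    intercept: float      # ln(mmol/L.h)
    ea: float             # J/mol, = -slope * R
    r_squared: float
    n_points: int
    t_min_c: float
    t_max_c: float

    def predict(self, temperature_c: float) -> float:
        """Rate (mmol/L.h) at a temperature in degC."""
        inv_t = 1.0 / (temperature_c + CELSIUS_OFFSET)
        return math.exp(self.intercept + self.slope * inv_t)


@dataclass(frozen=True)
class ArrheniusModel:
    """One- or two-segment Arrhenius description of a rate-temperature curve."""

    warm: ArrheniusSegment
    cold: ArrheniusSegment | None = None
    t_crit_k: float | None = None
    mode: str = "single"

    @property
    def t_crit_c(self) -> float | None:
        return None if self.t_crit_k is None else self.t_crit_k - CELSIUS_OFFSET

    def predict(self, temperature_c: float) -> float:
        """Evaluate the segment whose temperature range contains the query."""
        if self.cold is not None and self.t_crit_k is not None \
                and temperature_c + CELSIUS_OFFSET < self.t_crit_k:
            return self.cold.predict(temperature_c)
        return self.warm.predict(temperature_c)


def _usable(points) -> list[RatePoint]:
    usable = []
    for p in points:
        if p.rate <= 0:
            warnings.warn(f"rate {p.rate} at {p.temperature_c} degC is not positive; "
                          "excluded from Arrhenius fit")
        else:
            usable.append(p)
    return usable


def fit_segment(points) -> ArrheniusSegment:
    """Ordinary least squares of ln(rate) on inverse absolute temperature.

    Exact (residual-free) for two points.  Non-positive rates are excluded
    with a warning; fewer than two usable points raises
    :class:`InsufficientDataError`.
    """
    usable = _usable(points)
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 points with positive rates")
    x = np.array([1.0 / p.temperature_k for p in usable])
    y = np.log([p.rate for p in usable])
    if np.ptp(x) == 0:
        raise InsufficientDataError("need at least two distinct temperatures")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    temps = [p.temperature_c for p in usable]
    return ArrheniusSegment(slope=float(slope), intercept=float(intercept),
                            ea=-float(slope) * R_GAS, r_squared=r2,
                            n_points=len(usable), t_min_c=min(temps), t_max_c=max(temps))


def _segment_rss(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(resid @ resid)


def intersect_segments(warm: ArrheniusSegment, cold: ArrheniusSegment) -> float:
    """Critical temperature (kelvin) where the two fitted lines cross.

    ``1/T* = (intercept_cold - intercept_warm) / (slope_warm - slope_cold)``.
    Near-parallel segments raise :class:`ParallelSegmentsError` rather than
    returning a wildly extrapolated temperature.
    """
    dslope = warm.slope - cold.slope
    scale = max(abs(warm.slope), abs(cold.slope), 1.0)
    if abs(dslope) < PARALLEL_TOL * scale:
        raise ParallelSegmentsError("segments are (near-)parallel; no intersection")
    inv_t = (cold.intercept - warm.intercept) / dslope
    if inv_t <= 0:
        raise ParallelSegmentsError("segments intersect at a non-physical temperature")
    return 1.0 / inv_t


def segmented_fit(points, mode: str = "auto",
                  fixed_boundary_c: float | None = None) -> ArrheniusModel:
    """Fit one or two Arrhenius segments.

    ``mode='single'`` fits one line.  ``mode='fixed'`` splits at
    ``fixed_boundary_c`` (which must be an observed temperature); the
    boundary point is shared by both segments, matching the convention of
    fitting an optimal range down to the boundary and a stress range from
    it.  ``mode='auto'`` exhaustively searches shared-boundary positions
    with at least two points per segment and minimises the pooled residual
    sum of squares, breaking ties toward the warmest boundary.
    """
    usable = sorted(_usable(points), key=lambda p: -p.temperature_c)
    if mode == "single":
        return ArrheniusModel(warm=fit_segment(usable), mode="single")

    if mode == "fixed":
        if fixed_boundary_c is None:
            raise ValueError("fixed mode requires fixed_boundary_c")
        temps = [p.temperature_c for p in usable]
        if not any(math.isclose(t, fixed_boundary_c) for t in temps):
            raise InsufficientDataError(
                f"boundary {fixed_boundary_c} degC is not an observed temperature")
        warm_pts = [p for p in usable if p.temperature_c >= fixed_boundary_c - 1e-12]
        cold_pts = [p for p in usable if p.temperature_c <= fixed_boundary_c + 1e-12]
        warm, cold = fit_segment(warm_pts), fit_segment(cold_pts)
        model = ArrheniusModel(warm=warm, cold=cold, mode="fixed_split")
    elif mode == "auto":
        if len(usable) < 4:
            raise InsufficientDataError("auto mode needs >= 4 usable points")
        x = np.array([1.0 / p.temperature_k for p in usable])
        y = np.log([p.rate for p in usable])
        best_rss, best_b = math.inf, None
        for b in range(1, len(usable) - 1):  # boundary point shared by both
            rss = _segment_rss(x[:b + 1], y[:b + 1]) + _segment_rss(x[b:], y[b:])
            if rss < best_rss - 1e-15:
                best_rss, best_b = rss, b
        warm = fit_segment(usable[:best_b + 1])
        cold = fit_segment(usable[best_b:])
        model = ArrheniusModel(warm=warm, cold=cold, mode="auto_split")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if model.cold.ea < model.warm.ea:
        warnings.warn("cold-segment activation energy is below the warm segment; "
                      "no stress regime apparent")
    try:
        t_crit = intersect_segments(model.warm, model.cold)
    except ParallelSegmentsError:
        t_crit = None
    return ArrheniusModel(warm=model.warm, cold=model.cold,
                          t_crit_k=t_crit, mode=model.mode)


def predict_rate(model: ArrheniusModel, temperature_c: float) -> float:
    """Rate (mmol/L.h) predicted by the fitted model at a temperature in degC."""
    return model.predict(temperature_c)


def plot_table(points) -> "np.ndarray":
    """Plot-ready (1000/T, ln k) pairs for the conventional display axis."""
    usable = _usable(points)
    return np.array([(1000.0 / p.temperature_k, math.log(p.rate)) for p in usable])
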