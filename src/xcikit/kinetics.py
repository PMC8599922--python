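"""Transcript decay kinetics after transcription blockade.

qPCR Cq pairs are converted to reference-normalized levels, rescaled to 1
at the first timepoint, and fitted with a first-order exponential decay
model ``level = n0 * exp(-k t)`` by least squares on log-transformed
levels (a nonlinear fit on the natural scale is available and agrees on
noiseless data). Half-life is ln(2)/k. A two-phase variant fits the
points at/before a breakpoint and after it independently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DecaySeries:
    timepoints: np.ndarray  # hours, strictly increasing
    levels: np.ndarray  # > 0, typically rescaled so level(t0) = 1
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "levels", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("timepoints and levels must be equal-length 1-D arrays")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if (y <= 0).any():
            raise ValueError("levels must be positive")


@dataclass(frozen=True)
class DecayFit:
    n0: float
    k: float  # per hour; 0 when no decay detected
    r_squared: float
    points_used: np.ndarray
    no_decay: bool = False

    @property
    def half_life(self) -> float:
        """ln(2)/k, infinite when no decay was detected."""
        if self.no_decay or self.k <= 0:
            return math.inf
        return math.log(2) / self.k


def normalize_series(
    timepoints: Sequence[float],
    target_cq: Sequence[float],
    reference_cq: Sequence[float],
    efficiency: float = 2.0,
    replicate_id: str = "",
) -> DecaySeries:
    """Reference-normalized expression levels from Cq pairs.

    level(t) = efficiency^-(target_cq - reference_cq), rescaled so the
    first timepoint is 1.
    """
    t = np.asarray(timepoints, dtype=float)
    tc = np.asarray(target_cq, dtype=float)
    rc = np.asarray(reference_cq, dtype=float)
    if not (t.shape == tc.shape == rc.shape):
        raise ValueError("timepoints, target_cq and reference_cq must match in length")
    if np.isnan(rc).any() or np.isnan(tc).any():
        raise ValueError("missing Cq value")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    levels = efficiency ** -(tc - rc)
    levels = levels / levels[0]
    return DecaySeries(timepoints=t, levels=levels, replicate_id=replicate_id)


def _log_linear_fit(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least squares on log levels; returns (n0, k, r_squared on log scale)."""
    ly = np.log(y)
    slope, intercept = np.polyfit(t, ly, 1)
    resid = ly - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return math.exp(intercept), -slope, r2


def _nonlinear_fit(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    n0_ll, k_ll, _ = _log_linear_fit(t, y)
    popt, _ = curve_fit(
        lambda tt, n0, k: n0 * np.exp(-k * tt),
        t, y, p0=[max(n0_ll, 1e-12), max(k_ll, 1e-6)], maxfev=10000,
    )
    n0, k = float(popt[0]), float(popt[1])
    ly = np.log(y)
    pred = np.log(np.clip(n0 * np.exp(-k * t), 1e-300, None))
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return n0, k, r2


def fit_decay(
    series: DecaySeries,
    include_t0: bool = True,
    method: str = "log-linear",
    min_points: int = 3,
) -> DecayFit:
    """Fit a first-order decay; R^2 is reported on the log scale.

    ``include_t0=False`` drops the earliest timepoint before fitting. A
    non-positive fitted k is flagged ``no_decay`` (half-life infinite).
    """
    t, y = series.timepoints, series.levels
    if not include_t0:
        t, y = t[1:], y[1:]
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(t)}")
    if method == "log-linear":
        n0, k, r2 = _log_linear_fit(t, y)
    elif method == "nonlinear":
        n0, k, r2 = _nonlinear_fit(t, y)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    no_decay = bool(k <= 0)
    return DecayFit(
        n0=float(n0), k=0.0 if no_decay else float(k), r_squared=float(r2),
        points_used=t.copy(), no_decay=no_decay,
    )


def two_phase_fit(
    series: DecaySeries, breakpoint: float = 1.0, method: str = "log-linear"
) -> Tuple[DecayFit | None, DecayFit | None]:
    """Independent fits on t <= breakpoint and t > breakpoint.

    Phase 1 needs >= 2 points, phase 2 >= 3; an underpopulated phase is
    omitted (None) with a warning. Phase 2 is fitted with time re-zeroed
    at its first point, so its n0 is the fitted level there; k is
    unaffected by the shift.
    """
    t, y = series.timepoints, series.levels
    early = t <= breakpoint
    late = ~early
    phase1 = phase2 = None
    if early.sum() >= 2:
        s1 = DecaySeries(t[early], y[early], series.replicate_id)
        phase1 = fit_decay(s1, method=method, min_points=2)
    else:
        warnings.warn("phase 1 omitted: fewer than 2 points at or before breakpoint")
    if late.sum() >= 3:
        s2 = DecaySeries(t[late] - t[late][0], y[late], series.replicate_id)
        phase2 = fit_decay(s2, method=method, min_points=3)
    else:
        warnings.warn("phase 2 omitted: fewer than 3 points after breakpoint")
    return phase1, phase2


def survival_rate(n_plus_dox: float, n_minus_dox: float) -> float:
    """Cell survival ratio, +Dox count over -Dox count."""
    if n_minus_dox <= 0:
        raise ValueError("denominator cell count must be > 0")
    if n_plus_dox < 0:
        raise ValueError("cell counts must be non-negative")
    return n_plus_dox / n_minus_dox
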