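"""Growth-rate estimation from OD600 microculture curves and dose selection.

Screening doses are chosen where a compound inhibits the wild-type growth
rate by a modest 10-20%, so that both healthy and partially compromised
mutants remain measurable in the pooled screen.  Rates are taken as the
slope of log2(OD) over the best-fitting contiguous exponential window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthRateFit",
    "growth_rate",
    "percent_inhibition",
    "select_dose",
    "dose_response_table",
    "DEFAULT_INHIBITION_BAND",
]

#: Target inhibition band (percent) for screening-dose selection.
DEFAULT_INHIBITION_BAND = (10.0, 20.0)

MIN_WINDOW_POINTS = 6


@dataclass(frozen=True)
class GrowthRateFit:
    """Result of an exponential-window fit: rate in doublings/hr."""

    rate: float
    window: tuple[float, float]  # start/end time of the fitted window (hr)
    r_squared: float
    n_points: int


def _window_fit(t: np.ndarray, log2_od: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of log2(OD) ~ t; R^2 = 1 for an exact fit."""
    n = t.size
    st = t.sum()
    sy = log2_od.sum()
    s_tt = float(t @ t) - st * st / n
    s_ty = float(t @ log2_od) - st * sy / n
    s_yy = float(log2_od @ log2_od) - sy * sy / n
    slope = s_ty / s_tt
    if s_yy < 1e-12:
        # constant series: a zero-slope line fits exactly
        return float(slope), 1.0 if abs(s_ty) < 1e-9 else 0.0
    r2 = (s_ty * s_ty) / (s_tt * s_yy)
    return float(slope), min(r2, 1.0)


def growth_rate(
    time_hr: Sequence[float],
    od: Sequence[float],
    min_points: int = MIN_WINDOW_POINTS,
) -> GrowthRateFit:
    """Doublings/hr from the contiguous log-linear window maximizing R^2.

    All contiguous windows of at least ``min_points`` strictly positive OD
    readings are fit by least squares on log2(OD); the best-R^2 window wins.
    Exact R^2 ties (noiseless or saturated curves, where several segments
    fit perfectly) are broken toward the larger slope, then the longer
    window, then the earlier start, so a stationary plateau never outranks
    the exponential phase.  Raises if no candidate window has positive ODs.
    """
    t = np.asarray(time_hr, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("time and OD must be 1-D and equally long")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    positive = y > 0
    best: tuple[float, float, int, float] | None = None  # (r2, slope, length, -start)
    best_fit: GrowthRateFit | None = None
    n = t.size
    for start in range(n - min_points + 1):
        if not positive[start]:
            continue
        for stop in range(start + min_points, n + 1):
            if not positive[stop - 1]:
                break
            slope, r2 = _window_fit(t[start:stop], np.log2(y[start:stop]))
            key = (round(r2, 9), round(slope, 9), stop - start, -start)
            if best is None or key > best:
                best = key
                best_fit = GrowthRateFit(
                    rate=slope,
                    window=(float(t[start]), float(t[stop - 1])),
                    r_squared=r2,
                    n_points=stop - start,
                )
    if best_fit is None:
        raise ValueError("no window of positive OD readings available for rate fitting")
    return best_fit


def percent_inhibition(rate_treated: float, rate_control: float) -> float:
    """Percent decrease in growth rate relative to the control culture."""
    if rate_control <= 0:
        raise ValueError("control growth rate must be > 0")
    if rate_treated < 0:
        rate_treated = 0.0
    return 100.0 * (1.0 - rate_treated / rate_control)


def dose_response_table(
    curves: pd.DataFrame,
    control_dose: str | float = "0",
    band: tuple[float, float] = DEFAULT_INHIBITION_BAND,
) -> pd.DataFrame:
    """Fit every dose column of a time-indexed OD table and flag the band.

    Returns one row per dose with rate, R^2, fitted window, percent
    inhibition versus the control column, and whether the dose falls in the
    target band.
    """
    control_dose = str(control_dose)
    if control_dose not in curves.columns.astype(str).tolist():
        raise KeyError(f"control dose column {control_dose!r} not in table")
    t = curves.index.to_numpy(dtype=float)
    fits = {str(c): growth_rate(t, curves[c].to_numpy()) for c in curves.columns}
    control_rate = fits[control_dose].rate
    rows = []
    for dose, fit in fits.items():
        inhib = percent_inhibition(fit.rate, control_rate)
        rows.append(
            {
                "dose": dose,
                "rate_doublings_per_hr": fit.rate,
                "r_squared": fit.r_squared,
                "window_start_hr": fit.window[0],
                "window_end_hr": fit.window[1],
                "percent_inhibition": inhib,
                "selected": bool(dose != control_dose and band[0] <= inhib <= band[1]),
            }
        )
    return pd.DataFrame(rows).set_index("dose")


def select_dose(
    dose_inhibition: Mapping[str | float, float],
    band: tuple[float, float] = DEFAULT_INHIBITION_BAND,
) -> list[str]:
    """Doses whose percent inhibition lies inside [low, high], ascending.

    An empty result is valid (no dose in the band); callers should widen
    the ladder rather than the band.
    """
    low, high = band
    if not low < high:
        raise ValueError("band must satisfy low < high")
    if not dose_inhibition:
        raise ValueError("at least one dose must be measured")
    chosen = [
        (float(d), str(d)) for d, inh in dose_inhibition.items() if low <= inh <= high
    ]
    return [label for _, label in sorted(chosen)]
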