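"""Physiological characterization regressions.

Growth rates come from least-squares linear regression of ln(OD600) versus
time over a user-chosen exponential window; specific exchange rates
(glucose uptake, acetate secretion) from the best-fit slope of metabolite
concentration versus cell dry weight, multiplied by the growth rate.
Consumption is negative, production positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthCurve", "growth_rate", "exchange_rate"]

# OD600-to-biomass conversion, gDW/L per OD unit; configurable per instrument
OD_TO_GDW_PER_L = 0.4


@dataclass
class GrowthCurve:
    times: np.ndarray            # hours, strictly increasing
    od600: np.ndarray
    strain: str = ""
    temperature_c: float = 37.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def growth_rate(
    curve: GrowthCurve, window: slice | None = None
) -> tuple[float, dict]:
    """Exponential growth rate (1/h) from ln(OD600) vs time.

    Fits ordinary least squares on the window (default: all points) and
    returns the slope with fit diagnostics (intercept, R², n).  Invariant
    to rescaling OD by a positive constant, since that only shifts the
    intercept.
    """
    window = window or slice(None)
    t = curve.times[window]
    od = curve.od600[window]
    if t.size < 3:
        raise ValueError(f"need at least 3 points in the window, got {t.size}")
    if np.any(od <= 0):
        raise ValueError("nonpositive OD600 in the fitted window")
    ln_od = np.log(od)
    slope, intercept = np.polyfit(t, ln_od, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((ln_od - pred) ** 2))
    ss_tot = float(np.sum((ln_od - ln_od.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), {"intercept": float(intercept), "r_squared": r2,
                          "n_points": int(t.size)}


def exchange_rate(
    concentrations: np.ndarray,
    dry_weights: np.ndarray,
    growth_rate: float,
) -> float:
    """Specific exchange rate (mmol/gDW/h) during exponential growth.

    Best-fit slope of metabolite concentration (mmol/L) versus cell dry
    weight (gDW/L), multiplied by the growth rate (1/h).  Falling
    concentration gives a negative slope, hence consumption < 0 and
    production > 0; the rate is linear in the growth rate.
    """
    c = np.asarray(concentrations, dtype=float)
    w = np.asarray(dry_weights, dtype=float)
    if c.shape != w.shape:
        raise ValueError("concentration and dry-weight series must align")
    if c.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {c.size}")
    if np.ptp(w) == 0:
        raise ValueError("degenerate fit: cell dry weight is constant")
    slope = np.polyfit(w, c, 1)[0]
    return float(slope * growth_rate)
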