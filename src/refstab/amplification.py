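"""Standard-curve fitting and amplification-efficiency calibration.

A serial-dilution standard curve regresses mean Cq on log10 relative
input amount; for an efficient assay the slope is close to
-1/log10(2) = -3.32 cycles per decade.  The slope converts to the
amplification factor

    E_amp = 10 ** (-1 / slope),        e% = (E_amp - 1) * 100

so a slope of -3.58 corresponds to ~90% efficiency and -3.10 to ~110%.
Curves with slopes inside [-3.58, -3.10] (inclusive) are flagged
acceptable by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "fit_standard_curve",
    "fit_curves_from_dilution_table",
    "DEFAULT_SLOPE_WINDOW",
]

DEFAULT_SLOPE_WINDOW = (-3.58, -3.10)


@dataclass
class StandardCurve:
    """Fitted dilution series: slope/intercept/R^2 and derived efficiency."""

    points: list[tuple[float, float]]  # (log10 relative input, mean Cq)
    slope: float  # cycles per log10 dilution unit
    intercept: float  # cycles
    r2: float
    e_amp: float
    e_percent: float
    acceptable: bool

    def rounded_percent(self) -> int:
        """Percent efficiency rounded to the nearest integer (I/O only)."""
        return int(round(self.e_percent))


def efficiency_from_slope(slope: float) -> tuple[float, float]:
    """Convert a standard-curve slope to (E_amp, e_percent).

    E_amp = 10**(-1/slope); a positive or zero slope means the curve
    runs the wrong way and is rejected.
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    e_amp = 10.0 ** (-1.0 / slope)
    return e_amp, (e_amp - 1.0) * 100.0


def slope_from_efficiency(e_amp: float) -> float:
    """Inverse of :func:`efficiency_from_slope` (testing aid)."""
    if not e_amp > 1.0:
        raise ValueError(f"amplification factor must exceed 1, got {e_amp}")
    return -1.0 / np.log10(e_amp)


def fit_standard_curve(
    dilution_points,
    slope_window: tuple[float, float] = DEFAULT_SLOPE_WINDOW,
) -> StandardCurve:
    """OLS fit of mean Cq on log10 relative input.

    ``dilution_points`` is an iterable of (relative_input, cq) pairs;
    replicate Cq values at the same dilution level are averaged before
    the regression.  At least 3 distinct levels are required.
    """
    pts = [(float(x), float(cq)) for x, cq in dilution_points]
    if any(x <= 0 for x, _ in pts):
        raise ValueError("relative input amounts must be positive")
    df = pd.DataFrame(pts, columns=["input", "cq"])
    df["log10_input"] = np.log10(df["input"])
    per_level = df.groupby("log10_input")["cq"].mean().reset_index()
    if len(per_level) < 3:
        raise ValueError(
            f"need >=3 distinct dilution levels, got {len(per_level)}"
        )
    x = per_level["log10_input"].to_numpy()
    y = per_level["cq"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 input amounts")
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    e_amp, e_percent = efficiency_from_slope(slope)
    lo, hi = slope_window
    acceptable = lo <= slope <= hi
    return StandardCurve(
        points=list(zip(x.tolist(), y.tolist())),
        slope=slope,
        intercept=intercept,
        r2=r2,
        e_amp=e_amp,
        e_percent=e_percent,
        acceptable=acceptable,
    )


def fit_curves_from_dilution_table(
    df: pd.DataFrame,
    slope_window: tuple[float, float] = DEFAULT_SLOPE_WINDOW,
) -> dict[str, StandardCurve]:
    """Fit one curve per gene from a gene,dilution_factor,replicate,cq table.

    ``dilution_factor`` is the relative input amount (1, 0.1, 0.01, ...).
    """
    out: dict[str, StandardCurve] = {}
    for gene, sub in df.groupby("gene"):
        pts = list(zip(sub["dilution_factor"].astype(float), sub["cq"].astype(float)))
        out[str(gene)] = fit_standard_curve(pts, slope_window=slope_window)
    return out
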