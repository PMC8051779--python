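"""Calibration-curve quantification and HPLC peak-table summaries.

Spectrophotometric assays (Folin-Ciocalteu total phenolics, aluminium
chloride total flavonoids) and HPLC marker quantification all reduce to
the same arithmetic: fit a straight calibration line through standard
(concentration, signal) pairs, back-calculate the sample concentration,
and scale by extraction volume, dilution and extract mass to a content
per gram of dry weight (e.g. mg gallic-acid equivalents / g DW).

Peak tables from an integrated chromatogram are summarized by percent
area and percent height, the usual fingerprint normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class QuantError(ValueError):
    pass


class BelowRangeWarning(UserWarning):
    """Back-calculated concentration fell below zero and was clamped."""


@dataclass(frozen=True)
class CalibrationCurve:
    standard_concentrations: np.ndarray
    signals: np.ndarray
    slope: float
    intercept: float
    r2: float

    @property
    def usable(self) -> bool:
        return self.slope != 0.0


def fit_calibration(concs, signals) -> CalibrationCurve:
    """Ordinary least-squares calibration line; r2 is the squared Pearson
    correlation of signal with concentration."""
    c = np.asarray(concs, dtype=float)
    s = np.asarray(signals, dtype=float)
    if c.shape != s.shape or c.ndim != 1:
        raise QuantError("concentrations and signals must be equal-length vectors")
    if len(c) < 3:
        raise QuantError("need at least 3 calibration standards")
    if len(np.unique(c)) < 2:
        raise QuantError("degenerate calibration: all standard concentrations identical")
    res = stats.linregress(c, s)
    return CalibrationCurve(
        standard_concentrations=c,
        signals=s,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def content_from_signal(
    signal: float,
    curve: CalibrationCurve,
    extract_mass_g: float,
    volume_ml: float,
    dilution: float = 1.0,
) -> float:
    """Content (mg equivalents per g extract DW) from a measured signal.

    concentration = (signal - intercept) / slope   [mg/mL]
    content = concentration * volume * dilution / mass

    The caller owns the units: feed a curve in mg/mL and a volume in mL
    to get mg/g; scale by 100 for a per-100 g basis. Negative
    back-calculated concentrations are clamped to zero with a warning.
    """
    if not curve.usable:
        raise QuantError("calibration curve has zero slope and is unusable")
    if extract_mass_g <= 0 or volume_ml <= 0 or dilution <= 0:
        raise QuantError("mass, volume and dilution must be positive")
    conc = (signal - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"signal {signal} back-calculates below the calibration range; clamped to 0",
            BelowRangeWarning,
            stacklevel=2,
        )
        conc = 0.0
    return conc * volume_ml * dilution / extract_mass_g


def peak_percentages(raw_peaks: pd.DataFrame) -> pd.DataFrame:
    """Append percent_area / percent_height columns to a peak table.

    Expects columns id, rt_min, area, height; peaks must be in
    retention-time order. Each percent column sums to 100.
    """
    required = {"id", "rt_min", "area", "height"}
    if not required.issubset(raw_peaks.columns):
        raise QuantError(f"peak table needs columns {sorted(required)}")
    if len(raw_peaks) == 0:
        raise QuantError("empty peak table")
    if (raw_peaks["area"] < 0).any() or (raw_peaks["height"] < 0).any():
        raise QuantError("areas and heights must be >= 0")
    if not raw_peaks["rt_min"].is_monotonic_increasing:
        raise QuantError("peaks must be sorted by retention time")
    total_area = float(raw_peaks["area"].sum())
    total_height = float(raw_peaks["height"].sum())
    if total_area == 0:
        raise QuantError("zero total area")
    out = raw_peaks.copy()
    out["percent_area"] = 100.0 * out["area"] / total_area
    out["percent_height"] = 100.0 * out["height"] / total_height
    return out


def match_peak_by_rt(
    peaks: pd.DataFrame, rt_min: float, window_frac: float = 0.02
) -> pd.Series:
    """Find the peak whose retention time lies within +/-``window_frac``
    (relative) of ``rt_min`` — used to map a marker standard (quercetin)
    onto the sample fingerprint. Ambiguity or absence is an error."""
    lo, hi = rt_min * (1 - window_frac), rt_min * (1 + window_frac)
    hits = peaks[(peaks["rt_min"] >= lo) & (peaks["rt_min"] <= hi)]
    if len(hits) == 0:
        raise QuantError(f"no peak within {window_frac:.0%} of RT {rt_min} min")
    if len(hits) > 1:
        raise QuantError(
            f"ambiguous match: peaks {list(hits['id'])} all within {window_frac:.0%} of RT {rt_min}"
        )
    return hits.iloc[0]
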