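"""Seeded generators emulating every measured input of the study.

Each generator is a pure function of its parameters and a seed, so the
whole pipeline — design, fit, ANOVA, optimization, quantification,
bioassay statistics — can be exercised end to end without wet-lab data:

* ``simulate_ccrd``: CCRD responses = quadratic surface (defaults: the
  published coded TPC model) + per-block offset + iid Gaussian noise
  (default SD sqrt(5.81), the residual mean square of the published
  ANOVA).
* ``simulate_sfe``: single-factor yield curves that rise to a peak and
  decline, anchored at the published peaks (17.4 mg GAE/g DW at 70 degC,
  18 at 2 h, 17.7 at a 2.5% ratio).
* ``simulate_fpg_trial``: per-animal fasting-plasma-glucose and weight
  tables whose group x day cells are iid Gaussian draws matching the
  published mean/SEM summaries (n = 6 rats per group by default).
* ``simulate_calibration``: linear calibration standards with noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CCRDesign
from .rsm import ResponseData, model_from_coefficients, predict_many
from . import datasets


class SimulationError(ValueError):
    pass


class TruncationWarning(UserWarning):
    """Gaussian draws fell below a physical floor and were truncated."""


# -- CCRD responses ----------------------------------------------------------

@dataclass(frozen=True)
class SurfaceTruth:
    """Generating truth for CCRD responses: coded-unit coefficients,
    additive block offsets, and the response noise SD."""

    coefficients: Mapping[str, float]
    block_offsets: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


def default_surface_truth() -> SurfaceTruth:
    """The published coded TPC equation with noise SD sqrt(5.81) and no
    block offset — the study conditions the generator emulates."""
    return SurfaceTruth(
        coefficients=datasets.fitted_tpc_coefficients(),
        block_offsets={},
        noise_sd=datasets.residual_noise_sd(),
    )


def simulate_ccrd(design: CCRDesign, truth: SurfaceTruth, seed: int = 0) -> ResponseData:
    """Draw one response vector on a design from a quadratic truth."""
    model = model_from_coefficients(truth.coefficients, design.k, design.factors)
    mean = predict_many(model, design.coded_matrix())
    offsets = np.array(
        [truth.block_offsets.get(b, 0.0) for b in design.blocks()], dtype=float
    )
    rng = np.random.default_rng(seed)
    y = mean + offsets + rng.normal(0.0, truth.noise_sd, size=len(mean))
    return ResponseData(design=design, response=y, response_name="simulated_tpc")


# -- single-factor yield curves ---------------------------------------------

@dataclass(frozen=True)
class SfeProfile:
    """Rise-then-fall yield profile for one extraction factor.

    The noiseless curve is a piecewise concave parabola through the peak:
    ``peak_value - rise_rate*(x - peak)^2`` left of the peak and
    ``peak_value - fall_rate*(x - peak)^2`` right of it, floored at 0 —
    unimodal by construction. Rates are in yield units per (factor
    unit)^2.
    """

    factor: str
    peak_location: float
    peak_value: float
    rise_rate: float
    fall_rate: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_value <= 0:
            raise SimulationError("peak_value must be positive")
        if self.rise_rate < 0 or self.fall_rate < 0 or self.noise_sd < 0:
            raise SimulationError("rates and noise_sd must be >= 0")

    def noiseless(self, levels) -> np.ndarray:
        x = np.asarray(levels, dtype=float)
        rate = np.where(x <= self.peak_location, self.rise_rate, self.fall_rate)
        return np.maximum(self.peak_value - rate * (x - self.peak_location) ** 2, 0.0)


def default_sfe_profiles() -> dict[str, SfeProfile]:
    """Profiles anchored at the published single-factor screen peaks,
    with fall rates set so the curves decay to the published minima over
    the screened ranges (2.1 mg GAE/g at 90 degC; 0.9 mg GAE/g at 5 h)."""
    anchors = datasets.single_factor_peaks()
    return {
        # 17.4 at 70 degC, down to ~2.1 by 90 degC: rate (17.4-2.1)/20^2
        "temperature": SfeProfile(
            "temperature", *anchors["temperature"], rise_rate=0.008, fall_rate=0.03825
        ),
        # 18 at 2 h, down to ~0.9 by 5 h: rate (18-0.9)/3^2
        "time": SfeProfile("time", *anchors["time"], rise_rate=1.2, fall_rate=1.9),
        # 17.7 at 2.5%, declining toward 10%: gentle quadratic decay
        "ratio": SfeProfile("ratio", *anchors["ratio"], rise_rate=2.0, fall_rate=0.12),
    }


def simulate_sfe(profile: SfeProfile, levels: Sequence[float], seed: int = 0) -> pd.DataFrame:
    """Yield measurements along one factor: unimodal truth + iid noise."""
    x = np.asarray(levels, dtype=float)
    if len(x) == 0:
        raise SimulationError("levels must be non-empty")
    if np.any(np.diff(x) <= 0):
        raise SimulationError("levels must be strictly increasing")
    rng = np.random.default_rng(seed)
    y = profile.noiseless(x) + rng.normal(0.0, profile.noise_sd, size=len(x))
    return pd.DataFrame({"level": x, "yield": y})


# -- animal trial ------------------------------------------------------------

@dataclass(frozen=True)
class TrialTruth:
    """Per-group, per-day generating means/SDs for FPG and body weight.

    ``fpg`` and ``weight`` are DataFrames with columns group, dose
    (optional), timepoint_day, mean, sd. ``n`` animals per group.
    """

    fpg: pd.DataFrame
    weight: pd.DataFrame
    n: int = 6

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SimulationError("need n >= 2 animals per group")
        for name, df in (("fpg", self.fpg), ("weight", self.weight)):
            if (df["sd"] <= 0).any():
                raise SimulationError(f"{name} truth SDs must be positive")


def default_trial_truth(n: int = 6) -> TrialTruth:
    """Truth matching the published summaries: SD = SEM * sqrt(6)."""
    def to_truth(df: pd.DataFrame) -> pd.DataFrame:
        out = df[["group", "dose_mg_per_kg", "timepoint_day", "mean"]].copy()
        out["sd"] = df["sem"] * np.sqrt(df["n"])
        return out

    return TrialTruth(
        fpg=to_truth(datasets.fpg_summaries()),
        weight=to_truth(datasets.weight_summaries()),
        n=n,
    )


def simulate_fpg_trial(truth: TrialTruth, seed: int = 0, floor: float = 0.0) -> pd.DataFrame:
    """Per-animal long table (animal_id, group, day, fpg, weight).

    Each group x day cell holds n iid Normal(mean, sd) draws,
    independent across days. Draws below ``floor`` (glucose and weight
    cannot be negative) are truncated up to it with a warning.
    """
    rng = np.random.default_rng(seed)
    fpg = truth.fpg.set_index(["group", "timepoint_day"])
    wt = truth.weight.set_index(["group", "timepoint_day"])
    groups = list(dict.fromkeys(truth.fpg["group"]))
    days = sorted(truth.fpg["timepoint_day"].unique())
    rows = []
    truncated = 0
    for gi, g in enumerate(groups):
        for a in range(truth.n):
            animal = f"{g}_{a + 1:02d}"
            for day in days:
                fr = fpg.loc[(g, day)]
                wr = wt.loc[(g, day)]
                f_val = rng.normal(float(fr["mean"]), float(fr["sd"]))
                w_val = rng.normal(float(wr["mean"]), float(wr["sd"]))
                if f_val < floor or w_val < floor:
                    truncated += 1
                rows.append(
                    (animal, g, fr.get("dose_mg_per_kg"), int(day),
                     max(f_val, floor), max(w_val, floor))
                )
    if truncated:
        warnings.warn(
            f"{truncated} draws fell below {floor} and were truncated",
            TruncationWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "dose_mg_per_kg", "day", "fpg", "weight"]
    )


# -- calibration standards ---------------------------------------------------

DEFAULT_STANDARDS_UG_ML = (10.0, 50.0, 100.0, 150.0, 200.0)
"""Default gallic-acid / quercetin standard levels (ug/mL): five points
spanning the usual Folin-Ciocalteu working range."""


def simulate_calibration(
    slope: float,
    intercept: float,
    concs: Sequence[float] = DEFAULT_STANDARDS_UG_ML,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standard-curve signals: slope*c + intercept + iid Gaussian noise."""
    c = np.asarray(concs, dtype=float)
    if len(c) == 0:
        raise SimulationError("concs must be non-empty")
    rng = np.random.default_rng(seed)
    s = slope * c + intercept + rng.normal(0.0, noise_sd, size=len(c))
    return pd.DataFrame({"concentration": c, "signal": s})
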