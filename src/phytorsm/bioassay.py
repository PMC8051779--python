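"""In-vivo endpoint statistics from published group summaries.

Animal studies usually publish only (n, mean, SEM) per group, so every
test here is computed directly from summary statistics: Welch's
heteroscedastic one-way ANOVA, Games-Howell pairwise comparisons (the
unequal-variance analogue of Tukey's HSD, using the studentized-range
distribution with Welch-Satterthwaite degrees of freedom), baseline-to-
endpoint change summaries, and a four-parameter logistic (4PL)
dose-response fit whose EC50 is the dose halfway between the bottom and
top asymptotes.

Raw-vector entry points (``summarize_raw``, ``levene_raw``) exist for
synthetic per-animal data generated by :mod:`phytorsm.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sopt
from scipy import stats


class BioassayError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    """One treatment group at one timepoint, as published: n, mean, SEM."""

    group: str
    n: int
    mean: float
    sem: float
    dose: float | None = None
    units: str = ""
    timepoint: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise BioassayError(f"group {self.group!r}: need n >= 2")
        if not (self.sem > 0 and np.isfinite(self.sem)):
            raise BioassayError(f"group {self.group!r}: SEM must be positive and finite")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd**2


def summaries_from_frame(df: pd.DataFrame, timepoint: int | None = None) -> list[GroupSummary]:
    """Build GroupSummary rows from a table with columns
    group, n, mean, sem [, dose_mg_per_kg, timepoint_day, units]."""
    if timepoint is not None and "timepoint_day" in df.columns:
        df = df[df["timepoint_day"] == timepoint]
    out = []
    for _, r in df.iterrows():
        dose = r.get("dose_mg_per_kg")
        out.append(
            GroupSummary(
                group=str(r["group"]),
                n=int(r["n"]),
                mean=float(r["mean"]),
                sem=float(r["sem"]),
                dose=None if pd.isna(dose) else float(dose),
                units=str(r.get("units", "")),
                timepoint=int(r["timepoint_day"]) if "timepoint_day" in df.columns else None,
            )
        )
    return out


def summarize_raw(values: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """(n, mean, SEM) summaries from raw per-subject vectors."""
    out = []
    for g, v in values.items():
        arr = np.asarray(v, dtype=float)
        out.append(
            GroupSummary(
                group=str(g),
                n=len(arr),
                mean=float(arr.mean()),
                sem=float(arr.std(ddof=1) / np.sqrt(len(arr))),
            )
        )
    return out


def levene_raw(values: Mapping[str, Sequence[float]], center: str = "median"):
    """Levene's homogeneity-of-variance test on raw vectors (its statistic
    needs within-group deviations, so no summary-only version exists)."""
    stat, p = stats.levene(*[np.asarray(v, float) for v in values.values()], center=center)
    return float(stat), float(p)


def welch_anova(groups: Sequence[GroupSummary]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA from group summaries.

    Returns (F, df1, df2, p). Groups are weighted by n/s^2; df2 follows
    the Welch-Satterthwaite approximation. With two groups this equals
    the squared Welch t statistic.
    """
    k = len(groups)
    if k < 2:
        raise BioassayError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    v = np.array([g.var for g in groups], dtype=float)
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    t = ((1 - w / W) ** 2 / (n - 1)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * t
    f = a / b
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3.0 * t))
    if f == 0:
        return 0.0, df1, df2, 1.0
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


def games_howell(groups: Sequence[GroupSummary]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons from group summaries.

    For each pair: se^2 = s1^2/n1 + s2^2/n2, the Welch-Satterthwaite df,
    the studentized-range statistic q = |diff| * sqrt(2) / se, and the
    family-wise p from the studentized-range distribution with k groups.
    """
    k = len(groups)
    if k < 2:
        raise BioassayError("need at least 2 groups")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            v1, v2 = g1.var / g1.n, g2.var / g2.n
            se = np.sqrt(v1 + v2)
            diff = g1.mean - g2.mean
            df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append((g1.group, g2.group, diff, se, q, df, min(p, 1.0)))
    return pd.DataFrame(
        rows, columns=["group_1", "group_2", "mean_diff", "se", "q", "df", "p"]
    )


def fpg_change(baseline: GroupSummary, endpoint: GroupSummary) -> tuple[float, float]:
    """Baseline-minus-endpoint change for one group: (absolute, percent).

    Positive values mean the endpoint fell (e.g. glucose lowered);
    a negative "reduction" means worsening.
    """
    if baseline.group != endpoint.group:
        raise BioassayError(f"group mismatch: {baseline.group!r} vs {endpoint.group!r}")
    if baseline.units != endpoint.units:
        raise BioassayError(f"unit mismatch: {baseline.units!r} vs {endpoint.units!r}")
    absolute = baseline.mean - endpoint.mean
    return float(absolute), float(100.0 * absolute / baseline.mean)


# -- four-parameter logistic dose-response ----------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    rss: float

    def predict(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, float), self.bottom, self.top, self.ec50, self.hill)


def four_pl(dose, bottom, top, ec50, hill):
    """y = bottom + (top - bottom) / (1 + (dose/ec50)^hill).

    The response at dose = EC50 is exactly (top + bottom)/2. With
    positive ``hill`` the curve falls from ``top`` toward ``bottom`` as
    dose rises; a negative ``hill`` gives the rising (agonist) curve —
    hill = -1 is the classic Emax model y = top*d/(d + ec50) when
    bottom = 0.
    """
    d = np.asarray(dose, dtype=float)
    # extreme multi-start parameters can overflow the power; the resulting
    # inf propagates to a saturated (finite) response, which is what we want
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ratio = (d / ec50) ** hill
        out = bottom + (top - bottom) / (1.0 + ratio)
    return np.where(np.isfinite(out), out, bottom)


_PARAM_ORDER = ("bottom", "top", "ec50", "hill")


def fit_4pl(
    doses,
    responses,
    fixed: Mapping[str, float] | None = None,
    seed: int = 0,
    n_starts: int = 20,
    zero_dose_epsilon: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit with seeded multi-start.

    ``fixed`` pins any of bottom/top/ec50/hill (e.g. ``{"bottom": 0,
    "hill": 1}`` for the classic two-parameter reduction used when only
    a few doses are available). EC50 is searched on a log scale. A dose
    of exactly 0 is mapped to a small epsilon (default: 1e-6 times the
    smallest positive dose) since the power law is undefined at 0.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise BioassayError("doses and responses must be equal-length vectors")
    if np.any(d < 0):
        raise BioassayError("doses must be >= 0")
    if np.any(d == 0):
        pos = d[d > 0]
        if len(pos) == 0:
            raise BioassayError("need at least one positive dose")
        eps = zero_dose_epsilon if zero_dose_epsilon is not None else 1e-6 * pos.min()
        d = np.where(d == 0, eps, d)
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(_PARAM_ORDER)
    if unknown:
        raise BioassayError(f"unknown fixed parameters {sorted(unknown)}")
    free = [p for p in _PARAM_ORDER if p not in fixed]
    n_distinct = len(np.unique(d))
    if n_distinct < len(free):
        raise BioassayError(
            f"under-determined: {n_distinct} distinct doses cannot identify "
            f"{len(free)} free parameters ({free}); fix "
            f"{len(free) - n_distinct} of them (e.g. bottom and/or hill)"
        )

    lo, hi = float(d.min()), float(d.max())

    def unpack(theta):
        params = dict(fixed)
        for name, v in zip(free, theta):
            params[name] = np.exp(np.clip(v, -700.0, 700.0)) if name == "ec50" else v
        return params

    def residual(theta):
        p = unpack(theta)
        return four_pl(d, p["bottom"], p["top"], p["ec50"], p["hill"]) - y

    rng = np.random.default_rng(seed)
    ymin, ymax = float(y.min()), float(y.max())
    spread = max(ymax - ymin, 1e-12)
    starts = []
    base = {
        "bottom": ymin,
        "top": ymax,
        "ec50": np.sqrt(lo * hi),
        "hill": 1.0,
    }
    hill_grid = (0.5, 1.0, 2.0, 4.0, -1.0, -2.0)
    ec_grid = np.geomspace(max(lo, 1e-12), max(hi, 2e-12), 5)
    for h in hill_grid:
        for e in ec_grid:
            s = dict(base, hill=h, ec50=e)
            starts.append(s)
    for _ in range(n_starts):
        starts.append(
            {
                "bottom": ymin + spread * rng.uniform(-0.5, 0.5),
                "top": ymax + spread * rng.uniform(-0.5, 0.5),
                "ec50": float(np.exp(rng.uniform(np.log(max(lo, 1e-12)), np.log(max(hi, 2e-12))))),
                "hill": float(rng.uniform(-4, 4)),
            }
        )

    best = None
    for s in starts:
        theta0 = [
            np.log(s[name]) if name == "ec50" else s[name] for name in free
        ]
        try:
            res = sopt.least_squares(residual, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res)
    if best is None:
        raise BioassayError("4PL fit failed from every start")
    rss, res = best
    p = unpack(res.x)
    if p["ec50"] <= 0 or not np.isfinite(p["ec50"]):
        converged = False
    else:
        converged = bool(res.success)
    return DoseResponseFit(
        ec50=float(p["ec50"]),
        hill=float(p["hill"]),
        top=float(p["top"]),
        bottom=float(p["bottom"]),
        converged=converged,
        rss=rss,
    )


def ec50_from_reduction(
    summaries: Sequence[GroupSummary],
    baseline_key: int = 1,
    endpoint_key: int = 14,
    include_groups: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
    seed: int = 0,
) -> DoseResponseFit:
    """EC50 pipeline for glucose-lowering data: fit percent reduction in
    the endpoint (baseline minus endpoint, as % of baseline) against
    dose, for the dosed extract groups only (``include_groups`` should
    name them; groups given a different drug must be excluded even if
    they carry a dose). With few distinct doses the fit must be
    constrained; the default pins bottom = 0 and unit-slope rising
    hill = -1 (the Emax curve), leaving top and EC50 free. The result
    is method-dependent — a different constraint choice gives a
    different EC50 — and is reported as such rather than asserted
    against any external value.
    """
    by_group: dict[str, dict[int, GroupSummary]] = {}
    for s in summaries:
        if s.timepoint is None:
            raise BioassayError("summaries must carry timepoints")
        by_group.setdefault(s.group, {})[s.timepoint] = s
    doses, pct = [], []
    for g, tp in by_group.items():
        if include_groups is not None and g not in include_groups:
            continue
        base_s, end_s = tp.get(baseline_key), tp.get(endpoint_key)
        if base_s is None or end_s is None or base_s.dose is None:
            continue
        _, percent = fpg_change(base_s, end_s)
        doses.append(base_s.dose)
        pct.append(percent)
    if len(doses) < 2:
        raise BioassayError("need at least two dosed groups with baseline and endpoint")
    if fixed is None:
        fixed = {"bottom": 0.0, "hill": -1.0}
    return fit_4pl(np.array(doses), np.array(pct), fixed=fixed, seed=seed)
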