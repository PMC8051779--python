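"""Quadratic response-surface fitting with blocked ANOVA diagnostics.

Fits the full second-order polynomial in coded units,

    y = b0 + sum_j bj xj + sum_j bjj xj^2 + sum_{i<j} bij xi xj  (+ block),

by ordinary least squares, with the block modelled as a fixed effect in
sum-to-zero (+1/-1) coding so the reported intercept is block-averaged.
The ANOVA decomposes the corrected total sum of squares into block
(fitted first, sequentially), model, and residual components, splits
the residual into lack-of-fit and pure error using replicated settings,
and reports the usual adequacy statistics (R^2, adjusted R^2, CV%, and
adequate precision, the signal-to-noise measure
``(max yhat - min yhat) / sqrt(p * MSE / n)`` for which values above 4
conventionally indicate a model usable for navigating the design space).

Per-term sums of squares are partial (Type III): the SS drop from
removing that one column from the otherwise full model. On a perfectly
orthogonal design these coincide with sequential SS; blocked rotatable
CCDs are only near-orthogonal, which is why the distinction matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import CCRDesign


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseData:
    """A design paired with one measured response per run."""

    design: CCRDesign
    response: np.ndarray
    response_name: str = "response"

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", y)
        if y.shape != (self.design.n_runs,):
            raise FitError(
                f"response length {y.shape} does not match the "
                f"{self.design.n_runs}-run design"
            )
        if not np.all(np.isfinite(y)):
            raise FitError("responses must all be finite")


# -- model terms -------------------------------------------------------------

def term_names(k: int) -> list[str]:
    """Full-quadratic term labels in the conventional A, B, C... letters:
    linear, then two-factor interactions, then squares."""
    letters = [chr(ord("A") + j) for j in range(k)]
    names = list(letters)
    names += [letters[i] + letters[j] for i in range(k) for j in range(i + 1, k)]
    names += [letter + "^2" for letter in letters]
    return names


def _term_column(name: str, x: np.ndarray) -> np.ndarray:
    """Evaluate one term label on coded settings ``x`` of shape (n, k)."""
    if name.endswith("^2"):
        j = ord(name[0]) - ord("A")
        return x[:, j] ** 2
    if len(name) == 1:
        return x[:, ord(name) - ord("A")]
    i, j = (ord(c) - ord("A") for c in name)
    return x[:, i] * x[:, j]


@dataclass(frozen=True)
class ModelSpec:
    """Which polynomial terms to fit, and whether to include a block effect.

    Terms are labelled "A", "B", ..., "AB", ..., "A^2", ... Hierarchy is
    enforced: a square or interaction requires its parent linear terms.
    """

    terms: tuple[str, ...]
    include_block: bool = True

    def __post_init__(self) -> None:
        present = set(self.terms)
        for t in self.terms:
            parents = (
                {t[0]} if t.endswith("^2") else set(t) if len(t) == 2 else set()
            )
            missing = parents - present
            if missing:
                raise FitError(
                    f"term {t!r} violates model hierarchy: missing parent(s) {sorted(missing)}"
                )

    @classmethod
    def full_quadratic(cls, k: int, include_block: bool = True) -> "ModelSpec":
        return cls(terms=tuple(term_names(k)), include_block=include_block)


@dataclass(frozen=True)
class FittedRSModel:
    spec: ModelSpec
    coefficients: Mapping[str, float]  # includes "Intercept"; coded units
    block_effects: Mapping[int, float]  # sum-to-zero offsets per block
    fitted: np.ndarray
    residuals: np.ndarray
    mse: float
    n: int
    p_params: int
    k: int
    factors: tuple = ()

    def predict(self, coded_point: Sequence[float]) -> float:
        return predict(self, coded_point)


def _design_columns(
    spec: ModelSpec, x: np.ndarray, blocks: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Assemble the OLS design matrix: intercept | block contrast | terms."""
    cols = [np.ones(len(x))]
    names = ["Intercept"]
    if spec.include_block:
        ids = np.unique(blocks)
        if len(ids) > 2:
            raise FitError("at most two blocks are supported")
        if len(ids) == 2:
            contrast = np.where(blocks == ids[0], 1.0, -1.0)
            cols.append(contrast)
            names.append("Block")
    for t in spec.terms:
        cols.append(_term_column(t, x))
        names.append(t)
    return np.column_stack(cols), names


def fit_quadratic(data: ResponseData, spec: ModelSpec | None = None) -> FittedRSModel:
    """Least-squares fit of the coded polynomial (with block effect).

    Raises a singular-fit error naming the collinear terms when the
    design matrix is rank deficient, and requires more runs than
    parameters so the residual has at least one degree of freedom.
    """
    if spec is None:
        spec = ModelSpec.full_quadratic(data.design.k)
    x = data.design.coded_matrix()
    blocks = data.design.blocks()
    X, names = _design_columns(spec, x, blocks)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need n > p to fit: n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # diagnose: columns whose removal does not reduce the rank are
        # the ones living in the span of the others
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise FitError(f"singular fit: collinear terms {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, data.response, rcond=None)
    fitted = X @ beta
    resid = data.response - fitted
    dof = n - p
    mse = float(resid @ resid / dof)

    coefs = {}
    block_effects = {}
    ids = sorted(np.unique(blocks))
    for name, b in zip(names, beta):
        if name == "Block":
            block_effects = {ids[0]: float(b), ids[1]: float(-b)}
        else:
            coefs[name] = float(b)
    return FittedRSModel(
        spec=spec,
        coefficients=coefs,
        block_effects=block_effects,
        fitted=fitted,
        residuals=resid,
        mse=mse,
        n=n,
        p_params=p,
        k=data.design.k,
        factors=data.design.factors,
    )


def model_from_coefficients(
    coefficients: Mapping[str, float], k: int, factors: tuple = ()
) -> FittedRSModel:
    """Wrap externally supplied coded-unit coefficients (e.g. a published
    equation) in a FittedRSModel so predict/optimize can use them."""
    terms = tuple(t for t in coefficients if t != "Intercept")
    spec = ModelSpec(terms=terms, include_block=False)
    return FittedRSModel(
        spec=spec,
        coefficients={str(t): float(v) for t, v in coefficients.items()},
        block_effects={},
        fitted=np.empty(0),
        residuals=np.empty(0),
        mse=float("nan"),
        n=0,
        p_params=len(coefficients),
        k=k,
        factors=tuple(factors),
    )


def predict(model: FittedRSModel, coded_point: Sequence[float]) -> float:
    """Evaluate the coded polynomial at one point, block-averaged (the
    block offset is excluded, matching how coded equations are reported)."""
    c = np.asarray(coded_point, dtype=float)
    if c.shape != (model.k,):
        raise FitError(f"expected a length-{model.k} coded point, got shape {c.shape}")
    x = c[np.newaxis, :]
    y = model.coefficients.get("Intercept", 0.0)
    for t in model.spec.terms:
        y += model.coefficients[t] * _term_column(t, x)[0]
    return float(y)


def predict_many(model: FittedRSModel, coded_points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`predict` over an (n, k) array."""
    x = np.asarray(coded_points, dtype=float)
    y = np.full(len(x), model.coefficients.get("Intercept", 0.0))
    for t in model.spec.terms:
        y = y + model.coefficients[t] * _term_column(t, x)
    return y


# -- ANOVA -------------------------------------------------------------------

def f_ratio(ss_num: float, df_num: int, ss_den: float, df_den: int) -> tuple[float, float]:
    """F statistic and upper-tail p for a mean-square ratio."""
    if df_num < 1 or df_den < 1:
        raise FitError("degrees of freedom must be >= 1")
    if ss_num < 0 or ss_den < 0:
        raise FitError("sums of squares must be >= 0")
    if ss_den == 0:
        return float("inf"), 0.0
    f = (ss_num / df_num) / (ss_den / df_den)
    return float(f), float(stats.f.sf(f, df_num, df_den))


def r_squared(ss_model: float, ss_residual: float) -> float:
    """R^2 = SS_model / (SS_model + SS_resid); the block SS is excluded,
    following the convention of standard DOE software."""
    if ss_model < 0 or ss_residual < 0:
        raise FitError("sums of squares must be >= 0")
    total = ss_model + ss_residual
    if total == 0:
        raise FitError("R^2 undefined: zero model and residual SS")
    return float(ss_model / total)


def pure_error_split(
    data: ResponseData,
    ss_resid: float,
    df_resid: int,
    policy: str = "within_block",
) -> tuple[float, int, float, int]:
    """Split the residual SS into pure error and lack of fit.

    Pure error is the within-group SS over groups of runs with identical
    coded settings; under the default policy replicates only pool within
    a block (blocks are run on different occasions and can differ
    systematically), ``policy="across_blocks"`` pools them regardless.

    Returns ``(ss_pe, df_pe, ss_lof, df_lof)``. With no replicated
    settings, pure error is (0, 0) and the full residual is labelled
    lack of fit (the lack-of-fit test is then undefined).
    """
    if policy not in ("within_block", "across_blocks"):
        raise FitError(f"unknown pooling policy {policy!r}")
    x = np.round(data.design.coded_matrix(), 8)
    blocks = data.design.blocks()
    keys = [
        tuple(row) + ((int(b),) if policy == "within_block" else ())
        for row, b in zip(x, blocks)
    ]
    y = data.response
    groups: dict[tuple, list[float]] = {}
    for key, yi in zip(keys, y):
        groups.setdefault(key, []).append(yi)
    ss_pe = 0.0
    df_pe = 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss_pe += float(((v - v.mean()) ** 2).sum())
            df_pe += len(v) - 1
    ss_lof = max(ss_resid - ss_pe, 0.0)
    df_lof = df_resid - df_pe
    return ss_pe, df_pe, ss_lof, df_lof


@dataclass(frozen=True)
class AnovaTable:
    """Sums-of-squares decomposition: block | model | terms | residual |
    lack_of_fit | pure_error | corrected_total."""

    table: pd.DataFrame

    def row(self, source: str) -> pd.Series:
        match = self.table[self.table["source"] == source]
        if match.empty:
            raise KeyError(source)
        return match.iloc[0]

    def ss(self, source: str) -> float:
        return float(self.row(source)["ss"])

    def df(self, source: str) -> int:
        return int(self.row(source)["df"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova(
    model: FittedRSModel,
    data: ResponseData,
    pooling: str = "within_block",
) -> AnovaTable:
    """Full ANOVA for a fitted blocked response-surface model.

    The block SS is sequential (block after the mean); the model SS is
    the further drop from adding all polynomial terms, so block + model
    + residual add exactly to the corrected total. Per-term SS are
    partial (Type III). Model and term F-ratios test against the
    residual MS; lack of fit tests against pure error.
    """
    y = data.response
    x = data.design.coded_matrix()
    blocks = data.design.blocks()
    X_full, names = _design_columns(model.spec, x, blocks)
    n = len(y)

    ss_total = float(((y - y.mean()) ** 2).sum())
    has_block = "Block" in names
    if has_block:
        X_block = X_full[:, :2]
        rss_block_only = _rss(X_block, y)
        ss_block = ss_total - rss_block_only
        df_block = 1
    else:
        rss_block_only = ss_total
        ss_block = 0.0
        df_block = 0

    ss_resid = float(model.residuals @ model.residuals)
    df_resid = n - model.p_params
    ss_model = rss_block_only - ss_resid
    df_model = len(model.spec.terms)

    rows = []
    if has_block:
        rows.append(("block", ss_block, df_block, ss_block / df_block, None, None))
    fm, pm = (
        f_ratio(ss_model, df_model, ss_resid, df_resid)
        if df_resid > 0
        else (None, None)
    )
    rows.append(("model", ss_model, df_model, ss_model / df_model, fm, pm))

    rss_full = ss_resid
    for t in model.spec.terms:
        j = names.index(t)
        ss_t = _rss(np.delete(X_full, j, axis=1), y) - rss_full
        ss_t = max(ss_t, 0.0)
        ft, pt = f_ratio(ss_t, 1, ss_resid, df_resid) if df_resid > 0 else (None, None)
        rows.append((t, ss_t, 1, ss_t, ft, pt))

    rows.append(
        ("residual", ss_resid, df_resid, ss_resid / df_resid if df_resid else np.nan, None, None)
    )

    ss_pe, df_pe, ss_lof, df_lof = pure_error_split(data, ss_resid, df_resid, pooling)
    if df_pe > 0 and df_lof > 0:
        fl, pl = f_ratio(ss_lof, df_lof, ss_pe, df_pe)
    else:
        fl, pl = None, None
    rows.append(("lack_of_fit", ss_lof, df_lof, ss_lof / df_lof if df_lof else np.nan, fl, pl))
    rows.append(("pure_error", ss_pe, df_pe, ss_pe / df_pe if df_pe else np.nan, None, None))
    rows.append(("corrected_total", ss_total, n - 1, np.nan, None, None))

    return AnovaTable(
        table=pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "f", "p"])
    )


@dataclass(frozen=True)
class AdequacySummary:
    r2: float
    adj_r2: float
    adeq_precision: float
    cv_percent: float


def adequate_precision(model: FittedRSModel, data: ResponseData) -> float:
    """Signal-to-noise: prediction range over the design divided by the
    average prediction SD, ``sqrt(p * MSE / n)``. Infinite when MSE = 0."""
    yhat = model.fitted
    signal = float(yhat.max() - yhat.min())
    if model.mse == 0:
        return float("inf")
    return signal / float(np.sqrt(model.p_params * model.mse / model.n))


def adequacy(model: FittedRSModel, data: ResponseData) -> AdequacySummary:
    tab = anova(model, data)
    r2 = r_squared(tab.ss("model"), tab.ss("residual"))
    df_resid = tab.df("residual")
    df_model = tab.df("model")
    adj = 1.0 - (1.0 - r2) * (df_model + df_resid) / df_resid
    cv = 100.0 * float(np.sqrt(model.mse)) / float(np.mean(data.response))
    return AdequacySummary(
        r2=r2, adj_r2=adj, adeq_precision=adequate_precision(model, data), cv_percent=cv
    )


def surface_grid(
    model: FittedRSModel,
    factor_pair: tuple[int, int],
    fixed: Mapping[int, float],
    resolution: int = 25,
    coded_range: tuple[float, float] = (-1.0, 1.0),
) -> pd.DataFrame:
    """Tabulate the fitted surface over a coded grid in two factors.

    Returns ``resolution**2`` rows (x1, x2, yhat) with the remaining
    factors clamped at the coded values in ``fixed``. This is the data
    behind a 3-D response-surface plot; rendering is left to the caller.
    """
    if resolution < 2:
        raise FitError("resolution must be >= 2")
    i, j = factor_pair
    if i == j or i in fixed or j in fixed:
        raise FitError("factor_pair and fixed indices must not overlap")
    others = set(range(model.k)) - {i, j}
    if others != set(fixed):
        raise FitError(f"fixed must cover exactly the other factor indices {sorted(others)}")
    g = np.linspace(coded_range[0], coded_range[1], resolution)
    x1, x2 = np.meshgrid(g, g, indexing="ij")
    pts = np.zeros((resolution * resolution, model.k))
    pts[:, i] = x1.ravel()
    pts[:, j] = x2.ravel()
    for idx, v in fixed.items():
        pts[:, idx] = v
    return pd.DataFrame({"x1": pts[:, i], "x2": pts[:, j], "yhat": predict_many(model, pts)})


def coded_equation(model: FittedRSModel, decimals: int = 4) -> str:
    """The fitted model as a one-line coded-unit equation string."""
    parts = [f"{model.coefficients.get('Intercept', 0.0):.{decimals}g}"]
    for t in model.spec.terms:
        b = model.coefficients[t]
        sign = "-" if b < 0 else "+"
        parts.append(f"{sign} {abs(b):.{decimals}g}*{t}")
    return " ".join(parts)
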