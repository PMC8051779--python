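"""Blocked central composite rotatable designs (CCRD).

A central composite design for ``k`` factors combines ``2**k`` factorial
(cube-corner) runs, ``2*k`` axial ("star") runs at coded distance ``alpha``
from the centre, and replicated centre runs. The design is *rotatable* —
the prediction variance depends only on the distance from the centre —
when ``alpha = (2**k) ** 0.25``.

Runs are split into two blocks executed on different occasions: block 1
holds the factorial runs plus its centre replicates, block 2 the axial
runs plus further centre replicates. The centre replicates provide the
pure-error degrees of freedom used by the lack-of-fit test.

Factors are handled in *coded units*: the factorial low/high levels map
to -1/+1 via ``code = (actual - centre) / half_range``, so axial runs sit
at +/- alpha on one axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for invalid design requests (too few factors, bad levels...)."""


@dataclass(frozen=True)
class Factor:
    """A continuous experimental factor with its -1/+1 actual levels.

    ``low_actual`` and ``high_actual`` are the *factorial* levels (coded
    -1 and +1), not the axial extremes; axial runs extrapolate to
    ``centre +/- alpha * half_range``.
    """

    name: str
    units: str
    low_actual: float
    high_actual: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.low_actual) or not np.isfinite(self.high_actual):
            raise DesignError(f"factor {self.name!r}: levels must be finite")
        if self.low_actual >= self.high_actual:
            raise DesignError(
                f"factor {self.name!r}: low level {self.low_actual} must be "
                f"below high level {self.high_actual}"
            )

    @property
    def centre(self) -> float:
        return 0.5 * (self.low_actual + self.high_actual)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high_actual - self.low_actual)


def code_value(actual: float, factor: Factor) -> float:
    """Map an actual factor value to coded units.

    Values beyond +/-alpha are legal (extrapolation); callers that care
    should check the magnitude themselves.
    """
    return (actual - factor.centre) / factor.half_range


def decode_value(coded: float, factor: Factor) -> float:
    """Inverse of :func:`code_value`."""
    return factor.centre + coded * factor.half_range


def rotatable_alpha(k: int) -> float:
    """Axial distance making a ``k``-factor CCD rotatable: ``(2**k)**(1/4)``."""
    if k < 2:
        raise DesignError(f"a central composite design needs k >= 2 factors, got {k}")
    return float((2.0**k) ** 0.25)


def orthogonal_blocking_alpha(k: int, n_centre_factorial: int, n_centre_axial: int) -> float:
    """Axial distance giving orthogonal blocking instead of rotatability.

    With ``F = 2**k`` factorial runs, the blocks are orthogonal to the
    model terms when ``alpha**2 = F * (2*k + c_a) / (2 * (F + c_f))``
    where ``c_f``/``c_a`` are centre counts in the factorial and axial
    blocks. Provided for completeness; the rotatable alpha is the default.
    """
    if k < 2:
        raise DesignError(f"a central composite design needs k >= 2 factors, got {k}")
    f = 2**k
    return float(np.sqrt(f * (2 * k + n_centre_axial) / (2.0 * (f + n_centre_factorial))))


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    block_id: int
    coded: tuple[float, ...]
    point_class: str  # "factorial" | "axial" | "centre"
    run_order: int


@dataclass(frozen=True)
class CCRDesign:
    """A blocked central composite design in coded units."""

    factors: tuple[Factor, ...]
    points: tuple[DesignPoint, ...]
    alpha: float
    n_centre_by_block: Mapping[int, int]
    seed: int

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded_matrix(self) -> np.ndarray:
        """(n_runs, k) coded settings, ordered by run_id."""
        return np.array([p.coded for p in self.points], dtype=float)

    def actual_matrix(self) -> np.ndarray:
        coded = self.coded_matrix()
        out = np.empty_like(coded)
        for j, fac in enumerate(self.factors):
            out[:, j] = fac.centre + coded[:, j] * fac.half_range
        return out

    def blocks(self) -> np.ndarray:
        return np.array([p.block_id for p in self.points], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: run_id, block, run_order, point_class, coded + actual columns."""
        coded = self.coded_matrix()
        actual = self.actual_matrix()
        df = pd.DataFrame(
            {
                "run_id": [p.run_id for p in self.points],
                "block": [p.block_id for p in self.points],
                "run_order": [p.run_order for p in self.points],
                "point_class": [p.point_class for p in self.points],
            }
        )
        for j, fac in enumerate(self.factors):
            df[f"{fac.name}_coded"] = coded[:, j]
        for j, fac in enumerate(self.factors):
            df[f"{fac.name}_actual"] = actual[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_point(coded: Sequence[float], atol: float = 1e-8) -> str:
    """Label a coded run as factorial, axial or centre by its pattern.

    Factorial: every coordinate at +/-1. Centre: all zero. Axial: exactly
    one nonzero coordinate (any magnitude > 1 counts; the printed actuals
    of real designs are often rounded so the axial distance is not exact).
    """
    c = np.asarray(coded, dtype=float)
    if np.all(np.abs(c) <= atol):
        return "centre"
    if np.all(np.abs(np.abs(c) - 1.0) <= 1e-3):
        return "factorial"
    nonzero = np.abs(c) > 1e-3
    if nonzero.sum() == 1:
        return "axial"
    raise DesignError(f"coded point {tuple(c)} fits no CCD point class")


def build_ccrd(
    factors: Sequence[Factor],
    centre_counts: Mapping[int, int] | None = None,
    seed: int = 0,
    alpha: float | None = None,
) -> CCRDesign:
    """Construct a two-block rotatable central composite design.

    Block 1 holds the ``2**k`` factorial runs plus ``centre_counts[1]``
    centre replicates; block 2 the ``2*k`` axial runs plus
    ``centre_counts[2]`` replicates. Run order is a seeded uniform
    permutation within each block (blocks are executed in sequence, so
    randomization happens inside them).

    Parameters
    ----------
    factors
        Ordered factor definitions; ``k = len(factors) >= 2``.
    centre_counts
        Mapping ``{1: n_factorial_block_centres, 2: n_axial_block_centres}``;
        defaults to ``{1: 4, 2: 2}``, the classic 20-run layout for k=3.
    seed
        Seeds the run-order permutation only; the geometry is deterministic.
    alpha
        Axial distance override; defaults to :func:`rotatable_alpha`.
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 2:
        raise DesignError(f"need at least 2 factors, got {k}")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate factor names: {names}")
    if centre_counts is None:
        centre_counts = {1: 4, 2: 2}
    centre_counts = {int(b): int(c) for b, c in centre_counts.items()}
    if any(c < 0 for c in centre_counts.values()):
        raise DesignError("centre counts must be >= 0")
    if alpha is None:
        alpha = rotatable_alpha(k)

    rows: list[tuple[int, tuple[float, ...], str]] = []  # (block, coded, class)
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.append((1, corner, "factorial"))
    for _ in range(centre_counts.get(1, 0)):
        rows.append((1, (0.0,) * k, "centre"))
    for j in range(k):
        for sign in (-1.0, 1.0):
            coded = [0.0] * k
            coded[j] = sign * alpha
            rows.append((2, tuple(coded), "axial"))
    for _ in range(centre_counts.get(2, 0)):
        rows.append((2, (0.0,) * k, "centre"))

    rng = np.random.default_rng(seed)
    run_order = np.empty(len(rows), dtype=int)
    offset = 0
    for block in sorted({b for b, _, _ in rows}):
        idx = [i for i, (b, _, _) in enumerate(rows) if b == block]
        run_order[idx] = offset + 1 + rng.permutation(len(idx))
        offset += len(idx)

    points = tuple(
        DesignPoint(
            run_id=i + 1,
            block_id=block,
            coded=coded,
            point_class=cls,
            run_order=int(run_order[i]),
        )
        for i, (block, coded, cls) in enumerate(rows)
    )
    return CCRDesign(
        factors=factors,
        points=points,
        alpha=float(alpha),
        n_centre_by_block=dict(centre_counts),
        seed=int(seed),
    )


def design_from_actuals(
    factors: Sequence[Factor],
    actuals: np.ndarray,
    blocks: Iterable[int],
    alpha: float | None = None,
    seed: int = 0,
) -> CCRDesign:
    """Reconstruct a CCRDesign from a table of actual settings (e.g. a
    published run sheet). Points are classified from their coded pattern;
    run order is taken as the row order."""
    factors = tuple(factors)
    actuals = np.asarray(actuals, dtype=float)
    blocks = list(blocks)
    if actuals.shape != (len(blocks), len(factors)):
        raise DesignError("actuals must be (n_runs, k) matching blocks length")
    if alpha is None:
        alpha = rotatable_alpha(len(factors))
    points = []
    centre_counts: dict[int, int] = {}
    for i, (row, block) in enumerate(zip(actuals, blocks)):
        coded = tuple(code_value(v, f) for v, f in zip(row, factors))
        cls = classify_point(coded)
        if cls == "centre":
            centre_counts[block] = centre_counts.get(block, 0) + 1
        points.append(
            DesignPoint(run_id=i + 1, block_id=int(block), coded=coded,
                        point_class=cls, run_order=i + 1)
        )
    return CCRDesign(
        factors=factors,
        points=tuple(points),
        alpha=float(alpha),
        n_centre_by_block=centre_counts,
        seed=int(seed),
    )


def read_factors_csv(path) -> list[Factor]:
    """Read factor definitions from a CSV with columns name,units,low,high."""
    df = pd.read_csv(path)
    required = {"name", "units", "low", "high"}
    if not required.issubset(df.columns):
        raise DesignError(f"factors CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return [
        Factor(str(r["name"]), str(r["units"]), float(r["low"]), float(r["high"]))
        for _, r in df.iterrows()
    ]
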