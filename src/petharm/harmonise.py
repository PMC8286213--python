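"""Multi-scanner aggregation, specification limits and compliance checking.

Specification limits for multi-centre trials are derived as
mean +- k * SD (default k = 2) of each recovery metric across the
submitted scanner results, per sphere size and reconstruction family.
The Ga-68 limits table shipped with the package
(``data/limits_ga68_table2.csv``) carries one set of bounds for
conventional (OSEM / OSEM+TOF) and one for advanced (PSF / penalised
likelihood) reconstructions; user-supplied tables in the same CSV schema
(family, metric, diameter_mm, lower, upper) can be loaded instead, e.g.
the EARL F-18 standards, which are not shipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompatibleResultsError,
    IncompleteLimitsError,
    InsufficientDataError,
    InvalidReferenceError,
)
from .metrics import IQResult, RC_METRICS

__all__ = [
    "EnsembleSummary",
    "LimitsTable",
    "aggregate",
    "derive_limits",
    "check_compliance",
    "pct_difference",
    "welch_t_test",
]


@dataclass
class EnsembleSummary:
    """Across-scanner mean/SD/n per sphere and metric (long-format table)."""

    table: pd.DataFrame  # columns: diameter_mm, metric, mean, sd, n

    def value(self, diameter_mm: float, metric: str, column: str = "mean") -> float:
        sel = self.table[
            (self.table.diameter_mm == diameter_mm) & (self.table.metric == metric)
        ]
        if sel.empty:
            raise KeyError((diameter_mm, metric))
        return float(sel.iloc[0][column])


def aggregate(results: list[IQResult], metrics: tuple[str, ...] = RC_METRICS) -> EnsembleSummary:
    """Across-scanner mean and sample SD of each metric, per sphere."""
    if len(results) < 2:
        raise InsufficientDataError("aggregation needs at least 2 results")
    diameters = results[0].diameters()
    for r in results[1:]:
        if r.diameters() != diameters:
            raise IncompatibleResultsError("results have mismatched sphere sets")
    rows = []
    for d in diameters:
        for m in metrics:
            vals = np.array([r.spheres[d][m] for r in results])
            rows.append(
                {
                    "diameter_mm": d,
                    "metric": m,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": len(vals),
                }
            )
    return EnsembleSummary(pd.DataFrame(rows))


@dataclass
class LimitsTable:
    """Per-sphere, per-metric [lower, upper] acceptance bounds by family."""

    table: pd.DataFrame  # columns: family, metric, diameter_mm, lower, upper

    REQUIRED_COLUMNS = ("family", "metric", "diameter_mm", "lower", "upper")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED_COLUMNS) - set(self.table.columns)
        if missing:
            raise IncompleteLimitsError(f"limits table missing columns {sorted(missing)}")
        bad = self.table[self.table.lower > self.table.upper]
        if not bad.empty:
            raise IncompleteLimitsError("limits table has lower > upper entries")

    def bounds(self, family: str, metric: str, diameter_mm: float) -> tuple[float, float]:
        sel = self.table[
            (self.table.family == family)
            & (self.table.metric == metric)
            & (np.isclose(self.table.diameter_mm, diameter_mm))
        ]
        if sel.empty:
            raise IncompleteLimitsError(
                f"no limits for {family}/{metric}/{diameter_mm:g} mm"
            )
        row = sel.iloc[0]
        return float(row.lower), float(row.upper)

    def families(self) -> list[str]:
        return sorted(self.table.family.unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LimitsTable":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def shipped_ga68(cls) -> "LimitsTable":
        """The Ga-68 specification limits distributed with the package."""
        ref = resources.files("petharm.data").joinpath("limits_ga68_table2.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def derive_limits(
    summary: EnsembleSummary,
    k: float = 2.0,
    family: str = "advanced",
    metrics: tuple[str, ...] = RC_METRICS,
) -> LimitsTable:
    """Specification bounds = mean +- k * SD per sphere and metric."""
    rows = []
    for _, r in summary.table.iterrows():
        if r.metric not in metrics:
            continue
        if not np.isfinite(r.sd):
            raise InvalidReferenceError("non-finite SD in ensemble summary")
        if r.sd == 0:
            warnings.warn(
                f"degenerate limits (zero SD) for {r.metric} at {r.diameter_mm:g} mm",
                stacklevel=2,
            )
        rows.append(
            {
                "family": family,
                "metric": r.metric,
                "diameter_mm": r.diameter_mm,
                "lower": r["mean"] - k * r.sd,
                "upper": r["mean"] + k * r.sd,
            }
        )
    return LimitsTable(pd.DataFrame(rows))


def check_compliance(
    result: IQResult,
    limits: LimitsTable,
    family: str,
    metrics: tuple[str, ...] = RC_METRICS,
) -> pd.DataFrame:
    """Closed-interval pass/fail of one result against a limits table.

    Returns one row per sphere and metric with the percent deviation from
    the violated bound (0 for passing entries).
    """
    rows = []
    for d in result.diameters():
        for m in metrics:
            value = result.spheres[d][m]
            lower, upper = limits.bounds(family, m, d)
            passed = lower <= value <= upper
            if passed:
                deviation = 0.0
            elif value < lower:
                deviation = 100.0 * (value - lower) / lower
            else:
                deviation = 100.0 * (value - upper) / upper
            rows.append(
                {
                    "diameter_mm": d,
                    "metric": m,
                    "value": value,
                    "lower": lower,
                    "upper": upper,
                    "passed": passed,
                    "deviation_pct": deviation,
                }
            )
    return pd.DataFrame(rows)


def pct_difference(rc_a: float, rc_b: float) -> float:
    """100 * (a - b) / b — percent difference of a against reference b."""
    if rc_b <= 0:
        raise InvalidReferenceError("reference value must be > 0")
    return 100.0 * (rc_a - rc_b) / rc_b


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return 0.0, float(a.size + b.size - 2), 1.0
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)
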