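"""Guild-abundance epidemiology: median dichotomization, 2x2 odds ratios,
inverse-variance fixed-effect meta-analysis with I², and covariate-adjusted
outcome regression."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CohortEffect",
    "MetaResult",
    "OutcomeModel",
    "dichotomize_by_median",
    "odds_ratio_2x2",
    "cohort_effect_from_counts",
    "fixed_effect_meta",
    "adjusted_group_difference",
    "write_forest_data",
    "write_meta_json",
]

_Z95 = 1.959963984540054  # 97.5th normal percentile


@dataclass(frozen=True)
class CohortEffect:
    """Log odds ratio of case status for high vs low guild abundance.

    Cells: a = high/case, b = high/control, c = low/case, d = low/control.
    """

    cohort: str
    a: int
    b: int
    c: int
    d: int
    log_or: float
    se: float

    @property
    def or_(self) -> float:
        return math.exp(self.log_or)


@dataclass(frozen=True)
class MetaResult:
    pooled_log_or: float
    ci_low: float
    ci_high: float
    q: float
    i_squared: float  # percentage in [0, 100]
    effects: tuple[CohortEffect, ...]

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class OutcomeModel:
    outcome: str
    n: int
    coefficients: Mapping[str, tuple[float, float, float, float]]
    # name -> (estimate, ci_low, ci_high, p)

    @property
    def group_effect(self) -> tuple[float, float, float, float]:
        return self.coefficients["group_high"]


# ---------------------------------------------------------------------------

def dichotomize_by_median(values: Mapping[str, float]) -> dict[str, str]:
    """Split samples at the median: strictly above -> "high", else "low".

    The median of an even number of values is the mean of the middle
    pair; ties at the median go to "low".
    """
    if len(values) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    vals = np.array(list(values.values()), dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("all values identical: degenerate median split")
    med = float(np.median(vals))
    return {s: ("high" if v > med else "low") for s, v in values.items()}


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Odds ratio, log OR, and SE of a 2x2 table.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    before computing; exact tables are left untouched.  SE is
    sqrt(sum of reciprocal cells) on the (possibly corrected) cells.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    if 0 in cells:
        a2, b2, c2, d2 = (x + 0.5 for x in cells)
    else:
        a2, b2, c2, d2 = map(float, cells)
    or_ = (a2 * d2) / (b2 * c2)
    log_or = math.log(or_)
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    return or_, log_or, se


def cohort_effect_from_counts(
    cohort: str, a: int, b: int, c: int, d: int
) -> CohortEffect:
    _, log_or, se = odds_ratio_2x2(a, b, c, d)
    return CohortEffect(cohort=cohort, a=a, b=b, c=c, d=d, log_or=log_or, se=se)


def cohort_effect(
    cohort: str,
    abundance: Mapping[str, float],
    condition: Mapping[str, str],
) -> CohortEffect:
    """2x2 effect for one cohort from guild abundance + case/control labels."""
    groups = dichotomize_by_median(abundance)
    a = b = c = d = 0
    for sid, grp in groups.items():
        lab = condition[sid]
        if grp == "high":
            a += lab == "case"
            b += lab == "control"
        else:
            c += lab == "case"
            d += lab == "control"
    return cohort_effect_from_counts(cohort, a, b, c, d)


def fixed_effect_meta(effects: Sequence[CohortEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q and I².

    I² = max(0, (Q - df) / Q) * 100; the 95% CI is symmetric about the
    pooled log OR.
    """
    if not effects:
        raise ValueError("need at least one cohort effect")
    if any(e.se <= 0 for e in effects):
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / e.se**2 for e in effects])
    logors = np.array([e.log_or for e in effects])
    pooled = float(np.sum(w * logors) / np.sum(w))
    se_pooled = 1.0 / math.sqrt(float(np.sum(w)))
    q = float(np.sum(w * (logors - pooled) ** 2))
    df = len(effects) - 1
    i_squared = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    return MetaResult(
        pooled_log_or=pooled,
        ci_low=pooled - _Z95 * se_pooled,
        ci_high=pooled + _Z95 * se_pooled,
        q=q,
        i_squared=i_squared,
        effects=tuple(effects),
    )


def adjusted_group_difference(
    outcome: Sequence[float],
    group: Sequence[str],
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] | None = None,
    outcome_name: str = "outcome",
) -> OutcomeModel:
    """OLS of a continuous outcome on the high/low indicator + covariates.

    Reports each coefficient with its 95% CI and two-sided p-value; the
    group indicator codes "high" as 1.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.array([1.0 if v == "high" else 0.0 for v in group])
    n = y.size
    cols = [g]
    names = ["group_high"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if covariate_names is None:
            covariate_names = [f"x{i}" for i in range(cov.shape[1])]
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
        names.extend(covariate_names)
    if n <= len(names) + 2:
        raise ValueError("too few samples for the requested model")
    x = sm.add_constant(np.column_stack(cols))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"check collinearity among {['const'] + list(names)}"
        )
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)
    coefficients = {}
    for k, name in enumerate(["const"] + list(names)):
        coefficients[name] = (
            float(fit.params[k]),
            float(ci[k, 0]),
            float(ci[k, 1]),
            float(fit.pvalues[k]),
        )
    return OutcomeModel(outcome=outcome_name, n=n, coefficients=coefficients)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_forest_data(result: MetaResult, path: str | Path) -> None:
    """Forest-plot TSV: per-cohort OR, CI, and fixed-effect weight."""
    total_w = sum(1.0 / e.se**2 for e in result.effects)
    with open(path, "w") as fh:
        fh.write("cohort\tor\tci_low\tci_high\tweight\n")
        for e in result.effects:
            lo = math.exp(e.log_or - _Z95 * e.se)
            hi = math.exp(e.log_or + _Z95 * e.se)
            w = (1.0 / e.se**2) / total_w
            fh.write(f"{e.cohort}\t{e.or_:.6g}\t{lo:.6g}\t{hi:.6g}\t{w:.6g}\n")
        lo, hi = result.or_ci
        fh.write(f"POOLED\t{result.pooled_or:.6g}\t{lo:.6g}\t{hi:.6g}\t1\n")


def write_meta_json(result: MetaResult, path: str | Path) -> None:
    payload = {
        "pooled_log_or": result.pooled_log_or,
        "pooled_or": result.pooled_or,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "q": result.q,
        "i_squared": result.i_squared,
        "cohorts": [
            {
                "cohort": e.cohort,
                "a": e.a,
                "b": e.b,
                "c": e.c,
                "d": e.d,
                "log_or": e.log_or,
                "se": e.se,
            }
            for e in result.effects
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
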