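"""Rank-correlation analysis between degradation state and its drivers.

Spearman's rho with average-rank tie handling, two-tailed significance by
a t approximation (default) or by permutation (exact enumeration for small
n, Monte-Carlo otherwise), a correlation table mirroring the classic
"degradation state versus component" layout, and a class-count summary.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import CLASS_NAMES, LakeAssessment

__all__ = ["CorrelationRow", "spearman_rho", "spearman_pvalue",
           "correlation_table", "summary_report", "CLASS_ORDINAL"]

# ordinal encoding of the degradation classes: natural < semi < degraded
CLASS_ORDINAL = {"natural": 1, "semi_degraded": 2, "degraded": 3}


@dataclass(frozen=True)
class CorrelationRow:
    variable: str
    rho: float
    p_value: float
    n: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on midranks, average-rank ties).

    A constant sequence has undefined rank correlation: returns NaN with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant sequence: Spearman rho undefined", stacklevel=2)
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def spearman_pvalue(rho: float, n: int, method: str = "t_approx",
                    seed: int | None = None, n_resamples: int = 10000,
                    x: Sequence[float] | None = None,
                    y: Sequence[float] | None = None) -> float:
    """Two-tailed significance of a Spearman rho.

    ``t_approx`` uses t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom (|rho| = 1 -> p = 0 by convention).  ``permutation`` enumerates
    all n! orderings exactly for n <= 8 and Monte-Carlo samples
    ``n_resamples`` permutations above; it needs the data vectors x, y to
    respect ties.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a p-value")
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if method == "permutation":
        if x is None or y is None:
            x = np.arange(n, dtype=float)
            y = None
        x = np.asarray(x, dtype=float)
        yv = (np.asarray(y, dtype=float) if y is not None
              else None)
        if yv is None:
            raise ValueError("permutation method needs the data vectors x and y")
        obs = abs(rho)
        tol = 1e-12
        if n <= 8:
            count = total = 0
            for perm in itertools.permutations(range(n)):
                r = spearman_rho(x, yv[list(perm)])
                total += 1
                if abs(r) >= obs - tol:
                    count += 1
            return count / total
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_resamples):
            r = spearman_rho(x, rng.permutation(yv))
            if abs(r) >= obs - tol:
                count += 1
        return (count + 1) / (n_resamples + 1)
    raise ValueError(f"unknown method {method!r}")


def correlation_table(
    assessments: Sequence[LakeAssessment],
    variables: Mapping[str, Sequence[float]],
    method: str = "t_approx",
    seed: int | None = None,
) -> list[CorrelationRow]:
    """One Spearman correlation row per named variable against degradation
    state (encoded natural=1 < semi_degraded=2 < degraded=3)."""
    state = np.array([CLASS_ORDINAL[a.degradation_class] for a in assessments],
                     dtype=float)
    n = state.size
    rows = []
    for name, col in variables.items():
        col = np.asarray(col, dtype=float)
        if col.size != n:
            raise ValueError(f"variable {name!r} has {col.size} values, need {n}")
        rho = spearman_rho(state, col)
        if math.isnan(rho):
            p = float("nan")
        elif method == "permutation":
            p = spearman_pvalue(rho, n, method="permutation", seed=seed,
                                x=state, y=col)
        else:
            p = spearman_pvalue(rho, n)
        rows.append(CorrelationRow(name, rho, p, int(n)))
    return rows


def correlation_frame(rows: Sequence[CorrelationRow]) -> pd.DataFrame:
    """The correlation table as a DataFrame with significance stars
    (* p < .05, ** p < .01, two-tailed)."""
    def stars(p: float) -> str:
        if math.isnan(p):
            return ""
        return "**" if p < 0.01 else "*" if p < 0.05 else ""

    return pd.DataFrame({
        "variable": [r.variable for r in rows],
        "rho": [r.rho for r in rows],
        "p_value": [r.p_value for r in rows],
        "n": [r.n for r in rows],
        "sig": [stars(r.p_value) for r in rows],
    })


def summary_report(assessments: Sequence[LakeAssessment]) -> pd.DataFrame:
    """Counts and percentages of lakes per degradation class."""
    if len(assessments) == 0:
        warnings.warn("empty cohort: summary report has no rows", stacklevel=2)
        return pd.DataFrame(columns=["class", "count", "percent"])
    counts = {c: 0 for c in CLASS_NAMES}
    for a in assessments:
        counts[a.degradation_class] += 1
    total = len(assessments)
    return pd.DataFrame({
        "class": list(counts),
        "count": list(counts.values()),
        "percent": [100.0 * v / total for v in counts.values()],
    })
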