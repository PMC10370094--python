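"""Replicate CVs, Welch t-tests with Bonferroni correction, method agreement.

The assay's statistics are deliberately simple: coefficients of variation
over technical replicates (raw and TIC-normalized peak areas), two-tailed
heteroscedastic (Welch) t-tests on fold changes with Bonferroni correction
over a configured number of comparisons, and ordinary least-squares /
Pearson R^2 agreement between two quantification methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

BASIS_RAW = "raw"
BASIS_TIC = "tic_normalized"


@dataclass
class CvRecord:
    """Coefficient of variation of one peptide's replicate peak areas."""

    protein: str
    peptide: str
    basis: str
    cv: float
    n: int
    condition: str = ""


def compute_cv(
    areas: Sequence[float],
    tics: Sequence[float] | None = None,
    protein: str = "",
    peptide: str = "",
    ddof: int = 1,
) -> CvRecord:
    """CV = sample standard deviation / mean of (optionally TIC-divided) areas.

    The sample (n-1) standard deviation is used by default; ``ddof=0`` gives
    the population form.
    """
    x = np.asarray(areas, dtype=float)
    if len(x) < 2:
        raise StatsError("CV requires at least 2 replicates")
    if not np.all(np.isfinite(x)):
        raise StatsError("non-finite areas")
    basis = BASIS_RAW
    if tics is not None:
        t = np.asarray(tics, dtype=float)
        if t.shape != x.shape:
            raise StatsError("tics must match areas in length")
        if np.any(t <= 0):
            raise StatsError("non-positive TIC")
        x = x / t
        basis = BASIS_TIC
    mean = float(np.mean(x))
    if mean <= 0:
        raise StatsError("CV undefined for non-positive mean")
    return CvRecord(
        protein=protein,
        peptide=peptide,
        basis=basis,
        cv=float(np.std(x, ddof=ddof) / mean),
        n=len(x),
    )


def summarize_cv(records: Iterable[CvRecord]) -> dict[str, tuple[float, float]]:
    """Per-basis (median, max) of CVs.

    The median of an even count is the mean of the two central order
    statistics.
    """
    by_basis: dict[str, list[float]] = {}
    for rec in records:
        by_basis.setdefault(rec.basis, []).append(rec.cv)
    if not by_basis:
        raise StatsError("no CV records to summarize")
    return {
        basis: (float(np.median(cvs)), float(np.max(cvs)))
        for basis, cvs in by_basis.items()
    }


def cv_table(table: pd.DataFrame, ddof: int = 1) -> list[CvRecord]:
    """Raw and TIC-normalized CV records per peptide and condition.

    Replicates are technical replicates of one condition, so CVs are
    computed within each (protein, peptide, condition) group.
    """
    out: list[CvRecord] = []
    for (protein, peptide, condition), grp in table.groupby(
        ["protein", "peptide", "condition"], sort=False
    ):
        areas = grp["area"].to_numpy()
        tics = grp["tic"].to_numpy()
        for t in (None, tics):
            rec = compute_cv(areas, tics=t, protein=protein, peptide=peptide, ddof=ddof)
            rec.condition = condition
            out.append(rec)
    return out


@dataclass
class TestResult:
    """Welch t-test with Bonferroni-adjusted p-value."""

    comparison: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    m_comparisons: int
    adjusted_p: float


def welch_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    m: int = 1,
    comparison: str = "",
) -> TestResult:
    """Two-tailed heteroscedastic t-test with Welch-Satterthwaite df.

    ``adjusted_p = min(1, m * p)`` (Bonferroni).  Two groups with zero
    variance and equal means yield t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise StatsError("non-finite observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if np.mean(a) == np.mean(b):
            t_stat, df, p = 0.0, float(na + nb - 2), 1.0
        else:
            t_stat = math.inf if np.mean(a) > np.mean(b) else -math.inf
            df, p = float(na + nb - 2), 0.0
    else:
        t_stat = float((np.mean(a) - np.mean(b)) / math.sqrt(se2))
        if va == 0.0:
            df = float(nb - 1)
        elif vb == 0.0:
            df = float(na - 1)
        else:
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return TestResult(
        comparison=comparison,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        m_comparisons=m,
        adjusted_p=min(1.0, m * p),
    )


def method_agreement(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """OLS fit and squared Pearson correlation between two methods.

    Returns ``(slope, intercept, r_squared)``; used e.g. to compare
    sum-normalized PRM shares against immunoblot densitometry shares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("method agreement needs equal-length vectors, n >= 3")
    if np.var(x) == 0:
        raise StatsError("slope undefined: zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def significance_stars(adjusted_p: float) -> str:
    """Star annotation bands for adjusted p-values.

    ``>= 0.05`` -> no annotation; ``[0.01, 0.05)`` -> ``*``;
    ``[0.001, 0.01)`` -> ``**``; ``[0.0001, 0.001)`` -> ``***``;
    ``< 0.0001`` -> ``****``.
    """
    if not np.isfinite(adjusted_p) or adjusted_p >= 0.05:
        return ""
    if adjusted_p >= 0.01:
        return "*"
    if adjusted_p >= 0.001:
        return "**"
    if adjusted_p >= 0.0001:
        return "***"
    return "****"
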