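"""Normalization schemes, fold changes, and the labeling-activity diagnostic.

Four ways of normalizing the analyte's peak area within each run:

* ``TIC`` — divide by the run's MS1 total-ion-current area;
* ``INDEPENDENT`` — divide by a labeling-independent factor (endogenously
  biotinylated carboxylases such as pyruvate carboxylase);
* ``COMPARTMENT`` — divide by an abundant protein sharing the peroxidase's
  compartment (e.g. beta/gamma-actin);
* ``ENZYME`` — divide by the auto-labeled peroxidase itself (APEX2).

Because labeled-protein recovery scales with the peroxidase labeling
activity while carboxylase recovery does not, the ratio of ENZYME- to
INDEPENDENT-normalized fold changes diagnoses condition-dependent labeling
activity changes: a ratio above an equivalence band means labeling activity
decreased under treatment, below it means it increased, and the TIC-based
fold change sits between the two extremes whenever the TIC carries a
nonzero labeling-independent share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NormalizationError
from . import stats as _stats

SCHEME_KINDS = ("TIC", "INDEPENDENT", "COMPARTMENT", "ENZYME")

#: scheme kind -> protein role expected in the roles mapping
_ROLE_FOR_KIND = {
    "INDEPENDENT": "independent_factor",
    "COMPARTMENT": "compartment_factor",
    "ENZYME": "apex_factor",
}


@dataclass(frozen=True)
class NormalizationScheme:
    """One normalization scheme and (for non-TIC kinds) its factor proteins."""

    kind: str
    factor_proteins: tuple[str, ...] = ()
    combine: str = "sum"  # or "median_ratio"

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ConfigurationError(
                f"unknown scheme {self.kind!r}; expected one of {SCHEME_KINDS}"
            )
        if self.combine not in ("sum", "median_ratio"):
            raise ConfigurationError(f"unknown combine mode {self.combine!r}")

    def resolve_factors(self, roles: Mapping[str, str] | None) -> tuple[str, ...]:
        if self.kind == "TIC":
            return ()
        if self.factor_proteins:
            return self.factor_proteins
        if roles:
            want = _ROLE_FOR_KIND[self.kind]
            found = tuple(p for p, r in roles.items() if r == want)
            if found:
                return found
        raise ConfigurationError(
            f"scheme {self.kind} references no factor proteins and none were "
            f"found in the roles mapping"
        )


def scheme_from_roles(kind: str, roles: Mapping[str, str]) -> NormalizationScheme:
    """Build a scheme whose factor set is read off a protein->role mapping."""
    s = NormalizationScheme(kind=kind)
    return NormalizationScheme(kind=kind, factor_proteins=s.resolve_factors(roles))


_REQUIRED = {"protein", "peptide", "condition", "replicate", "area", "tic"}


def _check_table(table: pd.DataFrame) -> None:
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise NormalizationError(f"quant table missing columns: {sorted(missing)}")
    if (table["area"] < 0).any():
        raise NormalizationError("negative areas in quant table")
    per_run_tic = table.groupby(["condition", "replicate"])["tic"].nunique()
    if (per_run_tic != 1).any():
        bad = per_run_tic[per_run_tic != 1].index.tolist()
        raise NormalizationError(f"inconsistent TIC within runs: {bad}")


def normalize(
    table: pd.DataFrame,
    scheme: NormalizationScheme,
    analyte: str,
    roles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-run normalized analyte signal.

    For each (condition, replicate): the analyte's peptide areas are summed
    and divided by the factor signal of the same run — the TIC, or the
    summed (or median-ratio-combined) areas of the scheme's factor
    peptides.  Returns a frame with columns ``condition, replicate, value``.
    """
    _check_table(table)
    factors = scheme.resolve_factors(roles)
    rows = []
    for (condition, replicate), grp in table.groupby(
        ["condition", "replicate"], sort=False
    ):
        analyte_rows = grp[grp["protein"] == analyte]
        if analyte_rows.empty:
            raise NormalizationError(
                f"analyte {analyte!r} absent in run ({condition}, {replicate})"
            )
        analyte_area = float(analyte_rows["area"].sum())
        if scheme.kind == "TIC":
            factor_signal = float(grp["tic"].iloc[0])
            if factor_signal <= 0:
                raise NormalizationError(
                    f"zero TIC in run ({condition}, {replicate})"
                )
            value = analyte_area / factor_signal
        else:
            factor_rows = grp[grp["protein"].isin(factors)]
            if factor_rows.empty or float(factor_rows["area"].sum()) <= 0:
                raise NormalizationError(
                    f"factor {factors} absent or zero in run ({condition}, {replicate})"
                )
            if scheme.combine == "sum":
                value = analyte_area / float(factor_rows["area"].sum())
            else:  # median_ratio over factor peptides
                if (factor_rows["area"] <= 0).any():
                    raise NormalizationError(
                        f"zero factor peptide area in run ({condition}, {replicate})"
                    )
                value = float(np.median(analyte_area / factor_rows["area"].to_numpy()))
        if analyte_area == 0.0:
            warnings.warn(
                f"analyte area is zero in run ({condition}, {replicate}); "
                "normalized value set to 0",
                stacklevel=2,
            )
        rows.append({"condition": condition, "replicate": replicate, "value": value})
    return pd.DataFrame(rows)


def sum_normalize(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Within-replicate shares: each condition's value over the sum of all.

    This is the within-experiment normalization used when comparing methods
    that measure the same set of conditions (e.g. PRM vs immunoblot).
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise NormalizationError("sum-normalization needs at least 2 conditions")
    total = float(s.sum())
    if total <= 0:
        raise NormalizationError("sum of condition values is not positive")
    return s / total


@dataclass
class FoldChangeResult:
    """Fold change of one condition vs the reference under one scheme."""

    condition: str
    scheme: str
    values: np.ndarray  # per paired replicate experiment
    fold_change: float
    sem: float
    p_value: float
    adjusted_p: float
    n: int


def fold_change(
    table: pd.DataFrame,
    scheme: NormalizationScheme,
    analyte: str,
    reference_condition: str,
    roles: Mapping[str, str] | None = None,
    m_comparisons: int | None = None,
) -> list[FoldChangeResult]:
    """Per-condition fold changes vs the reference, paired by replicate.

    Each replicate experiment (identified by the ``replicate`` column) pairs
    one run per condition; the condition's normalized value is divided by
    the reference's value within the same replicate.  Means, standard
    errors, and Welch t-tests vs the reference (Bonferroni-adjusted over
    ``m_comparisons``, default the number of non-reference conditions) are
    reported.
    """
    norm = normalize(table, scheme, analyte, roles=roles)
    wide = norm.pivot(index="replicate", columns="condition", values="value")
    if reference_condition not in wide.columns:
        raise NormalizationError(f"reference {reference_condition!r} not in table")
    unpaired = wide.index[wide[reference_condition].isna()].tolist()
    if unpaired:
        raise NormalizationError(
            f"replicates without a reference run: {unpaired}"
        )
    conditions = [c for c in norm["condition"].unique()]
    if m_comparisons is None:
        m_comparisons = max(1, len(conditions) - 1)
    ref_vals = wide[reference_condition]
    if (ref_vals <= 0).any():
        raise NormalizationError("non-positive reference value; cannot form fold change")
    results = []
    for condition in conditions:
        col = wide[condition]
        unpaired = wide.index[col.isna()].tolist()
        if unpaired:
            raise NormalizationError(
                f"condition {condition!r} missing in replicates {unpaired}"
            )
        fc = (col / ref_vals).to_numpy(dtype=float)
        n = len(fc)
        mean = float(np.mean(fc))
        sem = float(np.std(fc, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if condition == reference_condition:
            p = 1.0
        else:
            ref_fc = (ref_vals / ref_vals).to_numpy(dtype=float)  # exactly ones
            p = _stats.welch_test(fc, ref_fc, m=1).p_value if n >= 2 else float("nan")
        adj = min(1.0, m_comparisons * p) if np.isfinite(p) else p
        results.append(
            FoldChangeResult(
                condition=condition,
                scheme=scheme.kind,
                values=fc,
                fold_change=mean,
                sem=sem,
                p_value=p,
                adjusted_p=adj,
                n=n,
            )
        )
    return results


def results_to_frame(results: Iterable[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "scheme": r.scheme,
                "fold_change": r.fold_change,
                "sem": r.sem,
                "p": r.p_value,
                "adj_p": r.adjusted_p,
                "n": r.n,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Labeling-activity diagnostic
# ---------------------------------------------------------------------------

REGIME_COMPARABLE = "comparable"
REGIME_DECREASED = "decreased"
REGIME_INCREASED = "increased"


@dataclass
class LabelingDiagnostic:
    """Outcome of the enzyme-vs-independent fold-change comparison."""

    regime: str
    ratio: float  # enzyme fc / independent fc; estimates alpha_ref / alpha_c
    implied_activity_ratio: float  # alpha_c / alpha_ref under the eluate model


def labeling_activity_diagnostic(
    enzyme_fc: float,
    independent_fc: float,
    equivalence_band: tuple[float, float] = (0.8, 1.25),
) -> LabelingDiagnostic:
    """Classify a condition's labeling-activity regime.

    Under the eluate-composition model, the ENZYME-normalized fold change
    equals ``m_c / m_ref`` while the INDEPENDENT-normalized one carries an
    extra factor ``alpha_c / alpha_ref``; their ratio therefore estimates
    ``alpha_ref / alpha_c``.  Within the equivalence band the labeling
    activity is called ``comparable``; above it, treatment ``decreased``
    labeling activity; below it, treatment ``increased`` it.
    """
    if not (enzyme_fc > 0 and independent_fc > 0):
        raise NormalizationError("diagnostic requires positive fold changes")
    lo, hi = equivalence_band
    if not 0 < lo < hi:
        raise ConfigurationError("equivalence band must satisfy 0 < lo < hi")
    ratio = enzyme_fc / independent_fc
    if ratio > hi:
        regime = REGIME_DECREASED
    elif ratio < lo:
        regime = REGIME_INCREASED
    else:
        regime = REGIME_COMPARABLE
    return LabelingDiagnostic(
        regime=regime, ratio=ratio, implied_activity_ratio=1.0 / ratio
    )


def diagnose_condition(
    results_by_scheme: Mapping[str, Sequence[FoldChangeResult]],
    condition: str,
    equivalence_band: tuple[float, float] = (0.8, 1.25),
) -> LabelingDiagnostic:
    """Run the diagnostic from fold-change results keyed by scheme kind.

    Prefers the ENZYME scheme; falls back to COMPARTMENT when absent.  The
    INDEPENDENT scheme is required.
    """
    labeled_key = "ENZYME" if "ENZYME" in results_by_scheme else "COMPARTMENT"
    if labeled_key not in results_by_scheme or "INDEPENDENT" not in results_by_scheme:
        raise NormalizationError(
            "diagnostic needs ENZYME (or COMPARTMENT) and INDEPENDENT fold changes"
        )

    def _get(key: str) -> float:
        for r in results_by_scheme[key]:
            if r.condition == condition:
                return r.fold_change
        raise NormalizationError(f"condition {condition!r} missing under {key}")

    return labeling_activity_diagnostic(
        _get(labeled_key), _get("INDEPENDENT"), equivalence_band
    )
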