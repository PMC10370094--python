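"""Chromatogram integration, boundary picking, and transition validation.

Quantification in PRM rests on areas under extracted-ion chromatograms.
This module integrates precursor/fragment traces by the trapezoidal rule
(with an optional linear baseline between the boundary points), picks peak
boundaries automatically around an expected retention time, computes the
per-run MS1 TIC area, and validates fragment transitions by the three
classical criteria: co-elution (chromatographic shape), constant fragment
intensity proportion across runs, and consistent apex retention time.  A
peptide is quantifiable when at least three fragments validate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, IntegrationError, ValidationError


@dataclass
class TransitionChromatogram:
    """Retention-time / intensity trace for one ion of one peptide in one run."""

    peptide: str
    ion_label: str
    rt: np.ndarray
    intensity: np.ndarray
    protein: str = ""
    boundaries: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.ndim != 1:
            raise InputError("rt and intensity must be 1-D arrays of equal length")
        if len(self.rt) and not np.all(np.diff(self.rt) > 0):
            raise InputError("rt must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise InputError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise InputError("intensity must be nonnegative")


@dataclass
class PeakArea:
    """Integrated area (intensity x minutes) and apex RT of one trace."""

    peptide: str
    ion_label: str
    area: float
    apex_rt: float
    protein: str = ""
    condition: str | None = None
    replicate: int | None = None
    found: bool = True


def integrate(
    chrom: TransitionChromatogram,
    boundaries: tuple[float, float] | None = None,
    baseline: str = "linear",
) -> PeakArea:
    """Trapezoidal peak area over ``[rt_left, rt_right]``.

    ``baseline="linear"`` subtracts the straight line between the boundary
    intensities (the subtracted signal is floored at 0); ``"none"`` integrates
    the raw trace.  Requires at least 3 samples inside the window.
    """
    if boundaries is None:
        boundaries = chrom.boundaries
    if boundaries is None:
        raise IntegrationError("no boundaries set for integration")
    left, right = boundaries
    if not (chrom.rt.size and chrom.rt[0] <= left < right <= chrom.rt[-1]):
        raise IntegrationError(
            f"boundaries ({left}, {right}) outside trace range"
        )
    mask = (chrom.rt >= left) & (chrom.rt <= right)
    if mask.sum() < 3:
        raise IntegrationError("fewer than 3 samples inside integration window")
    rt = chrom.rt[mask]
    sig = chrom.intensity[mask]
    if baseline == "linear":
        base = np.interp(rt, [rt[0], rt[-1]], [sig[0], sig[-1]])
        sig = np.maximum(sig - base, 0.0)
    elif baseline != "none":
        raise InputError(f"unknown baseline mode {baseline!r}")
    area = float(np.trapezoid(sig, rt))
    apex_rt = float(rt[int(np.argmax(chrom.intensity[mask]))])
    return PeakArea(
        peptide=chrom.peptide,
        ion_label=chrom.ion_label,
        area=area,
        apex_rt=apex_rt,
        protein=chrom.protein,
    )


def auto_boundaries(
    chrom: TransitionChromatogram,
    expected_rt: float,
    descent_fraction: float = 0.01,
    max_half_width: float = 1.5,
) -> tuple[float, float] | None:
    """Deterministic peak boundaries around ``expected_rt``.

    Starting from the local intensity maximum nearest ``expected_rt``, the
    boundaries extend outward until the intensity falls below
    ``descent_fraction`` of the apex or a ``max_half_width``-minute cap is
    reached.  Returns ``None`` ("not found") when the trace has no nonzero
    signal.
    """
    if not (chrom.rt.size and chrom.rt[0] <= expected_rt <= chrom.rt[-1]):
        raise IntegrationError(f"expected_rt {expected_rt} outside trace range")
    y = chrom.intensity
    if not np.any(y > 0):
        return None
    interior = np.zeros(len(y), dtype=bool)
    if len(y) >= 3:
        interior[1:-1] = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 0)
    interior[0] = y[0] > 0 and (len(y) == 1 or y[0] >= y[1])
    interior[-1] = y[-1] > 0 and (len(y) == 1 or y[-1] >= y[-2])
    maxima = np.flatnonzero(interior)
    apex = int(maxima[np.argmin(np.abs(chrom.rt[maxima] - expected_rt))])
    cutoff = descent_fraction * y[apex]
    left = apex
    while (
        left > 0
        and y[left - 1] >= cutoff
        and chrom.rt[apex] - chrom.rt[left - 1] <= max_half_width
    ):
        left -= 1
    right = apex
    while (
        right < len(y) - 1
        and y[right + 1] >= cutoff
        and chrom.rt[right + 1] - chrom.rt[apex] <= max_half_width
    ):
        right += 1
    return (float(chrom.rt[left]), float(chrom.rt[right]))


def quantify_trace(
    chrom: TransitionChromatogram,
    expected_rt: float,
    baseline: str = "linear",
) -> PeakArea:
    """Auto-pick boundaries and integrate; area 0 when no peak is found."""
    bounds = auto_boundaries(chrom, expected_rt)
    if bounds is None:
        return PeakArea(
            peptide=chrom.peptide,
            ion_label=chrom.ion_label,
            area=0.0,
            apex_rt=float("nan"),
            protein=chrom.protein,
            found=False,
        )
    return integrate(chrom, bounds, baseline=baseline)


# ---------------------------------------------------------------------------
# Transition validation
# ---------------------------------------------------------------------------


@dataclass
class FragmentVerdict:
    """Validation outcome of one fragment across runs."""

    ion_label: str
    validated: bool
    min_shape_correlation: float
    max_ratio_deviation: float
    max_rt_deviation: float
    reasons: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    peptide: str
    fragments: list[FragmentVerdict]
    quantifiable: bool
    consensus_apex_rt: float

    @property
    def validated_labels(self) -> list[str]:
        return [f.ion_label for f in self.fragments if f.validated]


def validate_transitions(
    runs: Mapping[object, Mapping[str, TransitionChromatogram]],
    expected_rt: float | None = None,
    shape_threshold: float = 0.90,
    ratio_tolerance: float = 0.30,
    rt_tolerance: float = 0.2,
    min_fragments: int = 3,
) -> ValidationReport:
    """Validate a peptide's fragment transitions across multiple runs.

    ``runs`` maps run identifiers to ``{fragment label: trace}`` for one
    peptide.  A fragment is validated iff, in every run, (a) the Pearson
    correlation of its trace with the summed-fragment trace inside the peak
    boundaries is at least ``shape_threshold``; (b) its intensity proportion
    is constant across runs — after rescaling each run by its median
    fragment ratio to the across-run consensus, the fragment's relative
    deviation from consensus stays within ``ratio_tolerance``; and (c) its
    apex RT is within ``rt_tolerance`` minutes of the peptide consensus
    apex.  The peptide is quantifiable iff at least ``min_fragments``
    fragments validate.  The verdict is invariant to run and fragment order.
    """
    if not runs:
        raise ValidationError("no runs supplied")
    run_keys = sorted(runs.keys(), key=repr)
    labels = sorted(runs[run_keys[0]].keys())
    if len(labels) < min_fragments:
        raise ValidationError(
            f"{len(labels)} fragment traces supplied; need at least {min_fragments}"
        )
    for key in run_keys:
        if sorted(runs[key].keys()) != labels:
            raise ValidationError(f"run {key!r} has a different fragment set")

    peptide = runs[run_keys[0]][labels[0]].peptide
    areas = np.zeros((len(labels), len(run_keys)))
    corrs = np.ones((len(labels), len(run_keys)))
    apexes = np.full((len(labels), len(run_keys)), np.nan)
    for j, key in enumerate(run_keys):
        traces = [runs[key][lab] for lab in labels]
        grid = traces[0].rt
        for tr in traces[1:]:
            if tr.rt.shape != grid.shape or not np.allclose(tr.rt, grid):
                raise ValidationError(
                    f"fragment traces in run {key!r} are on different RT grids"
                )
        summed = np.sum([tr.intensity for tr in traces], axis=0)
        total = TransitionChromatogram(peptide, "sum", grid, summed)
        center = expected_rt if expected_rt is not None else grid[int(np.argmax(summed))]
        bounds = auto_boundaries(total, center)
        if bounds is None:
            continue  # empty run: contributes nothing
        mask = (grid >= bounds[0]) & (grid <= bounds[1])
        for i, tr in enumerate(traces):
            pa = integrate(tr, bounds, baseline="none")
            areas[i, j] = pa.area
            apexes[i, j] = pa.apex_rt
            seg = tr.intensity[mask]
            if np.std(seg) == 0 or np.std(summed[mask]) == 0:
                corrs[i, j] = 0.0
            else:
                corrs[i, j] = float(np.corrcoef(seg, summed[mask])[0, 1])

    consensus_area = np.median(areas, axis=1)  # per fragment
    if np.any(consensus_area <= 0):
        consensus_area = np.where(consensus_area <= 0, np.nan, consensus_area)
    # robust per-run scale: median fragment ratio to consensus
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = areas / consensus_area[:, None]
        run_scale = np.nanmedian(ratio, axis=0)
        deviation = np.abs(ratio / run_scale[None, :] - 1.0)
    consensus_apex = float(np.nanmedian(apexes))
    rt_dev = np.abs(apexes - consensus_apex)

    verdicts: list[FragmentVerdict] = []
    for i, lab in enumerate(labels):
        reasons = []
        min_corr = float(np.min(corrs[i]))
        max_dev = float(np.nanmax(deviation[i])) if np.any(np.isfinite(deviation[i])) else math.inf
        max_rt = float(np.nanmax(rt_dev[i])) if np.any(np.isfinite(rt_dev[i])) else math.inf
        if min_corr < shape_threshold:
            reasons.append("shape")
        if max_dev > ratio_tolerance:
            reasons.append("ratio")
        if max_rt > rt_tolerance:
            reasons.append("rt")
        verdicts.append(
            FragmentVerdict(
                ion_label=lab,
                validated=not reasons,
                min_shape_correlation=min_corr,
                max_ratio_deviation=max_dev,
                max_rt_deviation=max_rt,
                reasons=reasons,
            )
        )
    quantifiable = sum(v.validated for v in verdicts) >= min_fragments
    return ValidationReport(
        peptide=peptide,
        fragments=verdicts,
        quantifiable=quantifiable,
        consensus_apex_rt=consensus_apex,
    )


# ---------------------------------------------------------------------------
# Run-level TIC and trace I/O
# ---------------------------------------------------------------------------


def compute_tic(traces: Iterable[TransitionChromatogram]) -> float:
    """Area under the run's MS1 TIC chromatogram.

    If a trace labeled ``"TIC"`` is present, its full-range trapezoidal area
    is returned; otherwise the precursor traces' areas are summed (component
    sum).  Empty input yields 0.
    """
    traces = list(traces)
    for tr in traces:
        if tr.ion_label == "TIC":
            return float(np.trapezoid(tr.intensity, tr.rt))
    total = 0.0
    for tr in traces:
        if tr.ion_label == "precursor":
            total += float(np.trapezoid(tr.intensity, tr.rt))
    return total


def traces_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], dict[str, TransitionChromatogram]]:
    """Parse the tabular trace format into nested chromatogram dicts.

    Expects columns ``protein, peptide, ion_label, rt, intensity``; returns
    ``{(protein, peptide): {ion_label: trace}}``.
    """
    required = {"protein", "peptide", "ion_label", "rt", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"trace table missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], dict[str, TransitionChromatogram]] = {}
    for (protein, peptide, label), grp in df.groupby(
        ["protein", "peptide", "ion_label"], sort=False
    ):
        grp = grp.sort_values("rt")
        out.setdefault((protein, peptide), {})[label] = TransitionChromatogram(
            peptide=peptide,
            ion_label=label,
            rt=grp["rt"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            protein=protein,
        )
    return out


def read_traces(path: str | Path) -> dict[tuple[str, str], dict[str, TransitionChromatogram]]:
    """Read one run's traces from the tabular CSV format."""
    return traces_from_frame(pd.read_csv(path))


def read_mzml_chromatograms(path: str | Path) -> list[TransitionChromatogram]:
    """Read chromatogram-list entries from an mzML file.

    Each chromatogram's id string becomes the ``ion_label`` (the TIC
    chromatogram is labeled ``"TIC"``).  Time is assumed to be in minutes.
    """
    from pyteomics import mzml  # deferred: lxml-backed parser

    out: list[TransitionChromatogram] = []
    with mzml.read(str(path)) as reader:
        for chrom in reader:
            label = chrom.get("id", "")
            out.append(
                TransitionChromatogram(
                    peptide="",
                    ion_label="TIC" if label == "TIC" else label,
                    rt=np.asarray(chrom["time array"], dtype=float),
                    intensity=np.asarray(chrom["intensity array"], dtype=float),
                )
            )
    return out
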