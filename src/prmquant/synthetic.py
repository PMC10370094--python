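"""Synthetic proximity-labeling / PRM experiments.

The generator embodies a compositional model of what an avidin eluate from a
cytosolic-peroxidase proximity-labeling experiment contains, at the level of
noise-free expected peak areas:

* **BP-labeled cytosolic proteins** (the peroxidase itself, actin, GAPDH, ...)
  scale with the per-condition labeling activity ``alpha_c`` — the relative
  biotin-phenol labeling yield of the peroxidase under drug treatment ``c``.
* **The secretory analyte** (e.g. FLAG-tagged transthyretin) is only labeled
  when mistargeted to the cytosol, so its signal additionally scales with the
  mistargeted fraction ``m_c`` in [0, 1].
* **Labeling-independent proteins** (endogenously biotinylated mitochondrial
  carboxylases such as pyruvate carboxylase) are captured by avidin regardless
  of peroxidase activity and track only the protein input.
* **Background contaminants** (avidin leached from beads, keratins, trypsin)
  enter the eluate without capture, at a constant level.

The per-run total ion current (TIC) is the sum of all component areas plus a
configurable non-peptide contaminant background.  Multiplicative log-normal
noise is applied per peptide per run.  Everything is deterministic given the
configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

ROLE_LABELED = "labeled_cytosolic"
ROLE_INDEPENDENT = "labeling_independent"
ROLE_ANALYTE = "secretory_analyte"
ROLE_CONTAMINANT = "background_contaminant"
ROLES = (ROLE_LABELED, ROLE_INDEPENDENT, ROLE_ANALYTE, ROLE_CONTAMINANT)


@dataclass
class ScenarioConfig:
    """Definition of one synthetic proximity-labeling PRM experiment.

    Parameters
    ----------
    conditions : list of str
        Treatment labels, e.g. ``["MG132+Veh", "Tg"]``.
    reference_condition : str
        The condition fold changes are computed against.
    labeling_activity : mapping condition -> float
        ``alpha_c`` > 0, relative peroxidase labeling yield per condition.
    mistargeted_fraction : mapping condition -> float
        ``m_c`` in [0, 1], cytosolic fraction of the secretory analyte.
    protein_abundances : mapping protein -> float
        ``a_p`` > 0, relative input abundance (input load is mass-balanced
        across conditions, so ``a_p`` does not vary by condition).
    protein_roles : mapping protein -> str
        One of :data:`ROLES`.  Exactly one ``secretory_analyte``; at least one
        ``labeling_independent`` and one ``labeled_cytosolic`` protein.
    capture_efficiency : mapping protein -> float
        ``eps_p`` in (0, 1]; avidin capture yield. Missing proteins default
        to 1.0. Not applied to ``background_contaminant`` proteins.
    peptides : mapping protein -> tuple of str
        Monitored peptides per protein; a protein's expected area is split
        equally across its peptides.  Defaults to one peptide named
        ``"<protein>_pep1"``.
    n_replicates : int
        Replicate experiments per condition.
    noise_sigma : float
        Standard deviation of the log-normal multiplicative noise (natural
        log scale).  Replicate CVs are ``sqrt(exp(sigma^2) - 1)``.
    contaminant_background : float or None
        Constant non-peptide signal added to every run's TIC. ``None`` means
        ``background_fraction`` of the reference condition's TIC.
    background_fraction : float
        Fraction of the reference TIC the default background represents.
    seed : int
        Seed for the random generator.
    """

    conditions: list[str]
    reference_condition: str
    labeling_activity: dict[str, float]
    mistargeted_fraction: dict[str, float]
    protein_abundances: dict[str, float]
    protein_roles: dict[str, str]
    capture_efficiency: dict[str, float] = field(default_factory=dict)
    peptides: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_replicates: int = 6
    noise_sigma: float = 0.1
    contaminant_background: float | None = None
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")
        if self.reference_condition not in self.conditions:
            raise ConfigurationError(
                f"reference_condition {self.reference_condition!r} not in conditions"
            )
        for c in self.conditions:
            if c not in self.labeling_activity:
                raise ConfigurationError(f"labeling_activity missing condition {c!r}")
            if c not in self.mistargeted_fraction:
                raise ConfigurationError(f"mistargeted_fraction missing condition {c!r}")
            if not self.labeling_activity[c] > 0:
                raise ConfigurationError(f"labeling_activity[{c!r}] must be > 0")
            if not 0.0 <= self.mistargeted_fraction[c] <= 1.0:
                raise ConfigurationError(f"mistargeted_fraction[{c!r}] must be in [0, 1]")
        for p, a in self.protein_abundances.items():
            if not a > 0:
                raise ConfigurationError(f"abundance of {p!r} must be > 0")
        for p, role in self.protein_roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown role {role!r} for protein {p!r}")
            if p not in self.protein_abundances:
                raise ConfigurationError(f"protein {p!r} has a role but no abundance")
        for p in self.protein_abundances:
            if p not in self.protein_roles:
                raise ConfigurationError(f"protein {p!r} has an abundance but no role")
        roles = list(self.protein_roles.values())
        if roles.count(ROLE_ANALYTE) != 1:
            raise ConfigurationError("exactly one protein must be the secretory_analyte")
        if ROLE_INDEPENDENT not in roles:
            raise ConfigurationError("at least one labeling_independent protein required")
        if ROLE_LABELED not in roles:
            raise ConfigurationError("at least one labeled_cytosolic protein required")
        for p, eps in self.capture_efficiency.items():
            if not 0.0 < eps <= 1.0:
                raise ConfigurationError(f"capture_efficiency[{p!r}] must be in (0, 1]")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ConfigurationError("background_fraction must be in [0, 1)")
        # default peptide names; proteins keep config order throughout
        peptides = dict(self.peptides)
        for p in self.protein_abundances:
            if p not in peptides or not peptides[p]:
                peptides[p] = (f"{p}_pep1",)
            else:
                peptides[p] = tuple(peptides[p])
        self.peptides = peptides

    @property
    def analyte(self) -> str:
        """Name of the secretory-analyte protein."""
        return next(p for p, r in self.protein_roles.items() if r == ROLE_ANALYTE)

    def background(self) -> float:
        """Resolved constant contaminant background added to each run's TIC."""
        if self.contaminant_background is not None:
            return float(self.contaminant_background)
        ref_sum = sum(
            expected_area(p, self.reference_condition, self)
            for p in self.protein_abundances
        )
        f = self.background_fraction
        return f / (1.0 - f) * ref_sum

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["peptides"] = {k: list(v) for k, v in d["peptides"].items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        d = json.loads(Path(path).read_text())
        d["peptides"] = {k: tuple(v) for k, v in d.get("peptides", {}).items()}
        return cls(**d)


@dataclass
class SyntheticRun:
    """One simulated LC-MS run: a condition x replicate eluate injection."""

    condition: str
    replicate: int
    peptide_areas: dict[tuple[str, str], float]
    tic: float
    true_params: dict[str, float]


def expected_area(protein: str, condition: str, cfg: ScenarioConfig) -> float:
    """Noise-free expected eluate signal of ``protein`` under ``condition``.

    Role formulas (``a`` abundance, ``eps`` capture efficiency, ``alpha``
    labeling activity, ``m`` mistargeted fraction):

    ========================  =======================
    labeled_cytosolic         ``alpha_c * a * eps``
    secretory_analyte         ``alpha_c * m_c * a * eps``
    labeling_independent      ``a * eps``
    background_contaminant    ``a`` (constant)
    ========================  =======================
    """
    try:
        role = cfg.protein_roles[protein]
        a = cfg.protein_abundances[protein]
    except KeyError as exc:
        raise ConfigurationError(f"unknown protein {protein!r}") from exc
    if condition not in cfg.labeling_activity:
        raise ConfigurationError(f"unknown condition {condition!r}")
    eps = cfg.capture_efficiency.get(protein, 1.0)
    alpha = cfg.labeling_activity[condition]
    if role == ROLE_LABELED:
        return alpha * a * eps
    if role == ROLE_ANALYTE:
        return alpha * cfg.mistargeted_fraction[condition] * a * eps
    if role == ROLE_INDEPENDENT:
        return a * eps
    return float(a)  # background_contaminant


def simulate_experiment(
    cfg: ScenarioConfig, seed: int | None = None
) -> list[SyntheticRun]:
    """Simulate ``n_replicates`` runs per condition.

    Each peptide area is ``expected_area / n_peptides`` times a log-normal
    factor ``exp(N(0, sigma^2))``; the run TIC is the sum of its peptide areas
    plus the constant contaminant background.  Output is deterministic given
    the seed (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    background = cfg.background()
    runs: list[SyntheticRun] = []
    for condition in cfg.conditions:
        for replicate in range(1, cfg.n_replicates + 1):
            areas: dict[tuple[str, str], float] = {}
            for protein in cfg.protein_abundances:
                peps = cfg.peptides[protein]
                base = expected_area(protein, condition, cfg) / len(peps)
                for pep in peps:
                    noise = math.exp(rng.normal(0.0, cfg.noise_sigma))
                    areas[(protein, pep)] = base * noise
            tic = sum(areas.values()) + background
            if not math.isfinite(tic):
                raise GenerationError(
                    f"non-finite signal in run ({condition}, {replicate})"
                )
            runs.append(
                SyntheticRun(
                    condition=condition,
                    replicate=replicate,
                    peptide_areas=areas,
                    tic=tic,
                    true_params={
                        "labeling_activity": cfg.labeling_activity[condition],
                        "mistargeted_fraction": cfg.mistargeted_fraction[condition],
                    },
                )
            )
    return runs


def runs_to_frame(runs: Iterable[SyntheticRun]) -> pd.DataFrame:
    """Long-format quantification table: protein, peptide, condition, replicate, area, tic."""
    rows = [
        {
            "protein": protein,
            "peptide": pep,
            "condition": run.condition,
            "replicate": run.replicate,
            "area": area,
            "tic": run.tic,
        }
        for run in runs
        for (protein, pep), area in run.peptide_areas.items()
    ]
    return pd.DataFrame(rows)


def write_quant_table(runs: Iterable[SyntheticRun], path: str | Path) -> None:
    runs_to_frame(runs).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Default scenario packs
# ---------------------------------------------------------------------------

_PACK_ALPHA = {"comparable": 1.0, "decreased": 0.5, "increased": 2.0}
_PACK_STRESS = {"comparable": "Tg", "decreased": "DTT", "increased": "ML"}


def scenario_pack(
    regime: str = "comparable",
    *,
    n_replicates: int = 6,
    noise_sigma: float = 0.1,
    seed: int = 0,
    m_reference: float = 0.02,
    m_fold: float = 2.5,
) -> ScenarioConfig:
    """Default scenario for one labeling-activity regime.

    Two conditions: an ``MG132+Veh`` reference (``alpha = 1``, mistargeted
    fraction ``m_reference``) and a stress condition whose mistargeted
    fraction is ``m_fold`` times higher and whose labeling activity is equal
    (``comparable``), halved (``decreased``, DTT/BFA-like) or doubled
    (``increased``, mycolactone-like).  The protein panel mirrors a typical
    assay: the analyte (FLAG-TTR), auto-labeled peroxidase (APEX2) and
    cytosolic loading controls as labeled proteins, pyruvate carboxylase as
    the labeling-independent factor, and leached avidin as contaminant.
    """
    if regime not in _PACK_ALPHA:
        raise ConfigurationError(
            f"unknown regime {regime!r}; expected one of {sorted(_PACK_ALPHA)}"
        )
    reference = "MG132+Veh"
    stress = _PACK_STRESS[regime]
    return ScenarioConfig(
        conditions=[reference, stress],
        reference_condition=reference,
        labeling_activity={reference: 1.0, stress: _PACK_ALPHA[regime]},
        mistargeted_fraction={reference: m_reference, stress: m_fold * m_reference},
        protein_abundances={
            "FLAG-TTR": 10.0,
            "APEX2": 30.0,
            "ACTB": 20.0,
            "GAPDH": 10.0,
            "PC": 15.0,
            "Avidin": 8.0,
        },
        protein_roles={
            "FLAG-TTR": ROLE_ANALYTE,
            "APEX2": ROLE_LABELED,
            "ACTB": ROLE_LABELED,
            "GAPDH": ROLE_LABELED,
            "PC": ROLE_INDEPENDENT,
            "Avidin": ROLE_CONTAMINANT,
        },
        peptides={
            "FLAG-TTR": ("AADDTWEPFASGK",),
            "APEX2": ("LAFHSAGTFDK", "EGLLQLPSDK"),
            "ACTB": ("VAPEEHPVLLTEAPLNPK",),
            "GAPDH": ("GALQNIIPASTGAAK",),
            "PC": ("ENNVDAVHPGYGFLSER", "VVEIAPAAHLDPQLR"),
            "Avidin": ("SSVNDIGDDWK",),
        },
        n_replicates=n_replicates,
        noise_sigma=noise_sigma,
        seed=seed,
    )


#: protein -> normalization role for the default packs (see :mod:`prmquant.normalize`)
PACK_NORMALIZATION_ROLES = {
    "FLAG-TTR": "analyte",
    "APEX2": "apex_factor",
    "ACTB": "compartment_factor",
    "GAPDH": "compartment_factor",
    "PC": "independent_factor",
    "Avidin": "contaminant",
}


# ---------------------------------------------------------------------------
# Chromatogram emission
# ---------------------------------------------------------------------------


@dataclass
class InterferenceSpec:
    """Inject a co-eluting contaminant into one fragment trace.

    The interferent is a Gaussian of area ``scale`` times the fragment's own
    area, apexing at the fragment RT plus ``rt_offset`` minutes, added in the
    listed ``runs`` (``None`` = every run).
    """

    peptide: tuple[str, str]
    fragment_index: int = 0
    runs: list[tuple[str, int]] | None = None
    scale: float = 3.0
    rt_offset: float = 0.0


@dataclass
class PeakModel:
    """Chromatographic shape parameters for emitted traces.

    ``retention_times`` maps (protein, peptide) to an apex RT in minutes.
    All peaks are Gaussian with standard deviation ``width`` minutes; each
    peptide's MS2 signal is split over ``len(fragment_fractions)`` fragment
    traces (labels ``f1, f2, ...``) in the given proportions, alongside a
    precursor trace carrying the full area.
    """

    retention_times: dict[tuple[str, str], float]
    width: float = 0.1
    fragment_fractions: tuple[float, ...] = (0.4, 0.35, 0.25)
    grid_step: float | None = None
    span_sigmas: float = 6.0
    interference: InterferenceSpec | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("peak width must be > 0")
        if len(self.fragment_fractions) < 3:
            raise ConfigurationError("at least 3 fragment-ion proportions required")
        total = sum(self.fragment_fractions)
        if not total > 0:
            raise ConfigurationError("fragment fractions must be positive")
        self.fragment_fractions = tuple(f / total for f in self.fragment_fractions)
        step = self.grid_step if self.grid_step is not None else self.width / 10.0
        if step >= self.width:
            raise GenerationError(
                "RT grid step must be finer than the peak width to represent areas"
            )
        self.grid_step = step


def default_peak_model(cfg: ScenarioConfig, start_rt: float = 15.0, spacing: float = 4.0,
                       **kwargs) -> PeakModel:
    """Assign evenly spaced retention times to every peptide in ``cfg``."""
    rts: dict[tuple[str, str], float] = {}
    i = 0
    for protein in cfg.protein_abundances:
        for pep in cfg.peptides[protein]:
            rts[(protein, pep)] = start_rt + spacing * i
            i += 1
    return PeakModel(retention_times=rts, **kwargs)


def _gaussian(rt: np.ndarray, area: float, mu: float, sigma: float) -> np.ndarray:
    amp = area / (sigma * math.sqrt(2.0 * math.pi))
    return amp * np.exp(-0.5 * ((rt - mu) / sigma) ** 2)


def emit_chromatograms(
    runs: Sequence[SyntheticRun],
    peak_model: PeakModel,
    out_dir: str | Path | None = None,
    background: float = 0.0,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Render each run's peak areas as Gaussian chromatogram traces.

    Per run, every peptide gets a precursor trace of its full area plus
    fragment traces ``f1..fk`` scaled by the model's fragment proportions,
    all sharing the peptide's apex RT; trapezoidal re-integration recovers
    the areas to well within 0.5%.  A run-level ``TIC`` trace (sum of
    precursor Gaussians plus a flat ``background``) is included on a global
    grid.  Returns ``{(condition, replicate): DataFrame}`` with columns
    ``protein, peptide, ion_label, rt, intensity``; also writes one CSV per
    run when ``out_dir`` is given.  An empty run list yields no files.
    """
    out: dict[tuple[str, int], pd.DataFrame] = {}
    if not runs:
        return out
    sigma = peak_model.width
    step = float(peak_model.grid_step)
    span = peak_model.span_sigmas * sigma
    for run in runs:
        missing = [k for k in run.peptide_areas if k not in peak_model.retention_times]
        if missing:
            raise ConfigurationError(f"peak model lacks retention times for {missing}")
        frames: list[pd.DataFrame] = []
        rts = [peak_model.retention_times[k] for k in run.peptide_areas]
        global_grid = np.arange(min(rts) - span, max(rts) + span + step / 2, step)
        tic_trace = np.full_like(
            global_grid, background / (global_grid[-1] - global_grid[0])
        )
        for (protein, pep), area in run.peptide_areas.items():
            mu = peak_model.retention_times[(protein, pep)]
            grid = np.arange(mu - span, mu + span + step / 2, step)
            traces = {"precursor": _gaussian(grid, area, mu, sigma)}
            for i, frac in enumerate(peak_model.fragment_fractions):
                traces[f"f{i + 1}"] = _gaussian(grid, area * frac, mu, sigma)
            spec = peak_model.interference
            if (
                spec is not None
                and spec.peptide == (protein, pep)
                and (spec.runs is None or (run.condition, run.replicate) in spec.runs)
            ):
                label = f"f{spec.fragment_index + 1}"
                if label not in traces:
                    raise ConfigurationError(
                        f"interference fragment_index {spec.fragment_index} out of range"
                    )
                frag_area = area * peak_model.fragment_fractions[spec.fragment_index]
                traces[label] = traces[label] + _gaussian(
                    grid, spec.scale * frag_area, mu + spec.rt_offset, sigma
                )
            tic_trace += _gaussian(global_grid, area, mu, sigma)
            for label, intensity in traces.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "protein": protein,
                            "peptide": pep,
                            "ion_label": label,
                            "rt": grid,
                            "intensity": intensity,
                        }
                    )
                )
        frames.append(
            pd.DataFrame(
                {
                    "protein": "__run__",
                    "peptide": "__run__",
                    "ion_label": "TIC",
                    "rt": global_grid,
                    "intensity": tic_trace,
                }
            )
        )
        df = pd.concat(frames, ignore_index=True)
        out[(run.condition, run.replicate)] = df
        if out_dir is not None:
            out_path = Path(out_dir)
            out_path.mkdir(parents=True, exist_ok=True)
            safe = run.condition.replace("/", "_").replace(" ", "_")
            df.to_csv(out_path / f"{safe}_rep{run.replicate}.csv", index=False)
    return out
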