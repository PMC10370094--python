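"""Target-peptide selection for a scheduled PRM assay.

Implements the standard workflow for building a targeted-proteomics panel:
in silico tryptic digestion (cleavage C-terminal to K/R, not before P),
candidate filtering on length / labile modification sites / ragged tryptic
ends / peroxidase-labeling sensitivity, proteome-wide uniqueness with
optional class-level grouping (so that e.g. a peptide shared by beta- and
gamma-actin still counts as unique to "actin"), and enumeration of singly
charged b/y fragment transitions with scheduling windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, InputError, SelectionError

# Monoisotopic residue masses (Da) for the 20 standard amino acids.
AA_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
#: static carbamidomethylation of cysteine (iodoacetamide alkylation)
CARBAMIDOMETHYL = 57.02146
PROTON = 1.00727646688
WATER = 18.0105646863

FLAG_TOO_SHORT = "too_short"
FLAG_TOO_LONG = "too_long"
FLAG_LABILE = "labile_modification"
FLAG_RAGGED = "ragged_end"
FLAG_LABELING = "labeling_sensitive"
FLAG_NON_UNIQUE = "non_unique"
FLAG_DEAMIDATION = "deamidation_prone"

#: flags that report a concern but do not by themselves disqualify a peptide
SOFT_FLAGS = frozenset({FLAG_RAGGED, FLAG_DEAMIDATION})


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion parameters (cleave after K/R unless followed by P)."""

    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ConfigurationError("missed_cleavages must be >= 0")


@dataclass
class TargetPeptide:
    """A candidate or validated peptide for the PRM panel.

    ``start``/``end`` are 1-based inclusive coordinates in the parent protein.
    ``prev_context`` holds up to two residues immediately preceding the
    peptide, ``next_context`` the residue following it (empty at termini);
    both are needed to evaluate ragged tryptic ends.
    """

    sequence: str
    parent_protein: str = ""
    start: int = 1
    end: int = 0
    charge: int = 2
    role: str = "analyte"
    flags: set[str] = field(default_factory=set)
    prev_context: str | None = None
    next_context: str | None = None

    def __post_init__(self) -> None:
        if self.end == 0:
            self.end = self.start + len(self.sequence) - 1

    @property
    def passing(self) -> bool:
        """True when no hard flag is set (soft flags are advisory)."""
        return not (self.flags - SOFT_FLAGS)


@dataclass
class FilterConfig:
    """Candidate-filter settings.

    Defaults follow common PRM practice: 8-25 residues; methionine treated as
    a labile (sub-stoichiometrically oxidized) residue; NG/QG motifs flagged
    as deamidation-prone; tryptophan not flagged. ``bp_labeled_parents``
    names proteins that are biotin-phenol labeled, whose tyrosine-containing
    peptides are flagged as sensitive to peroxidase labeling (+BP adds
    361.14601 Da on Y).
    """

    min_length: int = 8
    max_length: int = 25
    labile_residues: frozenset[str] = frozenset({"M"})
    deamidation_motifs: tuple[str, ...] = ("NG", "QG")
    bp_labeled_parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ConfigurationError("min_length must be <= max_length")


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that cleavage occurs between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    parent_protein: str = "",
    params: DigestParams = DigestParams(),
    charge: int = 2,
) -> list[TargetPeptide]:
    """Tryptic in silico digestion: cleave C-terminal to K/R, not before P.

    At 0 missed cleavages the returned peptides tile the sequence exactly.
    With ``missed_cleavages = k``, joins of up to ``k + 1`` adjacent fully
    tryptic fragments are also returned. No length filtering is applied here;
    that is :func:`apply_filters`'s job.
    """
    seq = protein_sequence.strip().upper()
    bad = set(seq) - set(AA_MONO)
    if bad:
        raise InputError(f"non-standard amino acid letters in sequence: {sorted(bad)}")
    if not seq:
        return []
    bounds = [0] + [i + 1 for i in _cleavage_sites(seq)] + [len(seq)]
    peptides: list[TargetPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + params.missed_cleavages, n_frag + 1)):
            s, e = bounds[i], bounds[j]
            peptides.append(
                TargetPeptide(
                    sequence=seq[s:e],
                    parent_protein=parent_protein,
                    start=s + 1,
                    end=e,
                    charge=charge,
                    prev_context=seq[max(0, s - 2):s],
                    next_context=seq[e:e + 1],
                )
            )
    return peptides


def apply_filters(
    peptides: Iterable[TargetPeptide],
    config: FilterConfig = FilterConfig(),
) -> list[TargetPeptide]:
    """Populate content flags on candidate peptides.

    Flags set: length outside ``[min_length, max_length]``; presence of a
    labile-modification residue; NG/QG deamidation motifs; ragged tryptic
    ends (the two residues preceding the peptide both K/R, or the last
    residue and the one following both K/R); tyrosine in a peptide whose
    parent is biotin-phenol labeled.  Idempotent: content flags are
    recomputed from scratch; a previously set ``non_unique`` flag (owned by
    :func:`check_uniqueness`) is preserved.
    """
    out: list[TargetPeptide] = []
    for pep in peptides:
        if pep.prev_context is None or pep.next_context is None:
            raise InputError(
                f"peptide {pep.sequence!r} lacks parent context; digest() provides it"
            )
        flags: set[str] = {FLAG_NON_UNIQUE} & pep.flags
        n = len(pep.sequence)
        if n < config.min_length:
            flags.add(FLAG_TOO_SHORT)
        if n > config.max_length:
            flags.add(FLAG_TOO_LONG)
        if set(pep.sequence) & config.labile_residues:
            flags.add(FLAG_LABILE)
        if any(m in pep.sequence for m in config.deamidation_motifs):
            flags.add(FLAG_DEAMIDATION)
        prev2 = pep.prev_context
        if len(prev2) == 2 and prev2[0] in "KR" and prev2[1] in "KR":
            flags.add(FLAG_RAGGED)
        if pep.next_context and pep.sequence[-1] in "KR" and pep.next_context in "KR":
            flags.add(FLAG_RAGGED)
        if "Y" in pep.sequence and pep.parent_protein in config.bp_labeled_parents:
            flags.add(FLAG_LABELING)
        out.append(replace(pep, flags=flags))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {identifier: sequence}; ids taken up to whitespace."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def check_uniqueness(
    peptide: TargetPeptide,
    proteome: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> str:
    """Classify a peptide as ``"unique"`` or ``"non_unique"`` in a proteome.

    A peptide is unique iff every proteome entry containing its sequence as
    an exact substring belongs to the same class as its parent.  ``groups``
    maps proteins to class labels (e.g. ACTB and ACTG1 both to ``"actin"``);
    ungrouped proteins form singleton classes.
    """
    if not proteome:
        raise ConfigurationError("uniqueness check requires a non-empty proteome")
    groups = groups or {}
    parent_class = groups.get(peptide.parent_protein, peptide.parent_protein)
    for name, seq in proteome.items():
        if peptide.sequence in seq and groups.get(name, name) != parent_class:
            return "non_unique"
    return "unique"


def annotate_uniqueness(
    peptides: Iterable[TargetPeptide],
    proteome: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> list[TargetPeptide]:
    """Set/clear the ``non_unique`` flag on each peptide."""
    out = []
    for pep in peptides:
        flags = set(pep.flags) - {FLAG_NON_UNIQUE}
        if check_uniqueness(pep, proteome, groups) == "non_unique":
            flags.add(FLAG_NON_UNIQUE)
        out.append(replace(pep, flags=flags))
    return out


# ---------------------------------------------------------------------------
# Transition enumeration
# ---------------------------------------------------------------------------


def _residue_mass(aa: str) -> float:
    m = AA_MONO[aa]
    return m + CARBAMIDOMETHYL if aa == "C" else m


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral peptide mass with static carbamidomethyl-C."""
    try:
        return sum(_residue_mass(aa) for aa in sequence) + WATER
    except KeyError as exc:
        raise InputError(f"non-standard residue {exc.args[0]!r}") from exc


def precursor_mz(sequence: str, charge: int) -> float:
    if charge < 1:
        raise InputError("charge must be >= 1")
    return (peptide_mass(sequence) + charge * PROTON) / charge


def fragment_mz(sequence: str, ion: str, index: int, charge: int = 1) -> float:
    """m/z of a b- or y-ion (``ion`` in {"b", "y"}), 1-based ``index``."""
    if not 1 <= index <= len(sequence) - 1:
        raise InputError(f"{ion}{index} out of range for a {len(sequence)}-mer")
    if ion == "b":
        masses = sum(_residue_mass(aa) for aa in sequence[:index])
    elif ion == "y":
        masses = sum(_residue_mass(aa) for aa in sequence[-index:]) + WATER
    else:
        raise InputError(f"unknown ion series {ion!r}")
    return (masses + charge * PROTON) / charge


@dataclass
class TransitionSet:
    """Precursor and fragment transitions for one targeted peptide."""

    peptide: TargetPeptide
    precursor_mz: float
    fragments: list[tuple[str, int, float]]  # (label, charge, m/z)
    rt_window: tuple[float, float] | None = None


def enumerate_transitions(
    peptide: TargetPeptide,
    min_fragments: int = 3,
    mz_range: tuple[float, float] = (110.0, 2000.0),
    expected_rt: float | None = None,
    rt_window_length: float = 10.0,
) -> TransitionSet:
    """Enumerate singly charged b/y fragments within the instrument m/z range.

    Raises :class:`SelectionError` when fewer than ``min_fragments`` survive
    the range filter.  When ``expected_rt`` is given, a scheduling window of
    ``rt_window_length`` minutes is centred on it.
    """
    seq = peptide.sequence
    fragments: list[tuple[str, int, float]] = []
    for ion in ("b", "y"):
        for idx in range(1, len(seq)):
            mz = fragment_mz(seq, ion, idx, charge=1)
            if mz_range[0] <= mz <= mz_range[1]:
                fragments.append((f"{ion}{idx}", 1, mz))
    if len(fragments) < min_fragments:
        raise SelectionError(
            f"only {len(fragments)} in-range fragments for {seq!r}; "
            f"need at least {min_fragments}"
        )
    window = None
    if expected_rt is not None:
        half = rt_window_length / 2.0
        window = (expected_rt - half, expected_rt + half)
    return TransitionSet(
        peptide=peptide,
        precursor_mz=precursor_mz(seq, peptide.charge),
        fragments=fragments,
        rt_window=window,
    )


def transitions_to_frame(transition_sets: Iterable[TransitionSet]) -> pd.DataFrame:
    """Skyline-style flat transition list."""
    rows = []
    for ts in transition_sets:
        rt_start, rt_end = ts.rt_window if ts.rt_window else (float("nan"),) * 2
        for label, z, mz in ts.fragments:
            rows.append(
                {
                    "protein": ts.peptide.parent_protein,
                    "peptide": ts.peptide.sequence,
                    "precursor_mz": ts.precursor_mz,
                    "precursor_charge": ts.peptide.charge,
                    "fragment": label,
                    "fragment_charge": z,
                    "fragment_mz": mz,
                    "rt_start": rt_start,
                    "rt_end": rt_end,
                }
            )
    return pd.DataFrame(rows)


def select_targets(
    sequences: Mapping[str, str],
    params: DigestParams = DigestParams(),
    config: FilterConfig = FilterConfig(),
    proteome: Mapping[str, str] | None = None,
    groups: Mapping[str, str] | None = None,
    charge: int = 2,
    min_fragments: int = 3,
) -> tuple[list[TargetPeptide], list[TransitionSet]]:
    """Full selection pipeline: digest, filter, uniqueness, transitions.

    Returns the passing peptides (hard-flag free) and their transition sets;
    peptides whose fragment count falls below ``min_fragments`` are dropped.
    """
    candidates: list[TargetPeptide] = []
    for name, seq in sequences.items():
        candidates.extend(digest(seq, parent_protein=name, params=params, charge=charge))
    candidates = apply_filters(candidates, config)
    if proteome:
        candidates = annotate_uniqueness(candidates, proteome, groups)
    passing = [p for p in candidates if p.passing]
    transition_sets = []
    for pep in passing:
        try:
            transition_sets.append(enumerate_transitions(pep, min_fragments))
        except SelectionError:
            continue
    kept = {id(ts.peptide) for ts in transition_sets}
    return [p for p in passing if id(p) in kept], transition_sets
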