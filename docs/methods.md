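# Methods

## The measurement problem

Secretory proteins that fail to translocate into the endoplasmic reticulum
(for example during ER pre-emptive quality control) accumulate in the
cytosol. A cytosolic peroxidase (APEX2 with a nuclear export signal)
biotinylates nearby proteins during a short biotin-phenol/H2O2 pulse;
avidin-purified eluates therefore contain the mistargeted fraction of a
secretory analyte such as FLAG-tagged transthyretin (TTR). Quantifying the
analyte in the eluate by targeted mass spectrometry (parallel reaction
monitoring, PRM) and normalizing appropriately yields a relative
mistargeting measurement per drug treatment.

`prmquant` implements the computational side of this assay: choosing target
peptides, integrating and validating chromatograms, normalizing, and
testing fold changes — plus a synthetic-data generator that makes every
stage verifiable end to end.

## The eluate-composition model

The generator assigns each protein `p` a role with a noise-free expected
eluate signal under condition `c`:

| role                   | expected signal        |
|------------------------|------------------------|
| labeled cytosolic      | `alpha_c * a_p * eps_p`        |
| secretory analyte      | `alpha_c * m_c * a_p * eps_p`  |
| labeling independent   | `a_p * eps_p`                  |
| background contaminant | `a_p`                          |

where `alpha_c > 0` is the relative peroxidase labeling activity, `m_c` in
[0, 1] the analyte's mistargeted (cytosolic) fraction, `a_p` the input
abundance (mass-balanced across conditions, so condition-independent unless
the user configures an expression change), and `eps_p` in (0, 1] the avidin
capture efficiency. Labeling-independent proteins model endogenously
biotinylated mitochondrial carboxylases (pyruvate carboxylase, PC);
background contaminants model avidin leached from beads, keratins and
trypsin. Each observed peptide area is the protein's expected signal,
split equally across its monitored peptides, times a multiplicative
log-normal factor `exp(N(0, sigma^2))`. The run TIC is the sum of all
peptide areas plus a constant contaminant background, by default 20% of the
reference condition's TIC (bead leaching is strongly condition- and
lot-dependent, so this is configurable).

Defaults: `sigma = 0.1` (implying replicate CVs of
`sqrt(exp(sigma^2) - 1) ≈ 10%`, consistent with technical-replicate CVs of
~5–18% observed for this assay class), `n = 6` replicates, reference
mistargeted fraction `m_ref = 0.02` with a 2.5-fold stress increase. Three
scenario packs cover the labeling-activity regimes: `comparable`
(`alpha` equal), `decreased` (`alpha` halved, DTT/BFA-like) and `increased`
(`alpha` doubled, mycolactone-like). The `alpha` values are illustrative
regime magnitudes, not calibrated measurements.

What the generator does **not** emulate: ionization and digestion
variability that differs per peptide, missing runs, retention-time drift,
heavy-isotope standards, or correlated (run-level) noise. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to every artifact of real LC-MS data.

## Normalization identities and the labeling-activity diagnostic

With analyte area `A_c ∝ alpha_c m_c` and factor signals `F_enz ∝ alpha_c`
(auto-labeled peroxidase, or a compartment-sharing protein like actin) and
`F_ind ∝ const` (carboxylases), the fold changes versus the reference are

* ENZYME (or COMPARTMENT): `(m_c / m_ref)` — labeling activity cancels;
* INDEPENDENT: `(alpha_c / alpha_ref) * (m_c / m_ref)`;
* TIC: between the two, because the TIC mixes `alpha`-scaled and
  `alpha`-independent components.

The ratio of ENZYME- to INDEPENDENT-normalized fold changes estimates
`alpha_ref / alpha_c` and drives the regime diagnostic: within an
equivalence band of [0.8, 1.25] (a conventional bioequivalence-style
default; the underlying prediction is qualitative) the labeling activity is
called *comparable*, above it *decreased*, below it *increased*.

These identities are exact in the tracer limit where the analyte's own
contribution to the TIC vanishes. The generator keeps the analyte in the
TIC (as it physically is), so with the realistic packs the TIC fold change
is additionally depressed by the analyte's own TIC share (~0.3% here); the
identity tests use a tracer-scale analyte and a 1e-4 relative tolerance.

## Target-peptide selection

Tryptic digestion cleaves C-terminal to K/R except before P; at 0 missed
cleavages the peptides tile the protein. Candidate filters (all
configurable):

* length 8–25 residues;
* labile-modification residues, default `{M}` (sub-stoichiometric oxidation);
  tryptophan is deliberately not flagged — W-containing peptides are
  routinely assayed;
* deamidation-prone motifs `NG`/`QG` — a **soft** flag, since motif presence
  predicts propensity but only empirical confirmation disqualifies;
* ragged tryptic ends (K/R-K/R junctions on either terminus) — also a
  **soft** flag: a peptide downstream of an R-K junction can still be an
  excellent target (the TTR assay peptide is one), so ragged ends are
  reported and ranked rather than rejected;
* peroxidase-labeling sensitivity: tyrosine-containing peptides of
  biotin-phenol-labeled parents (BP adds 361.14601 Da on Y);
  Y-peptides of labeling-independent proteins such as PC are fine.

Length bounds live in `FilterConfig` rather than `DigestParams`: digestion
itself must tile the sequence (short fragments included), and flagging is
the filter's responsibility.

Uniqueness requires that every background-proteome entry containing the
peptide belongs to the parent's class; class maps (e.g. ACTB/ACTG1 →
"actin") allow class-level rather than family-level uniqueness. Transition
enumeration emits singly charged b/y ions from a hardcoded monoisotopic
residue-mass table with static carbamidomethyl-C (+57.02146 Da), filtered
to the instrument range (default 110–2000 m/z), requiring at least three
fragments; scheduling windows default to 10 min. A user-supplied
spectral-library membership list can replace library-based filtering; the
package performs no library lookups.

## Chromatogram quantification

Integration is trapezoidal over explicit boundaries, after subtracting a
linear baseline drawn between the boundary intensities (floored at zero;
`baseline="none"` disables it). Automatic boundaries start at the local
apex nearest the expected retention time and extend until intensity falls
below 1% of the apex, capped at a 1.5-min half-width; a trace with no
nonzero signal is reported "not found" with area 0. These rules replace
the manual boundary adjustment a human operator would perform and are
deliberately deterministic.

Fragment validation applies three criteria per fragment: (a) Pearson
correlation ≥ 0.90 with the summed-fragment trace inside the boundaries
(co-elution/shape); (b) constant intensity proportion across runs; (c)
apex RT within 0.2 min of the peptide consensus apex. For (b), a naive
per-run share comparison lets one corrupted run distort every fragment's
share; instead each run is rescaled by its median fragment ratio to the
across-run consensus (a median-polish-style robust scale), and a fragment
fails when its relative deviation from consensus exceeds 30% in any run.
With at least three validated fragments the peptide is quantifiable from
their summed areas; peptides with clean MS1 signals (peroxidase, actin,
tubulin) may instead be quantified from the precursor trace via
configuration. All thresholds are exposed; the defaults quantify the
conventional qualitative criteria.

The per-run TIC is the area under the MS1 TIC trace when present,
otherwise the sum of precursor-trace areas. The canonical trace format is
a tabular CSV (`protein, peptide, ion_label, rt, intensity`); mzML
chromatogram lists are read via pyteomics. Chromatogram emission writes
Gaussian peaks on a grid of one-tenth the peak width (a coarser grid than
the peak width is rejected as unrepresentable), which keeps trapezoidal
re-integration well inside 0.5% of the requested area.

## Statistics

* CVs use the sample (n−1) standard deviation over the mean — the
  denominator choice is material at n = 8 and is configurable via `ddof`.
  TIC-normalized CVs divide each area by its run's TIC first. Summaries
  report median (mean of central order statistics for even counts) and max
  per basis.
* Fold changes are computed within replicate experiments (condition value
  over reference value, paired by the replicate identifier), then
  aggregated as mean ± SEM.
* Group comparisons use the two-tailed Welch (heteroscedastic) t-test with
  Welch–Satterthwaite degrees of freedom and Bonferroni adjustment
  `min(1, m·p)`, with `m` taken from configuration rather than inferred.
  Zero variance in both groups with equal means yields p = 1 by convention.
* Method agreement (e.g. PRM vs immunoblot shares after sum-normalization
  across conditions) is an OLS fit plus squared Pearson correlation.
* Significance stars: `*` for adjusted p in [0.01, 0.05), `**` [0.001,
  0.01), `***` [0.0001, 0.001), `****` below 0.0001.

Multiple factor peptides are combined by summed area by default (robust to
a single-peptide dropout); a median-of-ratios combination is available. A
zero-area analyte in a run yields a normalized value of 0 with a warning
rather than an error, to tolerate below-detection conditions.

## Problem sizes and numerical choices

The verification suite and `scripts/acceptance.py` use desk-scale sizes
chosen to make sampling error negligible relative to the asserted effects:
200 random sequences for the digestion oracle, a 5×5×5 grid
(`alpha` × m-fold × independent share) for the noise-free identities, 500
seeded simulated experiments (n = 6, sigma = 0.1) for parameter recovery
and for regime classification per pack, and 10^5 replicates for the
log-normal CV closed form. Gaussian traces are emitted at step = width/10
over ±6 widths. All randomness flows through `numpy.random.default_rng`
seeds; identical seeds give bitwise-identical simulations.

## Known limitations

* The eluate model is linear in its parameters; saturation of labeling or
  of the avidin resin is not modeled.
* The ENZYME fold-change estimator has a small positive bias under
  log-normal noise (ratio of log-normals; about +2% at sigma = 0.1,
  vanishing as sigma → 0).
* Boundary picking assumes a single dominant peak near the expected RT;
  heavily overlapping peaks are out of scope (no deconvolution).
* Chromatogram emission writes the tabular format only; mzML is supported
  for reading chromatogram lists, not writing.
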