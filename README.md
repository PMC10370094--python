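# prmquant

Quantification pipeline for measuring **secretory-protein mistargeting** by
cytosolic proximity labeling and **parallel reaction monitoring (PRM)** mass
spectrometry.

When the endoplasmic reticulum is stressed, translocation of some secretory
proteins is attenuated and a fraction of them (e.g. transthyretin, TTR)
remains in the cytosol, where a cytosolic peroxidase (APEX2) biotinylates
them during a short biotin-phenol/H2O2 pulse. Avidin-purified eluates are
digested and analyzed by PRM; the analyte's chromatographic peak areas,
properly normalized, report its relative mistargeted fraction per drug
treatment. The package is for proteomics researchers building or analyzing
such assays: it covers target-peptide selection, chromatogram integration
and transition validation, normalization, fold-change statistics — and a
synthetic-data generator so the whole pipeline can be exercised and
verified without instrument data.

## The model at the core

Eluate signal of protein *p* under condition *c*, with labeling activity
*α_c*, mistargeted fraction *m_c*, abundance *a_p*, capture efficiency *ε_p*:

* BP-labeled cytosolic protein: *α_c a_p ε_p*
* secretory analyte: *α_c m_c a_p ε_p*
* labeling-independent carboxylase (PC): *a_p ε_p*
* background contaminant: *a_p*

Consequently, fold changes versus a reference condition obey
*FC*<sub>ENZYME</sub> = *m_c/m_ref* (labeling activity cancels against the
auto-labeled peroxidase), *FC*<sub>INDEPENDENT</sub> =
(*α_c/α_ref*)(*m_c/m_ref*), and the TIC-normalized fold change lies between
them. Their ratio estimates *α_ref/α_c* and diagnoses treatment-dependent
labeling-activity changes — the reason normalizing to the peroxidase itself
is necessary for treatments (DTT, BFA, mycolactone) that alter labeling
yield. See `docs/methods.md` for the full account.

## Worked example

```bash
python examples/04_normalization_schemes.py
```

simulates the "decreased labeling activity" scenario (truth: mistargeting
×2.5 under DTT, labeling activity ×0.5) and prints:

```
         TIC: fold change 1.94 +/- 0.10 (adj. p = 2.32e-04) ***
 INDEPENDENT: fold change 1.47 +/- 0.12 (adj. p = 9.83e-03) **
 COMPARTMENT: fold change 2.63 +/- 0.17 (adj. p = 1.82e-04) ***
      ENZYME: fold change 2.93 +/- 0.27 (adj. p = 8.64e-04) ***

diagnostic: regime 'decreased', enzyme/independent ratio 1.99 -> implied labeling-activity ratio 0.50
```

ENZYME normalization cancels the labeling-activity confound and estimates
the true 2.5× mistargeting increase within sampling error; INDEPENDENT
(carboxylase) normalization is biased down toward 1.25×; TIC sits between;
and the enzyme/independent ratio ≈ 2 correctly reports that the treatment
halved labeling activity. The other examples cover simulation
(`01`), in-silico digestion and transition lists (`02`), chromatogram
integration with interference rejection (`03`), and replicate-CV /
statistical QC (`05` — the 20-peptide reference panel gives a raw-CV median
of 9.1% and a TIC-normalized median of 5.75%).

A thin CLI mirrors the library:

```bash
prmquant simulate --pack decreased --seed 17 --out out/
prmquant normalize --areas out/quant_table.csv --roles roles.json \
    --scheme all --reference "MG132+Veh" --out fc.csv
```

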