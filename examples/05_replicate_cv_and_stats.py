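"""Replicate-CV QC and the assay panel's summary statistics.

Summarizes the reference panel's published technical-replicate CVs (n = 8),
then recomputes CVs on a simulated 8-replicate experiment and demonstrates
the Welch test and method-agreement statistics.
"""

import numpy as np

import prmquant as pq
from prmquant.panel import PANEL

raw = [pq.CvRecord(e.protein, e.peptide, "raw", e.cv_raw, 8) for e in PANEL]
tic = [pq.CvRecord(e.protein, e.peptide, "tic_normalized", e.cv_tic, 8)
       for e in PANEL]
med_raw, max_raw = pq.summarize_cv(raw)["raw"]
med_tic, max_tic = pq.summarize_cv(tic)["tic_normalized"]
print(f"panel raw CVs:            median {100 * med_raw:.1f}%, max {100 * max_raw:.1f}%")
print(f"panel TIC-normalized CVs: median {100 * med_tic:.2f}%, max {100 * max_tic:.1f}%")

cfg = pq.scenario_pack("comparable", n_replicates=8, seed=4)
table = pq.runs_to_frame(pq.simulate_experiment(cfg))
records = [r for r in pq.cv_table(table) if r.condition == "MG132+Veh"]
med, mx = pq.summarize_cv([r for r in records if r.basis == "raw"])["raw"]
print(f"\nsimulated 8-replicate raw CVs (sigma = 0.1): median {100 * med:.1f}%, "
      f"max {100 * mx:.1f}%  (log-normal expectation ~10%)")

rng = np.random.default_rng(0)
veh = 1.0 + 0.08 * rng.standard_normal(6)
tg = 2.4 + 0.25 * rng.standard_normal(6)
r = pq.welch_test(tg, veh, m=6, comparison="Tg vs Veh")
print(f"\n{r.comparison}: t = {r.t_statistic:.2f}, df = {r.degrees_of_freedom:.1f}, "
      f"adj. p = {r.adjusted_p:.2e} {pq.significance_stars(r.adjusted_p)}")

ib = np.array([0.10, 0.12, 0.35, 0.18, 0.15, 0.10])
prm = 0.98 * ib + 0.004 + rng.normal(0, 0.004, 6)
slope, intercept, r2 = pq.method_agreement(ib, prm)
print(f"\nmethod agreement (sum-normalized shares, PRM vs IB): "
      f"y = {slope:.2f}x + {intercept:.3f}, R^2 = {r2:.3f}")
print(
    "\nTechnical CVs near 10% match the configured noise; the Welch test\n"
    "with Bonferroni correction (m = 6) flags the induced condition; a\n"
    "near-unit slope with R^2 ~ 0.99 indicates the two methods agree."
)
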