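"""Compare normalization schemes and diagnose labeling-activity changes.

Simulates the 'decreased labeling activity' scenario (truth: mistargeting
x2.5, labeling activity x0.5 under DTT) and computes the stress condition's
fold change under all four normalization schemes, then runs the
enzyme-vs-independent diagnostic.
"""

import prmquant as pq

cfg = pq.scenario_pack("decreased", seed=23)
table = pq.runs_to_frame(pq.simulate_experiment(cfg))
roles = pq.PACK_NORMALIZATION_ROLES

results = {}
for kind in ("TIC", "INDEPENDENT", "COMPARTMENT", "ENZYME"):
    scheme = (pq.NormalizationScheme("TIC") if kind == "TIC"
              else pq.scheme_from_roles(kind, roles))
    res = pq.fold_change(table, scheme, "FLAG-TTR", "MG132+Veh", roles=roles)
    results[kind] = res
    r = {x.condition: x for x in res}["DTT"]
    stars = pq.significance_stars(r.adjusted_p)
    print(f"{kind:>12}: fold change {r.fold_change:.2f} +/- {r.sem:.2f} "
          f"(adj. p = {r.adjusted_p:.2e}) {stars}")

d = pq.diagnose_condition(
    {"ENZYME": results["ENZYME"], "INDEPENDENT": results["INDEPENDENT"]}, "DTT"
)
print(f"\ndiagnostic: regime '{d.regime}', enzyme/independent ratio "
      f"{d.ratio:.2f} -> implied labeling-activity ratio {d.implied_activity_ratio:.2f}")

print(
    "\nENZYME normalization (auto-labeled APEX2) cancels the labeling-activity\n"
    "change and estimates the true 2.5x mistargeting increase within sampling\n"
    "error; INDEPENDENT normalization (PC) is confounded down toward ~1.25x;\n"
    "TIC sits in between. The ratio ~2 reports that DTT halved labeling activity."
)
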