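"""Pick PRM target peptides from a protein sequence.

Digests the mature chain of human transthyretin in silico, applies the
default candidate filters, and enumerates b/y transitions for the assay's
TTR peptide.
"""

import prmquant as pq
from prmquant.panel import TTR_MATURE

peptides = pq.apply_filters(pq.digest(TTR_MATURE, parent_protein="TTR"))

print("candidate tryptic peptides (0 missed cleavages):")
for p in peptides:
    status = "PASS" if p.passing else "drop"
    print(f"  {p.sequence:<25} [{p.start:3}-{p.end:3}]  {status}  "
          f"flags={sorted(p.flags) or '-'}")

target = next(p for p in peptides if p.sequence == "AADDTWEPFASGK")
ts = pq.enumerate_transitions(target, expected_rt=42.0)
print(f"\ntarget {target.sequence} (2+), precursor m/z {ts.precursor_mz:.4f}, "
      f"scheduled window {ts.rt_window} min")
print(f"{len(ts.fragments)} in-range b/y fragments, e.g.:")
for label, z, mz in ts.fragments[:3] + ts.fragments[-3:]:
    print(f"  {label:>4} ({z}+)  m/z {mz:.4f}")

print(
    "\nThe assay peptide carries only a soft ragged-end flag (it sits after\n"
    "an R-K junction in TTR) and is kept; peptides failing hard filters\n"
    "(length, methionine, non-uniqueness) would be dropped."
)
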