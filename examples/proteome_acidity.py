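"""Compute isoelectric points for an annotated proteome and summarize
the distribution.

Halophilic archaea carry strongly acidic proteomes (mean pI near 5,
single-peaked) — their proteins stay soluble in molar salt.  The pI of
each protein is the root of the Henderson-Hasselbalch net-charge model,
found by bisection; the packaged "embl" pKa set is the default and the
"dtaselect" set quantifies sensitivity to that choice.
"""

import numpy as np

from haloscan.proteome_pi import PKA_SETS, isoelectric_point, proteome_pi, proteome_pi_summary
from haloscan.synthgen import RepliconSpec, SynthSpec, generate

spec = SynthSpec(seed=12, replicons=[
    RepliconSpec(id="chr", length=150000, n_cds=100)])
replicons, _ = generate(spec)

results = proteome_pi(replicons)
summary = proteome_pi_summary(results, bin_width=0.5)
print(f"{summary['n_proteins']} proteins, mean pI {summary['mean_pI']}")
edges, counts = summary["histogram"]
peak = counts.argmax()
print(f"modal bin: {edges[peak]:.1f}-{edges[peak + 1]:.1f} "
      f"({counts[peak]} proteins)")

seq = "MDEEALKAADDFEEGLSKRK"  # an acidic halophile-style protein
for name in ("embl", "dtaselect"):
    print(f"pI({name} pKa set) = "
          f"{isoelectric_point(seq, PKA_SETS[name]):.2f}")
print("\nSynthetic proteins use near-uniform amino-acid usage, so their")
print("mean pI sits near neutral; a real haloarchaeal proteome shifts the")
print("whole single-peaked distribution down to ~5.")
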