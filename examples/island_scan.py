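"""Detect a laterally-acquired genomic island by its synonymous codon
usage (SCU).

A 30-CDS window slides along the replicon; each window's codon counts
are compared to the whole-replicon SCU table by a chi-square statistic
conditioned on the window's amino-acid composition.  A run of strongly
significant windows marks an island; per-CDS likelihood refinement then
sharpens its boundaries to the exact CDSs.
"""

from haloscan.scu import detect_islands
from haloscan.synthgen import IslandSpec, RepliconSpec, SynthSpec, codon_profile, generate

spec = SynthSpec(seed=3, replicons=[
    RepliconSpec(id="chr", length=300000, n_cds=300,
                 cds_profile=codon_profile(0.8),  # GC-rich host usage
                 islands=[IslandSpec(100, 35, codon_profile(0.3))]),
])
(replicon,), manifest = generate(spec)

scan, islands = detect_islands(replicon)
print(f"{len(scan.stats)} windows scanned; "
      f"{sum(s.p < 1e-4 for s in scan.stats)} significant at p < 1e-4")
for isl in islands:
    print(f"island: CDS {isl.cds_range[0]}..{isl.cds_range[1]}, "
          f"bp {isl.span[0] + 1}-{isl.span[1]}, min p = {isl.min_p:.3g}, "
          f"{isl.label}")
truth = manifest["chr"]["islands"][0]
print(f"planted: CDS {truth['start_cds']}..{truth['end_cds']}")
print("\nThe called CDS range should match the planted one to within a")
print("couple of CDSs; the window chi-square alone only locates it to")
print("window resolution.")
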