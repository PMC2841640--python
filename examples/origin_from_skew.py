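"""Locate a replication origin from the cumulative GC-skew curve.

Leading and lagging strands accumulate different G/C compositions, so
the running sum of (+1 per G, -1 per C) along a circular chromosome is
V-shaped with its vertex at the origin.  The curve is "closed" (linear
trend removed) so the vertex does not depend on where the sequence
happens to start.
"""

from haloscan.skew import cumulative_disparity, locate_skew_extremum, windowed_gc_skew
from haloscan.synthgen import RepliconSpec, SynthSpec, generate

spec = SynthSpec(seed=21, replicons=[
    RepliconSpec(id="chr", length=200000, n_cds=0, gc=0.6,
                 ori=70000, skew=0.04),
])
(replicon,), manifest = generate(spec)

curve = cumulative_disparity(replicon, "GC")
vertex = locate_skew_extremum(curve, detrend=True)
print(f"planted origin: {manifest['chr']['ori']:,} bp")
print(f"cumulative GC-skew vertex: {vertex:,} bp "
      f"(error {abs(vertex - manifest['chr']['ori']):,} bp)")

skews = windowed_gc_skew(replicon, window=10000)
signs = "".join("+" if v > 0 else "-" for _, v in skews if v is not None)
print(f"windowed (G-C)/(G+C) signs along the replicon: {signs}")
print("\nThe sign flips at the origin and its antipode (the terminus):")
print("windows downstream of the origin on the leading strand are G-rich.")
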