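# Methods

This note records the models behind each analysis, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was open.

## Coordinates and I/O

Internal coordinates are 0-based half-open; GenBank/GFF3 1-based
inclusive coordinates are converted on read, and human-facing reports
use 1-based inclusive again (BED/bedGraph stay 0-based half-open per
their standards).  A feature that wraps the origin of a circular
replicon is stored as two spans sharing one feature id, ordered 5′→3′
along the coding sequence.  Ambiguity codes other than N are mapped to N
with a warning; N never enters a GC numerator or denominator.  CDSs
flagged partial, or whose length is not a multiple of 3, are kept as
features but excluded from all codon statistics (with a warning) — how
such genes were treated in the original analyses is not recorded
anywhere we could follow, so exclusion is the conservative choice.
IS elements are recognized from annotation labels (default patterns
`ISH51`, `IS4`, `transposase`), not detected de novo.

## Synonymous codon usage and island calling

The reference distribution for a replicon is its family-conditional SCU
table over translation table 11, with the three stop codons plus ATG
(Met) and TGG (Trp) excluded — those families offer no synonymous
choice.  That leaves 59 codons in 18 families.  The window statistic
conditions on the window's amino-acid counts, so the nominal degrees of
freedom are Σ(family size − 1) = 41.  The published SCUBA analysis of
this genome quotes 40 df; `df` therefore defaults to 40 for
compatibility and is a configuration knob, while internal calibration
uses the nominal 41 (`NOMINAL_DF`).  The discrepancy changes the p-value
of a given χ² only mildly (at χ² = 55.8, p = 0.050 vs 0.062) but matters
for exact type-I-error calibration.

Parameters, with defaults and reasons:

| parameter | default | why |
|---|---|---|
| window | 30 CDSs | the published scan's window |
| step | 1 CDS | "moving window" with no stated stride |
| α | 1e−4 | a homogeneous multi-thousand-CDS replicon then yields ~0 false islands (0.05 would flag ~5% of windows) |
| min_run | 3 windows | single significant windows are noise |
| df | 40 | see above |

Island calling merges adjacent significant windows into runs and
discards runs shorter than `min_run`.  Two refinements are this
package's own design (the original publication does not state how island
boundaries were delimited, and its island count is threshold-dependent):

1. **Reference purification** (`detect_islands`): a large divergent
   island contaminates the whole-replicon SCU table, which can make
   ordinary windows significant against the mixture.  After the first
   pass the reference is rebuilt from CDSs outside any called island and
   the scan repeated once.
2. **Boundary refinement**: a run of significant windows locates an
   island only to window resolution (±30 CDSs).  An island profile is
   estimated from the middle third of the candidate CDS range, and each
   candidate CDS is classified by the log-likelihood ratio of its codon
   counts under the island profile vs the reference; the island is the
   maximal contiguous positive-LLR run containing the peak.  On
   synthetic islands whose usage differs strongly from the host this
   recovers boundaries to within a couple of CDSs.

Cross-replicon assignment scores an island's pooled codon counts against
each candidate replicon's SCU table; the minimizing replicon is reported
(ties break to the lexicographically smaller id) and "similar" means its
p ≥ α.

## Composition

GC percentages are computed over A/C/G/T only.  Coding GC is taken over
the union of CDS spans (overlap counted once); percent coding is the
union size over the replicon length.  Codon-position GC pools complete
codons across CDSs and excludes stop codons by default (configurable —
whether the published codon-position figures include stops is unstated).
Windowed tracks default to a 5 kb window and 1 kb stride: fine enough to
resolve a ~50 kb anomalous region ~50 windows wide, coarse enough that
per-window counts are in the thousands.  The windowed composition χ²
compares each window's base counts to expectations from the
replicon-wide base frequencies.  Whole-replicon GC is computed over the
full sequence without feature masking.

## Skew curves and origin signal

Cumulative disparity curves are exact prefix sums (one value per bp;
storage stride applies only to emitted tracks, default 100 bp).  On a
circular chromosome replicated bidirectionally the GC curve is V-shaped
with the vertex at the origin.  The raw global minimum, however, depends
on the arbitrary sequence start whenever the genome-wide G−C total is
nonzero, so `locate_skew_extremum(detrend=True)` first closes the curve
by removing the linear trend i·(final/L); this is what the pipeline uses
for circular replicons.  No smoothing is applied by default (an optional
moving average exists); ties break to the smallest coordinate.  The
package reports curve vertices and amplitudes but makes no claim that a
vertex *is* an origin — origins are an experimental matter; the curve is
a signal.

## Proteome pI

Net charge is the standard group-charge model over the N-terminus, His,
Lys, Arg (basic) and C-terminus, Asp, Glu, Cys, Tyr (acidic); unknown
residues are ignored, the initial Met is retained (the annotation's
translation is authoritative).  Q(pH) is strictly decreasing whenever an
ionizable group is present, so the pI is the unique root on [0, 14];
bisection runs to a bracket narrower than 1e−4 pH.  Termination is on
bracket width, not on |Q|: the charge curve can be nearly flat around
the root, where a |Q| criterion stops arbitrarily far from it.  Two pKa
sets ship as package data: `embl` (default; the EMBL set of the Bioperl
pI calculator, matching how the reference proteome figures were
computed) and `dtaselect`.  Individual pIs move by up to a few tenths of
a pH unit between sets, so summaries should state the set.
Transmembrane/cytosolic classification is an input label, never
computed.

## IS-context permutation test

The "evolving away from IS elements" observation was originally
presented graphically; the test here is this package's formalization.
Statistic: mean GC of fixed-width flanks (default 500 bp each side) at
the annotated IS sites.  Null: the same number of positions drawn
uniformly, excluding annotated IS spans so the elements' own AT-rich
sequence cannot leak into the null.  p = (1 + #{T_null ≤ T_obs})/(1 +
n_perm), one-sided for "sites are AT-richer than random"; seed and
n_perm are recorded in the result.  The overlay window for plots
defaults to 5 kb (unstated in the source material; flagged as a choice).
Calibration caveat: the null draws positions from the whole replicon, so
if coding and intergenic GC differ and IS sites are structurally
intergenic, the test partly measures that contrast; the generator's
calibration genomes match intergenic GC to realized coding GC for this
reason.

## Genetic-map calibration

Offsets are genome bp − 1000·map kb, pooled over marker starts and ends;
the estimate is the pooled median (a mean is also reported — the two
legacy summaries of this calibration differ by about 1 kb and the
package does not adjudicate).  Markers whose map gene length and
sequence gene length differ by more than 2× are flagged as outliers and
the median recomputed once; named markers can be excluded a priori
(genes too large for the map's ~10 kb resolution).  Projection of legacy
intervals wraps modulo the replicon length and lists overlapping
annotated genes.

## The synthetic-data generator

`synthgen` emulates the statistical structures the analyses assume, with
one pseudo-random stream per replicon spawned from the master seed (so
adding a replicon leaves the others byte-identical).  Per replicon:

* CDS lengths ~ lognormal (mean 250 codons, σ = 0.3, floor 60); amino
  acids near-uniform over the 18 degenerate families with Met/Trp at 2%;
  codons drawn from a family-conditional profile.  `codon_profile(gc3)`
  weights codons by third-base GC, the dominant axis of codon-usage
  variation in GC-biased genomes.
* Islands: contiguous CDS blocks drawn from a different profile.
* Intergenic DNA: i.i.d. at the background GC; gap lengths are
  Dirichlet-multinomial (α = 0.3), mostly short with a few long —
  matching the long-tailed spacer lengths of real genomes and providing
  gaps large enough to host IS elements.  Optional AT valleys are long
  gaps at reduced GC.
* IS elements: fixed-length (default 1400 bp) i.i.d. sequences at their
  own GC, placed inside eligible gaps with weight exp(−preference ·
  site GC%); preference 0 is uniform placement.
* Origin asymmetry: intergenic bases take P(G) ∝ (1+g)/2 of the strong
  fraction on the leading half and (1−g)/2 on the lagging half, giving a
  V-shaped cumulative GC curve with vertex at the origin.  Because
  g ≈ 0.02 on intergenic DNA alone is weak against the G−C random walk
  of randomly stranded CDS blocks, `cds_strand_bias` optionally
  co-orients genes with the fork (as real replicons do): each CDS takes
  the orientation whose genome-strand composition reinforces the
  leading-strand G excess with the given probability.
* Marker maps: map position = (assembly position − offset)/1000 + a
  shared per-marker jitter (the map's placement error, default ±5 kb)
  plus ±0.1 kb independent endpoint jitter; gross outliers get a 3×
  length discrepancy.

What the generator does **not** emulate: real codon-usage covariance
between amino-acid composition and GC (amino-acid usage is fixed),
substitution-over-time evolution, gene-length/function correlations,
tRNA/rRNA genes, and realistic protein composition (synthetic proteomes
average near-neutral pI, not the acid-shifted distribution of a real
halophile).  Passing tests therefore demonstrate that the detectors
recover planted structure under the stated noise models — not that any
particular biological genome will show these signals.

## Problem sizes in tests and the acceptance script

The recovery measurements run on a 300 kb, 300-CDS replicon (one 40-CDS
island, 4 IS elements, 6 AT valleys, g = 0.02, 16 markers), 2,000 null
windows for χ² calibration, 100 random peptides for the pI oracle, 2,000
permutations for the valley test and 12 replicate genomes for the
uniform-placement check — sizes at which every effect is comfortably
resolved while a full run stays in seconds.
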