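"""Synonymous codon usage (SCU) tables, the 30-CDS moving-window
chi-square scan, genomic-island calling, and cross-replicon SCU assignment.

The reference distribution for a replicon is its family-conditional SCU
table: for each amino acid, the relative frequencies of its synonymous
codons.  A window of consecutive CDSs is compared to the reference by a
chi-square statistic whose expected counts condition on the *window's*
amino-acid composition, so amino-acid usage differences between windows
do not masquerade as codon-usage bias.  Stop, Met (ATG) and Trp (TGG)
codons are excluded by default, leaving 59 codons in 18 degenerate
families; the nominal degrees of freedom of the statistic are then
sum(family size - 1) = 41, but ``df`` is configurable and defaults to 40,
the value used by the original SCUBA analysis of the Haloferax volcanii
genome.

Maximal runs of significant windows become genomic-island calls, with
CDS-level boundary refinement by a per-CDS log-likelihood ratio between
an island profile (estimated from the run core) and the reference.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import chi2 as chi2_dist

from .genome_io import Replicon, extract_cds_codons

log = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOPS = frozenset(_TABLE11.stop_codons)

#: Default excluded codons: the three stops plus the single-codon families
#: ATG (Met) and TGG (Trp), which carry no synonymous choice.
DEFAULT_EXCLUDED = frozenset(STOPS) | {"ATG", "TGG"}

#: aa -> sorted codon family, over the non-excluded codons.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _codon not in DEFAULT_EXCLUDED:
        FAMILIES.setdefault(_aa, ())
        FAMILIES[_aa] += (_codon,)

#: Nominal df of the family-conditional statistic with the default
#: exclusion set: sum over families of (size - 1) = 41.
NOMINAL_DF = sum(len(v) - 1 for v in FAMILIES.values())

DEFAULT_DF = 40  # the published SCUBA setting
DEFAULT_ALPHA = 1e-4
DEFAULT_MIN_RUN = 3
DEFAULT_WINDOW = 30


@dataclass
class SCUTable:
    """Family-conditional synonymous codon frequencies."""

    codon_freq: dict[str, float]
    codon_counts: dict[str, int]
    aa_counts: dict[str, int]
    excluded: frozenset[str]
    n_cds: int

    def family_freqs(self, aa: str) -> dict[str, float]:
        return {c: self.codon_freq[c] for c in FAMILIES[aa]}


@dataclass
class WindowStat:
    index: int
    cds_range: tuple[int, int]  # first/last CDS ordinal (inclusive)
    span: tuple[int, int]  # bp, 0-based half-open; end < start marks a wrap
    chi2: float
    df: int
    p: float


@dataclass
class Island:
    replicon_id: str
    span: tuple[int, int]  # bp, 0-based half-open; end < start marks a wrap
    cds_range: tuple[int, int]
    windows: list[int]
    min_p: float
    contains_is: bool = False
    best_reference: tuple[str, float, float] | None = None  # (id, chi2, p)
    similar_to_reference: bool = False

    @property
    def label(self) -> str:
        return "contains_IS" if self.contains_is else "no_IS"


def count_codons(codon_lists, excluded: frozenset[str] = DEFAULT_EXCLUDED
                 ) -> Counter:
    """Pooled codon counts over CDS codon lists; excluded codons, stop
    codons, codons with N and non-standard codons are dropped."""
    counts: Counter = Counter()
    for codons in codon_lists:
        for codon in codons:
            if codon in excluded or codon not in CODON_TO_AA:
                continue
            counts[codon] += 1
    return counts


def build_scu(codon_lists, excluded: frozenset[str] = DEFAULT_EXCLUDED
              ) -> SCUTable:
    """SCU table from CDS codon lists (e.g. ``extract_cds_codons`` output
    values).  Frequencies are conditional on the amino acid."""
    codon_lists = list(codon_lists)
    counts = count_codons(codon_lists, excluded)
    if not counts:
        raise ValueError("no usable codons")
    aa_counts: dict[str, int] = {}
    for codon, n in counts.items():
        aa = CODON_TO_AA[codon]
        aa_counts[aa] = aa_counts.get(aa, 0) + n
    freq = {}
    for aa, fam in FAMILIES.items():
        tot = aa_counts.get(aa, 0)
        for c in fam:
            if c in excluded:
                continue
            freq[c] = counts.get(c, 0) / tot if tot else 0.0
    return SCUTable(freq, dict(counts), aa_counts, frozenset(excluded),
                    n_cds=len(codon_lists))


def window_chi2(window_counts, ref: SCUTable, df: int = DEFAULT_DF,
                index: int = 0, cds_range=(0, 0), span=(0, 0)) -> WindowStat:
    """Chi-square of a window's codon counts against a reference SCU table.

    Expected count for codon c of amino acid a is (window count of a) *
    ref.freq(c); the sum runs over codons with positive expectation.  A
    codon observed in the window but absent from the reference gets a
    pseudo-expectation of 0.5 (with a warning).
    """
    counts = {c: n for c, n in dict(window_counts).items()
              if c not in ref.excluded and c in CODON_TO_AA}
    aa_tot: dict[str, int] = {}
    for codon, n in counts.items():
        aa = CODON_TO_AA[codon]
        aa_tot[aa] = aa_tot.get(aa, 0) + n
    stat = 0.0
    for aa, n_aa in aa_tot.items():
        for codon in FAMILIES[aa]:
            if codon in ref.excluded:
                continue
            exp = n_aa * ref.codon_freq.get(codon, 0.0)
            obs = counts.get(codon, 0)
            if exp == 0.0:
                if obs > 0:
                    log.warning("codon %s used in window but absent from "
                                "reference; pseudo-expectation 0.5", codon)
                    exp = 0.5
                else:
                    continue
            stat += (obs - exp) ** 2 / exp
    p = float(chi2_dist.sf(stat, df))
    return WindowStat(index=index, cds_range=tuple(cds_range),
                      span=tuple(span), chi2=stat, df=df, p=p)


@dataclass
class ScanResult:
    replicon_id: str
    stats: list[WindowStat]
    reference: SCUTable
    cds_ids: list[str]
    cds_codons: list[list[str]]
    cds_spans: list[tuple[int, int]]
    window: int
    circular: bool


def scan_replicon(r: Replicon, window: int = DEFAULT_WINDOW, step: int = 1,
                  df: int = DEFAULT_DF, ref: SCUTable | None = None,
                  excluded: frozenset[str] = DEFAULT_EXCLUDED) -> ScanResult:
    """Moving-window SCU chi-square scan along a replicon's CDS ordering.

    The reference defaults to the whole-replicon SCU table.  Circular
    replicons wrap the CDS list, giving one window per CDS; linear
    replicons give n - window + 1 windows.  A replicon with fewer CDSs
    than the window is scanned as a single whole-replicon window (with a
    warning).
    """
    groups = r.cds_groups()
    ids, codon_lists, spans = [], [], []
    usable = dict(extract_cds_codons(r))
    for fid, parts in groups:
        if fid not in usable:
            continue
        ids.append(fid)
        codon_lists.append(usable[fid])
        spans.append((parts[0].start, parts[-1].end))
    n = len(ids)
    if n == 0:
        raise ValueError(f"replicon {r.id}: no usable CDSs")
    if ref is None:
        ref = build_scu(codon_lists, excluded)
    circular = r.topology == "circular"
    if n < window:
        log.warning("replicon %s has %d CDSs < window %d; single window",
                    r.id, n, window)
        window = n
    if circular:
        first_indices = range(0, n, step)
    else:
        first_indices = range(0, n - window + 1, step)
    stats = []
    for w_idx, i in enumerate(first_indices):
        members = [(i + k) % n for k in range(window)]
        counts = count_codons([codon_lists[m] for m in members], excluded)
        span = (spans[members[0]][0], spans[members[-1]][1])
        stats.append(
            window_chi2(counts, ref, df=df, index=w_idx,
                        cds_range=(members[0], members[-1]), span=span)
        )
    return ScanResult(r.id, stats, ref, ids, codon_lists, spans,
                      window, circular)


# ---------------------------------------------------------------------------
# island calling


def _loglik(counts: Counter, table: SCUTable, eps: float = 1e-9) -> float:
    ll = 0.0
    for codon, n in counts.items():
        if codon in table.excluded or codon not in CODON_TO_AA:
            continue
        ll += n * math.log(table.codon_freq.get(codon, 0.0) + eps)
    return ll


def _refine_boundaries(scan: ScanResult, ordinals: list[int]) -> list[int]:
    """Per-CDS log-likelihood-ratio refinement of an island's CDS range.

    The island profile is estimated from the middle third of the candidate
    range; the refined island is the maximal contiguous run of CDSs with
    positive LLR (island vs reference) containing the LLR peak.
    """
    third = max(len(ordinals) // 3, 1)
    core = ordinals[third:len(ordinals) - third] or ordinals
    island_ref = build_scu([scan.cds_codons[i] for i in core],
                           scan.reference.excluded)
    llr = []
    for i in ordinals:
        c = count_codons([scan.cds_codons[i]], scan.reference.excluded)
        llr.append(_loglik(c, island_ref) - _loglik(c, scan.reference))
    peak = int(np.argmax(llr))
    lo = peak
    while lo > 0 and llr[lo - 1] > 0:
        lo -= 1
    hi = peak
    while hi < len(llr) - 1 and llr[hi + 1] > 0:
        hi += 1
    return ordinals[lo:hi + 1]


def call_islands(scan: ScanResult, r: Replicon, alpha: float = DEFAULT_ALPHA,
                 min_run: int = DEFAULT_MIN_RUN,
                 refine: bool = True) -> list[Island]:
    """Merge significant windows into islands.

    Windows with p < alpha that are adjacent in the scan order are merged;
    runs shorter than ``min_run`` windows are discarded.  With ``refine``,
    island CDS boundaries are sharpened by per-CDS likelihood ratio (see
    :func:`_refine_boundaries`).  Islands are labelled ``contains_IS``
    when any annotated IS element overlaps their span.
    """
    stats = scan.stats
    sig = [st.p < alpha for st in stats]
    n_win = len(stats)
    if not any(sig):
        return []
    runs: list[list[int]] = []
    cur: list[int] = []
    for i, s in enumerate(sig):
        if s:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    # circular scan: a run touching the end joins one starting at 0
    if scan.circular and len(runs) > 1 and runs[0][0] == 0 and \
            runs[-1][-1] == n_win - 1:
        runs[0] = runs.pop() + runs[0]

    n_cds = len(scan.cds_ids)
    islands = []
    for run in runs:
        if len(run) < min_run:
            continue
        first = stats[run[0]].cds_range[0]
        last = stats[run[-1]].cds_range[1]
        length = (last - first) % n_cds + 1
        ordinals = [(first + k) % n_cds for k in range(length)]
        if refine and len(ordinals) > 2:
            ordinals = _refine_boundaries(scan, ordinals)
        span = (scan.cds_spans[ordinals[0]][0], scan.cds_spans[ordinals[-1]][1])
        islands.append(
            Island(
                replicon_id=scan.replicon_id,
                span=span,
                cds_range=(ordinals[0], ordinals[-1]),
                windows=list(run),
                min_p=min(stats[i].p for i in run),
                contains_is=_overlaps_is(r, span),
            )
        )
    return islands


def _overlaps_is(r: Replicon, span: tuple[int, int]) -> bool:
    s, e = span
    for f in r.features:
        if f.kind != "IS":
            continue
        if e >= s:
            if f.start < e and f.end > s:
                return True
        else:  # wrapped span
            if f.end > s or f.start < e:
                return True
    return False


def detect_islands(r: Replicon, window: int = DEFAULT_WINDOW, step: int = 1,
                   df: int = DEFAULT_DF, alpha: float = DEFAULT_ALPHA,
                   min_run: int = DEFAULT_MIN_RUN, refine: bool = True,
                   max_iter: int = 2,
                   excluded: frozenset[str] = DEFAULT_EXCLUDED
                   ) -> tuple[ScanResult, list[Island]]:
    """Scan + island calling with reference purification.

    A large divergent island contaminates the whole-replicon SCU table,
    which can make ordinary windows look significant against the mixture.
    After the first pass, the reference is rebuilt from CDSs outside any
    called island and the scan is repeated (``max_iter`` passes total).
    """
    scan = scan_replicon(r, window=window, step=step, df=df,
                         excluded=excluded)
    islands = call_islands(scan, r, alpha=alpha, min_run=min_run,
                           refine=refine)
    n = len(scan.cds_ids)
    for _ in range(max_iter - 1):
        if not islands:
            break
        inside: set[int] = set()
        for isl in islands:
            first, last = isl.cds_range
            length = (last - first) % n + 1
            inside.update((first + k) % n for k in range(length))
        outside = [scan.cds_codons[i] for i in range(n) if i not in inside]
        if not outside:
            break
        ref = build_scu(outside, excluded)
        scan = scan_replicon(r, window=window, step=step, df=df, ref=ref,
                             excluded=excluded)
        islands = call_islands(scan, r, alpha=alpha, min_run=min_run,
                               refine=refine)
    return scan, islands


def island_codon_counts(scan: ScanResult, island: Island) -> Counter:
    n = len(scan.cds_ids)
    first, last = island.cds_range
    length = (last - first) % n + 1
    return count_codons(
        [scan.cds_codons[(first + k) % n] for k in range(length)],
        scan.reference.excluded,
    )


def assign_reference(island: Island, island_counts: Counter,
                     references: dict[str, SCUTable], df: int = DEFAULT_DF,
                     alpha: float = DEFAULT_ALPHA) -> Island:
    """Test the island's pooled codon counts against candidate
    whole-replicon SCU tables; the best reference minimizes chi-square
    (ties break to the lexicographically smaller replicon id, logged).
    The island is called "similar" only if the best p >= alpha.
    """
    if len(references) < 2:
        raise ValueError("need >= 2 candidate references")
    results = []
    for rid in sorted(references):
        st = window_chi2(island_counts, references[rid], df=df)
        results.append((st.chi2, rid, st.p))
    results.sort()
    if len(results) > 1 and results[0][0] == results[1][0]:
        log.info("reference tie between %s and %s; smaller id wins",
                 results[0][1], results[1][1])
    best_chi2, best_id, best_p = results[0]
    island.best_reference = (best_id, best_chi2, best_p)
    island.similar_to_reference = best_p >= alpha
    return island
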