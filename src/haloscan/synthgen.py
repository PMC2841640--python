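"""Deterministic, seeded generator of annotated synthetic multi-replicon
genomes.

The generator emulates every statistical structure the analysis modules
assume: CDSs drawn from specified family-conditional codon-usage
profiles (host vs island), intergenic DNA at a controlled background GC,
AT-rich valleys, IS elements of a given GC with a tunable preference for
low-GC insertion context, a replication origin inducing strand-asymmetric
G/C choice (a V-shaped cumulative GC curve with vertex at the origin),
and a genetic-marker map offset by a constant plus jitter.  Identical
spec + seed give identical output; each replicon consumes its own
pseudo-random stream spawned from the master seed, so adding a replicon
does not perturb the others.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scu as _scu
from .genome_io import Feature, Replicon, revcomp, write_genome

MIN_GAP = 20
IS_MARGIN = 200

#: Default amino-acid frequencies for synthetic CDSs: the 18 degenerate
#: families uniform, Met and Trp rare (they carry no synonymous signal).
DEFAULT_AA_FREQ: dict[str, float] = {aa: 0.96 / 18 for aa in _scu.FAMILIES}
DEFAULT_AA_FREQ["M"] = 0.02
DEFAULT_AA_FREQ["W"] = 0.02


def codon_profile(gc3: float) -> dict[str, float]:
    """Family-conditional codon frequencies where a codon's weight depends
    on whether its third base is G/C (weight ``gc3``) or A/T (``1-gc3``)."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError("gc3 must be in [0, 1]")
    prof = {}
    for fam in _scu.FAMILIES.values():
        w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in fam],
                     dtype=float)
        if w.sum() == 0:
            w[:] = 1.0
        w /= w.sum()
        prof.update(dict(zip(fam, w)))
    return prof


@dataclass
class ISSpec:
    family: str
    count: int
    gc: float  # element GC fraction
    site_preference: float = 0.0  # weight exp(-preference * site GC%)
    length: int = 1400


@dataclass
class IslandSpec:
    start_cds: int
    n_cds: int
    profile: dict[str, float]


@dataclass
class MarkerMapSpec:
    n_markers: int
    offset_bp: int
    jitter_kb: float = 5.0
    n_gross_outliers: int = 0


@dataclass
class RepliconSpec:
    id: str
    length: int
    topology: str = "circular"
    gc: float = 0.60  # intergenic background GC fraction
    n_cds: int = 0
    cds_profile: dict[str, float] | None = None  # default codon_profile(0.7)
    mean_cds_codons: int = 250
    islands: list[IslandSpec] = field(default_factory=list)
    is_specs: list[ISSpec] = field(default_factory=list)
    ori: int | None = None
    skew: float = 0.0  # excess probability of G over C on the leading strand
    #: probability that a CDS is oriented so its composition reinforces the
    #: leading-strand G excess (real replicons co-orient genes with the
    #: fork); 0.5 = unbiased.  Only used when ``ori`` is set.
    cds_strand_bias: float = 0.5
    n_at_valleys: int = 0
    valley_gc: float = 0.45
    valley_length: int = 4000
    marker_map: MarkerMapSpec | None = None


@dataclass
class SynthSpec:
    seed: int
    replicons: list[RepliconSpec]


def _validate(rs: RepliconSpec) -> None:
    for p in (rs.gc, rs.valley_gc, rs.skew):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    spans = sorted((isl.start_cds, isl.start_cds + isl.n_cds)
                   for isl in rs.islands)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("island CDS spans overlap")
    for isl in rs.islands:
        if isl.start_cds + isl.n_cds > rs.n_cds:
            raise ValueError("island exceeds CDS count")
    if rs.skew > 0 and rs.ori is None:
        raise ValueError("skew asymmetry requires an origin position")


def _draw_intergenic(rng, n: int, gcf: float, pos0: int, L: int,
                     ori: int | None, g: float) -> str:
    """Intergenic bases with optional leading/lagging G-vs-C asymmetry."""
    strong = rng.random(n) < gcf
    if ori is not None and g > 0:
        pos = (np.arange(pos0, pos0 + n) - ori) % L
        g_eff = np.where(pos < L // 2, g, -g)
    else:
        g_eff = np.zeros(n)
    pick_g = rng.random(n) < (1.0 + g_eff) / 2.0
    pick_a = rng.random(n) < 0.5
    out = np.where(strong, np.where(pick_g, "G", "C"),
                   np.where(pick_a, "A", "T"))
    return "".join(out)


def _expected_strand_gc_diff(profile: dict[str, float],
                             aa_freq: dict[str, float]) -> float:
    """Expected G-minus-C count per codon on the coding strand."""
    b = 0.0
    for aa, fam in _scu.FAMILIES.items():
        w = np.array([profile[c] for c in fam], dtype=float)
        if w.sum() <= 0:
            continue
        w /= w.sum()
        b += aa_freq.get(aa, 0.0) * sum(
            wi * (c.count("G") - c.count("C")) for wi, c in zip(w, fam))
    return b


def _profile_tables(profile: dict[str, float]) -> dict[str, tuple]:
    """aa -> (codon family, normalized cumulative weights) for sampling."""
    tables = {"M": (("ATG",), np.array([1.0])),
              "W": (("TGG",), np.array([1.0]))}
    for aa, fam in _scu.FAMILIES.items():
        w = np.array([profile[c] for c in fam], dtype=float)
        if w.sum() <= 0:
            w[:] = 1.0
        tables[aa] = (fam, np.cumsum(w / w.sum()))
    return tables


def _draw_cds(rng, n_codons: int, tables: dict[str, tuple],
              aa_freq: dict[str, float]) -> tuple[str, str]:
    """(nucleotide sequence incl. stop, amino-acid string incl. initial M)."""
    aas = list(aa_freq)
    probs = np.array([aa_freq[a] for a in aas])
    probs /= probs.sum()
    body = rng.choice(len(aas), size=n_codons - 2, p=probs)
    u = rng.random(n_codons - 2)
    codons = ["ATG"]
    aa_str = ["M"]
    for ai, ui in zip(body, u):
        aa = aas[ai]
        fam, cum = tables[aa]
        codons.append(fam[int(np.searchsorted(cum, ui * cum[-1]))])
        aa_str.append(aa)
    codons.append("TAA" if rng.random() < 0.5 else "TGA")
    return "".join(codons), "".join(aa_str)


def _generate_replicon(rs: RepliconSpec, rng) -> tuple[Replicon, dict]:
    _validate(rs)
    profile = rs.cds_profile or codon_profile(0.7)
    island_of = {}
    for k, isl in enumerate(rs.islands):
        for i in range(isl.start_cds, isl.start_cds + isl.n_cds):
            island_of[i] = k

    # CDS sizes in codons
    if rs.n_cds:
        sizes = np.maximum(
            60, rng.lognormal(np.log(rs.mean_cds_codons) - 0.045, 0.3,
                              rs.n_cds).astype(int))
    else:
        sizes = np.array([], dtype=int)
    total_cds_bp = int(3 * sizes.sum())
    n_is = sum(s.count for s in rs.is_specs)
    is_bp = sum(s.count * s.length for s in rs.is_specs)
    n_gaps = max(rs.n_cds if rs.topology == "circular" else rs.n_cds + 1, 1)
    budget = rs.length - total_cds_bp - is_bp
    if rs.n_at_valleys > n_gaps:
        raise ValueError("more AT valleys than intergenic gaps")
    budget -= rs.n_at_valleys * rs.valley_length
    n_plain = n_gaps - rs.n_at_valleys
    if budget < n_plain * MIN_GAP:
        raise ValueError("requested features exceed replicon capacity")

    valley_gaps = set(rng.choice(n_gaps, size=rs.n_at_valleys,
                                 replace=False).tolist())
    gap_len = np.full(n_gaps, MIN_GAP, dtype=int)
    extra = budget - n_plain * MIN_GAP
    plain = np.array([i for i in range(n_gaps) if i not in valley_gaps])
    if extra > 0 and len(plain):
        # heavy-tailed gap lengths (real intergenic spacers are mostly
        # short with a few long ones): Dirichlet-multinomial, alpha 0.3
        p = rng.dirichlet(np.full(len(plain), 0.3))
        add = rng.multinomial(extra, p)
        gap_len[plain] += add
    for i in valley_gaps:
        gap_len[i] = rs.valley_length
    gap_gc = np.full(n_gaps, rs.gc)
    for i in valley_gaps:
        gap_gc[i] = rs.valley_gc

    # choose IS host gaps, weighted toward low-GC context
    is_in_gap: dict[int, list[ISSpec]] = {}
    taken: set[int] = set()
    for spec_ in rs.is_specs:
        eligible = np.array([i for i in range(n_gaps)
                             if gap_len[i] >= spec_.length + 2 * IS_MARGIN
                             and i not in taken])
        if len(eligible) < spec_.count:
            raise ValueError(
                f"not enough intergenic gaps for {spec_.count} x "
                f"{spec_.family}")
        w = np.exp(-spec_.site_preference * 100.0 * gap_gc[eligible])
        w /= w.sum()
        chosen = rng.choice(eligible, size=spec_.count, replace=False, p=w)
        for i in chosen:
            is_in_gap.setdefault(int(i), []).append(spec_)
            taken.add(int(i))

    # assemble
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    truth = dict(id=rs.id, length=rs.length, background_gc=rs.gc,
                 n_cds=rs.n_cds, ori=rs.ori, skew=rs.skew,
                 islands=[], is_sites=[], cds_spans=[])
    is_counter = 0

    def emit_gap(gi: int):
        nonlocal pos, is_counter
        glen, gcf = int(gap_len[gi]), float(gap_gc[gi])
        specs_here = is_in_gap.get(gi, [])
        if specs_here:
            spec_ = specs_here[0]
            off = int(rng.integers(IS_MARGIN, glen - IS_MARGIN + 1))
            left = _draw_intergenic(rng, off, gcf, pos, rs.length, rs.ori,
                                    rs.skew)
            parts.append(left)
            pos += off
            elem = _draw_intergenic(rng, spec_.length, spec_.gc, pos,
                                    rs.length, None, 0.0)
            fid = f"{rs.id}_is{is_counter:03d}"
            is_counter += 1
            features.append(Feature("IS", pos, pos + spec_.length, "+",
                                    fid, spec_.family))
            truth["is_sites"].append((fid, pos, pos + spec_.length,
                                      spec_.family))
            parts.append(elem)
            pos += spec_.length
            rest = glen - off
            parts.append(_draw_intergenic(rng, rest, gcf, pos, rs.length,
                                          rs.ori, rs.skew))
            pos += rest
        else:
            parts.append(_draw_intergenic(rng, glen, gcf, pos, rs.length,
                                          rs.ori, rs.skew))
            pos += glen

    host_tables = _profile_tables(profile)
    island_tables = [_profile_tables(isl.profile) for isl in rs.islands]
    for ci in range(rs.n_cds):
        emit_gap(ci)
        tables = host_tables
        if ci in island_of:
            tables = island_tables[island_of[ci]]
        nt, aa = _draw_cds(rng, int(sizes[ci]), tables, DEFAULT_AA_FREQ)
        u = rng.random()
        if rs.ori is not None and rs.cds_strand_bias != 0.5:
            prof = rs.islands[island_of[ci]].profile if ci in island_of \
                else profile
            b = _expected_strand_gc_diff(prof, DEFAULT_AA_FREQ)
            mid = pos + len(nt) // 2
            leading = ((mid - rs.ori) % rs.length) < rs.length // 2
            # orientation whose genome-forward text carries excess G here
            reinforce = "+" if (b >= 0) == leading else "-"
            other = "-" if reinforce == "+" else "+"
            strand = reinforce if u < rs.cds_strand_bias else other
        else:
            strand = "+" if u < 0.5 else "-"
        seg = nt if strand == "+" else revcomp(nt)
        fid = f"{rs.id}_c{ci:04d}"
        features.append(Feature("CDS", pos, pos + len(nt), strand, fid,
                                translation=aa))
        truth["cds_spans"].append((fid, pos, pos + len(nt), strand))
        parts.append(seg)
        pos += len(nt)
    for gi in range(rs.n_cds, n_gaps):
        emit_gap(gi)

    seq = "".join(parts)
    assert len(seq) == rs.length, (len(seq), rs.length)

    for isl in rs.islands:
        s = truth["cds_spans"][isl.start_cds][1]
        e = truth["cds_spans"][isl.start_cds + isl.n_cds - 1][2]
        truth["islands"].append(
            dict(start_cds=isl.start_cds,
                 end_cds=isl.start_cds + isl.n_cds - 1,
                 start_bp=s, end_bp=e))

    r = Replicon(rs.id, seq, rs.topology, features)

    markers = None
    if rs.marker_map is not None:
        markers = _make_markers(rs, truth, rng)
        truth["marker_offset_bp"] = rs.marker_map.offset_bp
    return r, dict(truth=truth, markers=markers)


def _make_markers(rs: RepliconSpec, truth: dict, rng) -> pd.DataFrame:
    mm = rs.marker_map
    spans = truth["cds_spans"]
    if mm.n_markers > len(spans):
        raise ValueError("more markers than CDSs")
    idx = np.linspace(0, len(spans) - 1, mm.n_markers).astype(int)
    rows = []
    for j, i in enumerate(idx):
        fid, s, e, _ = spans[i]
        gs, ge = s + 1, e  # 1-based inclusive
        # map error is mostly locus placement (shared by both endpoints,
        # the map's ~10 kb resolution) plus a small independent part
        shared = rng.uniform(-mm.jitter_kb, mm.jitter_kb)
        ms = (gs - mm.offset_bp) / 1000.0 + shared + rng.uniform(-0.1, 0.1)
        me = (ge - mm.offset_bp) / 1000.0 + shared + rng.uniform(-0.1, 0.1)
        if j < mm.n_gross_outliers:
            gene_kb = (ge - gs) / 1000.0
            ms += 50.0
            me = ms + 3.0 * gene_kb  # length discrepancy flags this marker
        rows.append(dict(name=fid, map_start_kb=ms, map_end_kb=me,
                         genome_start=gs, genome_end=ge))
    return pd.DataFrame(rows)


def generate(spec: SynthSpec) -> tuple[list[Replicon], dict]:
    """Generate all replicons; returns (replicons, manifest).

    The manifest maps replicon id to its ground truth (island spans, IS
    sites, origin, marker offset, ...) and carries any marker tables
    under ``manifest[rid]["markers"]``.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.replicons))
    replicons, manifest = [], {}
    for rs, ss in zip(spec.replicons, streams):
        r, info = _generate_replicon(rs, np.random.default_rng(ss))
        replicons.append(r)
        manifest[rs.id] = dict(info["truth"], markers=info["markers"])
    return replicons, manifest


def generate_to_dir(spec: SynthSpec, out_dir, prefix="synthetic") -> dict:
    """Generate and write FASTA + GFF3 + protein FASTA + marker TSVs +
    manifest TSV; returns the written paths."""
    import os

    replicons, manifest = generate(spec)
    paths = write_genome(replicons, out_dir, prefix=prefix)
    rows = []
    for rid, info in manifest.items():
        mk = info.get("markers")
        if mk is not None:
            p = os.path.join(out_dir, f"{prefix}.{rid}.markers.tsv")
            mk.to_csv(p, sep="\t", index=False)
            paths[f"markers_{rid}"] = p
        for isl in info["islands"]:
            rows.append(dict(replicon=rid, kind="island", **isl))
        for fid, s, e, fam in info["is_sites"]:
            rows.append(dict(replicon=rid, kind="is_site", id=fid,
                             start_bp=s, end_bp=e, family=fam))
        if info["ori"] is not None:
            rows.append(dict(replicon=rid, kind="ori", start_bp=info["ori"]))
    man_path = os.path.join(out_dir, f"{prefix}.manifest.tsv")
    with open(man_path, "w") as fh:
        fh.write("# haloscan synthetic-genome manifest v1\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    paths["manifest"] = man_path
    return paths


def null_window_sampler(ref: _scu.SCUTable, n_windows: int,
                        window_size: int = 30, seed: int = 0,
                        mean_cds_codons: int = 250) -> list[Counter]:
    """Codon-count windows sampled from a reference SCU table's
    family-conditional frequencies — the null for chi-square calibration.

    Amino-acid counts per window follow the reference's amino-acid
    composition with CDS lengths drawn from the generator's empirical
    length model.
    """
    rng = np.random.default_rng(seed)
    aas = [a for a in _scu.FAMILIES if ref.aa_counts.get(a, 0) > 0]
    aa_probs = np.array([ref.aa_counts[a] for a in aas], dtype=float)
    aa_probs /= aa_probs.sum()
    fam_freqs = {}
    for a in aas:
        fam = _scu.FAMILIES[a]
        w = np.array([ref.codon_freq.get(c, 0.0) for c in fam])
        if w.sum() <= 0:
            continue
        fam_freqs[a] = (fam, w / w.sum())
    windows = []
    for _ in range(n_windows):
        lengths = np.maximum(
            60, rng.lognormal(np.log(mean_cds_codons) - 0.045, 0.3,
                              window_size).astype(int))
        n_codons = int(lengths.sum())
        aa_counts = rng.multinomial(n_codons, aa_probs)
        counts: Counter = Counter()
        for a, n_aa in zip(aas, aa_counts):
            if n_aa == 0 or a not in fam_freqs:
                continue
            fam, w = fam_freqs[a]
            draw = rng.multinomial(n_aa, w)
            for c, n in zip(fam, draw):
                if n:
                    counts[c] += int(n)
        windows.append(counts)
    return windows
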