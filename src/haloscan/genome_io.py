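"""Reading, writing and normalizing annotated replicon sequences.

All coordinates are internal 0-based half-open; GenBank/GFF3 1-based
inclusive coordinates are converted on read, and emitted reports use
1-based inclusive again (BED/bedGraph stay 0-based half-open per their
standards).  A feature that wraps the origin of a circular replicon is
stored as origin-split parts sharing one feature id, ordered by ``part``.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "IS", "tRNA", "rRNA", "other")

#: Annotation label substrings that mark a feature as an insertion sequence.
#: IS elements are recognized from annotation labels, not detected de novo.
DEFAULT_IS_PATTERNS = ("ISH51", "IS4", "transposase")


@dataclass
class Feature:
    """One annotated feature on a replicon.

    ``start``/``end`` are 0-based half-open on the forward strand.  A
    circular-wrapping feature is represented as two Features sharing
    ``id`` with ``part`` 0 and 1 in 5'->3' order of the coding sequence.
    """

    kind: str
    start: int
    end: int
    strand: str = "+"
    id: str = ""
    label: str = ""
    translation: str | None = None
    partial: bool = False
    part: int = 0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.id!r}: invalid span ({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    """A named DNA sequence (circular or linear) with its features."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.sequence = _normalize_sequence(self.sequence, self.id)
        self.features.sort(key=lambda f: (f.start, f.id, f.part))
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.id!r} span ({f.start},{f.end}) exceeds "
                    f"replicon length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def cds_groups(self) -> list[tuple[str, list[Feature]]]:
        """CDS features grouped by id, parts in 5'->3' order, groups ordered
        by the genomic start of their first part."""
        groups: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.kind == "CDS":
                groups.setdefault(f.id, []).append(f)
        out = []
        for fid, parts in groups.items():
            parts.sort(key=lambda f: f.part)
            out.append((fid, parts))
        out.sort(key=lambda t: t[1][0].start)
        return out


def _normalize_sequence(seq: str, rid: str) -> str:
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        log.warning("replicon %s: ambiguity codes %s mapped to N", rid, bad)
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# reading


def _classify(feature_type: str, label: str, is_patterns) -> str:
    lab = label.upper()
    if feature_type in ("tRNA", "rRNA"):
        return feature_type
    if feature_type in ("mobile_element", "repeat_region", "IS"):
        return "IS"
    if any(p.upper() in lab for p in is_patterns):
        return "IS"
    if feature_type == "CDS":
        return "CDS"
    return "other"


def read_genome(
    paths,
    format: str = "genbank",
    is_patterns=DEFAULT_IS_PATTERNS,
) -> list[Replicon]:
    """Read one or more files into Replicon objects.

    ``format`` is ``"genbank"`` (flat files, possibly multi-record) or
    ``"fasta+gff3"`` (paths holds FASTA and GFF3 files, matched by record
    id).  CDS translations are taken from the file when present, otherwise
    translated with the bacterial/archaeal code (table 11).
    """
    paths = [os.fspath(p) for p in paths]
    if format == "genbank":
        replicons = []
        for p in paths:
            for rec in SeqIO.parse(p, "genbank"):
                replicons.append(_replicon_from_genbank(rec, is_patterns))
        return replicons
    if format == "fasta+gff3":
        return _read_fasta_gff3(paths, is_patterns)
    raise ValueError(f"unknown format {format!r}")


def _replicon_from_genbank(rec, is_patterns) -> Replicon:
    topology = rec.annotations.get("topology", "circular")
    feats: list[Feature] = []
    counter = 0
    length = len(rec.seq)
    for sf in rec.features:
        if sf.type in ("source", "gene"):
            continue
        label = ""
        for key in ("product", "mobile_element_type", "note", "label"):
            if key in sf.qualifiers:
                label = sf.qualifiers[key][0]
                break
        kind = _classify(sf.type, label, is_patterns)
        if kind == "other" and sf.type not in ("misc_feature", "CDS"):
            continue
        fid = sf.qualifiers.get("locus_tag", [f"{rec.id}_f{counter}"])[0]
        counter += 1
        translation = sf.qualifiers.get("translation", [None])[0]
        partial = "<" in str(sf.location) or ">" in str(sf.location)
        parts = sorted(sf.location.parts, key=lambda loc: loc.start)
        strand = "+" if (sf.location.strand or 1) >= 0 else "-"
        if len(parts) > 1 and parts[-1].end == length and parts[0].start == 0:
            # origin-wrapping join: 5'->3' order is [x..L) then [0..y)
            ordered = [parts[-1], parts[0]] if strand == "+" else parts
        else:
            ordered = parts if strand == "+" else parts[::-1]
        for i, loc in enumerate(ordered):
            feats.append(
                Feature(
                    kind=kind,
                    start=int(loc.start),
                    end=int(loc.end),
                    strand=strand,
                    id=fid,
                    label=label,
                    translation=translation if i == 0 else None,
                    partial=partial,
                    part=i,
                )
            )
    return Replicon(rec.id, str(rec.seq), topology, feats)


def _read_fasta_gff3(paths, is_patterns) -> list[Replicon]:
    import gffutils

    fastas = [p for p in paths if os.path.splitext(p)[1].lower() in
              (".fa", ".fasta", ".fna")]
    gffs = [p for p in paths if os.path.splitext(p)[1].lower() in
            (".gff", ".gff3")]
    if not fastas or not gffs:
        raise ValueError("fasta+gff3 format needs at least one FASTA and one GFF3 path")
    seqs: dict[str, tuple[str, str]] = {}
    for p in fastas:
        for rec in SeqIO.parse(p, "fasta"):
            topo = "linear" if "linear" in rec.description.lower() else "circular"
            seqs[rec.id] = (str(rec.seq), topo)
    feats: dict[str, list[Feature]] = {rid: [] for rid in seqs}
    for p in gffs:
        db = gffutils.create_db(
            p, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for sf in db.all_features():
            if sf.featuretype in ("region", "gene"):
                continue
            if sf.seqid not in seqs:
                raise ValueError(f"{p}: GFF3 seqid {sf.seqid!r} has no FASTA record")
            label = (sf.attributes.get("product") or sf.attributes.get("Name") or [""])[0]
            kind = _classify(sf.featuretype, label, is_patterns)
            fid = (sf.attributes.get("ID") or [f"{sf.seqid}_f{len(feats[sf.seqid])}"])[0]
            part = int((sf.attributes.get("part") or ["0"])[0])
            feats[sf.seqid].append(
                Feature(
                    kind=kind,
                    start=sf.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                    end=sf.end,
                    strand=sf.strand if sf.strand in "+-" else "+",
                    id=fid,
                    label=label,
                    partial="true" in [v.lower() for v in
                                       (sf.attributes.get("partial") or [])],
                    part=part,
                )
            )
    out = []
    for rid, (seq, topo) in seqs.items():
        r = Replicon(rid, seq, topo, feats.get(rid, []))
        _fill_translations(r)
        out.append(r)
    return out


def _fill_translations(r: Replicon) -> None:
    for fid, codons in extract_cds_codons(r):
        first = next(f for f in r.features if f.id == fid and f.kind == "CDS")
        if first.translation is None:
            aa = str(Seq("".join(codons)).translate(table=11)).rstrip("*")
            first.translation = aa


# ---------------------------------------------------------------------------
# codon extraction


def extract_cds_codons(r: Replicon) -> list[tuple[str, list[str]]]:
    """Codon lists (5'->3', stop retained) for every usable CDS.

    Minus-strand CDSs are reverse-complemented; multi-part CDSs (origin
    wraps) are concatenated in part order.  CDSs flagged partial or whose
    length is not a multiple of 3 are excluded with a warning.
    """
    out = []
    for fid, parts in r.cds_groups():
        seq = "".join(r.sequence[f.start:f.end] for f in parts)
        if parts[0].strand == "-":
            seq = revcomp(seq)
        if any(f.partial for f in parts):
            continue
        if len(seq) % 3 != 0:
            warnings.warn(
                f"CDS {fid} on {r.id}: length {len(seq)} not a multiple of 3; "
                "excluded from codon analyses"
            )
            continue
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        out.append((fid, codons))
    return out


# ---------------------------------------------------------------------------
# writing


def write_genome(replicons, out_dir, prefix="genome") -> dict[str, str]:
    """Write FASTA + GFF3 + protein FASTA; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, f"{prefix}.fna")
    gff = os.path.join(out_dir, f"{prefix}.gff3")
    faa = os.path.join(out_dir, f"{prefix}.faa")
    with open(fasta, "w") as fh:
        for r in replicons:
            fh.write(f">{r.id} topology={r.topology}\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i:i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in replicons:
            fh.write(f"##sequence-region {r.id} 1 {r.length}\n")
            for f in r.features:
                ftype = {"CDS": "CDS", "IS": "mobile_element",
                         "tRNA": "tRNA", "rRNA": "rRNA"}.get(f.kind, "misc_feature")
                attrs = [f"ID={f.id}"]
                if f.label:
                    attrs.append(f"product={f.label}")
                if f.part:
                    attrs.append(f"part={f.part}")
                if f.partial:
                    attrs.append("partial=true")
                fh.write(
                    "\t".join(
                        [r.id, "haloscan", ftype, str(f.start + 1), str(f.end),
                         ".", f.strand, "0" if f.kind == "CDS" else ".",
                         ";".join(attrs)]
                    )
                    + "\n"
                )
    with open(faa, "w") as fh:
        for r in replicons:
            for fid, parts in r.cds_groups():
                aa = parts[0].translation
                if aa is None:
                    continue
                fh.write(f">{fid} replicon={r.id}\n")
                for i in range(0, len(aa), 70):
                    fh.write(aa[i:i + 70] + "\n")
    return {"fasta": fasta, "gff3": gff, "faa": faa}


def write_feature_table(replicons, path) -> None:
    """Normalized feature table, 1-based inclusive coordinates."""
    import pandas as pd

    rows = []
    for r in replicons:
        for f in r.features:
            rows.append(
                dict(replicon=r.id, id=f.id, kind=f.kind, start=f.start + 1,
                     end=f.end, strand=f.strand, label=f.label, part=f.part)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(path, rows) -> None:
    """rows: iterable of (chrom, start0, end, name[, score])."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path, chrom, starts, ends, values) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if v is None:
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
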