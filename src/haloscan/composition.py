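"""GC-content metrics and the windowed base-composition chi-square track.

Percentages are over unambiguous bases only: N never enters a numerator
or denominator.  Windowed scans wrap around the origin on circular
replicons and default to a 5 kb window with 1 kb stride, wide enough to
resolve multi-kb composition anomalies while keeping per-window counts
in the thousands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import Replicon, extract_cds_codons

log = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # translation table 11

DEFAULT_WINDOW = 5000
DEFAULT_STRIDE = 1000


@dataclass
class CompositionProfile:
    replicon_id: str
    global_gc: float
    coding_gc: float | None
    noncoding_gc: float | None
    pos_gc: tuple[float, float, float] | None
    percent_coding: float
    window_gc: list[tuple[int, float | None]]
    window_chi2: list[tuple[int, float]]


def base_counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in BASES}


def gc_percent(seq: str) -> float | None:
    """100*(G+C)/(A+C+G+T); ``None`` if the slice has no unambiguous base."""
    if not seq:
        raise ValueError("empty sequence slice")
    c = base_counts(seq)
    denom = sum(c.values())
    if denom == 0:
        return None
    return 100.0 * (c["G"] + c["C"]) / denom


def _cumulative_indicators(seq: str) -> dict[str, np.ndarray]:
    """Per-base indicator prefix sums, index i = count in seq[:i]."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = {}
    for b in BASES:
        ind = (arr == ord(b)).astype(np.int64)
        out[b] = np.concatenate([[0], np.cumsum(ind)])
    return out


def _window_counts(cums: dict[str, np.ndarray], L: int, starts: np.ndarray,
                   window: int, circular: bool) -> np.ndarray:
    """(n_windows, 4) base counts, wrapping if circular."""
    ends = starts + window
    counts = np.empty((len(starts), 4), dtype=np.int64)
    for j, b in enumerate(BASES):
        cs = cums[b]
        if circular:
            wrap = ends > L
            e = np.where(wrap, L, ends)
            counts[:, j] = cs[e] - cs[starts]
            counts[wrap, j] += cs[np.where(wrap, ends - L, 0)[wrap]]
        else:
            counts[:, j] = cs[ends] - cs[starts]
    return counts


def _window_starts(L: int, window: int, stride: int, circular: bool) -> np.ndarray:
    if window > L:
        raise ValueError(f"window {window} exceeds replicon length {L}")
    if circular:
        return np.arange(0, L, stride)
    return np.arange(0, L - window + 1, stride)


def windowed_gc(r: Replicon, window: int = DEFAULT_WINDOW,
                stride: int = DEFAULT_STRIDE) -> list[tuple[int, float | None]]:
    circular = r.topology == "circular"
    starts = _window_starts(r.length, window, stride, circular)
    counts = _window_counts(_cumulative_indicators(r.sequence), r.length,
                            starts, window, circular)
    tot = counts.sum(axis=1)
    gc = counts[:, 1] + counts[:, 2]
    out = []
    for s, t, g in zip(starts, tot, gc):
        out.append((int(s), 100.0 * g / t if t else None))
    return out


def window_composition_chi2(r: Replicon, window: int = DEFAULT_WINDOW,
                            stride: int = DEFAULT_STRIDE) -> list[tuple[int, float]]:
    """Per-window chi-square deviation of base composition from the
    replicon-wide base frequencies.

    chi2 = sum_b (obs_b - L*p_b)^2 / (L*p_b) with L the window's non-N
    count.  A base absent from the whole replicon is skipped with a warning.
    """
    circular = r.topology == "circular"
    whole = base_counts(r.sequence)
    total = sum(whole.values())
    if total == 0:
        raise ValueError(f"replicon {r.id}: all-N sequence")
    p = np.array([whole[b] / total for b in BASES])
    usable = p > 0
    if not usable.all():
        log.warning("replicon %s: bases %s absent genome-wide; their chi2 "
                    "terms are skipped",
                    r.id, [b for b, u in zip(BASES, usable) if not u])
    starts = _window_starts(r.length, window, stride, circular)
    counts = _window_counts(_cumulative_indicators(r.sequence), r.length,
                            starts, window, circular)
    Lw = counts.sum(axis=1).astype(float)
    exp = Lw[:, None] * p[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - exp) ** 2 / exp
    terms[:, ~usable] = 0.0
    terms[exp == 0] = 0.0
    chi2 = terms.sum(axis=1)
    return [(int(s), float(v)) for s, v in zip(starts, chi2)]


def _cds_union_mask(r: Replicon) -> np.ndarray:
    mask = np.zeros(r.length, dtype=bool)
    for f in r.features:
        if f.kind == "CDS":
            mask[f.start:f.end] = True
    return mask


def coding_noncoding_gc(r: Replicon) -> tuple[float | None, float | None, float]:
    """(coding GC%, noncoding GC%, percent coding).

    Coding bases are the union of CDS spans (overlaps counted once).
    """
    mask = _cds_union_mask(r)
    if not mask.any():
        raise ValueError(f"replicon {r.id}: no CDS features")
    arr = np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))

    def _gc(sel):
        denom = int((is_acgt & sel).sum())
        return 100.0 * int((is_gc & sel).sum()) / denom if denom else None

    percent_coding = 100.0 * int(mask.sum()) / r.length
    return _gc(mask), _gc(~mask), percent_coding


def codon_position_gc(codon_lists, include_stop: bool = False
                      ) -> tuple[float, float, float]:
    """GC% at codon positions 1..3 pooled over all codons of all CDSs.

    ``codon_lists`` is an iterable of codon-string lists (one per CDS),
    e.g. the second elements of :func:`extract_cds_codons` output.  Stop
    codons are excluded by default; codons containing N are skipped.
    """
    gc = np.zeros(3, dtype=np.int64)
    tot = np.zeros(3, dtype=np.int64)
    for codons in codon_lists:
        for codon in codons:
            if "N" in codon:
                continue
            if not include_stop and codon in STOP_CODONS:
                continue
            for i, b in enumerate(codon):
                tot[i] += 1
                if b in "GC":
                    gc[i] += 1
    if tot.sum() == 0:
        raise ValueError("no usable codons")
    return tuple(100.0 * g / t for g, t in zip(gc, tot))


def composition_profile(r: Replicon, window: int = DEFAULT_WINDOW,
                        stride: int = DEFAULT_STRIDE,
                        include_stop: bool = False) -> CompositionProfile:
    has_cds = any(f.kind == "CDS" for f in r.features)
    coding = noncoding = pos = None
    pct_coding = 0.0
    if has_cds:
        coding, noncoding, pct_coding = coding_noncoding_gc(r)
        codon_lists = [c for _, c in extract_cds_codons(r)]
        if codon_lists:
            pos = codon_position_gc(codon_lists, include_stop=include_stop)
    return CompositionProfile(
        replicon_id=r.id,
        global_gc=gc_percent(r.sequence),
        coding_gc=coding,
        noncoding_gc=noncoding,
        pos_gc=pos,
        percent_coding=pct_coding,
        window_gc=windowed_gc(r, window, stride),
        window_chi2=window_composition_chi2(r, window, stride),
    )
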