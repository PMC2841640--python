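"""GC context of insertion-sequence (IS) elements and a permutation test
of the IS-avoidance hypothesis.

Haloarchaeal genomes appear to be "evolving away" from the composition
their IS elements prefer: in a GC-rich genome the AT-rich IS elements sit
in locally AT-rich (largely non-coding) context.  The original
observation was graphical; this module formalizes it as a one-sided
permutation test on the mean GC of fixed-width flanks at the observed
insertion sites versus flanks at random positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import gc_percent, windowed_gc
from .genome_io import Replicon

DEFAULT_FLANK = 500
DEFAULT_N_PERM = 1000


@dataclass
class ISContextResult:
    replicon_id: str
    per_is: pd.DataFrame  # id, family, element_gc, host_gc
    mean_element_gc: float
    mean_host_gc: float
    p_value: float
    n_permutations: int
    seed: int
    flank: int


def is_gc_overlay(r: Replicon, window: int = 5000):
    """(genome GC windows, per-IS (position, GC) marks) for plotting or
    track emission.  The mark GC is the element's own sequence GC."""
    track = windowed_gc(r, window=window, stride=window)
    is_feats = r.features_of_kind("IS")
    if not is_feats:
        import logging
        logging.getLogger(__name__).warning(
            "replicon %s: no annotated IS elements", r.id)
    marks = pd.DataFrame(
        [dict(id=f.id, position=f.start, family=f.label,
              gc=gc_percent(r.sequence[f.start:f.end]))
         for f in is_feats],
        columns=["id", "position", "family", "gc"],
    )
    return track, marks


def _flank_gc_means(gc_cum: np.ndarray, acgt_cum: np.ndarray, L: int,
                    circular: bool, lefts: np.ndarray, rights: np.ndarray,
                    flank: int) -> float:
    """Mean GC%% over left flanks [l-flank, l) and right flanks
    [r, r+flank), wrapped if circular."""

    def seg(starts, ends):
        if circular:
            starts = starts % L
            ends0 = starts + flank
            wrap = ends0 > L
            e = np.where(wrap, L, ends0)
            g = gc_cum[e] - gc_cum[starts]
            t = acgt_cum[e] - acgt_cum[starts]
            g = g + np.where(wrap, gc_cum[ends0 - L], 0)
            t = t + np.where(wrap, acgt_cum[ends0 - L], 0)
        else:
            g = gc_cum[ends] - gc_cum[starts]
            t = acgt_cum[ends] - acgt_cum[starts]
        return g, t

    lg, lt = seg((lefts - flank) % L if circular else lefts - flank,
                 lefts)
    rg, rt = seg(rights, rights + flank)
    g = np.concatenate([lg, rg]).sum()
    t = np.concatenate([lt, rt]).sum()
    return 100.0 * g / t if t else np.nan


def insertion_site_permutation_test(
    r: Replicon,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
) -> ISContextResult:
    """One-sided permutation test: are IS insertion sites AT-richer than
    random positions?

    The statistic T is the mean GC of ``flank``-bp windows on each side of
    each IS element (the element itself excluded).  The null resamples the
    same number of positions uniformly, avoiding annotated IS spans, and
    p = (1 + #{T_null <= T_obs}) / (1 + n_perm).
    """
    is_feats = r.features_of_kind("IS")
    if not is_feats:
        raise ValueError(f"replicon {r.id}: no IS elements")
    circular = r.topology == "circular"
    L = r.length
    if not circular and any(f.start < flank or f.end + flank > L
                            for f in is_feats):
        raise ValueError("linear replicon too short for the flank width "
                         "at some IS site")
    if L < 2 * flank + 2:
        raise ValueError("replicon shorter than the flank requirement")

    arr = np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc.astype(np.int64))])
    acgt_cum = np.concatenate([[0], np.cumsum(is_acgt.astype(np.int64))])

    lefts = np.array([f.start for f in is_feats])
    rights = np.array([f.end for f in is_feats])
    t_obs = _flank_gc_means(gc_cum, acgt_cum, L, circular, lefts, rights,
                            flank)

    in_is = np.zeros(L, dtype=bool)
    for f in is_feats:
        in_is[f.start:f.end] = True
    allowed = np.flatnonzero(~in_is)
    if not circular:
        allowed = allowed[(allowed >= flank) & (allowed <= L - flank)]
    if allowed.size == 0:
        raise ValueError("no allowed positions outside IS spans")

    rng = np.random.default_rng(seed)
    k = len(is_feats)
    hits = 0
    for _ in range(n_perm):
        pos = rng.choice(allowed, size=k, replace=False)
        t_null = _flank_gc_means(gc_cum, acgt_cum, L, circular, pos, pos,
                                 flank)
        if t_null <= t_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)

    per_is = pd.DataFrame(
        [dict(
            id=f.id, family=f.label,
            element_gc=gc_percent(r.sequence[f.start:f.end]),
            host_gc=_flank_gc_means(gc_cum, acgt_cum, L, circular,
                                    np.array([f.start]), np.array([f.end]),
                                    flank),
        ) for f in is_feats]
    )
    return ISContextResult(
        replicon_id=r.id,
        per_is=per_is,
        mean_element_gc=float(per_is["element_gc"].mean()),
        mean_host_gc=float(t_obs),
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        flank=flank,
    )
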