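"""Protein isoelectric points under a Henderson-Hasselbalch group-charge
model, and proteome-level pI summaries.

Net charge at a given pH sums the protonated fraction of the basic groups
(N-terminus, His, Lys, Arg) minus the deprotonated fraction of the acidic
groups (C-terminus, Asp, Glu, Cys, Tyr):

    Q(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH))

Q is strictly decreasing in pH whenever at least one ionizable group is
present, so the isoelectric point is the unique root on [0, 14], found by
bisection.  Two published pKa sets ship as a packaged table: ``embl``
(the default, the EMBL set of the Bioperl pI calculator) and
``dtaselect`` for sensitivity checks — individual pIs can move by a few
tenths of a pH unit between sets (most for strongly acidic proteins), so
distribution summaries should state the set used.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

BASIC = ("H", "K", "R")
ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PKaSet:
    name: str
    side_chain: dict[str, float]  # residue -> pKa, residues in BASIC+ACIDIC
    n_term: float
    c_term: float

    def __post_init__(self):
        for v in (*self.side_chain.values(), self.n_term, self.c_term):
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {v} outside (0, 14)")


def _load_pka_sets() -> dict[str, PKaSet]:
    path = resources.files("haloscan.data").joinpath("pka_sets.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    out = {}
    for name, sub in df.groupby("set"):
        vals = dict(zip(sub["group"], sub["pka"]))
        out[name] = PKaSet(
            name=name,
            side_chain={r: vals[r] for r in BASIC + ACIDIC},
            n_term=vals["Nterm"],
            c_term=vals["Cterm"],
        )
    return out


PKA_SETS: dict[str, PKaSet] = _load_pka_sets()
DEFAULT_PKA = PKA_SETS["embl"]


@dataclass
class PiResult:
    protein_id: str
    pI: float
    replicon_id: str | None = None
    protein_class: str | None = None


def _group_pkas(seq: str, pka: PKaSet):
    """(basic pKas with counts, acidic pKas with counts) for a sequence.
    Unknown residues are ignored; termini always contribute."""
    seq = seq.upper()
    basic = [(pka.n_term, 1)] + [(pka.side_chain[r], seq.count(r))
                                 for r in BASIC]
    acidic = [(pka.c_term, 1)] + [(pka.side_chain[r], seq.count(r))
                                  for r in ACIDIC]
    return ([(k, n) for k, n in basic if n], [(k, n) for k, n in acidic if n])


def net_charge(seq: str, ph: float, pka: PKaSet = DEFAULT_PKA) -> float:
    if not seq:
        raise ValueError("empty sequence")
    basic, acidic = _group_pkas(seq, pka)
    q = sum(n / (1.0 + 10.0 ** (ph - k)) for k, n in basic)
    q -= sum(n / (1.0 + 10.0 ** (k - ph)) for k, n in acidic)
    return q


def isoelectric_point(seq: str, pka: PKaSet = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which net charge is zero, by bisection on [0, 14] to a
    bracket narrower than ``tol`` pH units.

    The charge curve can be nearly flat around the root (few, weak
    groups), so termination is on bracket width, not on |Q|.
    """
    lo, hi = 0.0, 14.0
    q_lo, q_hi = net_charge(seq, lo, pka), net_charge(seq, hi, pka)
    if q_lo <= 0.0 or q_hi >= 0.0:
        if q_lo == 0.0:
            return lo
        if q_hi == 0.0:
            return hi
        raise ValueError("no isoelectric point: net charge does not change "
                         "sign on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka)
        if q == 0.0:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def proteome_pi(replicons, pka: PKaSet = DEFAULT_PKA) -> pd.DataFrame:
    """pI of every annotated protein; columns protein_id, replicon_id, pI.

    Translations come from the annotation (initial Met retained).
    """
    rows = []
    for r in replicons:
        for fid, parts in r.cds_groups():
            aa = parts[0].translation
            if not aa:
                continue
            try:
                rows.append(dict(protein_id=fid, replicon_id=r.id,
                                 pI=isoelectric_point(aa, pka)))
            except ValueError:
                continue
    return pd.DataFrame(rows, columns=["protein_id", "replicon_id", "pI"])


def proteome_pi_summary(results: pd.DataFrame,
                        classes: dict[str, str] | None = None,
                        bin_width: float = 0.2) -> dict:
    """Per-replicon and per-class mean pI (two decimals) plus a histogram
    for uni/bimodality inspection.  ``classes`` maps protein id to a label
    (e.g. cytosolic / transmembrane); unlabeled proteins are excluded from
    class means only."""
    if results.empty:
        raise ValueError("no proteins")
    per_replicon = {
        rid: round(float(sub["pI"].mean()), 2)
        for rid, sub in results.groupby("replicon_id")
    }
    per_class = {}
    if classes:
        labeled = results.assign(
            cls=results["protein_id"].map(classes)).dropna(subset=["cls"])
        per_class = {
            cls: round(float(sub["pI"].mean()), 2)
            for cls, sub in labeled.groupby("cls")
        }
    edges = np.arange(0.0, 14.0 + bin_width, bin_width)
    counts, edges = np.histogram(results["pI"], bins=edges)
    return {
        "mean_pI": round(float(results["pI"].mean()), 2),
        "per_replicon": per_replicon,
        "per_class": per_class,
        "histogram": (edges, counts),
        "n_proteins": int(len(results)),
    }
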