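"""Genome-wide summary table (per-replicon sizes, GC, feature counts,
percent coding, mean pI) and the start-codon census.

Aggregation in the Total row: sizes and counts sum; %GC and percent
coding are length-weighted means; mean pI is protein-count-weighted.
Percentages print to one decimal and pI to two.
"""

from __future__ import annotations

import pandas as pd

from .composition import coding_noncoding_gc, gc_percent
from .genome_io import Replicon, extract_cds_codons

IS_FAMILY_PATTERNS = ("ISH51", "IS4")
START_CODONS = ("ATG", "GTG", "TTG")


def is_family_counts(r: Replicon) -> dict[str, int]:
    counts = {fam: 0 for fam in IS_FAMILY_PATTERNS}
    counts["other"] = 0
    for f in r.features_of_kind("IS"):
        lab = f.label.upper()
        for fam in IS_FAMILY_PATTERNS:
            if fam in lab:
                counts[fam] += 1
                break
        else:
            counts["other"] += 1
    counts["total"] = sum(counts.values())
    return counts


def start_codon_census(replicons) -> dict[str, float]:
    """Percentage of CDSs starting with ATG / GTG / TTG / other."""
    counts = {c: 0 for c in START_CODONS}
    counts["other"] = 0
    total = 0
    for r in replicons:
        for _, codons in extract_cds_codons(r):
            first = codons[0]
            counts[first if first in counts else "other"] = \
                counts.get(first if first in counts else "other", 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no usable CDSs")
    return {k: 100.0 * v / total for k, v in counts.items()}


def summarize_genome(replicons, pi_results: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Per-replicon summary plus a Total row.

    ``pi_results`` is the output of :func:`haloscan.proteome_pi.proteome_pi`
    (optional; without it the mean-pI column is NaN).
    """
    rows = []
    for r in replicons:
        n_cds = len(r.cds_groups())
        isc = is_family_counts(r)
        try:
            _, _, pct_coding = coding_noncoding_gc(r)
        except ValueError:
            pct_coding = 0.0
        mean_pi = float("nan")
        if pi_results is not None and not pi_results.empty:
            sub = pi_results[pi_results["replicon_id"] == r.id]
            if len(sub):
                mean_pi = float(sub["pI"].mean())
        rows.append(dict(
            replicon=r.id,
            size_bp=r.length,
            gc_pct=gc_percent(r.sequence),
            n_cds=n_cds,
            n_trna=len(r.features_of_kind("tRNA")),
            n_rrna=len(r.features_of_kind("rRNA")),
            is_ISH51=isc["ISH51"],
            is_IS4=isc["IS4"],
            is_other=isc["other"],
            is_total=isc["total"],
            percent_coding=pct_coding,
            mean_pI=mean_pi,
        ))
    df = pd.DataFrame(rows)
    total_size = df["size_bp"].sum()
    w = df["size_bp"] / total_size
    if pi_results is not None and not pi_results.empty:
        total_pi = float(pi_results["pI"].mean())
    else:
        total_pi = float("nan")
    total = dict(
        replicon="Total",
        size_bp=int(total_size),
        gc_pct=float((df["gc_pct"] * w).sum()),
        n_cds=int(df["n_cds"].sum()),
        n_trna=int(df["n_trna"].sum()),
        n_rrna=int(df["n_rrna"].sum()),
        is_ISH51=int(df["is_ISH51"].sum()),
        is_IS4=int(df["is_IS4"].sum()),
        is_other=int(df["is_other"].sum()),
        is_total=int(df["is_total"].sum()),
        percent_coding=float((df["percent_coding"] * w).sum()),
        mean_pI=total_pi,
    )
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def format_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Rounded for printing: percentages to one decimal, pI to two."""
    out = df.copy()
    for col in ("gc_pct", "percent_coding"):
        out[col] = out[col].round(1)
    out["mean_pI"] = out["mean_pI"].round(2)
    return out
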