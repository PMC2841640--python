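"""Calibrating legacy genetic-map coordinates against the assembly.

The 1989 genetic map of the Haloferax volcanii chromosome places markers
in kb with ~10 kb resolution.  Given a table of markers with both map
positions and assembly coordinates, the conversion is a single constant
offset, estimated as the median of the pooled start- and end-position
differences (genome bp - 1000 * map kb) over usable markers.  Markers
whose map gene length disagrees with the sequence gene length by more
than a factor (default 2x) are flagged as outliers and the median is
recomputed once without them; a mean-based estimate is also reported for
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import Replicon

MARKER_COLUMNS = ["name", "map_start_kb", "map_end_kb",
                  "genome_start", "genome_end"]


@dataclass
class CalibrationResult:
    offset_bp: float  # median of pooled start/end offsets
    mean_offset_bp: float
    markers: pd.DataFrame  # with offset_start, offset_end, residual_*, outlier
    n_used: int


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns {sorted(missing)}")
    return df


def calibrate_offset(markers: pd.DataFrame, length_ratio: float = 2.0,
                     exclude_names=()) -> CalibrationResult:
    """Median-offset calibration with one round of outlier rejection.

    Offsets are genome bp minus 1000 * map kb, pooled over marker starts
    and ends.  ``exclude_names`` lists markers excluded a priori (e.g.
    genes too large for the map's resolution).
    """
    df = markers.copy()
    df["offset_start"] = df["genome_start"] - 1000.0 * df["map_start_kb"]
    df["offset_end"] = df["genome_end"] - 1000.0 * df["map_end_kb"]
    map_len = (df["map_end_kb"] - df["map_start_kb"]).abs() * 1000.0
    gen_len = (df["genome_end"] - df["genome_start"]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(map_len, gen_len) / np.minimum(map_len, gen_len)
    df["outlier"] = (ratio > length_ratio) | df["name"].isin(exclude_names)

    def _pooled(sub):
        return np.concatenate([sub["offset_start"], sub["offset_end"]])

    usable = df[~df["outlier"]]
    if len(usable) < 3:
        raise ValueError(f"only {len(usable)} usable markers (< 3)")
    pooled = _pooled(usable)
    offset = float(np.median(pooled))
    df["residual_start"] = df["offset_start"] - offset
    df["residual_end"] = df["offset_end"] - offset
    return CalibrationResult(
        offset_bp=offset,
        mean_offset_bp=float(np.mean(pooled)),
        markers=df,
        n_used=len(usable),
    )


def map_to_genome(x_kb: float, offset_bp: float,
                  replicon_length: int | None = None) -> int:
    """Genome coordinate (1-based bp) of genetic-map position ``x_kb``;
    wraps modulo the replicon length for circular chromosomes."""
    pos = int(round(1000.0 * x_kb + offset_bp))
    if replicon_length is not None:
        pos = (pos - 1) % replicon_length + 1
    return pos


def genome_to_map(pos_bp: int, offset_bp: float,
                  replicon_length: int | None = None) -> float:
    """Inverse of :func:`map_to_genome`, in kb."""
    x = (pos_bp - offset_bp) / 1000.0
    if replicon_length is not None and x < 0:
        x += replicon_length / 1000.0
    return x


def project_intervals(intervals: pd.DataFrame, offset_bp: float,
                      r: Replicon) -> pd.DataFrame:
    """Project legacy map-kb intervals onto the assembly.

    ``intervals`` needs columns start_kb, end_kb, label.  Output rows are
    BED-style (0-based half-open) with the label carried through and the
    ids of annotated genes overlapping each projected interval; a record
    with no overlap keeps an empty gene list.  Intervals that wrap the
    origin are split into two rows sharing the label.
    """
    L = r.length
    rows = []
    for _, iv in intervals.iterrows():
        length_bp = int(round((iv["end_kb"] - iv["start_kb"]) * 1000.0))
        if length_bp > L:
            raise ValueError(
                f"interval {iv['label']!r} longer than the replicon")
        s = int(round(1000.0 * iv["start_kb"] + offset_bp)) % L
        e = s + length_bp
        if e <= L:
            pieces = [(s, e)]
        elif r.topology == "circular":
            pieces = [(s, L), (0, e - L)]
        else:
            raise ValueError(
                f"interval {iv['label']!r} projects outside the linear replicon")
        for ps, pe in pieces:
            genes = [fid for fid, parts in r.cds_groups()
                     if any(f.start < pe and f.end > ps for f in parts)]
            rows.append(dict(chrom=r.id, start=ps, end=pe,
                             label=iv["label"], genes=",".join(genes)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "genes"])
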