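"""Cumulative base-disparity ("Z-curve" style) skews and windowed GC skew.

The cumulative curve for component GC is the running sum of +1 per G and
-1 per C (analogously for the other base classes); its slope changes mark
strand-composition shifts, and on a circular chromosome replicated
bidirectionally from a single origin the curve is V-shaped with the
vertex at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Replicon

#: Base increments per component.  RY = purine - pyrimidine,
#: MK = amino - keto, WS = weak - strong.
COMPONENTS: dict[str, dict[str, int]] = {
    "GC": {"G": 1, "C": -1},
    "AT": {"A": 1, "T": -1},
    "RY": {"A": 1, "G": 1, "C": -1, "T": -1},
    "MK": {"A": 1, "C": 1, "G": -1, "T": -1},
    "WS": {"A": 1, "T": 1, "G": -1, "C": -1},
}


@dataclass
class SkewCurve:
    replicon_id: str
    component: str
    values: np.ndarray  # cumulative sum, one entry per bp
    offset_origin: int = 0

    @property
    def final(self) -> int:
        return int(self.values[-1])


def _increments(seq: str, component: str) -> np.ndarray:
    try:
        inc_map = COMPONENTS[component]
    except KeyError:
        raise ValueError(f"unknown component {component!r}; "
                         f"one of {sorted(COMPONENTS)}") from None
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    inc = np.zeros(len(arr), dtype=np.int64)
    for base, v in inc_map.items():
        inc[arr == ord(base)] = v
    return inc  # N contributes 0


def cumulative_disparity(r: Replicon, component: str,
                         origin: int = 0) -> SkewCurve:
    """Cumulative disparity curve; ``origin`` rotates the sequence so that
    x=0 is that bp (sums recomputed from the rotated sequence)."""
    if origin:
        if r.topology != "circular":
            raise ValueError("origin rotation requires a circular replicon")
        if not 0 <= origin < r.length:
            raise ValueError(f"origin {origin} outside [0, {r.length})")
        seq = r.sequence[origin:] + r.sequence[:origin]
    else:
        seq = r.sequence
    values = np.cumsum(_increments(seq, component))
    return SkewCurve(r.id, component, values, offset_origin=origin)


def rotate_to_origin(r: Replicon, curve: SkewCurve, origin: int) -> SkewCurve:
    return cumulative_disparity(r, curve.component, origin=origin)


def windowed_gc_skew(r: Replicon, window: int = 5000,
                     stride: int | None = None) -> list[tuple[int, float | None]]:
    """Per-window (G-C)/(G+C); windows with G+C = 0 yield ``None``."""
    if window < 1:
        raise ValueError("window must be >= 1")
    from .composition import _cumulative_indicators, _window_starts, _window_counts

    stride = stride or window
    circular = r.topology == "circular"
    starts = _window_starts(r.length, window, stride, circular)
    counts = _window_counts(_cumulative_indicators(r.sequence), r.length,
                            starts, window, circular)
    g, c = counts[:, 2], counts[:, 1]
    out = []
    for s, gi, ci in zip(starts, g, c):
        tot = gi + ci
        out.append((int(s), float(gi - ci) / tot if tot else None))
    return out


def locate_skew_extremum(curve: SkewCurve, kind: str = "min",
                         smooth: int = 0, detrend: bool = False) -> int:
    """Position (bp, in the curve's rotated frame) of the global extremum
    of the cumulative curve.  Ties break to the smallest coordinate.

    With ``detrend`` the linear trend ``i * final / L`` is removed first
    ("closing" the curve).  For circular replicons this makes the vertex
    independent of the arbitrary sequence start and robust to a nonzero
    genome-wide base-count difference; use it when hunting origins.
    """
    values = curve.values.astype(float)
    if detrend:
        L = len(values)
        values = values - np.arange(1, L + 1) * (values[-1] / L)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        values = np.convolve(values, kernel, mode="same")
    if np.all(values == values[0]):
        raise ValueError("constant curve: no extremum")
    if kind == "min":
        return int(np.argmin(values))
    if kind == "max":
        return int(np.argmax(values))
    raise ValueError("kind must be 'min' or 'max'")
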