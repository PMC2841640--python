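"""Cumulative disparity curves, windowed GC skew, extremum location."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haloscan.genome_io import revcomp
from haloscan.skew import (
    COMPONENTS,
    cumulative_disparity,
    locate_skew_extremum,
    rotate_to_origin,
    windowed_gc_skew,
)

from conftest import make_replicon, random_seq

dna = st.text(alphabet="ACGTN", min_size=2, max_size=300)


class TestCumulativeDisparity:
    def test_gc_component_by_hand(self):
        r = make_replicon("GGCC")
        assert cumulative_disparity(r, "GC").values.tolist() == [1, 2, 1, 0]

    def test_all_a_is_flat_for_gc(self):
        r = make_replicon("AAAA")
        assert cumulative_disparity(r, "GC").values.tolist() == [0, 0, 0, 0]

    def test_matches_prefix_sum_oracle(self, rng):
        seq = random_seq(rng, 50000, "ACGTN")
        r = make_replicon(seq)
        inc = {"G": 1, "C": -1}
        oracle = np.cumsum([inc.get(b, 0) for b in seq])
        assert (cumulative_disparity(r, "GC").values == oracle).all()

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            cumulative_disparity(make_replicon("ACGT"), "XY")

    @settings(deadline=None, derandomize=True)
    @given(dna)
    def test_final_value_is_total_count_difference(self, seq):
        r = make_replicon(seq)
        c = cumulative_disparity(r, "AT")
        assert c.final == seq.count("A") - seq.count("T")

    @settings(deadline=None, derandomize=True)
    @given(dna)
    def test_component_sum_rules(self, seq):
        """RY + MK = 2*AT and RY - MK = 2*GC, exactly, on any input."""
        r = make_replicon(seq)
        curves = {k: cumulative_disparity(r, k).values
                  for k in ("RY", "MK", "AT", "GC")}
        assert (curves["RY"] + curves["MK"] == 2 * curves["AT"]).all()
        assert (curves["RY"] - curves["MK"] == 2 * curves["GC"]).all()

    @settings(deadline=None, derandomize=True)
    @given(dna)
    def test_reverse_complement_negates_and_reverses(self, seq):
        r = make_replicon(seq)
        rc = make_replicon(revcomp(seq))
        for comp in ("GC", "AT"):
            fwd = cumulative_disparity(r, comp).values
            back = cumulative_disparity(rc, comp).values
            # increments of the revcomp are the reversed, negated increments
            inc_f = np.diff(np.concatenate([[0], fwd]))
            inc_b = np.diff(np.concatenate([[0], back]))
            assert (inc_b == -inc_f[::-1]).all()


class TestRotation:
    def test_rotation_by_zero_and_full_length_is_identity(self):
        r = make_replicon(random_seq(np.random.default_rng(0), 1000))
        base = cumulative_disparity(r, "GC")
        assert (rotate_to_origin(r, base, 0).values == base.values).all()

    def test_rotation_moves_minimum_of_closed_v_curve(self):
        # closed V-shaped curve: C-run then G-run, total G-C difference 0
        r = make_replicon("C" * 1000 + "G" * 1000)
        base = cumulative_disparity(r, "GC")
        assert locate_skew_extremum(base) == 999
        rotated = rotate_to_origin(r, base, 1000)
        assert locate_skew_extremum(rotated) == (999 - 1000) % r.length

    def test_origin_out_of_range_rejected(self):
        r = make_replicon("ACGT" * 10)
        c = cumulative_disparity(r, "GC")
        with pytest.raises(ValueError):
            rotate_to_origin(r, c, 40)

    def test_linear_replicon_cannot_rotate(self):
        r = make_replicon("ACGT" * 10, topology="linear")
        c = cumulative_disparity(r, "GC")
        with pytest.raises(ValueError):
            rotate_to_origin(r, c, 5)


class TestWindowedSkew:
    def test_pure_g_and_pure_c_windows(self):
        r = make_replicon("GGGG" + "CCCC", topology="linear")
        vals = dict(windowed_gc_skew(r, window=4, stride=4))
        assert vals[0] == 1.0 and vals[4] == -1.0

    def test_gc_free_window_is_missing(self):
        r = make_replicon("ATAT" * 5, topology="linear")
        assert windowed_gc_skew(r, window=4, stride=4)[0][1] is None

    def test_equals_cumulative_difference_quotient(self, rng):
        seq = random_seq(rng, 8000)
        r = make_replicon(seq, topology="linear")
        g = np.concatenate([[0], np.cumsum([b == "G" for b in seq])])
        c = np.concatenate([[0], np.cumsum([b == "C" for b in seq])])
        for s, v in windowed_gc_skew(r, window=500, stride=500):
            dg, dc = g[s + 500] - g[s], c[s + 500] - c[s]
            assert v == pytest.approx((dg - dc) / (dg + dc))


class TestExtremum:
    def test_origin_recovery_on_skewed_genome(self, island_genome):
        replicons, manifest = island_genome
        r = replicons[0]
        ext = locate_skew_extremum(cumulative_disparity(r, "GC"),
                                   detrend=True)
        true_ori = manifest["chrA"]["ori"]
        err = abs(ext - true_ori)
        assert min(err, r.length - err) <= 0.05 * r.length

    def test_monotone_all_g_extremum_at_start(self):
        r = make_replicon("G" * 100)
        c = cumulative_disparity(r, "GC")
        assert locate_skew_extremum(c, kind="min") == 0
        assert locate_skew_extremum(c, kind="max") == 99

    def test_mirrored_sequence_reflects_extremum(self):
        seq = "C" * 50 + "G" * 150
        fwd = locate_skew_extremum(cumulative_disparity(make_replicon(seq), "GC"))
        back = locate_skew_extremum(
            cumulative_disparity(make_replicon(seq[::-1]), "GC"), kind="max")
        assert fwd == 49 and back == 149

    def test_constant_curve_rejected(self):
        r = make_replicon("A" * 50)
        with pytest.raises(ValueError, match="no extremum"):
            locate_skew_extremum(cumulative_disparity(r, "GC"))
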