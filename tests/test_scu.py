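"""SCU tables, window chi-square, scanning and island calling."""

import numpy as np
import pytest

from haloscan.genome_io import Feature, Replicon
from haloscan.scu import (
    DEFAULT_EXCLUDED,
    FAMILIES,
    NOMINAL_DF,
    build_scu,
    call_islands,
    detect_islands,
    scan_replicon,
    window_chi2,
)
from haloscan.synthgen import (
    IslandSpec,
    RepliconSpec,
    SynthSpec,
    codon_profile,
    generate,
    null_window_sampler,
)


class TestBuildScu:
    def test_single_codon_family_usage(self):
        t = build_scu([["GAA", "GAA"], ["GAA"]])
        assert t.codon_freq["GAA"] == 1.0
        assert t.codon_freq["GAG"] == 0.0
        assert t.n_cds == 2

    def test_balanced_two_codon_family(self):
        t = build_scu([["GAA", "GAG"]])
        assert t.codon_freq["GAA"] == t.codon_freq["GAG"] == 0.5

    def test_excluded_codons_absent(self):
        t = build_scu([["ATG", "GAA", "TGG", "TAA"]])
        for c in ("ATG", "TGG", "TAA"):
            assert c not in t.codon_freq

    def test_family_frequencies_sum_to_one(self, rng):
        codons = [c for fam in FAMILIES.values() for c in fam]
        lists = [[codons[i] for i in rng.integers(0, len(codons), 200)]
                 for _ in range(10)]
        t = build_scu(lists)
        for aa, fam in FAMILIES.items():
            if t.aa_counts.get(aa, 0):
                assert sum(t.codon_freq[c] for c in fam) == pytest.approx(1.0)

    def test_matches_count_and_normalize_oracle(self, rng):
        from collections import Counter
        codons = [c for fam in FAMILIES.values() for c in fam]
        lists = [[codons[i] for i in rng.integers(0, len(codons), 300)]]
        t = build_scu(lists)
        counts = Counter(lists[0])
        for aa, fam in FAMILIES.items():
            tot = sum(counts[c] for c in fam)
            if tot:
                for c in fam:
                    assert t.codon_freq[c] == pytest.approx(counts[c] / tot)

    def test_no_usable_codons_rejected(self):
        with pytest.raises(ValueError):
            build_scu([["ATG", "TAA"]])


class TestWindowChi2:
    def test_proportional_window_scores_zero(self):
        ref = build_scu([["GAA", "GAG", "GAA", "GAG"]])
        st = window_chi2({"GAA": 7, "GAG": 7}, ref)
        assert st.chi2 == pytest.approx(0.0)
        assert st.p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # ref 0.5/0.5 on {GAA, GAG}; window 10 GAA, 0 GAG:
        # chi2 = (10-5)^2/5 + (0-5)^2/5 = 10
        ref = build_scu([["GAA", "GAG"]])
        st = window_chi2({"GAA": 10}, ref)
        assert st.chi2 == pytest.approx(10.0)

    def test_default_df_is_forty_and_nominal_is_41(self):
        ref = build_scu([["GAA", "GAG"]])
        assert window_chi2({"GAA": 2}, ref).df == 40
        assert NOMINAL_DF == sum(len(f) - 1 for f in FAMILIES.values()) == 41

    def test_order_invariance_within_window(self, rng):
        from haloscan.scu import count_codons
        codons = [c for fam in FAMILIES.values() for c in fam]
        ref = build_scu([[codons[i] for i in rng.integers(0, 59, 500)]])
        window = [codons[i] for i in rng.integers(0, 59, 400)]
        a = window_chi2(count_codons([window]), ref).chi2
        shuffled = list(window)
        rng.shuffle(shuffled)
        b = window_chi2(count_codons([shuffled]), ref).chi2
        assert a == pytest.approx(b)

    def test_missing_reference_codon_gets_pseudo_expectation(self):
        ref = build_scu([["GAA"] * 10])  # GAG absent from reference
        st = window_chi2({"GAG": 3}, ref)
        # GAG: exp 0 -> 0.5 pseudo, (3-0.5)^2/0.5; GAA: exp 3, obs 0
        assert st.chi2 == pytest.approx((3 - 0.5) ** 2 / 0.5 + 3.0, rel=1e-6)


def _toy_replicon(n_cds, codons_per_cds=80, profile_gc3=0.5, seed=0,
                  topology="linear"):
    spec = SynthSpec(seed=seed, replicons=[
        RepliconSpec(id="toy",
                     length=n_cds * codons_per_cds * 4 + 20000,
                     topology=topology, n_cds=n_cds,
                     mean_cds_codons=codons_per_cds,
                     cds_profile=codon_profile(profile_gc3))])
    return generate(spec)[0][0]


class TestScan:
    def test_exactly_window_cds_linear_gives_one_window(self):
        r = _toy_replicon(30, topology="linear")
        scan = scan_replicon(r, window=30)
        assert len(scan.stats) == 1

    def test_circular_gives_one_window_per_cds(self):
        r = _toy_replicon(45, topology="circular")
        assert len(scan_replicon(r, window=30).stats) == 45

    def test_fewer_cds_than_window_warns_single_window(self, caplog):
        r = _toy_replicon(10, topology="linear")
        with caplog.at_level("WARNING"):
            scan = scan_replicon(r, window=30)
        assert len(scan.stats) == 1

    def test_null_calibration_type_one_error(self):
        """Windows resampled from the reference: empirical fraction with
        p < 0.05 matches 0.05 within 2*SE (df matching the statistic)."""
        ref = reference_from_profile(codon_profile(0.55))
        windows = null_window_sampler(ref, 1000, seed=9)
        ps = np.array([window_chi2(w, ref, df=NOMINAL_DF).p for w in windows])
        frac = (ps < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) <= 2 * se


def reference_from_profile(profile):
    """SCU table carrying exactly the given family-conditional frequencies
    (uniform amino-acid usage), for sampling-based calibration."""
    from haloscan.scu import SCUTable

    return SCUTable(codon_freq=dict(profile), codon_counts={},
                    aa_counts={aa: 1000 for aa in FAMILIES},
                    excluded=DEFAULT_EXCLUDED, n_cds=0)


class TestIslands:
    def test_no_significant_windows_no_islands(self):
        r = _toy_replicon(60)
        scan, islands = detect_islands(r)
        assert islands == []

    def test_planted_island_recovered_with_tight_boundaries(self, island_genome):
        replicons, manifest = island_genome
        scan, islands = detect_islands(replicons[0])
        truth = manifest["chrA"]["islands"][0]
        assert len(islands) == 1
        isl = islands[0]
        assert abs(isl.cds_range[0] - truth["start_cds"]) <= 2
        assert abs(isl.cds_range[1] - truth["end_cds"]) <= 2
        assert isl.min_p < 1e-10

    def test_two_separated_islands_stay_separate(self):
        spec = SynthSpec(seed=8, replicons=[
            RepliconSpec(id="two", length=400000, n_cds=400,
                         cds_profile=codon_profile(0.75),
                         islands=[
                             IslandSpec(80, 35, codon_profile(0.3)),
                             IslandSpec(260, 35, codon_profile(0.3)),
                         ])])
        (r,), _ = generate(spec)
        _, islands = detect_islands(r)
        assert len(islands) == 2

    def test_island_calls_invariant_to_rotation(self, island_genome):
        replicons, manifest = island_genome
        r = replicons[0]
        shift = 150000
        rotated = Replicon(
            r.id, r.sequence[shift:] + r.sequence[:shift], "circular",
            [Feature(f.kind, (f.start - shift) % r.length,
                     (f.end - shift - 1) % r.length + 1, f.strand, f.id,
                     f.label, f.translation, f.partial, f.part)
             for f in r.features
             if f.start >= shift or f.end <= shift])  # drop any straddler
        _, islands = detect_islands(rotated)
        assert len(islands) == 1
        truth = manifest["chrA"]["islands"][0]
        s, e = islands[0].span
        assert (s + shift) % r.length == pytest.approx(truth["start_bp"],
                                                       abs=3000)

    def test_best_reference_identifies_donor(self, island_genome):
        from haloscan.scu import assign_reference, island_codon_counts

        replicons, _ = island_genome
        scan, islands = detect_islands(replicons[0])
        scan_b = scan_replicon(replicons[1])
        isl = assign_reference(islands[0],
                               island_codon_counts(scan, islands[0]),
                               {"chrA": scan.reference,
                                "pB": scan_b.reference})
        assert isl.best_reference[0] == "pB"

    def test_reference_tie_breaks_to_smaller_id(self):
        from haloscan.scu import Island, assign_reference
        ref = build_scu([["GAA", "GAG"] * 5])
        isl = Island("x", (0, 10), (0, 1), [0], 1.0)
        out = assign_reference(isl, {"GAA": 4, "GAG": 4},
                               {"b_rep": ref, "a_rep": ref})
        assert out.best_reference[0] == "a_rep"

    def test_homogeneous_replicon_rarely_yields_false_islands(self):
        r = _toy_replicon(200, codons_per_cds=100, seed=21)
        _, islands = detect_islands(r)
        assert islands == []
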