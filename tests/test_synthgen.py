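"""The synthetic genome generator: determinism, realized statistics,
losslessness through I/O, and the null window sampler."""

import numpy as np
import pytest

from haloscan.composition import gc_percent
from haloscan.genome_io import read_genome
from haloscan.scu import build_scu, count_codons, window_chi2
from haloscan.synthgen import (
    ISSpec,
    IslandSpec,
    RepliconSpec,
    SynthSpec,
    codon_profile,
    generate,
    generate_to_dir,
    null_window_sampler,
)


def _spec(seed=3):
    return SynthSpec(seed=seed, replicons=[
        RepliconSpec(id="a", length=120000, n_cds=80,
                     cds_profile=codon_profile(0.7),
                     is_specs=[ISSpec("ISH51", 2, 0.45)]),
        RepliconSpec(id="b", length=40000, n_cds=20,
                     cds_profile=codon_profile(0.4)),
    ])


class TestDeterminism:
    def test_same_spec_and_seed_identical_output(self):
        r1, m1 = generate(_spec())
        r2, m2 = generate(_spec())
        for a, b in zip(r1, r2):
            assert a.sequence == b.sequence
            assert [(f.kind, f.start, f.end, f.id) for f in a.features] == \
                   [(f.kind, f.start, f.end, f.id) for f in b.features]
        assert m1["a"]["is_sites"] == m2["a"]["is_sites"]

    def test_adding_a_replicon_does_not_perturb_earlier_ones(self):
        base = _spec()
        extended = _spec()
        extended.replicons = extended.replicons + [
            RepliconSpec(id="c", length=30000, n_cds=10)]
        (a1, _), (a2, _, _) = generate(base)[0], generate(extended)[0]
        assert a1.sequence == a2.sequence

    def test_different_seeds_differ(self):
        assert generate(_spec(1))[0][0].sequence != \
            generate(_spec(2))[0][0].sequence


class TestRealizedStatistics:
    def test_background_gc_concentrates_at_spec(self):
        spec = SynthSpec(seed=6, replicons=[
            RepliconSpec(id="g", length=100000, n_cds=0, gc=0.62)])
        (r,), _ = generate(spec)
        assert gc_percent(r.sequence) == pytest.approx(62.0, abs=1.0)

    def test_island_scu_diverges_from_host_by_construction(self):
        spec = SynthSpec(seed=9, replicons=[
            RepliconSpec(id="i", length=200000, n_cds=150,
                         cds_profile=codon_profile(0.75),
                         islands=[IslandSpec(60, 30, codon_profile(0.3))])])
        (r,), man = generate(spec)
        groups = {fid: None for fid, *_ in man["i"]["cds_spans"]}
        ids = list(groups)
        from haloscan.genome_io import extract_cds_codons
        codons = dict(extract_cds_codons(r))
        host = build_scu([codons[i] for i in ids[:60]])
        island_counts = count_codons([codons[i] for i in ids[60:90]])
        assert window_chi2(island_counts, host).chi2 > 1000

    def test_v_shaped_skew_with_vertex_at_origin(self, island_genome):
        from haloscan.skew import cumulative_disparity, locate_skew_extremum
        replicons, manifest = island_genome
        curve = cumulative_disparity(replicons[0], "GC")
        ori = manifest["chrA"]["ori"]
        L = replicons[0].length
        # vertex near ori, peak near the antipode (closed-curve frame)
        lo = locate_skew_extremum(curve, "min", detrend=True)
        hi = locate_skew_extremum(curve, "max", detrend=True)
        assert abs(lo - ori) < 0.05 * L
        anti = (ori + L // 2) % L
        err = abs(hi - anti)
        assert min(err, L - err) < 0.05 * L


class TestFilesAndCapacity:
    def test_generated_files_parse_losslessly(self, tmp_path):
        replicons, _ = generate(_spec())
        paths = generate_to_dir(_spec(), tmp_path)
        back = read_genome([paths["fasta"], paths["gff3"]],
                           format="fasta+gff3")
        for a, b in zip(replicons, back):
            assert a.sequence == b.sequence
            assert len(a.features) == len(b.features)
            # annotated translation survives the protein-FASTA round trip
            assert a.cds_groups()[0][1][0].translation == \
                b.cds_groups()[0][1][0].translation

    def test_manifest_and_marker_files_written(self, tmp_path):
        from haloscan.synthgen import MarkerMapSpec

        spec = SynthSpec(seed=4, replicons=[
            RepliconSpec(id="m", length=60000, n_cds=30,
                         marker_map=MarkerMapSpec(8, 10000, 2.0))])
        paths = generate_to_dir(spec, tmp_path)
        assert "manifest" in paths and "markers_m" in paths

    def test_overfull_replicon_rejected(self):
        spec = SynthSpec(seed=0, replicons=[
            RepliconSpec(id="x", length=10000, n_cds=50)])
        with pytest.raises(ValueError, match="capacity"):
            generate(spec)

    def test_overlapping_islands_rejected(self):
        spec = SynthSpec(seed=0, replicons=[
            RepliconSpec(id="x", length=500000, n_cds=100,
                         islands=[IslandSpec(10, 20, codon_profile(0.4)),
                                  IslandSpec(25, 20, codon_profile(0.4))])])
        with pytest.raises(ValueError, match="overlap"):
            generate(spec)


class TestNullSampler:
    def _ref(self, gc3=0.55):
        from haloscan.scu import DEFAULT_EXCLUDED, FAMILIES, SCUTable
        return SCUTable(codon_freq=codon_profile(gc3), codon_counts={},
                        aa_counts={aa: 1000 for aa in FAMILIES},
                        excluded=DEFAULT_EXCLUDED, n_cds=0)

    def test_seed_reproducibility(self):
        a = null_window_sampler(self._ref(), 5, seed=2)
        b = null_window_sampler(self._ref(), 5, seed=2)
        assert a == b

    def test_degenerate_reference_always_scores_zero(self):
        from haloscan.scu import DEFAULT_EXCLUDED, FAMILIES, SCUTable
        freq = {}
        for fam in FAMILIES.values():
            for i, c in enumerate(fam):
                freq[c] = 1.0 if i == 0 else 0.0
        ref = SCUTable(freq, {}, {aa: 100 for aa in FAMILIES},
                       DEFAULT_EXCLUDED, 0)
        for w in null_window_sampler(ref, 5, seed=1):
            assert window_chi2(w, ref).chi2 == pytest.approx(0.0)
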