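import numpy as np
import pytest

from haloscan.genome_io import Feature, Replicon
from haloscan.synthgen import (
    ISSpec,
    IslandSpec,
    MarkerMapSpec,
    RepliconSpec,
    SynthSpec,
    codon_profile,
    generate,
)


def make_replicon(seq, features=(), rid="r1", topology="circular"):
    return Replicon(rid, seq, topology, list(features))


def cds(start, end, strand="+", fid="g1", **kw):
    return Feature("CDS", start, end, strand, fid, **kw)


@pytest.fixture(scope="session")
def island_genome():
    """300-CDS circular replicon with a planted 40-CDS divergent island,
    IS elements preferring AT valleys, a skewed origin, and a marker map."""
    spec = SynthSpec(seed=42, replicons=[
        RepliconSpec(id="chrA", length=300000, n_cds=300,
                     cds_profile=codon_profile(0.8),
                     islands=[IslandSpec(130, 40, codon_profile(0.25))],
                     is_specs=[ISSpec("ISH51", 4, 0.42, site_preference=1.0)],
                     n_at_valleys=6, ori=60000, skew=0.02,
                     cds_strand_bias=0.8,
                     marker_map=MarkerMapSpec(16, 120000, 5.0,
                                              n_gross_outliers=1)),
        RepliconSpec(id="pB", length=80000, n_cds=60,
                     cds_profile=codon_profile(0.3)),
    ])
    return generate(spec)


@pytest.fixture(scope="session")
def plain_genome():
    """Homogeneous 150-CDS replicon, no islands, uniform IS placement."""
    spec = SynthSpec(seed=11, replicons=[
        RepliconSpec(id="chrP", length=200000, n_cds=100,
                     cds_profile=codon_profile(0.6),
                     is_specs=[ISSpec("IS4", 5, 0.55, site_preference=0.0)]),
    ])
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
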