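import pytest

from mitocompare.records import FeatureRecord, GenomeRecord
from mitocompare.simulate import SimParams, simulate_clade


@pytest.fixture(scope="session")
def clade42():
    """Default 8-leaf simulated clade, shared across the suite."""
    return simulate_clade(SimParams(seed=42))


@pytest.fixture(scope="session")
def small_clade():
    """Fast 4-leaf clade for pipeline-level tests."""
    params = SimParams(
        tree="((A:0.2,B:0.2):0.3,(C:0.35,D:0.35):0.15);",
        seed=7,
        n_decoy_contigs=1,
        decoy_contig_len=8000,
    )
    return simulate_clade(params)


def make_genome(sequence, features=(), genome_id="toy", topology="circular", species=""):
    g = GenomeRecord(id=genome_id, sequence=sequence, species=species or genome_id,
                     topology=topology, features=list(features))
    g.validate()
    return g


def feat(kind, name, intervals, strand="+", **kw):
    return FeatureRecord(kind=kind, name=name, intervals=list(intervals), strand=strand, **kw)
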