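import pytest

from magrecode.io import Contig, Feature
from magrecode.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """One genome simulated at the default study conditions."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_genome():
    """A quick-to-generate genome for tests that only need features."""
    cfg = SimConfig(seed=2, n_cds=80, n_contigs=2, contig_len=60_000)
    return simulate_genome(cfg)


def flip_genome(contigs: list[Contig], features: list[Feature]):
    """Reverse-complement every contig and mirror all features.

    Used to assert strand invariance of the detectors.
    """
    from magrecode.io import revcomp

    lengths = {c.id: len(c.seq) for c in contigs}
    new_contigs = [Contig(c.id, revcomp(c.seq)) for c in contigs]
    new_features = [
        Feature(
            contig_id=f.contig_id,
            start=lengths[f.contig_id] - f.end,
            end=lengths[f.contig_id] - f.start,
            strand="-" if f.strand == "+" else "+",
            kind=f.kind,
            product=f.product,
            function_ids=set(f.function_ids),
            attrs=dict(f.attrs),
            id=f.id,
        )
        for f in features
    ]
    return new_contigs, new_features
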