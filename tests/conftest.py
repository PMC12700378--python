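import pytest
from hypothesis import HealthCheck, settings

import methylscan as m

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_dataset():
    """A 60 kb methylome with two planted motifs, genes, a promoter dip and
    WGA-surviving artifacts; shared by the slower integration-style tests."""
    spec = m.MethylomeSpec(
        genome_length=60_000,
        n_genes=30,
        motifs=(
            m.PlantedMotif(m.Motif("GTNNAC", 4), 0.80),
            m.PlantedMotif(m.Motif("CTAG", 2), 0.65),
        ),
        promoter_dip=(50, 0.005),
        artifacts=(20, 0.30),
    )
    return m.simulate_methylome(spec, 1234)


@pytest.fixture(scope="session")
def planted_summaries(planted_dataset):
    summaries = m.aggregate_replicates(planted_dataset.replicates)
    return m.wga_correct(summaries, planted_dataset.wga)


@pytest.fixture(scope="session")
def planted_index(planted_summaries):
    return m.index_summaries(planted_summaries)
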