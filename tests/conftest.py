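import pytest

from ethnoquant.io import CitationRecord, StudyConfig
from ethnoquant.simulate import CitationSimConfig, gen_citations, gen_informants, sim_study_config


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture
def small_citations() -> list[CitationRecord]:
    """Hand-built citation set with known collapse behaviour.

    i1 cites sp1 for two ailments of category 9 (one use-report) and one of
    category 14 (a second); i2 cites sp1 for category 9; i2 cites sp2 once.
    """
    mk = lambda i, s, a, c: CitationRecord(i, s, a, c)
    return [
        mk("i1", "sp1", "diarrhea", 9),
        mk("i1", "sp1", "ulcer", 9),
        mk("i1", "sp1", "fever", 14),
        mk("i2", "sp1", "diarrhea", 9),
        mk("i2", "sp2", "cough", 8),
    ]


def tiny_sim(seed: int, **kw) -> CitationSimConfig:
    defaults = dict(n_informants=25, n_species=15, mean_citations=10.0, nb_dispersion=6.0)
    defaults.update(kw)
    return CitationSimConfig(seed=seed, **defaults)


@pytest.fixture
def tiny_dataset():
    """Small seeded synthetic dataset: (citations, profiles, StudyConfig)."""
    cfg = tiny_sim(seed=11)
    profiles = gen_informants(cfg)
    citations = gen_citations(cfg, profiles)
    return citations, profiles, sim_study_config(cfg)
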