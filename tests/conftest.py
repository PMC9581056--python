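import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from strpop.repeat_finder import RepeatArray, ScoringConfig, canonical_motif
from strpop.synthetic_data import (DemographyConfig, PopulationSpec, Split,
                                   generate_reference)

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


def make_array(start, end, period=2, motif=None, score=20, seq="chr1",
               n_mismatch=0, n_indel=0):
    """Minimal RepeatArray for filter tests."""
    motif = motif or "AC"[:period].ljust(period, "G")
    return RepeatArray(sequence_id=seq, start=start, end=end,
                       motif=canonical_motif(motif), period=period,
                       copy_number=(end - start) / period, consensus=motif,
                       score=score, n_mismatch=n_mismatch, n_indel=n_indel)


@pytest.fixture(scope="session")
def scoring():
    return ScoringConfig()


@pytest.fixture(scope="session")
def small_pack():
    """Seeded 20-kb reference with 40 planted arrays."""
    return generate_reference(20_000, 40, seed=11)


@pytest.fixture(scope="session")
def two_pop_config():
    def factory(seed, n=6, rate=1e-3, split=2000.0, ne=(500.0, 500.0)):
        return DemographyConfig(
            populations=(PopulationSpec("pop1", n, ne[0], (30.0,) * n),
                         PopulationSpec("pop2", n, ne[1], (30.0,) * n)),
            splits=(Split(split, ("pop1", "pop2"), "anc"),),
            ancestral_sizes=(("anc", 1000.0),),
            reference_population="pop1", seed=seed, smm_rate=rate)
    return factory
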