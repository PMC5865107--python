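import numpy as np
import pandas as pd
import pytest

from pollinet import SimulationConfig, simulate_dataset
from pollinet.containers import PollenCountMatrix


@pytest.fixture(scope="session")
def tiny_taxonomy() -> pd.DataFrame:
    """Six references: two genera in family F1 (one species lacking a
    species-level name), two singleton genera in family F2."""
    return pd.DataFrame(
        {
            "species": ["Alpha una", "Alpha duo", "Beta una", None,
                        "Gamma una", "Delta una"],
            "genus": ["Alpha", "Alpha", "Beta", None, "Gamma", "Delta"],
            "tribe": ["T1", "T1", "T1", "T1", "T2", "T2"],
            "family": ["F1", "F1", "F1", "F1", "F2", "F2"],
        },
        index=[f"ref{i}" for i in range(6)],
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_families=6,
        genera_per_family=2,
        species_per_genus=2,
        reads_per_individual=25,
        individuals_per_species_site=2,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    """One simulated survey shared (read-only) across the suite."""
    return simulate_dataset(small_config)


def make_pcm(counts: dict, ranks: dict, meta: dict | None = None) -> PollenCountMatrix:
    """Hand-build a count matrix; ``counts`` maps insect -> {taxon: n}."""
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    insects = meta or {
        i: {"pollinator_species": "Hov sp1", "genus": "Hov", "site": "S1"}
        for i in frame.index
    }
    return PollenCountMatrix(
        counts=frame,
        ranks=pd.Series(ranks),
        insects=pd.DataFrame(insects).T,
    )
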