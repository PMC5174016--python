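import numpy as np
import pytest

from salivalink.profiles import GeneRecord
from salivalink.synthetic import (
    CommunityConfig,
    generate_community,
    generate_function_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return generate_function_catalog((3, 6, 12, 40), seed=11)


@pytest.fixture(scope="session")
def community(catalog):
    cfg = CommunityConfig(
        n_genomes=8,
        abundance_law="manual",
        law_params={"abundances": [0.30, 0.20, 0.15, 0.12, 0.09, 0.07, 0.04, 0.03]},
        repertoire_rule=lambda rank: 40 - 4 * rank,
        seed=23,
    )
    abundances, genes = generate_community(cfg, catalog, sample_id="S1")
    return abundances, genes


def make_records(spec, sample_id="S1"):
    """Helper: spec items are (function_counts dict under paths, genome)."""
    records = []
    i = 0
    for path, genome, count in spec:
        records.append(GeneRecord(f"g{i:03d}", sample_id, path, genome, count))
        i += 1
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(7)
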