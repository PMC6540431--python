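from __future__ import annotations

import numpy as np
import pytest

from famseq import redundancy, workflow
from famseq.family_annotation import iterate_annotation
from famseq.homology_search import SearchConfig


@pytest.fixture(scope="session")
def default_scenario():
    """The seed-pinned planted-family scenario (4 families x 8 members,
    divergence 0.3, 20% partials, 30 decoys, 5% near-duplicates)."""
    return workflow.default_scenario(seed=1)


@pytest.fixture(scope="session")
def default_annotation(default_scenario):
    """Collapse + full iterative annotation of the default scenario,
    shared across tests because the search stage dominates runtime."""
    clusters = redundancy.collapse(default_scenario.records)
    records, log = iterate_annotation(
        clusters.representatives,
        default_scenario.known_refs,
        default_scenario.policies,
        SearchConfig(),
    )
    return clusters, records, log


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
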