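"""Shared fixtures: one small synthetic benchmark reused across modules."""

import pytest

from submarker import markers as mk
from submarker.simulate import SimConfig, simulate_references


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=424242,
        core_gene_count=60,
        specific_gene_count=25,
        gene_length_mean=400.0,
        gene_length_sd=60.0,
        read_count=20_000,
    )


@pytest.fixture(scope="session")
def small_refs(small_cfg):
    return simulate_references(small_cfg)


@pytest.fixture(scope="session")
def small_db(small_refs):
    _, truth = small_refs
    cands = mk.select_candidates(truth.to_matrix())
    kept, verdicts = mk.filter_specificity(cands, truth.decoys)
    return mk.build_marker_db(kept, verdicts)
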