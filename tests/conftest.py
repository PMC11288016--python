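"""Shared fixtures: synthetic communities with planted ground truth.

Session-scoped so the (comparatively) expensive all-vs-all alignments run
once per test session.
"""

import pytest

from commprime import all_vs_all, build_catalog
from commprime.synth import generate_community, subsumed_plan, uniform_plan

# fixed study seeds: a 10-member community with 5 private + 2 all-shared
# genes per genome at 0.95 planted identity, and a 4-member community in
# which one genome is fully subsumed by another
GUT_SEED = 101
SUBSUMED_SEED = 202


@pytest.fixture(scope="session")
def gut_community(tmp_path_factory):
    d = tmp_path_factory.mktemp("gut")
    plan = uniform_plan(
        n_genomes=10, n_private=5, n_all_shared=2, identity=0.95, seed=GUT_SEED
    )
    truth = generate_community(plan, d)
    return d, truth


@pytest.fixture(scope="session")
def gut_catalog(gut_community):
    d, _ = gut_community
    return build_catalog(d)


@pytest.fixture(scope="session")
def gut_hits(gut_catalog):
    return all_vs_all(gut_catalog)


@pytest.fixture(scope="session")
def subsumed_community(tmp_path_factory):
    d = tmp_path_factory.mktemp("subsumed")
    plan = subsumed_plan(n_other=3, n_genes=5, identity=0.95, seed=SUBSUMED_SEED)
    truth = generate_community(plan, d)
    return d, truth


@pytest.fixture(scope="session")
def subsumed_catalog(subsumed_community):
    d, _ = subsumed_community
    return build_catalog(d)


@pytest.fixture(scope="session")
def subsumed_hits(subsumed_catalog):
    return all_vs_all(subsumed_catalog)
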