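"""Shared fixtures: a small seeded synthetic collection and a built database.

The "mini" scenario keeps the full 7-rank structure (3 genera × 3 species
× 5 strains) at a reduced genome length so module tests stay fast; the
database indexes strains 01–04 of every species, leaving strain 05 of
each species held out for profiling tests.
"""

from __future__ import annotations

import copy

import pytest

from sbtax.database import build_database, default_manifest
from sbtax.kmers import extract_kmers
from sbtax.simulate import SimulationConfig, simulate_collection

K = 15
MINI_SEED = 11


@pytest.fixture(scope="session")
def mini_scenario():
    config = SimulationConfig(seed=MINI_SEED, genome_length=12_000,
                              n_strains_per_species=5)
    genomes, truth = simulate_collection(config)
    lineages = truth.lineages()
    signatures = {g: extract_kmers([s], K) for g, s in genomes.items()}
    return {"genomes": genomes, "truth": truth, "lineages": lineages,
            "signatures": signatures, "config": config}


@pytest.fixture(scope="session")
def mini_train_ids(mini_scenario):
    return sorted(g for g in mini_scenario["genomes"] if not g.endswith("_05"))


@pytest.fixture(scope="session")
def mini_holdout_ids(mini_scenario):
    return sorted(g for g in mini_scenario["genomes"] if g.endswith("_05"))


@pytest.fixture(scope="session")
def mini_db_session(mini_scenario, mini_train_ids):
    sigs = mini_scenario["signatures"]
    lineages = mini_scenario["lineages"]
    entries = [(g, sigs[g], lineages[g]) for g in mini_train_ids]
    return build_database(entries, default_manifest(K))


@pytest.fixture()
def mini_db(mini_db_session):
    """Function-scoped deep copy, safe to mutate."""
    return copy.deepcopy(mini_db_session)
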