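"""Shared fixtures: small planted-signal datasets and trained bundles."""

import functools

import pytest

import zincsite as z
from zincsite.datasets import (
    known_sites_by_sequence,
    sample_negative_sequence,
    sample_negative_structure,
    sequence_candidates_from_catalogue,
    structure_candidates_from_catalogue,
)

# small grid used where the test is not about grid protocol itself
TINY_GRID = {
    "criterion": ["gini"],
    "max_depth": [None],
    "n_estimators": [30],
    "max_features": ["sqrt"],
}


def make_sequence_dataset(config: z.FixtureConfig, seed: int) -> z.LabeledDataset:
    fx = z.generate_sequence_fixtures(config)
    positives = sequence_candidates_from_catalogue(fx.catalogue, fx.sequences)
    sampler = functools.partial(
        sample_negative_sequence, fx.background_pool, config.signature,
        known_sites_by_sequence(fx.catalogue),
    )
    return z.build_balanced_dataset(
        positives, sampler, z.SequenceSiteFeaturizer(), rng=seed
    )


def make_structure_dataset(config: z.FixtureConfig, seed: int) -> z.LabeledDataset:
    fx = z.generate_structure_fixtures(config)
    positives = structure_candidates_from_catalogue(fx.catalogue, fx.structures)
    sampler = functools.partial(
        sample_negative_structure, fx.background_pool, config.signature
    )
    return z.build_balanced_dataset(
        positives, sampler, z.StructureSiteFeaturizer(), rng=seed
    )


@pytest.fixture(scope="session")
def seq_fixtures():
    return z.generate_sequence_fixtures(
        z.FixtureConfig(family="C2H2", n_positives=40, n_background=40, seed=11)
    )


@pytest.fixture(scope="session")
def seq_dataset(seq_fixtures):
    config = z.FixtureConfig(family="C2H2", n_positives=40, n_background=40, seed=11)
    return make_sequence_dataset(config, seed=11)


@pytest.fixture(scope="session")
def struct_fixtures():
    return z.generate_structure_fixtures(
        z.FixtureConfig(family="C4", n_positives=30, n_background=30, seed=7)
    )


@pytest.fixture(scope="session")
def struct_dataset():
    config = z.FixtureConfig(family="C4", n_positives=30, n_background=30, seed=7)
    return make_structure_dataset(config, seed=7)


@pytest.fixture(scope="session")
def seq_bundle(seq_dataset):
    """A sequence C2H2 model trained on the small strong-signal fixtures."""
    train, _ = z.split_train_test(seq_dataset, seed=11)
    params, _ = z.grid_search(train, grid=TINY_GRID, seed=11)
    return z.train_final(train, params, seed=11)


@pytest.fixture(scope="session")
def struct_bundle(struct_dataset):
    """A structure C4 model trained on the small strong-signal fixtures."""
    train, _ = z.split_train_test(struct_dataset, seed=7)
    params, _ = z.grid_search(train, grid=TINY_GRID, seed=7)
    return z.train_final(train, params, seed=7)
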