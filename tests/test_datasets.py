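"""Catalogue filtering, negative sampling and balanced dataset building."""

import functools

import numpy as np
import pandas as pd
import pytest

import zincsite as z
from zincsite.datasets import (
    SamplingExhaustedError,
    SiteCatalogueEntry,
    known_sites_by_sequence,
    read_catalogue,
    read_cluster_assignments,
    sequence_candidates_from_catalogue,
    write_catalogue,
)

C2H2 = z.parse_family("C2H2")


def entry(site_id, chains=("A",), resolution=None, positions=(0, 1, 2, 3),
          modality="sequence"):
    return SiteCatalogueEntry(
        site_id=site_id, family=C2H2, source_id=f"src_{site_id}",
        modality=modality, chains=tuple(chains),
        positions=tuple(positions) if modality == "sequence" else None,
        residues=(("A", 10, ""),) if modality == "structure" else None,
        resolution=resolution,
    )


class TestFilters:
    def test_multi_chain_sites_discarded(self):
        entries = [entry("a", chains=("A",)), entry("b", chains=("A", "B")),
                   entry("c", chains=("B",))]
        kept = z.filter_single_chain(entries)
        assert [e.site_id for e in kept] == ["a", "c"]
        assert z.filter_single_chain([]) == []

    def test_resolution_strictly_better_than_cutoff(self):
        entries = [entry("a", resolution=1.8), entry("b", resolution=2.4),
                   entry("c", resolution=2.0)]
        kept = z.filter_resolution(entries)
        assert [e.site_id for e in kept] == ["a"]  # 2.0 itself is excluded

    def test_missing_resolution_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = z.filter_resolution([entry("a", resolution=None)])
        assert kept == []
        assert "no resolution" in caplog.text


class TestCatalogueRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        entries = [
            entry("s1", positions=(4, 9, 14, 19)),
            entry("s2", modality="structure", resolution=1.5),
        ]
        path = tmp_path / "catalogue.tsv"
        write_catalogue(entries, path)
        back = read_catalogue(path)
        assert back[0].positions == (4, 9, 14, 19)
        assert back[1].residues == (("A", 10, ""),)
        assert back[1].resolution == 1.5
        assert back[0].family == C2H2


class TestNegativeSequenceSampling:
    def test_known_site_never_sampled(self):
        pool = {"s": "CCHHAAAA"}  # exactly one C2H2 arrangement
        known = {"s": {(0, 1, 2, 3)}}
        with pytest.raises(SamplingExhaustedError):
            z.sample_negative_sequence(pool, C2H2, known, rng=0, max_attempts=50)

    def test_pool_without_matches_errors(self):
        with pytest.raises(SamplingExhaustedError):
            z.sample_negative_sequence(
                {"a": "AAAAAA"}, z.parse_family("H3"), {}, rng=0, max_attempts=20)

    def test_deterministic_under_seed(self, seq_fixtures):
        known = known_sites_by_sequence(seq_fixtures.catalogue)
        draws_a = [z.sample_negative_sequence(
            seq_fixtures.background_pool, C2H2, known, rng=np.random.default_rng(3))
            for _ in range(5)]
        a = [(c.source_id, c.positions) for c in draws_a]
        rng = np.random.default_rng(3)
        b = [(c.source_id, c.positions) for c in
             [z.sample_negative_sequence(seq_fixtures.background_pool, C2H2,
                                         known, rng=rng) for _ in range(5)]]
        # a used a fresh generator per draw; b shared one - first draws agree
        assert a[0] == b[0]

    def test_overlapping_but_different_combination_allowed(self):
        pool = {"s": "CCCHHAAA"}  # 3 arrangements; one is a known site
        known = {"s": {(0, 1, 3, 4)}}
        for seed in range(10):
            c = z.sample_negative_sequence(pool, C2H2, known, rng=seed)
            assert c.positions != (0, 1, 3, 4)


class TestNegativeStructureSampling:
    def test_infeasible_only_structure_errors(self, struct_fixtures):
        far = z.generate_structure_fixtures(z.FixtureConfig(
            family="C4", n_positives=1, n_background=2, seed=1,
            decoy_scale=40.0, decoy_jitter=0.0))
        with pytest.raises(SamplingExhaustedError):
            z.sample_negative_structure(
                far.background_pool, z.parse_family("C4"), rng=0, max_attempts=30)

    def test_single_feasible_combination_returned(self, struct_fixtures):
        pool = {"one": struct_fixtures.structures[struct_fixtures.background_ids[0]]}
        c = z.sample_negative_structure(pool, z.parse_family("C4"), rng=0)
        cands = z.enumerate_structure_candidates(pool["one"], z.parse_family("C4"))
        assert len(cands) == 1
        assert c.residue_labels == cands[0].residue_labels

    def test_deterministic_under_seed(self, struct_fixtures):
        a = z.sample_negative_structure(
            struct_fixtures.background_pool, z.parse_family("C4"), rng=5)
        b = z.sample_negative_structure(
            struct_fixtures.background_pool, z.parse_family("C4"), rng=5)
        assert (a.source_id, a.residue_labels) == (b.source_id, b.residue_labels)


class TestBuildBalancedDataset:
    def test_exact_one_to_one_ratio(self, seq_dataset):
        assert seq_dataset.n_positive == 40
        assert seq_dataset.n_negative == 40
        assert seq_dataset.class_ratio == 1.0

    def test_single_positive(self, seq_fixtures):
        positives = sequence_candidates_from_catalogue(
            seq_fixtures.catalogue[:1], seq_fixtures.sequences)
        sampler = functools.partial(
            z.sample_negative_sequence, seq_fixtures.background_pool, C2H2, {})
        ds = z.build_balanced_dataset(positives, sampler,
                                      z.SequenceSiteFeaturizer(), rng=0)
        assert len(ds) == 2

    def test_negatives_share_schema_with_positives(self, seq_dataset):
        assert list(seq_dataset.X.columns) == z.sequence_feature_names(C2H2)
        assert not seq_dataset.X.isna().any().any()

    def test_no_negative_equals_a_known_positive(self, seq_fixtures, seq_dataset):
        known = known_sites_by_sequence(seq_fixtures.catalogue)
        negatives = seq_dataset.provenance[seq_dataset.y == 0]
        for _, row in negatives.iterrows():
            positions = tuple(int(p) - 1 for p in row["site"].split(","))
            assert positions not in known.get(row["source_id"], set())

    def test_exhausted_sampler_yields_partial_with_warning(self, seq_fixtures):
        positives = sequence_candidates_from_catalogue(
            seq_fixtures.catalogue, seq_fixtures.sequences)
        # a pool with a single distinct candidate cannot balance 40 positives
        pool = {"only": "AACAACAAHAAHAA"}
        sampler = functools.partial(
            z.sample_negative_sequence, pool, C2H2, {}, max_attempts=20)
        with pytest.warns(UserWarning, match="exhausted"):
            ds = z.build_balanced_dataset(
                positives, sampler, z.SequenceSiteFeaturizer(), rng=0)
        assert ds.n_negative < ds.n_positive

    def test_pure_function_of_seed(self, seq_fixtures):
        def build():
            positives = sequence_candidates_from_catalogue(
                seq_fixtures.catalogue, seq_fixtures.sequences)
            sampler = functools.partial(
                z.sample_negative_sequence, seq_fixtures.background_pool, C2H2,
                known_sites_by_sequence(seq_fixtures.catalogue))
            return z.build_balanced_dataset(
                positives, sampler, z.SequenceSiteFeaturizer(), rng=123)
        a, b = build(), build()
        pd.testing.assert_frame_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)
        pd.testing.assert_frame_equal(a.provenance, b.provenance)

    def test_tsv_round_trip(self, seq_dataset, tmp_path):
        path = tmp_path / "dataset.tsv"
        seq_dataset.to_tsv(path)
        back = z.LabeledDataset.from_tsv(path)
        assert back.family == seq_dataset.family
        assert back.modality == "sequence"
        np.testing.assert_allclose(back.X.to_numpy(), seq_dataset.X.to_numpy())
        np.testing.assert_array_equal(back.y, seq_dataset.y)


class TestRedundancyFilter:
    def test_singleton_clusters_keep_everything(self):
        entries = [entry(f"e{i}") for i in range(10)]
        clusters = {e.site_id: f"c{i}" for i, e in enumerate(entries)}
        assert len(z.apply_redundancy_filter(entries, clusters, rng=0)) == 10

    def test_one_cluster_keeps_one(self):
        entries = [entry(f"e{i}") for i in range(10)]
        clusters = {e.site_id: "c0" for e in entries}
        kept = z.apply_redundancy_filter(entries, clusters, rng=0)
        assert len(kept) == 1

    def test_deterministic_representatives(self):
        entries = [entry(f"e{i}") for i in range(12)]
        clusters = {e.site_id: f"c{i % 3}" for i, e in enumerate(entries)}
        a = [e.site_id for e in z.apply_redundancy_filter(entries, clusters, rng=9)]
        b = [e.site_id for e in z.apply_redundancy_filter(entries, clusters, rng=9)]
        assert a == b and len(a) == 3

    def test_missing_cluster_id_errors(self):
        entries = [entry("e0"), entry("e1")]
        with pytest.raises(KeyError, match="e1"):
            z.apply_redundancy_filter(entries, {"e0": "c0"}, rng=0)

    def test_cluster_file_round_trip(self, tmp_path, seq_fixtures):
        path = tmp_path / "clusters.tsv"
        assignment = z.generate_cluster_file(
            seq_fixtures.sequences, identity_proxy=0.9, seed=0, path=path)
        assert read_cluster_assignments(path) == assignment
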