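"""The synthetic generator: determinism, planted divergences and table shape."""
from __future__ import annotations

import dataclasses
import filecmp

import numpy as np
import pytest
from scipy import stats

from nivimyx.errors import ConfigError
from nivimyx.sequences import global_identity
from nivimyx.simulate import (SimulationConfig, generate_bundle, generate_fruitbody_survey,
                              generate_reference_pool, generate_soil_otu_table, write_bundle)

from conftest import SMALL_CONFIG

from _oracles import dp_identity

TINY = SimulationConfig(seed=19, n_morphospecies=4, n_genera=2, n_soil_only_species=1,
                        mean_clusters_per_species=1.5, mean_ribotypes_per_cluster=1.5,
                        n_specimens=60, n_samples=8, reads_per_sample_range=(500, 900),
                        n_unknown_otus=6, n_genus_level_otus=2)


class TestDeterminism:
    def test_same_seed_gives_identical_files(self, tmp_path):
        for d in ("a", "b"):
            write_bundle(generate_bundle(TINY), tmp_path / d)
        for rel in ("pool.fasta", "specimens.fasta", "specimens.tsv", "otu_table.tsv",
                    "otu_reps.fasta", "samples.tsv", "truth.json",
                    "temperature/1cl.csv", "snow/1cl.csv"):
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False), rel

    def test_different_seed_changes_sequences(self):
        p1, _ = generate_reference_pool(TINY)
        p2, _ = generate_reference_pool(dataclasses.replace(TINY, seed=20))
        assert {r.sequence for r in p1} != {r.sequence for r in p2}


class TestReferencePool:
    def test_degenerate_single_species_single_ribotype(self):
        cfg = SimulationConfig(n_morphospecies=1, n_genera=1, n_soil_only_species=0,
                               mean_clusters_per_species=1.0, mean_ribotypes_per_cluster=1.0)
        pool, truth = generate_reference_pool(cfg)
        assert len(pool) == 1
        assert len(truth.clusters) == 1

    def test_planted_divergences_verified_by_alignment(self):
        """All-pairs DP alignment: intra-cluster identity >= 0.991,
        inter-cluster identity <= 0.97."""
        pool, truth = generate_reference_pool(TINY)
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                ident, _, _ = dp_identity(a.sequence, b.sequence)
                same = truth.partition[a.id] == truth.partition[b.id]
                if same:
                    assert ident >= 0.991
                else:
                    assert ident <= 0.97

    def test_every_sequence_in_exactly_one_cluster(self):
        pool, truth = generate_reference_pool(SMALL_CONFIG)
        assert set(truth.partition) == {r.id for r in pool}
        members = [m for t in truth.clusters.values() for m in t.member_ids]
        assert sorted(members) == sorted(truth.partition)

    def test_unsatisfiable_divergence_raises(self):
        cfg = SimulationConfig(n_morphospecies=28, seq_length=60,
                               mean_ribotypes_per_cluster=1.0,
                               between_species_divergence=0.2)
        with pytest.raises(ConfigError, match="unsatisfiable"):
            generate_reference_pool(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(within_species_divergence=0.05,
                             between_species_divergence=0.03).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(soil_overlap_fraction=0.8, near_match_fraction=0.4).validate()


class TestFruitSurvey:
    def test_zero_error_rate_copies_pool_sequences(self, small_bundle):
        pool_seqs = {r.sequence for r in small_bundle.pool}
        assert all(s.sequence in pool_seqs for s in small_bundle.specimens)

    def test_empty_survey(self):
        cfg = dataclasses.replace(TINY, n_specimens=0)
        pool, truth = generate_reference_pool(cfg)
        assert generate_fruitbody_survey(cfg, pool, truth) == []

    def test_specimen_elevations_follow_planted_optimum(self):
        """Monte Carlo: with one taxon at optimum 1600 m the empirical mean
        elevation is within 3 standard errors."""
        cfg = SimulationConfig(seed=23, n_morphospecies=1, n_genera=1, n_soil_only_species=0,
                               mean_clusters_per_species=1.0, mean_ribotypes_per_cluster=1.0,
                               optimum_mean=1600.0, optimum_sd=0.0, elevation_breadth=100.0,
                               n_specimens=400)
        pool, truth = generate_reference_pool(cfg)
        specimens = generate_fruitbody_survey(cfg, pool, truth)
        elev = np.array([s.elevation for s in specimens])
        se = 100.0 / np.sqrt(len(elev))
        assert abs(elev.mean() - 1600.0) < 3 * se

    def test_specimen_metadata_complete(self, small_bundle):
        for s in small_bundle.specimens:
            assert s.year in SMALL_CONFIG.survey_years
            assert s.morphospecies and s.genus and s.site
            assert s.elevation is not None


class TestSoilTable:
    def test_read_totals_within_configured_range(self, small_bundle):
        lo, hi = SMALL_CONFIG.reads_per_sample_range
        per_sample = small_bundle.otu_table.reads_per_sample()
        assert ((per_sample >= lo) & (per_sample <= hi)).all()

    def test_full_overlap_plants_every_ribotype(self):
        cfg = dataclasses.replace(TINY, soil_overlap_fraction=1.0, near_match_fraction=0.0)
        pool, truth = generate_reference_pool(cfg)
        table = generate_soil_otu_table(cfg, pool, truth)
        soil_seqs = set(table.rep_seqs.values())
        fruit_ids = [r.id for r in pool if truth.partition[r.id].startswith("C")]
        by_id = {r.id: r for r in pool}
        assert all(by_id[i].sequence in soil_seqs for i in fruit_ids)

    def test_richness_declines_with_elevation(self, default_bundle):
        """Planted trend: Spearman correlation between per-sample OTU count
        and sample elevation is negative (39 samples)."""
        table = default_bundle.otu_table
        rho, p = stats.spearmanr(table.samples["elevation_m"], table.otus_per_sample())
        assert len(table.sample_ids) >= 16
        assert rho < 0
        assert p < 0.01

    def test_every_otu_has_reads_and_a_representative(self, small_bundle):
        table = small_bundle.otu_table
        assert (table.reads_per_otu() > 0).all()
        assert set(table.otu_ids) == set(table.rep_seqs)

    def test_planted_otu_kinds_have_correct_identity_bands(self, small_bundle):
        """Exact OTUs match a pool sequence verbatim; near OTUs peak in
        [0.991, 1); genus OTUs in [0.95, 0.98); unknown OTUs below 0.95."""
        pool_seqs = [r.sequence for r in small_bundle.pool]
        for otu_id, info in small_bundle.truth.soil_otus.items():
            seq = small_bundle.otu_table.rep_seqs[otu_id]
            best = max(global_identity(seq, p).identity for p in pool_seqs)
            kind = info["kind"]
            if kind in ("exact", "soil_only"):
                assert best == 1.0
            elif kind == "near":
                assert 0.991 <= best < 1.0
            elif kind == "genus":
                assert 0.95 <= best < 0.98
            else:
                assert best < 0.95
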