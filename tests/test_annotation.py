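"""Tiered OTU annotation: best hit, bootstrap confidence and the tier rules."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nivimyx.annotation import (MatchPolicy, Reference, ReferenceDB, annotate_otus,
                                best_hit, confidence_score)
from nivimyx.otu import OtuTable
from nivimyx.sequences import global_identity
from nivimyx.simulate import SimulationConfig, generate_bundle

from _oracles import dp_identity


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, seq, k):
    arr = list(seq)
    for p in rng.choice(len(seq), size=k, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


@pytest.fixture(scope="module")
def toy_refdb():
    rng = np.random.default_rng(17)
    refs = []
    for i in range(6):
        seq = random_dna(rng, 200)
        refs.append(Reference(f"R{i:02d}", seq, f"Lamproderma sp{i:02d}",
                              "Lamproderma", nivicolous=i % 2 == 0))
    return ReferenceDB(refs)


class TestBestHit:
    def test_exact_member_wins_with_identity_one(self, toy_refdb):
        ref = toy_refdb.refs[3]
        assert best_hit(ref.sequence, toy_refdb) == (ref.id, 1.0)

    def test_tie_goes_to_smaller_id(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 150)
        db = ReferenceDB([Reference("B", seq, "x", "g"), Reference("A", seq, "x", "g")])
        assert best_hit(seq, db)[0] == "A"

    def test_agrees_with_exhaustive_oracle(self):
        """50 random queries vs 20 references equal an all-pairs DP argmax."""
        rng = np.random.default_rng(99)
        refs = [Reference(f"R{i:02d}", random_dna(rng, 40), f"sp{i}", "g") for i in range(20)]
        db = ReferenceDB(refs)
        for _ in range(50):
            q = random_dna(rng, int(rng.integers(30, 50)))
            got_id, got_ident = best_hit(q, db)
            scores = {r.id: dp_identity(q, r.sequence)[0] for r in refs}
            best = max(scores.values())
            expect_id = min(r for r, s in scores.items() if s == best)
            assert got_id == expect_id
            assert got_ident == pytest.approx(best, abs=0)


class TestConfidence:
    def test_single_species_db_gives_full_confidence(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 200)
        db = ReferenceDB([Reference("A", seq, "only species", "g")])
        assert confidence_score(random_dna(rng, 200), db) == 1.0

    def test_unambiguous_query_gives_full_confidence(self, toy_refdb):
        # the query is a reference; all other species are ~75% identical
        q = toy_refdb.refs[0].sequence
        assert confidence_score(q, toy_refdb, seed=3) == 1.0

    def test_deterministic_under_seed(self, toy_refdb):
        rng = np.random.default_rng(8)
        q = mutate(rng, toy_refdb.refs[1].sequence, 30)
        assert confidence_score(q, toy_refdb, seed=42) == confidence_score(q, toy_refdb, seed=42)


class TestTierRules:
    def _single_otu_table(self, seq, samples=("S1",)):
        counts = pd.DataFrame({s: [100] for s in samples}, index=["OTU1"])
        return OtuTable(counts=counts, rep_seqs={"OTU1": seq},
                        samples=pd.DataFrame(index=list(samples)))

    @pytest.mark.parametrize("n_subs,expected_rank", [
        (0, "species"),    # identity 1.0 >= 0.98, confidence high
        (2, "species"),    # 0.99
        (8, "genus"),      # 0.96 in [0.95, 0.98)
        (14, "unassigned"),  # 0.93 < 0.95
    ])
    def test_identity_tiers(self, toy_refdb, n_subs, expected_rank):
        rng = np.random.default_rng(n_subs)
        ref = toy_refdb.refs[0]
        otu = mutate(rng, ref.sequence, n_subs)
        results, _ = annotate_otus(self._single_otu_table(otu), toy_refdb, seed=1)
        assert results[0].assigned_rank == expected_rank
        if expected_rank == "species":
            assert results[0].assigned_name == ref.species
        elif expected_rank == "genus":
            assert results[0].assigned_name == ref.genus

    def test_species_rank_requires_confidence(self, toy_refdb):
        """An OTU above the species identity cutoff but with a failed
        bootstrap falls back to the genus tier (never species)."""
        rng = np.random.default_rng(10)
        otu = mutate(rng, toy_refdb.refs[0].sequence, 2)
        strict = MatchPolicy(species_confidence=1.0)  # > 1.0 impossible
        results, _ = annotate_otus(self._single_otu_table(otu), toy_refdb, strict, seed=1)
        assert results[0].assigned_rank == "genus"

    def test_missing_representative_skipped_with_warning(self, toy_refdb):
        counts = pd.DataFrame({"S1": [5, 7]}, index=["OTU1", "OTU2"])
        table = OtuTable(counts=counts,
                         rep_seqs={"OTU1": toy_refdb.refs[0].sequence, "OTU2": ""},
                         samples=pd.DataFrame(index=["S1"]))
        with pytest.warns(UserWarning, match="OTU2"):
            results, _ = annotate_otus(table, toy_refdb, seed=1)
        assert [r.otu_id for r in results] == ["OTU1"]


class TestOnSyntheticTable:
    def test_planted_annotatable_read_fraction_recovered(self):
        """A table planted with 60% annotatable reads reports an annotated
        read fraction within 2 points of 60%."""
        cfg = SimulationConfig(seed=13, n_morphospecies=8, n_genera=4, n_soil_only_species=1,
                               n_specimens=100, n_samples=12, reads_per_sample_range=(2000, 5000),
                               n_unknown_otus=12, n_genus_level_otus=3,
                               annotatable_read_fraction=0.60)
        b = generate_bundle(cfg)
        db = ReferenceDB.from_records(
            b.pool, nivicolous={t.species: t.nivicolous for t in b.truth.clusters.values()})
        _, summary = annotate_otus(b.otu_table, db, seed=13)
        assert summary.annotated_read_fraction == pytest.approx(0.60, abs=0.02)

    def test_planted_otus_all_species_ranked(self, small_bundle):
        """With the planted pool as reference and substitution-free OTUs,
        every exact/near/soil-only OTU reaches species rank."""
        b = small_bundle
        db = ReferenceDB.from_records(
            b.pool, nivicolous={t.species: t.nivicolous for t in b.truth.clusters.values()})
        results, _ = annotate_otus(b.otu_table, db, seed=7)
        rank = {r.otu_id: r.assigned_rank for r in results}
        for otu_id, info in b.truth.soil_otus.items():
            if info["kind"] in ("exact", "near", "soil_only"):
                assert rank[otu_id] == "species", (otu_id, info)
            elif info["kind"] == "genus":
                assert rank[otu_id] == "genus"
            else:
                assert rank[otu_id] == "unassigned"

    def test_raising_species_threshold_is_monotone(self, small_bundle):
        b = small_bundle
        db = ReferenceDB.from_records(b.pool)
        _, loose = annotate_otus(b.otu_table, db, MatchPolicy(species_identity=0.98), seed=1)
        _, tight = annotate_otus(b.otu_table, db, MatchPolicy(species_identity=0.99), seed=1)
        assert tight.n_species_rank <= loose.n_species_rank
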