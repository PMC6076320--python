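"""Fruit-vs-soil matching, site sharing, genus composition and year overlap."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from nivimyx.concordance import (EXACT, NEAR, UNMATCHED, genus_composition,
                                 match_inventories, shared_unique_per_site, year_overlap)
from nivimyx.sequences import SequenceRecord, dedup_ribotypes


def random_dna(rng, n=300):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMatchInventories:
    def test_verbatim_soil_gives_all_exact(self):
        rng = np.random.default_rng(1)
        seqs = [random_dna(rng) for _ in range(5)]
        rts = dedup_ribotypes([SequenceRecord(f"f{i}", s, source="fruit")
                               for i, s in enumerate(seqs)])
        report = match_inventories(rts, [(f"o{i}", s) for i, s in enumerate(seqs)])
        assert report.n_exact == 5 and report.n_near == 0 and report.n_unmatched == 0

    def test_categories_match_planted_truth(self, default_bundle, pool_ribotypes):
        """Every pool ribotype falls in the category its cluster was planted
        with: exact clusters verbatim, near clusters within [0.991, 1),
        unmatched clusters below 0.991."""
        truth = default_bundle.truth
        report = match_inventories(pool_ribotypes, default_bundle.otu_table)
        by_id = {r.ribotype_id: r for r in report.results}
        expected = {"exact": EXACT, "near": NEAR, "unmatched": UNMATCHED, "soil_only": EXACT}
        for rt in pool_ribotypes:
            cat = truth.clusters[truth.partition[rt.member_ids[0]]].category
            assert by_id[rt.id].category == expected[cat]
        assert report.n_exact + report.n_near + report.n_unmatched == report.n_ribotypes

    def test_category_invariants(self, default_bundle, pool_ribotypes):
        report = match_inventories(pool_ribotypes, default_bundle.otu_table)
        for r in report.results:
            if r.category == EXACT:
                assert r.best_identity == 1.0
            elif r.category == NEAR:
                assert 0.991 <= r.best_identity < 1.0
            else:
                assert r.best_identity < 0.991
        if report.n_unmatched:
            lo, hi = report.unmatched_identity_range
            assert lo <= report.unmatched_identity_mean <= hi

    def test_overlap_fraction_within_binomial_ci(self, default_bundle, pool_ribotypes):
        """The recovered exact-match fraction is consistent (exact binomial
        95% CI) with the planted soil-overlap fraction."""
        fruit_rts = [rt for rt in pool_ribotypes
                     if default_bundle.truth.partition[rt.member_ids[0]].startswith("C")]
        report = match_inventories(fruit_rts, default_bundle.otu_table)
        ci = stats.binomtest(report.n_exact, report.n_ribotypes).proportion_ci(0.95)
        assert ci.low <= default_bundle.config.soil_overlap_fraction <= ci.high

    def test_lower_near_threshold_never_decreases_matches(self, default_bundle, pool_ribotypes):
        strict = match_inventories(pool_ribotypes, default_bundle.otu_table, near_threshold=0.995)
        loose = match_inventories(pool_ribotypes, default_bundle.otu_table, near_threshold=0.985)
        assert loose.n_unmatched <= strict.n_unmatched

    def test_cluster_rollup(self, default_bundle, pool_ribotypes, pool_clusters):
        report = match_inventories(pool_ribotypes, default_bundle.otu_table,
                                   clusters=pool_clusters)
        truth = default_bundle.truth
        rt_by_id = {r.id: r for r in pool_ribotypes}
        for cl in pool_clusters:
            cat = truth.clusters[truth.partition[rt_by_id[cl.member_ids[0]].member_ids[0]]].category
            assert report.cluster_matched[cl.cluster_id] == (cat != "unmatched")


class TestSiteSharing:
    def _records(self, counts_by_site):
        rng = np.random.default_rng(77)
        recs = []
        k = 0
        for site, n in counts_by_site.items():
            for _ in range(n):
                k += 1
                recs.append(SequenceRecord(f"f{k}", random_dna(rng), source="fruit", site=site))
        return recs

    def test_proportional_counts_give_r_one(self):
        recs = self._records({"1cl": 2, "2cl": 4, "3cl": 6, "4cl": 8})
        sharing = shared_unique_per_site(recs, [("o1", "ACGT" * 75)])
        assert sharing.r_unique == pytest.approx(1.0)

    def test_constant_counts_give_absent_r(self):
        recs = self._records({"1cl": 3, "2cl": 3, "3cl": 3})
        sharing = shared_unique_per_site(recs, [("o1", "ACGT" * 75)])
        assert sharing.r_unique is None  # zero variance in n_sequenced

    def test_specimen_effort_correlation_on_bundle(self, default_bundle):
        sharing = shared_unique_per_site(default_bundle.specimens, default_bundle.otu_table)
        assert sharing.r_unique is not None and sharing.r_unique > 0.5
        assert sharing.r_shared is not None and sharing.r_shared > 0.5
        assert (sharing.table["n_shared"] <= sharing.table["n_unique_ribotypes"]).all()


class TestGenusComposition:
    def test_two_dominant_genera_account_for_80_percent(self):
        items = ([("Lamproderma", 1)] * 40 + [("Diderma", 1)] * 40
                 + [("Physarum", 1)] * 10 + [("Meriderma", 1)] * 10)
        tab = genus_composition(items)
        assert tab["fraction"].head(2).sum() == pytest.approx(0.80)
        assert tab["fraction"].sum() == pytest.approx(1.0)

    def test_single_genus(self):
        tab = genus_composition([("Diderma", 7)])
        assert list(tab["fraction"]) == [1.0]

    def test_empty_inventory(self):
        assert genus_composition([]).empty

    def test_nivicolous_filter(self):
        tab = genus_composition([("A", 5), ("B", 5)], nivicolous={"A": True, "B": False},
                                nivicolous_only=True)
        assert list(tab["genus"]) == ["A"]


class TestYearOverlap:
    def _rec(self, k, year, species):
        rng = np.random.default_rng(k)
        return SequenceRecord(f"y{k}", random_dna(rng, 40), source="fruit",
                              year=year, morphospecies=species)

    def test_identical_lists_share_everything(self):
        recs = [self._rec(i * 10 + y, 2013 + y, f"sp{i}") for i in range(3) for y in range(3)]
        out = year_overlap(recs)
        assert out["regions"][(2013, 2014, 2015)] == 3
        assert sum(out["regions"].values()) == 3

    def test_disjoint_lists_have_empty_intersection(self):
        recs = [self._rec(1, 2013, "a"), self._rec(2, 2015, "b")]
        out = year_overlap(recs)
        assert out["regions"][(2013, 2015)] == 0
        assert out["regions"][(2013,)] == 1 and out["regions"][(2015,)] == 1

    def test_regions_equal_brute_force_set_arithmetic(self):
        sets = {2013: {"a", "b", "c"}, 2015: {"b", "c", "d"}, 2016: {"c", "d", "e", "f"}}
        recs = []
        k = 0
        for year, species in sets.items():
            for sp in sorted(species):
                k += 1
                recs.append(self._rec(k, year, sp))
        out = year_overlap(recs)
        # brute force with raw set operations
        assert out["regions"][(2013, 2015, 2016)] == len(sets[2013] & sets[2015] & sets[2016])
        assert out["regions"][(2013,)] == len(sets[2013] - sets[2015] - sets[2016])
        assert out["regions"][(2015, 2016)] == len((sets[2015] & sets[2016]) - sets[2013])
        assert sum(out["regions"].values()) == len(sets[2013] | sets[2015] | sets[2016])

    def test_excluded_year_is_dropped(self):
        recs = [self._rec(1, 2013, "a"), self._rec(2, 2017, "b")]
        out = year_overlap(recs, exclude_years=(2017,))
        assert set(out["per_year"]) == {2013}
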