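"""Genome-level analyses: similarity matrices, distinctiveness, enrichment."""

import math
from collections import Counter

import numpy as np
import pytest

from domarch import (
    GenomeSet,
    all_vs_all,
    align,
    distinctive_mdas,
    fisher_enrichment,
    fisher_test,
    group_by_taxon,
    mda_length_distribution,
    unique_compositions,
)
from domarch.model import MDA

from .conftest import fisher_two_sided_oracle, make_mda, make_token


@pytest.fixture
def genome_ab(hierarchy):
    fams = ["1.10.8.10/FF/1", "1.10.8.10/FF/2", "1.10.8.20/FF/1",
            "2.60.40.10/FF/1", "PF00069"]
    ga = GenomeSet(
        name="A",
        proteins={
            f"a{i}": make_mda(f"a{i}", fams[i:i + 2], hierarchy) for i in range(4)
        },
    )
    gb = GenomeSet(
        name="B",
        proteins={
            f"b{i}": make_mda(f"b{i}", fams[4 - i:4 - i + 2], hierarchy)
            for i in range(4)
        },
    )
    return ga, gb


class TestAllVsAll:
    def test_self_matrix_unit_diagonal_symmetric(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        m = all_vs_all(ga, ga, hierarchy)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)

    def test_empty_genome_gives_empty_matrix(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        m = all_vs_all(ga, GenomeSet(name="empty"), hierarchy)
        assert m.shape == (4, 0)

    def test_equals_pairwise_align_without_dedup(self, hierarchy, genome_ab):
        ga, gb = genome_ab
        # Add duplicate-architecture proteins to exercise the dedup path.
        ga.proteins["a_dup"] = make_mda("a_dup", ["1.10.8.10/FF/1", "1.10.8.10/FF/2"],
                                        hierarchy)
        m = all_vs_all(ga, gb, hierarchy)
        for pa, mda_a in ga.proteins.items():
            for pb, mda_b in gb.proteins.items():
                expected = align(mda_a, mda_b, hierarchy).normalized_score
                assert m.loc[pa, pb] == pytest.approx(expected)


class TestDistinctiveMDAs:
    def test_verbatim_copy_not_distinctive(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        copy = GenomeSet(name="C", proteins={
            "c0": make_mda("c0", ["1.10.8.10/FF/1", "1.10.8.10/FF/2"], hierarchy)
        })
        records = distinctive_mdas(copy, [ga], hierarchy, threshold=0.99)
        assert records[0].max_normalized_score == pytest.approx(1.0)
        assert not records[0].distinctive
        assert records[0].best_match_protein_id == "a0"

    def test_planted_unique_architecture_distinctive(self, hierarchy):
        query = GenomeSet(name="q", proteins={
            "u": make_mda("u", ["PF99999", "PF99998"], hierarchy)
        })
        comparison = GenomeSet(name="c", proteins={
            "c0": make_mda("c0", ["1.10.8.10/FF/1"], hierarchy)
        })
        (rec,) = distinctive_mdas(query, [comparison], hierarchy, threshold=0.5)
        assert rec.max_normalized_score <= 0.0
        assert rec.distinctive

    def test_empty_comparison_all_distinctive(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        records = distinctive_mdas(ga, [], hierarchy, threshold=0.5)
        assert all(r.distinctive for r in records)
        assert all(r.max_normalized_score == -math.inf for r in records)
        assert all(r.best_match_protein_id is None for r in records)

    def test_threshold_zero_nothing_distinctive_with_matches(self, hierarchy, genome_ab):
        ga, gb = genome_ab
        good = GenomeSet(name="g", proteins={
            "g0": make_mda("g0", ["1.10.8.10/FF/1", "1.10.8.10/FF/2"], hierarchy)
        })
        records = distinctive_mdas(good, [ga], hierarchy, threshold=0.0)
        assert not any(r.distinctive for r in records)

    def test_monotone_in_threshold(self, hierarchy, genome_ab):
        ga, gb = genome_ab
        flagged = {}
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            records = distinctive_mdas(ga, [gb], hierarchy, threshold=thr)
            flagged[thr] = {r.protein_id for r in records if r.distinctive}
        thresholds = sorted(flagged)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert flagged[lo] <= flagged[hi]

    def test_sorted_ascending_by_score(self, hierarchy, genome_ab):
        ga, gb = genome_ab
        records = distinctive_mdas(ga, [gb], hierarchy)
        scores = [r.max_normalized_score for r in records]
        assert scores == sorted(scores)

    def test_invalid_threshold_rejected(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        with pytest.raises(ValueError, match="threshold"):
            distinctive_mdas(ga, [], hierarchy, threshold=1.5)


class TestUniqueCompositions:
    def test_identical_genomes_give_empty_set(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        assert unique_compositions(ga, ga) == set()

    def test_multiset_semantics(self, hierarchy):
        f1, f2 = "1.10.8.10/FF/1", "1.10.8.20/FF/1"
        ga = GenomeSet(name="A", proteins={"x": make_mda("x", [f1, f1, f2], hierarchy)})
        gb = GenomeSet(name="B", proteins={"y": make_mda("y", [f1, f2], hierarchy)})
        assert unique_compositions(ga, gb) == {"x"}

    def test_permuted_order_is_not_unique(self, hierarchy):
        f1, f2, f3 = "1.10.8.10/FF/1", "1.10.8.20/FF/1", "2.60.40.10/FF/1"
        ga = GenomeSet(name="A", proteins={"x": make_mda("x", [f3, f1, f2], hierarchy)})
        gb = GenomeSet(name="B", proteins={"y": make_mda("y", [f1, f2, f3], hierarchy)})
        assert unique_compositions(ga, gb) == set()


class TestFisherEnrichment:
    def test_ubiquitous_family_not_enriched(self, hierarchy):
        fam = "1.10.8.10/FF/1"
        ga = GenomeSet(name="A", proteins={
            f"a{i}": make_mda(f"a{i}", [fam], hierarchy) for i in range(5)
        })
        gb = GenomeSet(name="B", proteins={
            f"b{i}": make_mda(f"b{i}", [fam], hierarchy) for i in range(8)
        })
        (res,) = fisher_enrichment(ga, [gb])
        assert res.p_value == pytest.approx(1.0)

    def test_fg_equals_bg_no_association(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        results = fisher_enrichment(ga, [ga])
        assert all(r.p_value == pytest.approx(1.0) for r in results)
        assert all(r.odds_ratio == pytest.approx(1.0) for r in results)

    def test_table_3_7_0_10_matches_enumeration(self):
        _, p = fisher_test(3, 7, 0, 10)
        assert p == pytest.approx(fisher_two_sided_oracle(3, 7, 0, 10), abs=1e-12)

    def test_enriched_family_detected(self, hierarchy):
        hot, cold = "1.10.8.10/FF/1", "2.60.40.10/FF/1"
        ga = GenomeSet(name="A", proteins={
            f"a{i}": make_mda(f"a{i}", [hot], hierarchy) for i in range(10)
        })
        gb = GenomeSet(name="B", proteins={
            f"b{i}": make_mda(f"b{i}", [cold], hierarchy) for i in range(10)
        })
        results = fisher_enrichment(ga, [gb])
        top = results[0]
        assert top.family_id == hot
        assert top.odds_ratio == math.inf
        assert top.q_value < 0.01
        assert (top.count_fg, top.total_fg, top.count_bg, top.total_bg) == (10, 10, 0, 10)

    def test_qvalues_bounded_and_ordered(self, hierarchy, genome_ab):
        ga, gb = genome_ab
        results = fisher_enrichment(ga, [gb])
        for r in results:
            assert 0.0 <= r.p_value <= 1.0
            assert r.p_value <= r.q_value <= 1.0
        assert [r.q_value for r in results] == sorted(r.q_value for r in results)

    def test_presence_mode_collapses_tandem_repeats(self, hierarchy):
        fam = "1.10.8.10/FF/1"
        ga = GenomeSet(name="A", proteins={
            "a0": make_mda("a0", [fam, fam, fam], hierarchy)
        })
        gb = GenomeSet(name="B", proteins={"b0": make_mda("b0", [fam], hierarchy)})
        (res,) = fisher_enrichment(ga, [gb], mode="presence")
        assert (res.count_fg, res.total_fg) == (1, 1)
        (res_c,) = fisher_enrichment(ga, [gb], mode="counts")
        assert (res_c.count_fg, res_c.total_fg) == (3, 3)

    def test_empty_foreground_rejected(self, hierarchy):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(GenomeSet(name="E"), [])


class TestMDALengthDistribution:
    def test_counts_domains_per_protein(self, hierarchy):
        g = GenomeSet(name="g", proteins={
            "p1": make_mda("p1", ["1.10.8.10/FF/1"], hierarchy),
            "p2": make_mda("p2", ["1.10.8.20/FF/1"], hierarchy),
            "p3": make_mda("p3", ["1.10.8.10/FF/1"] * 4, hierarchy),
        })
        assert mda_length_distribution(g) == Counter({1: 2, 4: 1})

    def test_empty_genome(self):
        assert mda_length_distribution(GenomeSet(name="g")) == Counter()

    def test_longest_transcript_applied_first(self, hierarchy):
        proteins = {
            "t_short": make_mda("t_short", ["1.10.8.10/FF/1"], hierarchy),
            "t_long": make_mda("t_long", ["1.10.8.10/FF/1", "1.10.8.20/FF/1"], hierarchy),
            "solo": make_mda("solo", ["2.60.40.10/FF/1"], hierarchy),
        }
        g = GenomeSet(name="g", proteins=proteins,
                      gene_map={"gene1": {"t_short", "t_long"}, "gene2": {"solo"}})
        hist = mda_length_distribution(g)
        assert sum(hist.values()) == 2
        assert hist == Counter({2: 1, 1: 1})

    def test_total_equals_representative_proteins(self, hierarchy, genome_ab):
        ga, _ = genome_ab
        assert sum(mda_length_distribution(ga).values()) == len(ga.proteins)


class TestGroupByTaxon:
    def _genome(self, name, lineage):
        return GenomeSet(name=name, proteins={}, taxon_lineage=lineage)

    def test_shared_level_single_group(self):
        gs = [
            self._genome("human", [("superkingdom", "Eukaryota"), ("kingdom", "Metazoa")]),
            self._genome("fly", [("superkingdom", "Eukaryota"), ("kingdom", "Metazoa")]),
        ]
        groups = group_by_taxon(gs, "kingdom")
        assert set(groups) == {"Metazoa"} and len(groups["Metazoa"]) == 2

    def test_empty_list(self):
        assert group_by_taxon([], "kingdom") == {}

    def test_partition_exhaustive_and_disjoint(self):
        import random

        rng = random.Random(13)
        ranks = ["superkingdom", "kingdom", "phylum"]
        gs = []
        for i in range(30):
            lineage = [
                (r, f"{r}_{rng.randint(0, 2)}") for r in ranks[: rng.randint(0, 3)]
            ] or None
            gs.append(self._genome(f"g{i}", lineage))
        groups = group_by_taxon(gs, "phylum")
        seen = [g.name for members in groups.values() for g in members]
        assert sorted(seen) == sorted(g.name for g in gs)
        assert len(seen) == len(set(seen))

    def test_missing_level_goes_unclassified(self):
        gs = [self._genome("mystery", [("superkingdom", "Eukaryota")])]
        groups = group_by_taxon(gs, "phylum")
        assert set(groups) == {"unclassified"}
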