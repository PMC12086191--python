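import numpy as np
import pytest

from drugvec.datasets import ERBB_PATHWAY_ID, erbb_catalog, load_erbb_fixture
from drugvec.relations import (RelationDataError, RelationSet,
                               eligible_pathways, load_concept_years,
                               load_pair_years, load_pathways, load_relations,
                               mean_answer_sizes, relation_statistics,
                               restrict_by_year, restrict_to_pathway,
                               split_known_unknown, PathwayCatalog,
                               PathwayEntry, YearAnnotations)


class TestLoadRelations:
    def test_deduplicates(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("d1\tgA\nd1\tgA\nd2\tgB\n")
        assert len(load_relations(p)) == 2

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("")
        rel = load_relations(p)
        assert len(rel) == 0 and not rel.drugs_related and not rel.genes_related

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("d1\tgA\nonlyonecolumn\n")
        with pytest.raises(RelationDataError, match="line 2"):
            load_relations(p)

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("drug_id\tgene_id\nd1\tgA\n")
        assert len(load_relations(p)) == 1


class TestErbBFixture:
    """The packaged ErbB signaling pathway data (KEGG hsa04012)."""

    def test_membership_sizes(self):
        rel, entry = load_erbb_fixture()
        assert len(entry.drugs) == 19
        assert len(entry.genes) == 84
        assert len(rel) == 34

    def test_known_pairs_present(self):
        rel, _ = load_erbb_fixture()
        assert ("Temsirolimus", "MTOR") in rel
        assert rel.genes_of("Bosutinib") == {"ABL1", "SRC"}

    def test_projection_counts(self):
        rel, _ = load_erbb_fixture()
        assert len(rel.drugs_related) == 19    # every listed drug has a pair
        assert len(rel.genes_related) == 10    # distinct target genes

    def test_pathway_restriction_is_identity_on_fixture(self):
        rel, _ = load_erbb_fixture()
        view = restrict_to_pathway(rel, erbb_catalog(), ERBB_PATHWAY_ID)
        assert view.pairs == rel.pairs


class TestAnswerSets:
    def test_empty_relations(self):
        rel = RelationSet.from_pairs([])
        by_drug, by_gene = rel.answer_sets()
        assert by_drug == {} and by_gene == {}

    def test_sizes_sum_to_relation_count(self, tiny_relations):
        by_drug, by_gene = tiny_relations.answer_sets()
        n = len(tiny_relations)
        assert sum(len(v) for v in by_drug.values()) == n
        assert sum(len(v) for v in by_gene.values()) == n

    def test_random_instances_preserve_count_identity(self, rng):
        for _ in range(10):
            pairs = {(f"d{rng.integers(6)}", f"g{rng.integers(8)}")
                     for _ in range(rng.integers(1, 25))}
            rel = RelationSet.from_pairs(pairs)
            by_drug, by_gene = rel.answer_sets()
            assert sum(map(len, by_drug.values())) == len(rel)
            assert sum(map(len, by_gene.values())) == len(rel)


class TestPathwayRestriction:
    def test_disjoint_memberships_give_empty_view(self, tiny_relations):
        cat = PathwayCatalog([PathwayEntry("p", "p", frozenset({"d4"}),
                                           frozenset({"g4"}))])
        assert len(restrict_to_pathway(tiny_relations, cat, "p")) == 0

    def test_unknown_pathway_errors(self, tiny_relations, tiny_catalog):
        with pytest.raises(RelationDataError, match="unknown pathway"):
            restrict_to_pathway(tiny_relations, tiny_catalog, "nope")

    def test_matches_bruteforce_filter(self, rng, tiny_catalog):
        pairs = {(f"d{rng.integers(5)}", f"g{rng.integers(5)}")
                 for _ in range(12)}
        rel = RelationSet.from_pairs(pairs)
        for pid in tiny_catalog.pathway_ids:
            e = tiny_catalog[pid]
            expected = {(d, g) for d in e.drugs for g in e.genes
                        if (d, g) in pairs}
            assert restrict_to_pathway(rel, tiny_catalog, pid).pairs == expected

    def test_subset_and_idempotent(self, tiny_relations, tiny_catalog):
        view = restrict_to_pathway(tiny_relations, tiny_catalog, "pA")
        assert view.pairs <= tiny_relations.pairs
        again = restrict_to_pathway(view.as_relation_set(), tiny_catalog, "pA")
        assert again.pairs == view.pairs


class TestEligiblePathways:
    def test_single_related_drug_excluded(self):
        rel = RelationSet.from_pairs([("d0", "g0"), ("d0", "g1")])
        cat = PathwayCatalog([PathwayEntry("p", "p", frozenset({"d0"}),
                                           frozenset({"g0", "g1"}))])
        assert eligible_pathways(rel, cat) == []

    def test_erbb_fixture_included(self):
        rel, _ = load_erbb_fixture()
        assert eligible_pathways(rel, erbb_catalog()) == [ERBB_PATHWAY_ID]

    def test_empty_catalog(self, tiny_relations):
        assert eligible_pathways(tiny_relations, PathwayCatalog([])) == []


class TestYearRestriction:
    def test_late_cutoff_keeps_everything(self, tiny_relations, tiny_years):
        assert restrict_by_year(tiny_relations, tiny_years, 2100).pairs \
            == tiny_relations.pairs

    def test_early_cutoff_empties(self, tiny_relations, tiny_years):
        assert len(restrict_by_year(tiny_relations, tiny_years, 1900)) == 0

    def test_matches_bruteforce(self, tiny_relations, tiny_years):
        for y in (1985, 1995, 2005):
            got = restrict_by_year(tiny_relations, tiny_years, y)
            expected = {(d, g) for d, g in tiny_relations.pairs
                        if tiny_years.drug_year[d] <= y
                        and tiny_years.gene_year[g] <= y}
            assert got.pairs == expected

    def test_monotone_in_year(self, tiny_relations, tiny_years):
        prev = frozenset()
        for y in range(1980, 2030, 5):
            cur = restrict_by_year(tiny_relations, tiny_years, y).pairs
            assert prev <= cur
            prev = cur

    def test_missing_year_lists_offenders(self, tiny_relations):
        with pytest.raises(RelationDataError, match="d0"):
            restrict_by_year(tiny_relations, YearAnnotations(), 2000)


class TestKnownUnknownSplit:
    def test_all_pairs_known_when_cutoff_late(self, tiny_relations, tiny_years):
        ry = restrict_by_year(tiny_relations, tiny_years, 2100)
        # (d3, g3) has no co-appearance year, so it stays unknown forever
        known, unknown = split_known_unknown(ry, tiny_years, 2100)
        assert unknown.pairs == {("d3", "g3")}
        assert known.pairs | unknown.pairs == ry.pairs

    def test_pair_seen_late_is_unknown(self):
        years = YearAnnotations(drug_year={"d": 1990}, gene_year={"g": 1990},
                                pair_year={("d", "g"): 2005})
        rel = RelationSet.from_pairs([("d", "g")])
        ry = restrict_by_year(rel, years, 2000)
        assert ("d", "g") in ry
        known, unknown = split_known_unknown(ry, years, 2000)
        assert ("d", "g") in unknown and len(known) == 0

    def test_partition_matches_predicate(self, tiny_relations, tiny_years):
        for y in (1990, 2000, 2012):
            ry = restrict_by_year(tiny_relations, tiny_years, y)
            known, unknown = split_known_unknown(ry, tiny_years, y)
            assert not (known.pairs & unknown.pairs)
            assert known.pairs | unknown.pairs == ry.pairs
            for pair in ry.pairs:
                py = tiny_years.pair_year.get(pair)
                assert (pair in known.pairs) == (py is not None and py <= y)

    def test_known_monotone_in_year(self, tiny_relations, tiny_years):
        prev = frozenset()
        for y in range(1985, 2025, 5):
            ry = restrict_by_year(tiny_relations, tiny_years, 2100)
            known, _ = split_known_unknown(ry, tiny_years, y)
            assert prev <= known.pairs
            prev = known.pairs

    def test_inconsistent_pair_year_rejected(self):
        years = YearAnnotations(drug_year={"d": 2000}, gene_year={"g": 1990},
                                pair_year={("d", "g"): 1995})
        with pytest.raises(RelationDataError, match="before concept years"):
            years.validate()


class TestLoaders:
    def test_pathway_and_year_files(self, tmp_path):
        (tmp_path / "p.tsv").write_text(
            "pw1\tPathway One\td1\tdrug\npw1\tPathway One\tgA\tgene\n")
        cat = load_pathways(tmp_path / "p.tsv")
        assert cat["pw1"].drugs == {"d1"} and cat["pw1"].genes == {"gA"}

        (tmp_path / "cy.tsv").write_text("d1\tdrug\t1999\ngA\tgene\t2001\n")
        years = load_concept_years(tmp_path / "cy.tsv")
        assert years.drug_year["d1"] == 1999

        (tmp_path / "py.tsv").write_text("d1\tgA\t2003\n")
        load_pair_years(tmp_path / "py.tsv", into=years)
        years.validate()
        assert years.pair_year[("d1", "gA")] == 2003

    def test_bad_member_type_rejected(self, tmp_path):
        (tmp_path / "p.tsv").write_text("pw1\tP\tx\tprotein\n")
        with pytest.raises(RelationDataError, match="member_type"):
            load_pathways(tmp_path / "p.tsv")


class TestStatistics:
    def test_mean_answer_sizes_identity(self, tiny_relations):
        stats = relation_statistics(tiny_relations)
        by_drug, by_gene = tiny_relations.answer_sets()
        assert stats["mean_genes_per_drug"] == pytest.approx(
            np.mean([len(v) for v in by_drug.values()]))
        assert stats["mean_drugs_per_gene"] == pytest.approx(
            np.mean([len(v) for v in by_gene.values()]))

    def test_closed_form(self):
        md, mg = mean_answer_sizes(34, 19, 10)
        assert md == pytest.approx(34 / 19)
        assert mg == pytest.approx(3.4)
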