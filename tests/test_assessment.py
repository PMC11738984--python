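"""Assessment: lineage, repertoires, completeness, consistency, invariants."""

import numpy as np
import pytest

from hogqc.assessment import (
    CompletenessClass,
    ConsistencyClass,
    ThresholdConfig,
    assess_completeness,
    assess_consistency,
    conserved_repertoire,
    database_species,
    fragment_set_overlap,
    lineage_repertoire,
    run_full_assessment,
    select_ancestral_lineage,
)
from hogqc.hogdb import HOG, HOGMember, build_database
from hogqc.placement import Placement
from hogqc.species_inference import TaxaInference
from hogqc.taxonomy import RankWarning

from conftest import make_tree


def _pl(pid, hog, root, length=100, overlap=1.0, ratio=1.0):
    return Placement(protein_id=pid, gene_id=pid, query_length=length,
                     placed_hog=hog, root_hog=root, score=10.0,
                     overlap_fraction=overlap, length_ratio=ratio)


def _unplaced(pid):
    return Placement(protein_id=pid, gene_id=pid, query_length=50)


@pytest.fixture()
def genus_tree():
    """Lineage ladder: root(7 sp) > mid(6 sp) > genus(6 sp? no: 5 sp)."""
    edges = [("root", None), ("mid", "root"), ("genus", "mid"),
             ("sx", "root"), ("sy", "mid")]
    edges += [(f"s{i}", "genus") for i in range(6)]
    ranks = {"root": "domain", "mid": "family", "genus": "genus"}
    return make_tree(edges, ranks)


def _db_with_members(tree, level_members, k=6):
    """One single-member-list HOG per (hog_id, level, [species..]) tuple."""
    hogs = []
    for hog_id, level, species_list, parent in level_members:
        hog = HOG(hog_id=hog_id, level=level, parent_hog=parent)
        hog.members = [HOGMember(sp, f"{sp}.{hog_id}", 100, None)
                       for sp in species_list]
        hogs.append(hog)
    return build_database(tree, hogs, k=k, apply_retention_filter=False)


class TestAncestralLineage:
    def test_genus_with_enough_species_warns_too_specific(self, genus_tree):
        db = _db_with_members(genus_tree, [
            ("f1", "genus", [f"s{i}" for i in range(6)], None),
        ])
        lineage, warning = select_ancestral_lineage("s0", db)
        assert lineage == "genus"
        assert warning == RankWarning.TOO_SPECIFIC

    def test_walks_to_root_when_all_ancestors_sparse(self, genus_tree):
        db = _db_with_members(genus_tree, [
            ("f1", "root", ["s0", "s1", "s2", "sx", "sy"], None),
        ])
        lineage, warning = select_ancestral_lineage(
            "s0", db, ThresholdConfig(min_lineage_species=5))
        assert lineage == "root"
        assert warning == RankWarning.TOO_BROAD

    def test_matches_path_scan_oracle(self, world):
        db = world.database
        cfg = ThresholdConfig()
        db_sp = database_species(db)
        q = world.query_species[0]
        lineage, _ = select_ancestral_lineage(q, db, cfg)
        # oracle: linear scan of the lineage path
        expected = None
        for clade in reversed(world.taxonomy.lineage_path(q)):
            if len(world.taxonomy.species_under(clade) & db_sp) >= 5:
                expected = clade
                break
        assert lineage == expected

    def test_held_out_species_does_not_count(self, world):
        assert world.query_species[0] not in database_species(world.database)

    def test_too_small_database_is_config_error(self, genus_tree):
        db = _db_with_members(genus_tree, [("f1", "root", ["s0"], None)])
        with pytest.raises(ValueError):
            select_ancestral_lineage("s0", db)


class TestRepertoires:
    def _cov_db(self, genus_tree, n_present):
        species = [f"s{i}" for i in range(n_present)]
        return _db_with_members(genus_tree, [("f1", "genus", species, None)])

    def test_full_coverage_included(self, genus_tree):
        db = self._cov_db(genus_tree, 6)
        assert conserved_repertoire("genus", db) == {"f1"}

    def test_half_coverage_excluded(self, genus_tree):
        db = self._cov_db(genus_tree, 3)
        assert conserved_repertoire("genus", db) == set()

    def test_exact_boundary_is_conserved_by_default(self, genus_tree):
        # hold the held-out convention aside: 5 of 6 species is not 0.8,
        # use a 5-species clade via config on the world below instead;
        # here 6 species and 0.8 boundary needs a 5-member set on 6:
        # 5/6 = 0.833 >= 0.8 included; 4/6 = 0.667 excluded
        assert conserved_repertoire("genus", self._cov_db(genus_tree, 5)) \
            == {"f1"}
        assert conserved_repertoire("genus", self._cov_db(genus_tree, 4)) \
            == set()

    def test_strict_variant_excludes_exact_boundary(self):
        tree = make_tree([("root", None)] +
                         [(f"s{i}", "root") for i in range(5)])
        db = _db_with_members(tree, [("f1", "root",
                                      ["s0", "s1", "s2", "s3"], None)])
        assert db.species_coverage("f1") == pytest.approx(0.8)
        assert conserved_repertoire("root", db) == {"f1"}
        strict = ThresholdConfig(conserved_strict=True)
        assert conserved_repertoire("root", db, strict) == set()

    def test_matches_filter_oracle_on_world(self, world):
        db = world.database
        lineage = world.reference_clade
        cfg = ThresholdConfig()
        got = conserved_repertoire(lineage, db, cfg)
        expected = {h for h in db.hogs_defined_at(lineage)
                    if db.species_coverage(h) >= cfg.conserved_coverage}
        assert got == expected
        assert len(got) > 50

    def test_lineage_repertoire_includes_later_families(self, genus_tree):
        db = _db_with_members(genus_tree, [
            ("old", "genus", [f"s{i}" for i in range(6)], None),
            ("young", "s0", ["s0"], None),
            ("foreign", "root", ["sx"], None),
        ])
        rep = lineage_repertoire("genus", db)
        assert "old" in rep and "young" in rep
        assert "foreign" not in rep

    def test_lineage_repertoire_matches_scan_on_world(self, world):
        db = world.database
        lineage = world.reference_clade
        rep = lineage_repertoire(lineage, db)
        lineage_species = world.taxonomy.species_under(lineage)
        expected = set(conserved_repertoire(lineage, db))
        for hid, hog in db.hogs.items():
            if hog.level != lineage and \
                    world.taxonomy.is_descendant(hog.level, lineage):
                members = {m.species_id for m in db.subtree_members(hid)}
                if members & lineage_species:
                    expected.add(hid)
        assert rep == expected


@pytest.fixture()
def comp_db(genus_tree):
    """A conserved family with sub-HOGs, plus an independent family."""
    all_sp = [f"s{i}" for i in range(6)]
    return _db_with_members(genus_tree, [
        ("fam", "genus", all_sp, None),
        ("fam.a", "s0", ["s0"], "fam"),
        ("fam.b", "s0", ["s0"], "fam"),
        ("other", "genus", all_sp, None),
        ("parent", "mid", ["sy"] + all_sp, None),
        ("parent.g", "genus", all_sp, "parent"),
    ])


class TestCompleteness:
    def test_single_copy(self, comp_db):
        classes = assess_completeness([_pl("p", "fam", "fam")],
                                      {"fam"}, comp_db)
        assert classes["fam"] == CompletenessClass.SINGLE

    def test_single_overspecific_hit(self, comp_db):
        classes = assess_completeness([_pl("p", "fam.a", "fam")],
                                      {"fam"}, comp_db)
        assert classes["fam"] == CompletenessClass.SINGLE

    def test_single_underspecific_hit(self, comp_db):
        classes = assess_completeness([_pl("p", "parent", "parent")],
                                      {"parent.g"}, comp_db)
        assert classes["parent.g"] == CompletenessClass.SINGLE

    def test_duplicated_unexpected(self, comp_db):
        pls = [_pl("p1", "fam", "fam"), _pl("p2", "fam", "fam")]
        classes = assess_completeness(pls, {"fam"}, comp_db)
        assert classes["fam"] == CompletenessClass.DUPLICATED_UNEXPECTED

    def test_duplicated_expected_via_subfamilies(self, comp_db):
        pls = [_pl("p1", "fam.a", "fam"), _pl("p2", "fam.b", "fam")]
        classes = assess_completeness(pls, {"fam"}, comp_db)
        assert classes["fam"] == CompletenessClass.DUPLICATED_EXPECTED

    def test_mixed_ancestral_and_sub_placement_is_expected(self, comp_db):
        pls = [_pl("p1", "fam", "fam"), _pl("p2", "fam.a", "fam")]
        classes = assess_completeness(pls, {"fam"}, comp_db)
        assert classes["fam"] == CompletenessClass.DUPLICATED_EXPECTED

    def test_missing(self, comp_db):
        classes = assess_completeness([], {"fam", "other"}, comp_db)
        assert classes == {"fam": CompletenessClass.MISSING,
                           "other": CompletenessClass.MISSING}

    def test_ancestor_hits_never_duplicate(self, comp_db):
        pls = [_pl("p1", "parent", "parent"), _pl("p2", "parent", "parent")]
        classes = assess_completeness(pls, {"parent.g"}, comp_db)
        assert classes["parent.g"] == CompletenessClass.SINGLE

    def test_classes_partition_conserved_set(self, comp_db):
        conserved = {"fam", "other", "parent.g"}
        pls = [_pl("p1", "fam.a", "fam")]
        classes = assess_completeness(pls, conserved, comp_db)
        assert set(classes) == conserved


class TestConsistency:
    def _taxa(self, contaminants=(), proteins=(), ambiguous=()):
        taxa = TaxaInference(likely_clades=["genus"] + list(contaminants),
                             main_taxon="genus",
                             contaminants=list(contaminants))
        for clade in contaminants:
            taxa.unambiguous[clade] = set(proteins)
        taxa.ambiguous_contaminant = set(ambiguous)
        return taxa

    def test_unplaced_is_unknown(self, comp_db):
        out = assess_consistency([_unplaced("u")], "genus", self._taxa(),
                                 comp_db)
        assert out[0].category == ConsistencyClass.UNKNOWN

    def test_lineage_member_is_consistent(self, comp_db):
        out = assess_consistency([_pl("p", "fam", "fam")], "genus",
                                 self._taxa(), comp_db)
        assert out[0].category == ConsistencyClass.CONSISTENT

    def test_contaminant_attribution(self, comp_db):
        # a HOG with no genus member: private to sx under the root
        pls = [_pl("c", "foreign", "foreign")]
        db2 = _db_with_members(comp_db.taxonomy, [
            ("foreign", "sx", ["sx"], None)])
        taxa = self._taxa(contaminants=["sx"], proteins=["c"])
        out = assess_consistency(pls, "genus", taxa, db2)
        assert out[0].category == ConsistencyClass.CONTAMINANT

    def test_inconsistent_when_no_evidence(self, genus_tree):
        db = _db_with_members(genus_tree, [("foreign", "sx", ["sx"], None)])
        out = assess_consistency([_pl("p", "foreign", "foreign")], "genus",
                                 self._taxa(), db)
        assert out[0].category == ConsistencyClass.INCONSISTENT

    def test_fragment_flag_with_consistent_category(self, comp_db):
        out = assess_consistency(
            [_pl("p", "fam", "fam", overlap=0.95, ratio=0.4)],
            "genus", self._taxa(), comp_db)
        assert out[0].category == ConsistencyClass.CONSISTENT
        assert out[0].fragment and not out[0].partial

    def test_partial_takes_precedence_over_fragment(self, comp_db):
        out = assess_consistency(
            [_pl("p", "fam", "fam", overlap=0.6, ratio=0.4)],
            "genus", self._taxa(), comp_db)
        assert out[0].partial and not out[0].fragment

    def test_boundaries_are_strict(self, comp_db):
        out = assess_consistency(
            [_pl("p", "fam", "fam", overlap=0.8, ratio=0.5)],
            "genus", self._taxa(), comp_db)
        assert not out[0].partial
        assert not out[0].fragment


class TestFragmentSetOverlap:
    def test_identical_sets(self):
        assert fragment_set_overlap({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert fragment_set_overlap({"a"}, {"b"}) == 0.0

    def test_subset_symmetric_is_one(self):
        assert fragment_set_overlap({"a"}, {"a", "b", "c"}) == 1.0

    def test_symmetry(self):
        a, b = {"a", "b", "c"}, {"b", "c", "d", "e"}
        assert fragment_set_overlap(a, b) == fragment_set_overlap(b, a)

    def test_reference_mode_uses_first_set(self):
        assert fragment_set_overlap({"a", "b"}, {"a"}, mode="reference") == 0.5

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            fragment_set_overlap(set(), {"a"})

    def test_bounded(self):
        rng = np.random.default_rng(4)
        universe = [f"x{i}" for i in range(30)]
        for _ in range(50):
            a = {u for u in universe if rng.random() < 0.4}
            b = {u for u in universe if rng.random() < 0.4}
            if a and b:
                assert 0.0 <= fragment_set_overlap(a, b) <= 1.0


class TestFullAssessment:
    def test_self_consistency_of_held_out_species(self, world):
        report = run_full_assessment(world.query_records(), world.database)
        comp = report.completeness_percentages()
        cons = report.consistency_percentages()
        assert comp["missing"] < 10.0
        assert cons["consistent"] > 90.0
        assert cons["contaminant"] == 0.0
        assert report.contaminant_clades == []
        assert report.ancestral_lineage == world.reference_clade

    def test_half_deleted_proteome_recovers_rate(self, world):
        from hogqc.simulate import subsample_proteome

        records, _ = subsample_proteome(world.query_records(), 0.5, seed=99)
        report = run_full_assessment(records, world.database,
                                     taxon=world.query_species[0])
        missing = report.completeness_percentages()["missing"]
        assert missing == pytest.approx(50.0, abs=10.0)

    def test_partition_invariants(self, world):
        report = run_full_assessment(world.query_records(), world.database)
        comp_counts = report.completeness_counts()
        assert sum(comp_counts.values()) == report.conserved_total
        cons_counts = report.consistency_counts()
        assert sum(cons_counts.values()) == len(report.proteins)
        assert sum(report.completeness_percentages().values()) == \
            pytest.approx(100.0, abs=0.05)
        assert sum(report.consistency_percentages().values()) == \
            pytest.approx(100.0, abs=0.05)

    def test_empty_proteome_rejected(self, world):
        with pytest.raises(ValueError):
            run_full_assessment([], world.database)

    def test_user_taxon_bypasses_lineage_inference(self, world):
        q = world.query_species[0]
        report = run_full_assessment(world.query_records(), world.database,
                                     taxon=q)
        assert report.ancestral_lineage == world.reference_clade
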