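"""Tiered assignment, NJ trees, bootstrap, MRCA and combination rules."""
import numpy as np
import pytest
from skbio import DistanceMatrix

from mesofish.io import HitRecord, SequenceRecord, ValidationError
from mesofish.taxonomy import (Assignment, _splits, bootstrap_support,
                               center_star_align, combine_assignments,
                               mrca_assign, nj_build,
                               pairwise_distance_matrix, region_validate,
                               tiered_assign)
from mesofish.io import read_newick
from oracles import minimum_evolution_tree, random_additive_matrix


def hit(identity, species=None, genus="Diaphus", family="Myctophidae",
        coverage=100.0, evalue=1e-30, subject="ref"):
    lineage = {"class": "Actinopteri", "order": "Myctophiformes",
               "family": family}
    if genus is not None:
        lineage["genus"] = genus
    if species is not None:
        lineage["species"] = species
    return HitRecord("z1", subject, identity, coverage, evalue, lineage)


class TestTieredAssign:
    def test_species_tier(self):
        hits = [hit(99.4, "Diaphus splendidus", subject="r1"),
                hit(99.4, "Diaphus splendidus", subject="r2")]
        a = tiered_assign(hits)
        assert a.rank == "species" and a.taxon == "Diaphus splendidus"
        assert set(a.support) == {"r1", "r2"}

    def test_genus_tier_on_two_species(self):
        hits = [hit(98.2, "Diaphus splendidus"),
                hit(98.2, "Diaphus brachycephalus")]
        a = tiered_assign(hits)
        assert a.rank == "genus" and a.taxon == "Diaphus"

    def test_below_all_tiers_unassigned(self):
        a = tiered_assign([hit(94.1, "Diaphus splendidus")])
        assert a.rank == "unassigned" and a.taxon is None

    def test_gates_drop_low_coverage_and_weak_evalue(self):
        hits = [hit(99.9, "Diaphus splendidus", coverage=80.0),
                hit(99.9, "Diaphus splendidus", evalue=1e-10),
                hit(98.0, "Diaphus splendidus")]
        a = tiered_assign(hits)
        assert a.rank == "genus"  # only the 98% hit survives the gates

    def test_empty_lineage_hit_skipped(self):
        bare = HitRecord("z1", "r", 99.5, 100, 1e-30, lineage={})
        a = tiered_assign([bare, hit(99.5, "Diaphus splendidus")])
        assert a.rank == "species"

    def test_higher_tier_lca_capped_at_family(self):
        hits = [hit(95.5, "Diaphus splendidus"),
                hit(95.5, "Bolinichthys longipes", genus="Bolinichthys")]
        a = tiered_assign(hits)
        assert a.rank == "family" and a.taxon == "Myctophidae"

    def test_higher_tier_lca_across_families(self):
        hits = [hit(95.5, None, genus=None, family="Myctophidae"),
                hit(95.5, None, genus=None, family="Serranidae")]
        a = tiered_assign(hits)
        assert a.rank == "order"

    def test_conflicting_hit_coarsens_not_deepens(self):
        base = [hit(99.4, "Diaphus splendidus")]
        extra = base + [hit(99.6, "Diaphus brachycephalus")]
        a0, a1 = tiered_assign(base), tiered_assign(extra)
        assert a0.rank == "species" and a1.rank == "genus"

    def test_cumulative_tiers(self):
        # the 99.5% hits fail tier (i) between them but still participate
        # in the 97% tier, where the genus is unanimous
        hits = [hit(99.5, "Diaphus splendidus"),
                hit(99.5, "Diaphus brachycephalus"),
                hit(97.5, "Diaphus perspicillatus")]
        a = tiered_assign(hits)
        assert a.rank == "genus" and a.taxon == "Diaphus"


class TestRegionValidate:
    def species_call(self):
        return Assignment("z1", "Diaphus splendidus", "species",
                          lineage={"class": "Actinopteri", "order": "M",
                                   "family": "Myctophidae",
                                   "genus": "Diaphus",
                                   "species": "Diaphus splendidus"})

    def test_present_unchanged(self):
        a = region_validate(self.species_call(), ["Diaphus splendidus"])
        assert a.rank == "species" and not a.flags

    def test_absent_demoted_and_flagged(self):
        a = region_validate(self.species_call(), ["Other fish"])
        assert a.rank == "genus" and a.taxon == "Diaphus"
        assert "region_unvalidated" in a.flags
        assert "species" not in a.lineage

    def test_genus_untouched_by_empty_list(self):
        g = Assignment("z1", "Diaphus", "genus",
                       lineage={"genus": "Diaphus"})
        assert region_validate(g, []) is g


class TestDistances:
    def seqs(self, *strings, aligned=True):
        return [SequenceRecord(f"s{i}", s, aligned=aligned)
                for i, s in enumerate(strings)]

    def test_single_mismatch(self):
        dm = pairwise_distance_matrix(self.seqs("ACGT", "ACGA"))
        assert dm["s0", "s1"] == 1.0

    def test_complete_deletion_removes_gap_column(self):
        dm = pairwise_distance_matrix(self.seqs("AC-T", "ACGT"))
        assert dm["s0", "s1"] == 0.0  # column 3 deleted, rest identical

    def test_identical(self):
        dm = pairwise_distance_matrix(self.seqs("ACGT", "ACGT"))
        assert dm["s0", "s1"] == 0.0

    def test_all_columns_deleted(self):
        with pytest.raises(ValidationError, match="comparable"):
            pairwise_distance_matrix(self.seqs("-N", "AC"))

    def test_proportional(self):
        dm = pairwise_distance_matrix(self.seqs("ACGTACGTAC", "ACGAACGTAC"),
                                      proportional=True)
        assert dm["s0", "s1"] == pytest.approx(0.1)


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_build(D, ids=["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_split_recovered(self):
        # additive matrix with ((A,B),(C,D)) signal
        D = np.array([[0, 2, 7, 7], [2, 0, 7, 7],
                      [7, 7, 0, 2], [7, 7, 2, 0]], float)
        tree = nj_build(D, ids=["A", "B", "C", "D"])
        assert frozenset({"C", "D"}) in _splits(tree) or \
               frozenset({"A", "B"}) in _splits(tree)

    def test_matches_minimum_evolution_on_additive_matrices(self, rng):
        for n in (4, 5):
            for _ in range(15):
                D, true_splits = random_additive_matrix(n, rng)
                ids = [str(i) for i in range(n)]
                tree = nj_build(D, ids=ids)
                nj_splits = {frozenset(int(x) for x in s)
                             for s in _splits(tree)}
                assert nj_splits == minimum_evolution_tree(D) == {
                    s for s in true_splits}

    def test_matches_reference_nj_on_random_matrices(self, rng):
        from skbio.tree import nj as skbio_nj
        for _ in range(10):
            n = int(rng.integers(4, 9))
            X = rng.random((n, n))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"t{i}" for i in range(n)]
            ours = _splits(nj_build(D, ids=ids))
            ref = _splits(skbio_nj(DistanceMatrix(D, ids=ids)))
            assert ours == ref

    def test_non_symmetric_rejected(self):
        with pytest.raises(Exception):
            nj_build(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),
                     ids=list("ABC"))

    def test_tie_break_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)  # fully tied, equidistant
        t1 = nj_build(D.copy(), ids=list("ABCD"))
        t2 = nj_build(D.copy(), ids=list("ABCD"))
        assert _splits(t1) == _splits(t2)


class TestBootstrap:
    def two_clades(self):
        a = "A" * 30
        b = "T" * 30
        return [SequenceRecord("a1", a), SequenceRecord("a2", a),
                SequenceRecord("b1", b), SequenceRecord("b2", b)]

    def test_identical_clades_full_support(self):
        tree = bootstrap_support(self.two_clades(), replicates=100, seed=0)
        supports = {getattr(n, "support", None)
                    for n in tree.non_tips(include_self=False)}
        supports.discard(None)
        assert supports == {100.0}

    def test_single_replicate_supports_binary(self, rng):
        seqs = [SequenceRecord(f"s{i}",
                               "".join(rng.choice(list("ACGT"), 40)))
                for i in range(5)]
        tree = bootstrap_support(seqs, replicates=1, seed=1)
        for node in tree.non_tips(include_self=False):
            s = getattr(node, "support", None)
            if s is not None:
                assert s in (0.0, 100.0)

    def test_deterministic_per_seed(self, rng):
        seqs = [SequenceRecord(f"s{i}",
                               "".join(rng.choice(list("ACGT"), 40)))
                for i in range(6)]

        def supports(seed):
            tree = bootstrap_support(seqs, replicates=50, seed=seed)
            return sorted(getattr(n, "support", -1)
                          for n in tree.non_tips(include_self=False))

        assert supports(7) == supports(7)


class TestMrcaAssign:
    def lineages(self):
        base = {"class": "Actinopteri", "order": "Perciformes",
                "family": "Serranidae"}
        return {
            "R1": {**base, "genus": "Pseudanthias",
                   "species": "Pseudanthias squamipinnis"},
            "R2": {**base, "genus": "Pseudanthias",
                   "species": "Pseudanthias evansi"},
            "R3": {**base, "genus": "Epinephelus",
                   "species": "Epinephelus merra"},
        }

    def test_sister_to_single_reference_gives_species(self):
        tree = read_newick("(((Z:0.01,R1:0.02):0.3,R2:0.4):0.2,"
                           "(R3:0.5,R4:0.6):0.2);")
        for n in tree.non_tips(include_self=False):
            n.support = 98.0
        a = mrca_assign(tree, "Z", self.lineages())
        assert a.rank == "species"
        assert a.taxon == "Pseudanthias squamipinnis"
        assert "low_bootstrap" not in a.flags

    def test_clade_with_two_congeners_gives_genus(self):
        tree = read_newick("((Z:0.05,(R1:0.02,R2:0.02):0.05):0.3,"
                           "(R3:0.5,R4:0.6):0.2);")
        a = mrca_assign(tree, "Z", self.lineages())
        assert a.rank == "genus" and a.taxon == "Pseudanthias"

    def test_low_support_flagged(self):
        tree = read_newick("(((Z:0.01,R1:0.02):0.3,R2:0.4):0.2,"
                           "(R3:0.5,R4:0.6):0.2);")
        for n in tree.non_tips(include_self=False):
            n.support = 40.0
        a = mrca_assign(tree, "Z", self.lineages())
        assert a.taxon == "Pseudanthias squamipinnis"
        assert "low_bootstrap" in a.flags

    def test_no_reference_leaf_rejected(self):
        tree = read_newick("((Z:1,X:1):1,(Y:1,W:1):1);")
        with pytest.raises(ValidationError, match="reference"):
            mrca_assign(tree, "Z", self.lineages())


class TestCombine:
    def auto(self, rank, taxon, lineage):
        return Assignment("z1", taxon, rank, method="automatic",
                          lineage=lineage)

    def phylo(self, rank, taxon, lineage):
        return Assignment("z1", taxon, rank, method="phylogenetic",
                          lineage=lineage)

    def test_agreement_keeps_lower_rank(self):
        a = self.auto("genus", "G1", {"family": "F", "genus": "G1"})
        p = self.phylo("species", "G1 s1",
                       {"family": "F", "genus": "G1", "species": "G1 s1"})
        c = combine_assignments(a, p)
        assert c.rank == "species" and c.method == "combined"

    def test_conflict_phylogenetic_wins(self):
        a = self.auto("species", "G1 s1",
                      {"family": "F", "genus": "G1", "species": "G1 s1"})
        p = self.phylo("genus", "G2", {"family": "F", "genus": "G2"})
        c = combine_assignments(a, p)
        assert c.rank == "genus" and c.taxon == "G2"

    def test_single_source_passthrough(self):
        a = self.auto("species", "G1 s1", {"genus": "G1",
                                           "species": "G1 s1"})
        assert combine_assignments(a, None) is a
        c = combine_assignments(None, self.phylo("genus", "G1",
                                                 {"genus": "G1"}))
        assert c.rank == "genus"


class TestCenterStar:
    def test_uniform_length_passthrough(self):
        recs = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGA")]
        out = center_star_align(recs)
        assert [r.sequence for r in out] == ["ACGT", "ACGA"]
        assert all(r.aligned for r in out)

    def test_indels_aligned_to_uniform_length(self):
        recs = [SequenceRecord("a", "ACGTACGTAC"),
                SequenceRecord("b", "ACGACGTAC"),    # deletion
                SequenceRecord("c", "ACGTTACGTAC")]  # insertion
        out = center_star_align(recs)
        lengths = {len(r) for r in out}
        assert len(lengths) == 1
        for rec, orig in zip(out, recs):
            assert rec.sequence.replace("-", "") == orig.sequence
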