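import random

import dendropy
import numpy as np
import pytest

from genefam import phylo
from genefam.phylo import (DistanceMatrix, bootstrap_support, mrca_copy_count,
                           nj_tree, protein_distance_matrix, reconcile_lca,
                           reciprocal_best_pairs, root_minimizing_duplications)


def species_tree(newick="(A:1,B:1)AB;"):
    return dendropy.Tree.get(data=newick, schema="newick")


def rooted(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestDistances:
    def test_identical_pair_has_zero_distance(self):
        dm = protein_distance_matrix({"a": "MKVLW" * 10, "b": "MKVLW" * 10})
        assert dm.get("a", "b") == 0.0

    def test_poisson_correction_closed_form(self):
        # 5 of 50 columns differ -> p = 0.1 -> d = -ln(0.9)
        a = "A" * 50
        b = "W" * 5 + "A" * 45
        dm = protein_distance_matrix({"a": a, "b": b})
        assert dm.get("a", "b") == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_too_few_shared_columns_is_an_error(self):
        a = "MKV" + "-" * 47
        b = "---" + "W" * 47
        with pytest.raises(ValueError, match="shared"):
            protein_distance_matrix({"a": a, "b": b})

    def test_saturated_pair_is_an_error(self):
        with pytest.raises(ValueError, match="saturated"):
            protein_distance_matrix({"a": "A" * 40, "b": "W" * 40})


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        labels = ["a", "b", "c"]
        M = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=labels, matrix=M))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_additive_topology(self):
        pyrng = random.Random(0)
        for rep in range(5):
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
            true = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
                taxon_namespace=tns, rng=pyrandom_for(rep))
            nprng = np.random.default_rng(rep)
            for e in true.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(nprng.uniform(0.05, 1.0))
            pdm = true.phylogenetic_distance_matrix()
            labels = [t.label for t in tns]
            M = np.zeros((8, 8))
            for i, a in enumerate(tns):
                for j, b in enumerate(tns):
                    if i < j:
                        M[i, j] = M[j, i] = pdm.distance(a, b)
            nj = nj_tree(DistanceMatrix(labels=labels, matrix=M),
                         taxon_namespace=tns)
            true.is_rooted = False
            true.update_bipartitions()
            nj.update_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(true, nj) == 0

    def test_invariant_to_label_permutation(self):
        nprng = np.random.default_rng(1)
        labels = ["a", "b", "c", "d", "e"]
        M = nprng.uniform(0.1, 2.0, (5, 5))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 0)
        ref = nj_tree(DistanceMatrix(labels=labels, matrix=M))
        perm = [3, 0, 4, 1, 2]
        M2 = M[np.ix_(perm, perm)]
        out = nj_tree(DistanceMatrix(labels=[labels[i] for i in perm], matrix=M2))
        ref.update_bipartitions()
        out.migrate_taxon_namespace(ref.taxon_namespace)
        out.update_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(ref, out) == 0

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b", "c"], matrix=M)


def pyrandom_for(seed):
    return random.Random(seed)


class TestBootstrap:
    @staticmethod
    def _clade_alignment():
        # two clearly separated clades, identical within each, sharing
        # invariant columns so no resampled pair saturates
        a = "MKVLWAAYQR" * 6
        b = "MKVLWAAYQR" * 3 + "GDEFHKNPST" * 3
        return {"a1": a, "a2": a, "b1": b, "b2": b}

    def test_separated_clades_get_full_support(self):
        tree = bootstrap_support(self._clade_alignment(), n_reps=50, seed=0)
        supports = [float(n.label) for n in tree.preorder_internal_node_iter()
                    if n.label is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_reproduces_supports(self):
        aln = self._clade_alignment()
        t1 = bootstrap_support(aln, n_reps=20, seed=7)
        t2 = bootstrap_support(aln, n_reps=20, seed=7)
        s1 = sorted(n.label for n in t1.preorder_internal_node_iter() if n.label)
        s2 = sorted(n.label for n in t2.preorder_internal_node_iter() if n.label)
        assert s1 == s2

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self._clade_alignment(), n_reps=1, seed=3)
        supports = {float(n.label) for n in tree.preorder_internal_node_iter()
                    if n.label is not None}
        assert supports <= {0.0, 100.0}

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._clade_alignment(), n_reps=0)


class TestReconciliation:
    def test_two_family_copies_duplicated_before_speciation(self):
        rec = reconcile_lca(rooted("((a1:1,b1:1):1,(a2:1,b2:1):1);"),
                            species_tree(),
                            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
        events = [n.event for n in rec.gene_tree.preorder_internal_node_iter()]
        assert events[0] == "duplication"
        assert events[1:] == ["speciation", "speciation"]
        assert rec.n_duplications == 1

    def test_congruent_single_copy_tree_has_no_duplications(self):
        sp = species_tree("((A:1,B:1)AB:1,C:2)ROOT;")
        rec = reconcile_lca(rooted("((a1:1,b1:1):1,c1:2);"), sp,
                            {"a1": "A", "b1": "B", "c1": "C"})
        assert rec.n_duplications == 0 and rec.n_losses == 0

    def test_within_species_duplication_maps_to_terminal_species(self):
        rec = reconcile_lca(rooted("((a1:1,a2:1):1,b1:1);"), species_tree(),
                            {"a1": "A", "a2": "A", "b1": "B"})
        dup_nodes = [n for n in rec.gene_tree.preorder_internal_node_iter()
                     if n.event == "duplication"]
        assert len(dup_nodes) == 1
        assert phylo._species_label(dup_nodes[0].species_map) == "A"

    def test_unknown_species_tag_rejected(self):
        with pytest.raises(KeyError):
            reconcile_lca(rooted("(a1:1,x1:1);"), species_tree(),
                          {"a1": "A", "x1": "X"})


class TestMrcaCounts:
    def test_hand_reconciled_cases(self):
        sp = species_tree()
        rec = reconcile_lca(rooted("((a1:1,b1:1):1,(a2:1,b2:1):1);"), sp,
                            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
        assert mrca_copy_count(rec, "AB") == 2
        rec2 = reconcile_lca(rooted("((a1:1,a2:1):1,b1:1);"), sp,
                             {"a1": "A", "a2": "A", "b1": "B"})
        assert mrca_copy_count(rec2, "AB") == 1

    def test_species_leaf_rejected(self):
        sp = species_tree()
        rec = reconcile_lca(rooted("(a1:1,b1:1);"), sp, {"a1": "A", "b1": "B"})
        leaf = [n for n in sp.leaf_node_iter()][0]
        with pytest.raises(ValueError):
            mrca_copy_count(rec, leaf)

    def test_rice_like_subspecies_history_counts_six_ancestral_copies(self):
        """Six ortholog pairs between two subspecies; lineage-specific tandem
        gains on either side do not change the ancestral count of 6."""
        sp = species_tree("(indica:1,japonica:1)IJ;")
        pairs = []
        species_of = {}
        for k in range(1, 7):
            i, j = f"i{k}", f"j{k}"
            species_of[i] = "indica"
            species_of[j] = "japonica"
            pairs.append(f"({i}:1,{j}:1)")
        # chr2 and chr6 indica-specific tandem duplications; chr4 japonica gain
        pairs[1] = f"((i2:0.5,i2b:0.5):0.5,j2:1)"
        species_of["i2b"] = "indica"
        pairs[5] = f"((i6:0.5,i6b:0.5):0.5,j6:1)"
        species_of["i6b"] = "indica"
        pairs[3] = f"(i4:1,(j4:0.5,j4b:0.5):0.5)"
        species_of["j4b"] = "japonica"
        newick = "(" * 5 + pairs[0] + "".join(f",{p})" for p in pairs[1:]) + ";"
        rec = reconcile_lca(rooted(newick), sp, species_of)
        assert mrca_copy_count(rec, "IJ") == 6

    def test_adding_duplication_below_node_does_not_change_count(self):
        sp = species_tree("((A:1,B:1)AB:1,(C:1,D:1)CD:1)ROOT;")
        base = "((a1:1,b1:1):1,((c1:1,d1:1):0.5,(c2:1,d2:1):0.5):1);"
        species_of = {"a1": "A", "b1": "B", "c1": "C", "d1": "D",
                      "c2": "C", "d2": "D"}
        rec = reconcile_lca(rooted(base), sp, species_of)
        ref = {n: mrca_copy_count(rec, n) for n in ("ROOT", "AB", "CD")}
        # duplicate a C leaf (a within-species event below CD and ROOT)
        grown = base.replace("c1:1", "(c1a:0.5,c1b:0.5):0.5")
        so2 = dict(species_of)
        so2.pop("c1")
        so2.update({"c1a": "C", "c1b": "C"})
        rec2 = reconcile_lca(rooted(grown), sp, so2)
        assert {n: mrca_copy_count(rec2, n) for n in ref} == ref

    def test_root_count_never_exceeds_leaf_count(self, small_dataset):
        truth = small_dataset["truth"]
        seqs = {g: truth.cds[g] for g in truth.genes}
        if len(seqs) < 3:
            pytest.skip("degenerate family")
        sp = dendropy.Tree.get(data=small_dataset["config"].species_tree,
                               schema="newick")
        tree = nj_tree(protein_distance_matrix(seqs))
        rec = reconcile_lca(root_minimizing_duplications(tree, sp, truth.species_of()),
                            sp, truth.species_of())
        assert mrca_copy_count(rec, "ROOT") <= len(seqs)


class TestRootingByDuplicationParsimony:
    def test_congruent_tree_roots_at_species_split(self):
        sp = species_tree("((A:1,B:1)AB:1,(C:1,D:1)CD:1)ROOT;")
        unrooted = nj_tree(DistanceMatrix(
            labels=["a1", "b1", "c1", "d1"],
            matrix=np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                             [4, 4, 0, 2], [4, 4, 2, 0]], float)))
        t = root_minimizing_duplications(unrooted, sp,
                                         {"a1": "A", "b1": "B", "c1": "C", "d1": "D"})
        rec = reconcile_lca(t, sp, {"a1": "A", "b1": "B", "c1": "C", "d1": "D"})
        assert rec.n_duplications == 0
        assert mrca_copy_count(rec, "ROOT") == 1


class TestReciprocalBestPairs:
    def _dm(self, labels, M):
        return DistanceMatrix(labels=labels, matrix=np.array(M, float))

    def test_single_pair_between_singleton_groups(self):
        dm = self._dm(["x", "y"], [[0, 1], [1, 0]])
        assert reciprocal_best_pairs(dm, {"x": "g1", "y": "g2"}) == [("x", "y")]

    def test_planted_nearest_neighbour_structure_recovered(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        M = np.full((6, 6), 10.0)
        np.fill_diagonal(M, 0)
        for i, j in ((0, 3), (1, 4), (2, 5)):  # planted partners
            M[i, j] = M[j, i] = 1.0
        dm = self._dm(labels, M)
        groups = {l: l[0] for l in labels}
        assert reciprocal_best_pairs(dm, groups) == [("a1", "b1"), ("a2", "b2"),
                                                     ("a3", "b3")]

    def test_tie_broken_deterministically(self):
        labels = ["a1", "b1", "b2"]
        M = np.array([[0, 2, 2], [2, 0, 5], [2, 5, 0]], float)
        dm = self._dm(labels, M)
        out1 = reciprocal_best_pairs(dm, {"a1": "A", "b1": "B", "b2": "B"})
        out2 = reciprocal_best_pairs(dm, {"a1": "A", "b1": "B", "b2": "B"})
        assert out1 == out2 == [("a1", "b1")]

    def test_single_group_yields_nothing(self):
        dm = self._dm(["a1", "a2"], [[0, 1], [1, 0]])
        assert reciprocal_best_pairs(dm, {"a1": "A", "a2": "A"}) == []
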