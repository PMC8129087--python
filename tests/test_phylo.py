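import numpy as np
import pytest

from mkevo import (
    Phylogeny,
    TraitTable,
    match_tree_and_traits,
    read_newick,
    read_trait_table,
    write_newick,
)
from mkevo.phylo import NewickError, TraitTableError
from mkevo.simulate import simulate_tree


class TestReadNewick:
    def test_three_tip(self, three_tip):
        assert three_tip.n_tips == 3
        assert len(three_tip.root.children) == 2
        depths = three_tip.node_depths()
        assert all(abs(depths[t.id] - 2.0) < 1e-12 for t in three_tip.tips())

    def test_star_polytomy(self):
        t = read_newick("(A:1,B:1,C:1);")
        assert t.n_tips == 3
        assert len(t.root.children) == 3

    def test_malformed_raises(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_raises(self):
        with pytest.raises(NewickError, match="branch length"):
            read_newick("((A:1,B):1,C:2);")

    def test_duplicate_tip_labels_raise(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick("((A:1,A:1):1,C:2);")

    def test_negative_length_raises(self):
        with pytest.raises(NewickError):
            read_newick("((A:1,B:-0.5):1,C:2);")

    def test_underscore_normalization_optional(self):
        strict = read_newick("(Geoemyda_japonica:1,B:1);")
        assert "Geoemyda_japonica" in strict.tip_labels()
        relaxed = read_newick("(Geoemyda_japonica:1,B:1);", normalize_underscores=True)
        assert "Geoemyda japonica" in relaxed.tip_labels()


class TestWriteNewick:
    def test_round_trip_small(self, three_tip):
        again = read_newick(write_newick(three_tip))
        assert write_newick(again) == write_newick(three_tip)

    def test_quoted_label_survives(self):
        t = read_newick("('G. japonica':1.5,B:1.5);")
        assert "G. japonica" in t.tip_labels()
        t2 = read_newick(write_newick(t))
        assert "G. japonica" in t2.tip_labels()

    def test_bifurcating_292_structure(self):
        t = simulate_tree(292, 200.0, seed=3)
        s = write_newick(t)
        assert s.count("(") == 291  # fully bifurcating: n-1 internal nodes
        assert sum(1 for lab in t.tip_labels()) == 292

    @pytest.mark.parametrize("seed", range(100))
    def test_round_trip_random_trees(self, seed):
        t = simulate_tree(10, height=float(5 + seed % 7), seed=seed)
        u = read_newick(write_newick(t))
        assert sorted(u.tip_labels()) == sorted(t.tip_labels())
        # exact length preservation via shortest-repr serialization
        d1, d2 = t.node_depths(), u.node_depths()
        t_depth = {nd.label: d1[nd.id] for nd in t.tips()}
        u_depth = {nd.label: d2[nd.id] for nd in u.tips()}
        for lab in t_depth:
            assert abs(t_depth[lab] - u_depth[lab]) < 1e-12


class TestMrca:
    def test_cherry_node(self, three_tip):
        m = three_tip.mrca({"A", "B"})
        assert sorted(nd.label for nd in three_tip.descendant_tips(m)) == ["A", "B"]

    def test_spanning_pair_is_root(self, three_tip):
        assert three_tip.mrca({"A", "C"}) == three_tip.root_id

    def test_all_tips_is_root(self):
        t = simulate_tree(20, 10.0, seed=5)
        assert t.mrca(t.tip_labels()) == t.root_id

    def test_unknown_label_raises(self, three_tip):
        with pytest.raises(KeyError):
            three_tip.mrca({"A", "Z"})

    def test_monotone_under_union(self, rng):
        t = simulate_tree(20, 10.0, seed=9)
        labs = t.tip_labels()
        for _ in range(20):
            s1 = set(rng.choice(labs, size=3, replace=False))
            s2 = set(rng.choice(labs, size=3, replace=False))
            m12 = t.mrca(s1 | s2)
            for m in (t.mrca(s1), t.mrca(s2)):
                anc, cur = set(), m
                while cur is not None:
                    anc.add(cur)
                    cur = t.nodes[cur].parent
                assert m12 in anc


class TestPrune:
    def test_prune_cherry(self, three_tip):
        sub = three_tip.prune_to_clade(three_tip.mrca({"A", "B"}))
        assert sorted(sub.tip_labels()) == ["A", "B"]
        assert all(abs(nd.length - 1.0) < 1e-15 for nd in sub.tips())

    def test_prune_at_root_is_identity(self, three_tip):
        assert three_tip.prune_to_clade(three_tip.root_id) == three_tip

    def test_prune_tip_raises(self, three_tip):
        tip = three_tip.node_by_label("C")
        with pytest.raises(ValueError):
            three_tip.prune_to_clade(tip.id)

    def test_tip_count_and_length_preserved(self, rng):
        t = simulate_tree(50, 30.0, seed=11)
        internals = [i for i in t.internal_ids() if i != t.root_id]
        for nid in rng.choice(internals, size=5, replace=False):
            nid = int(nid)
            sub = t.prune_to_clade(nid)
            assert sub.n_tips == len(t.descendant_tips(nid))
            clade_len = sum(
                nd.length
                for nd in t.nodes
                if nd.id != nid and _is_descendant(t, nd.id, nid)
            )
            assert abs(sub.total_branch_length() - clade_len) < 1e-12


def _is_descendant(tree, nid, anc):
    cur = nid
    while cur is not None:
        if cur == anc:
            return True
        cur = tree.nodes[cur].parent
    return False


class TestTraitTable:
    def test_basic_with_missing(self):
        tt = read_trait_table("species,mg\nA,0\nB,1\nC,?\n")
        assert tt.states["C"] == (None,)
        assert tt.n_missing("mg") == 1

    def test_292_species_6_missing(self):
        rows = ["species,mg"]
        for i in range(292):
            rows.append(f"s{i}," + ("?" if i < 6 else str(i % 2)))
        tt = read_trait_table("\n".join(rows))
        assert len(tt.species) == 292
        assert tt.n_missing("mg") == 6

    def test_duplicate_species_raises(self):
        with pytest.raises(TraitTableError, match="duplicate"):
            read_trait_table("species,mg\nA,0\nA,1\n")

    def test_state_outside_alphabet_names_row(self):
        with pytest.raises(TraitTableError, match="B"):
            read_trait_table("species,mg\nA,0\nB,2\n")

    def test_empty_cell_is_error_not_missing(self):
        with pytest.raises(TraitTableError, match="empty state cell"):
            read_trait_table("species,mg\nA,0\nB,\n")

    def test_custom_missing_code(self):
        tt = read_trait_table("species,mg\nA,NA\n", missing_code="NA")
        assert tt.states["A"] == (None,)

    def test_csv_round_trip(self):
        tt = read_trait_table("species,mg,hab\nA,0,1\nB,?,0\n")
        tt2 = read_trait_table(tt.to_csv())
        assert tt2.states == tt.states


class TestMatch:
    def test_tip_without_trait_flagged_missing(self, three_tip):
        tt = read_trait_table("species,mg\nA,0\nB,1\n")
        states, report = match_tree_and_traits(three_tip, tt)
        assert states["C"] is None
        assert report["tips_without_traits"] == ["C"]

    def test_extra_species_dropped(self, three_tip):
        tt = read_trait_table("species,mg\nA,0\nB,1\nC,0\nD,1\n")
        states, report = match_tree_and_traits(three_tip, tt)
        assert "D" not in states
        assert report["dropped_rows"] == ["D"]

    def test_empty_intersection_raises(self, three_tip):
        tt = read_trait_table("species,mg\nX,0\nY,1\n")
        with pytest.raises(TraitTableError):
            match_tree_and_traits(three_tip, tt)

    def test_full_fixture_no_mismatch(self, paper_like):
        tree, gland, _ = paper_like
        states, report = match_tree_and_traits(tree, gland)
        assert report["tips_without_traits"] == []
        assert report["dropped_rows"] == []
        assert sum(1 for v in states.values() if v is None) == 6
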