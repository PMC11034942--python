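"""MNTD / NTI: exhaustive and graph-search oracles, null-model behaviour."""

import itertools
import subprocess
import textwrap

import dendropy
import networkx as nx
import numpy as np
import pytest

from qsipx import (
    Phylogeny,
    PhyloError,
    RunConfig,
    cophenetic_matrix,
    mntd,
    nti,
    simulate_tree,
)


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def graph_distances(tree: dendropy.Tree):
    """Independent oracle: shortest paths on the tree as a weighted graph."""
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
    tips = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    out = {}
    for a, b in itertools.combinations(sorted(tips), 2):
        out[(a, b)] = nx.dijkstra_path_length(g, tips[a], tips[b])
    return out


class TestCopheneticMatrix:
    def test_four_tip_values(self, four_tip_tree):
        labels, dmat = cophenetic_matrix(four_tip_tree)
        i = {l: k for k, l in enumerate(labels)}
        assert dmat[i["A"], i["B"]] == pytest.approx(2.0)
        assert dmat[i["A"], i["C"]] == pytest.approx(4.0)
        assert np.allclose(np.diag(dmat), 0.0)
        assert np.allclose(dmat, dmat.T)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_graph_search_on_random_trees(self, seed):
        tree = simulate_tree([f"t{i}" for i in range(8)], seed=seed)
        labels, dmat = cophenetic_matrix(tree)
        i = {l: k for k, l in enumerate(labels)}
        oracle = graph_distances(tree)
        for (a, b), d in oracle.items():
            assert dmat[i[a], i[b]] == pytest.approx(d, rel=1e-10, abs=1e-10)


class TestMntd:
    def test_two_member_group(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        assert mntd(phy.indices(["A", "B"]), phy.dmat) == pytest.approx(2.0)

    def test_star_tree_symmetry(self):
        phy = Phylogeny.from_tree(tree_from("(A:2,B:2,C:2,D:2,E:2);"))
        assert mntd(phy.indices(list("ABCDE")), phy.dmat) == pytest.approx(4.0)

    def test_matches_exhaustive_scan(self):
        tree = simulate_tree([f"t{i}" for i in range(12)], seed=5)
        phy = Phylogeny.from_tree(tree)
        rng = np.random.default_rng(0)
        for _ in range(10):
            group = rng.choice(12, size=5, replace=False)
            expected = np.mean(
                [
                    min(phy.dmat[i, j] for j in group if j != i)
                    for i in group
                ]
            )
            assert mntd(group, phy.dmat) == pytest.approx(expected, rel=1e-12)

    def test_small_group_rejected(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        with pytest.raises(PhyloError):
            mntd(phy.indices(["A"]), phy.dmat)

    def test_matches_picante_reference(self, tmp_path):
        """Cross-check MNTD against the R picante implementation on a fixed
        tree and group."""
        newick = "((A:1.5,B:0.5):1,((C:2,D:1):0.5,E:3):1);"
        script = textwrap.dedent(
            """
            suppressMessages(library(picante))
            tree <- read.tree(text="%s")
            comm <- matrix(c(1,1,0,1,0), nrow=1,
                           dimnames=list("g", c("A","B","C","D","E")))
            cat(sprintf("%%.10f", mntd(comm, cophenetic(tree))))
            """
            % newick
        )
        r_out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = float(r_out.stdout.strip().split()[-1])
        phy = Phylogeny.from_tree(tree_from(newick))
        ours = mntd(phy.indices(["A", "B", "D"]), phy.dmat)
        assert ours == pytest.approx(expected, rel=1e-9)


def exhaustive_nti(phy: Phylogeny, group):
    """Oracle: null by complete enumeration of equal-size tip subsets."""
    k = len(group)
    obs = mntd(phy.indices(group), phy.dmat)
    nulls = [
        mntd(np.array(c), phy.dmat)
        for c in itertools.combinations(range(len(phy.tip_labels)), k)
    ]
    mean, sd = np.mean(nulls), np.std(nulls, ddof=1)
    return obs, mean, sd, -(obs - mean) / sd


class TestNti:
    def test_four_tip_exhaustive_oracle(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        obs, mean, sd, nti_exact = exhaustive_nti(phy, ["A", "B"])
        assert obs == pytest.approx(2.0)
        assert mean == pytest.approx(10 / 3)
        assert sd == pytest.approx(1.0328, abs=1e-4)
        assert nti_exact == pytest.approx(1.2910, abs=1e-4)

    def test_sampled_null_matches_exhaustive(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        config = RunConfig(rng_seed=1, n_null_nti=10_000)
        res = nti(["A", "B"], phy, config, group_id="AB")
        assert res.nti == pytest.approx(1.2910, abs=0.1)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_enumerated_null_is_exact_on_small_trees(self, k):
        tree = simulate_tree([f"t{i}" for i in range(8)], seed=k)
        phy = Phylogeny.from_tree(tree)
        group = phy.tip_labels[:k]
        _, _, _, exact = exhaustive_nti(phy, group)
        config = RunConfig(rng_seed=7, n_null_nti=10_000)
        res = nti(group, phy, config, group_id=f"g{k}")
        assert res.nti == pytest.approx(exact, abs=1e-9)

    def test_sampled_null_converges_on_large_pool(self):
        """When subsets outnumber the draw budget the sampled null must land
        close to the full enumeration."""
        tree = simulate_tree([f"t{i}" for i in range(20)], seed=2)
        phy = Phylogeny.from_tree(tree)
        group = phy.tip_labels[:6]  # C(20,6) = 38760 >> 10000 draws
        _, _, _, exact = exhaustive_nti(phy, group)
        config = RunConfig(rng_seed=7, n_null_nti=10_000)
        res = nti(group, phy, config, group_id="g6")
        assert res.nti == pytest.approx(exact, abs=0.1)

    def test_whole_tree_group_degenerate(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        with pytest.raises(PhyloError, match="degenerate"):
            nti(list("ABCD"), phy, RunConfig(rng_seed=0, n_null_nti=50))

    def test_deterministic_under_seed(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        config = RunConfig(rng_seed=3, n_null_nti=499)
        a = nti(["A", "B"], phy, config)
        b = nti(["A", "B"], phy, config)
        assert a == b

    def test_branch_length_scale_invariance(self, four_tip_tree):
        phy = Phylogeny.from_tree(four_tip_tree)
        scaled = Phylogeny(
            tree=phy.tree, tip_labels=phy.tip_labels, dmat=phy.dmat * 13.7
        )
        config = RunConfig(rng_seed=5, n_null_nti=999)
        a = nti(["A", "B"], phy, config)
        b = nti(["A", "B"], scaled, config)
        assert a.nti == pytest.approx(b.nti, rel=1e-9)
        assert a.p_value == b.p_value

    def test_sister_clade_clusters_dispersed_group_does_not(self):
        newick = "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1);"
        phy = Phylogeny.from_tree(tree_from(newick))
        config = RunConfig(rng_seed=9, n_null_nti=2000)
        sisters = nti(["A", "B", "C", "D"], phy, config, rng=config.rng(1))
        spread = nti(["A", "C", "E", "G"], phy, config, rng=config.rng(2))
        assert sisters.nti > 0
        assert spread.nti < 0
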