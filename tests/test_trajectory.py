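import itertools

import numpy as np
import pandas as pd
import pytest

from precevo.trajectory import (
    ArmStateProfile,
    Clone,
    CloneTree,
    VariantCluster,
    build_cna_tree,
    build_snv_tree,
    classify_topology,
    cluster_variants,
    compare_trajectories,
    detect_minor_expansion,
    _enumerate_unrooted,
    _root_edges,
    _sankoff,
)


def chain_tree(lg_dom="C1", hg_dom="C2"):
    clones = [
        Clone("C1", "root", muts=frozenset({"a"})),
        Clone("C2", "C1", muts=frozenset({"a", "b"})),
    ]
    fractions = {
        "LG": {"C1": 0.7, "C2": 0.0},
        "HG": {"C1": 0.2, "C2": 0.7},
    }
    return CloneTree(clones, fractions)


def branched_tree():
    clones = [
        Clone("C1", "root", muts=frozenset({"a"})),
        Clone("C2", "C1", muts=frozenset({"a", "b"})),
        Clone("C3", "C1", muts=frozenset({"a", "c"})),
    ]
    fractions = {
        "LG": {"C1": 0.2, "C2": 0.7, "C3": 0.0},
        "HG": {"C1": 0.1, "C2": 0.0, "C3": 0.8},
    }
    return CloneTree(clones, fractions)


GRADES = {"LG": "LG", "HG": "HG"}


class TestCloneTree:
    def test_ccf_is_subtree_sum(self):
        t = chain_tree()
        assert t.ccf("HG", "C1") == pytest.approx(0.9)
        assert t.ccf("HG", "C2") == pytest.approx(0.7)

    def test_dominant(self):
        t = chain_tree()
        assert t.dominant("LG") == "C1"
        assert t.dominant("HG") == "C2"

    def test_mutation_nesting_enforced(self):
        with pytest.raises(ValueError, match="nest"):
            CloneTree(
                [
                    Clone("C1", "root", muts=frozenset({"a"})),
                    Clone("C2", "C1", muts=frozenset({"b"})),
                ],
                {"LG": {"C1": 0.5, "C2": 0.2}},
            )

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="exceed"):
            CloneTree(
                [Clone("C1", "root"), Clone("C2", "C1")],
                {"LG": {"C1": 0.8, "C2": 0.8}},
            )


class TestClusterVariants:
    def test_identical_profiles_one_cluster(self):
        vaf = pd.DataFrame(
            {"v1": [0.25, 0.25], "v2": [0.25, 0.25]}, index=["LG", "HG"]
        )
        clusters = cluster_variants(vaf, {"LG": 1.0, "HG": 1.0})
        assert len(clusters) == 1
        assert sorted(clusters[0].variants) == ["v1", "v2"]

    def test_truncal_plus_private(self):
        vaf = pd.DataFrame(
            {
                "t1": [0.5, 0.5],
                "t2": [0.5, 0.5],
                "p1": [0.0, 0.25],
                "p2": [0.0, 0.25],
            },
            index=["LG", "HG"],
        )
        clusters = cluster_variants(vaf, {"LG": 1.0, "HG": 1.0})
        assert len(clusters) == 2
        assert clusters[0].ccf == {"LG": 1.0, "HG": 1.0}
        assert clusters[1].ccf == {"LG": 0.0, "HG": 0.5}

    def test_low_ccf_still_present(self):
        vaf = pd.DataFrame({"v": [0.01, 0.45]}, index=["LG", "HG"])
        clusters = cluster_variants(vaf, {"LG": 1.0, "HG": 1.0})
        assert clusters[0].ccf["LG"] >= 0.01  # 2% clone counts as present

    def test_single_region_error(self):
        vaf = pd.DataFrame({"v": [0.2]}, index=["LG"])
        with pytest.raises(ValueError, match="cannot cluster"):
            cluster_variants(vaf, {"LG": 1.0})

    def test_min_variants_filter(self):
        vaf = pd.DataFrame(
            {"t1": [0.5, 0.5], "t2": [0.5, 0.5], "lone": [0.0, 0.1]},
            index=["LG", "HG"],
        )
        clusters = cluster_variants(vaf, {"LG": 1.0, "HG": 1.0}, min_variants=2)
        assert len(clusters) == 1


class TestBuildSnvTree:
    def test_nested_chain(self):
        clusters = [
            VariantCluster("C1", ["a"], {"LG": 1.0, "HG": 1.0}),
            VariantCluster("C2", ["b"], {"LG": 0.5, "HG": 0.6}),
            VariantCluster("C3", ["c"], {"LG": 0.2, "HG": 0.3}),
        ]
        tree = build_snv_tree(clusters)
        assert not tree.unresolved
        assert tree.clones["C2"].parent == "C1"
        assert tree.clones["C3"].parent == "C2"

    def test_two_branches(self):
        clusters = [
            VariantCluster("C1", ["a"], {"LG": 1.0, "HG": 1.0}),
            VariantCluster("C2", ["b"], {"LG": 0.7, "HG": 0.0}),
            VariantCluster("C3", ["c"], {"LG": 0.0, "HG": 0.6}),
        ]
        tree = build_snv_tree(clusters)
        assert tree.clones["C2"].parent == "C1"
        assert tree.clones["C3"].parent == "C1"

    def test_sum_rule_violation_flagged(self):
        # pigeonhole: siblings 0.6 + 0.4 cannot fit under a 0.8 parent
        clusters = [
            VariantCluster("C1", ["a"], {"LG": 0.8, "HG": 0.8}),
            VariantCluster("C2", ["b"], {"LG": 0.6, "HG": 0.2}),
            VariantCluster("C3", ["c"], {"LG": 0.4, "HG": 0.7}),
        ]
        tree = build_snv_tree(clusters)
        assert tree.unresolved

    def test_sum_rule_across_regions_allowed(self):
        # 0.6 + 0.6 under a full parent is fine when split across regions
        clusters = [
            VariantCluster("C1", ["a"], {"LG": 1.0, "HG": 1.0}),
            VariantCluster("C2", ["b"], {"LG": 0.6, "HG": 0.0}),
            VariantCluster("C3", ["c"], {"LG": 0.0, "HG": 0.6}),
        ]
        assert not build_snv_tree(clusters).unresolved


class TestClassifyTopology:
    def test_linear_chain(self):
        assert classify_topology(chain_tree(), GRADES) == "linear"

    def test_branched_siblings(self):
        assert classify_topology(branched_tree(), GRADES) == "branched"

    def test_unresolved_is_unclassifiable(self):
        t = chain_tree()
        t.unresolved = True
        assert classify_topology(t, GRADES) == "unclassifiable"

    def test_missing_grade_unclassifiable(self):
        assert classify_topology(chain_tree(), {"LG": "LG"}) == "unclassifiable"

    def test_region_order_invariance(self):
        t = branched_tree()
        for perm in itertools.permutations(["LG", "HG"]):
            grades = {r: r for r in perm}
            assert classify_topology(t, grades) == "branched"


class TestMinorExpansion:
    def _tree(self, ccf_by_region):
        clones = [Clone("C1", "root", muts=frozenset({"a"}))]
        return CloneTree(clones, {r: {"C1": f} for r, f in ccf_by_region.items()})

    def test_hg_to_pdac(self):
        t = self._tree({"HG": 0.03, "PDAC": 0.85})
        out = detect_minor_expansion(t, {"HG": "HG", "PDAC": "PDAC"})
        assert len(out) == 1 and out[0]["clone"] == "C1"

    def test_lg_to_hg(self):
        t = self._tree({"LG": 0.02, "HG": 0.6})
        assert len(detect_minor_expansion(t, GRADES)) == 1

    def test_stable_clone_not_reported(self):
        t = self._tree({"LG": 0.4, "HG": 0.4})
        assert detect_minor_expansion(t, GRADES) == []


class TestCnaTree:
    def test_linear_hand_parsimony(self):
        profiles = [
            ArmStateProfile("LG", {"1q": 3, "8p": 2}),
            ArmStateProfile("HG", {"1q": 3, "8p": 1}),
        ]
        res = build_cna_tree(profiles, {"LG": "LG", "HG": "HG"})
        assert res.cost == 2
        assert res.classification == "linear"

    def test_branched_hand_parsimony(self):
        profiles = [
            ArmStateProfile("LG", {"7p": 3, "1q": 2}),
            ArmStateProfile("HG", {"7p": 2, "1q": 3}),
        ]
        res = build_cna_tree(profiles, {"LG": "LG", "HG": "HG"})
        assert res.cost == 2
        assert res.classification == "branched"

    def test_identical_profiles_unclassifiable(self):
        profiles = [
            ArmStateProfile("LG", {"1q": 3}),
            ArmStateProfile("HG", {"1q": 3}),
        ]
        res = build_cna_tree(profiles, {"LG": "LG", "HG": "HG"})
        assert res.cost == 1  # the single shared gain
        assert res.classification == "unclassifiable"

    def test_too_many_regions(self):
        profiles = [ArmStateProfile(f"R{i}", {"1q": 2}) for i in range(7)]
        with pytest.raises(ValueError, match="exhaustive bound"):
            build_cna_tree(profiles)

    def test_region_order_invariance(self):
        profiles = [
            ArmStateProfile("LG", {"1q": 3, "4p": 2}),
            ArmStateProfile("HG", {"1q": 3, "4p": 1}),
            ArmStateProfile("ND", {"1q": 2, "4p": 2}),
        ]
        grades = {"LG": "LG", "HG": "HG", "ND": "ND"}
        base = build_cna_tree(profiles, grades)
        for perm in itertools.permutations(profiles):
            res = build_cna_tree(list(perm), grades)
            assert (res.cost, res.classification) == (base.cost, base.classification)


def _oracle_parsimony_cost(parent, leaf_states, root):
    """Exhaustive enumeration over all internal-state assignments."""
    internals = [n for n in parent if n not in leaf_states]
    best = None
    for states in itertools.product(range(5), repeat=len(internals)):
        assign = dict(leaf_states)
        assign.update(dict(zip(internals, states)))
        cost = sum(
            1
            for node, par in parent.items()
            if par is not None and assign[node] != assign[par]
        )
        best = cost if best is None else min(best, cost)
    return best


class TestSankoffOracle:
    def test_matches_exhaustive_enumeration(self):
        """Unit-cost DP equals brute force for <= 4 leaves and <= 3 arms."""
        rng = np.random.default_rng(3)
        for n_leaves in (2, 3, 4):
            leaves = ["ROOT"] + [f"R{i}" for i in range(n_leaves)]
            for edges, _ in _enumerate_unrooted(leaves):
                parent = _root_edges(edges, "ROOT")
                for _ in range(3):  # 3 random arm characters
                    leaf_states = {
                        leaf: int(rng.integers(0, 5)) for leaf in leaves
                    }
                    leaf_states["ROOT"] = 2
                    cost, assign = _sankoff(parent, leaf_states, "ROOT")
                    assert cost == _oracle_parsimony_cost(parent, leaf_states, "ROOT")
                    # the returned assignment must realise the optimal cost
                    realized = sum(
                        1
                        for node, par in parent.items()
                        if par is not None and assign[node] != assign[par]
                    )
                    assert realized == cost


class TestCompareTrajectories:
    def test_identical_vectors(self):
        df, frac = compare_trajectories(
            {"P1": "linear", "P2": "branched"}, {"P1": "linear", "P2": "branched"}
        )
        assert frac == 1.0

    def test_half_agreement(self):
        _, frac = compare_trajectories(
            {"P1": "linear", "P2": "branched"}, {"P1": "branched", "P2": "branched"}
        )
        assert frac == 0.5

    def test_unclassifiable_excluded(self):
        _, frac = compare_trajectories(
            {"P1": "linear", "P2": "unclassifiable"},
            {"P1": "linear", "P2": "branched"},
        )
        assert frac == 1.0
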