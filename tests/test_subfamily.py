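import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from algevo import subfamily as sf
from algevo import synthetic_data as sd
from algevo import treeio
from algevo.subfamily import SiteLogLikMatrix
from algevo.treeio import TaxonEntry, TaxonMap


class TestExtractFocalClades:
    def test_single_clade(self, focal_map):
        t = treeio.parse_newick("((F1:1,F2:1):1,(O1:1,O2:1):1);")
        clades = sf.extract_focal_clades(t, focal_map(t.leaf_labels()))
        assert clades == [frozenset({"F1", "F2"})]

    def test_outgroup_splits_focal(self, focal_map):
        t = treeio.parse_newick("(((F1:1,O1:1):1,F2:1):1,O2:1);")
        clades = sf.extract_focal_clades(t, focal_map(t.leaf_labels()))
        assert clades == [frozenset({"F1"}), frozenset({"F2"})]

    def test_no_focal_leaves(self, focal_map):
        t = treeio.parse_newick("(O1:1,O2:1);")
        assert sf.extract_focal_clades(t, focal_map(t.leaf_labels())) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_clade_scan(self, seed, focal_map):
        """Oracle: brute-force scan of every clade for maximal focal-only."""
        rng = random.Random(seed)
        t = sd.sim_species_tree(15, seed=seed, normalize_height=False)
        labels = t.leaf_labels()
        flags = {lb: rng.random() < 0.6 for lb in labels}
        taxa = TaxonMap({lb: TaxonEntry(lb, "p", flags[lb]) for lb in labels})
        got = set(sf.extract_focal_clades(t, taxa))
        focal = {lb for lb in labels if flags[lb]}
        all_clades = [t.clade_leaves(n) for n in t.d.preorder_node_iter()]
        focal_only = [c for c in all_clades if c <= focal]
        expected = {
            c for c in focal_only
            if not any(c < other for other in focal_only)
        }
        assert got == expected
        assert frozenset().union(*got) == focal if got else focal == set()


class TestConstrainMerge:
    def test_identity_when_already_monophyletic(self):
        t = treeio.parse_newick("(((A:1,B:1):1,C:1):1,D:1);")
        out = sf.constrain_merge(t, [frozenset({"A", "B"})])
        node = out.mrca({"A", "B"})
        assert out.clade_leaves(node) == {"A", "B"}

    def test_union_becomes_monophyletic(self):
        t = treeio.parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        out = sf.constrain_merge(t, [frozenset({"A"}), frozenset({"B"})])
        node = out.mrca({"A", "B"})
        assert out.clade_leaves(node) == {"A", "B"}
        assert sorted(out.leaf_labels()) == ["A", "B", "C", "D"]

    def test_all_leaves_rejected(self):
        t = treeio.parse_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(treeio.TreeError):
            sf.constrain_merge(t, [frozenset({"A", "B"}), frozenset({"C"})])

    @pytest.mark.parametrize("seed", range(25))
    def test_random_instances_contain_union(self, seed):
        rng = random.Random(seed)
        t = sd.sim_species_tree(12, seed=seed, normalize_height=False)
        labels = sorted(t.leaf_labels())
        k = rng.choice([2, 3])
        picks = rng.sample(labels, k)
        clades = [frozenset({p}) for p in picks]
        out = sf.constrain_merge(t, clades)
        union = frozenset(picks)
        node = out.mrca(union)
        assert out.clade_leaves(node) == union
        assert sorted(out.leaf_labels()) == labels


class TestSiteLoglik:
    def test_identical_leaves_zero_lengths(self):
        t = treeio.parse_newick("(A:0,B:0);")
        ll = sf.site_loglik({"A": "A", "B": "A"}, t)
        assert np.isclose(ll[0], math.log(0.25))

    def test_two_leaf_closed_form(self):
        t_tot = 0.3
        t = treeio.parse_newick("(A:0.1,B:0.2);")
        ll = sf.site_loglik({"A": "A", "B": "C"}, t)[0]
        e = math.exp(-4 * t_tot / 3)
        assert np.isclose(ll, math.log(0.25 * (0.25 - 0.25 * e)), atol=1e-12)

    def test_gap_is_missing_data(self):
        t = treeio.parse_newick("(A:0.1,B:0.2);")
        ll = sf.site_loglik({"A": "A", "B": "-"}, t)[0]
        assert np.isclose(ll, math.log(0.25))  # sums over B's states

    def test_leaf_mismatch_rejected(self):
        t = treeio.parse_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError, match="match"):
            sf.site_loglik({"A": "A", "C": "A"}, t)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_leaf_brute_force_state_sum(self, seed):
        """Oracle: enumerate all 16 internal-state combinations per site."""
        t = treeio.parse_newick("((A:0.12,B:0.3):0.2,(C:0.08,D:0.4):0.15);")
        aln = sd.sim_alignment(t, 30, seed=seed)
        ours = sf.site_loglik(aln, t)

        idx = {b: i for i, b in enumerate("ACGT")}

        def p(t_, i, j):
            e = math.exp(-4 * t_ / 3)
            return 0.25 + 0.75 * e if i == j else 0.25 - 0.25 * e

        for s in range(30):
            states = {lb: idx[aln[lb][s]] for lb in aln}
            total = 0.0
            for x in range(4):  # AB ancestor
                for y in range(4):  # CD ancestor
                    for r in range(4):  # root
                        total += (
                            0.25
                            * p(0.2, r, x) * p(0.15, r, y)
                            * p(0.12, x, states["A"]) * p(0.3, x, states["B"])
                            * p(0.08, y, states["C"]) * p(0.4, y, states["D"])
                        )
            assert np.isclose(ours[s], math.log(total), atol=1e-9)


class TestAuTest:
    def test_identical_rows_degenerate(self):
        m = SiteLogLikMatrix(np.zeros((2, 100)), ["A", "B"])
        res = sf.au_test(m, replicates=200, seed=0)
        assert res.p_values == {"A": 1.0, "B": 1.0}
        assert res.degenerate == {"A": True, "B": True}
        assert np.isclose(sum(res.bp_scale1.values()), 1.0)

    def test_dominance(self):
        L = np.zeros((2, 1000))
        L[0] += 0.1
        res = sf.au_test(SiteLogLikMatrix(L, ["A", "B"]), replicates=500, seed=1)
        assert res.p_values["A"] >= 0.99
        assert res.p_values["B"] <= 0.01

    def test_single_topology_rejected(self):
        with pytest.raises(ValueError):
            SiteLogLikMatrix(np.zeros((1, 10)), ["A"])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        L = rng.normal(0, 1, (3, 200))
        res = sf.au_test(SiteLogLikMatrix(L, ["A", "B", "C"]),
                         replicates=300, seed=2)
        assert np.isclose(sum(res.bp_scale1.values()), 1.0)

    def test_scale1_matches_naive_rell(self):
        """Independent naive RELL bootstrap agrees within 3 MC SE."""
        rng = np.random.default_rng(11)
        L = np.cumsum(rng.normal(0, 0.05, (2, 400)), axis=0)
        m = SiteLogLikMatrix(L, ["A", "B"])
        B = 4000
        res = sf.au_test(m, replicates=B, seed=3)
        naive = sf.naive_rell_bootstrap(m, replicates=B, seed=99)
        for t in ("A", "B"):
            p1, p2 = res.bp_scale1[t], naive[t]
            pbar = (p1 + p2) / 2
            se = math.sqrt(max(pbar * (1 - pbar), 1e-9) * 2 / B)
            assert abs(p1 - p2) <= 3 * se + 1e-12

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        L = rng.normal(0, 1, (2, 150))
        m = SiteLogLikMatrix(L, ["A", "B"])
        r1 = sf.au_test(m, replicates=300, seed=5)
        r2 = sf.au_test(m, replicates=300, seed=5)
        assert r1.p_values == r2.p_values
        assert r1.bp_scale1 == r2.bp_scale1


class TestDeriveCutoff:
    def test_small_example(self):
        t = treeio.parse_newick("((A:0.2,B:0.3):0.1,C:0.5);")
        assert np.isclose(sf.derive_cutoff(t), 0.5)

    def test_published_reference_value(self):
        t = treeio.parse_newick("(L:0.66);")
        assert np.isclose(sf.derive_cutoff(t), 0.66)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_max_depth(self, seed):
        t = sd.sim_species_tree(10, seed=seed, normalize_height=False)
        depths = t.depths()
        assert np.isclose(
            sf.derive_cutoff(t), max(depths[l] for l in t.leaves())
        )


class TestClusterByCutoff:
    def make_two_blob(self):
        labels = [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)]
        m = np.full((8, 8), 2.0)
        m[:4, :4] = 0.2
        m[4:, 4:] = 0.2
        np.fill_diagonal(m, 0.0)
        return pd.DataFrame(m, index=labels, columns=labels)

    def test_cutoff_zero_all_singletons(self):
        d = self.make_two_blob()
        assert len(sf.cluster_by_cutoff(d, 1e-12)) == 8

    def test_cutoff_above_max_one_cluster(self):
        d = self.make_two_blob()
        assert len(sf.cluster_by_cutoff(d, 10.0)) == 1

    def test_planted_two_blobs(self):
        d = self.make_two_blob()
        parts = sf.cluster_by_cutoff(d, 0.66)
        assert sorted(map(sorted, parts)) == [
            ["x0", "x1", "x2", "x3"], ["y0", "y1", "y2", "y3"],
        ]

    def test_asymmetric_rejected(self):
        d = self.make_two_blob()
        d.iloc[0, 1] = 99.0
        with pytest.raises(ValueError):
            sf.cluster_by_cutoff(d, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_cutoff(self, seed):
        """Raising the cutoff never splits an existing cluster."""
        t = sd.sim_species_tree(12, seed=seed, normalize_height=False)
        d = treeio.patristic_matrix(t)
        cuts = sorted(np.random.default_rng(seed).uniform(0, d.values.max(), 4))
        prev = sf.cluster_by_cutoff(d, cuts[0])
        for c in cuts[1:]:
            cur = sf.cluster_by_cutoff(d, c)
            for old in prev:
                assert any(old <= new for new in cur)
            prev = cur

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage(self, seed):
        """Cross-check against scipy's UPGMA on tie-free random matrices."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(100 + seed)
        n = 10
        pts = rng.normal(0, 1, (n, 3))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"l{i}" for i in range(n)]
        d = pd.DataFrame(m, index=labels, columns=labels)
        cutoff = float(np.median(m[np.triu_indices(n, 1)]))
        ours = sf.cluster_by_cutoff(d, cutoff)
        Z = hierarchy.linkage(squareform(m), method="average")
        flat = hierarchy.fcluster(Z, t=cutoff, criterion="distance")
        scipy_parts = {
            frozenset(labels[i] for i in range(n) if flat[i] == c)
            for c in set(flat)
        }
        assert set(ours) == scipy_parts


class TestDelineate:
    def test_all_high_support_passthrough(self, focal_map):
        t = treeio.parse_newick(
            "(((F1:1,F2:1)100:1,O1:2):1,((F3:1,F4:1)100:1,O2:2):1);"
        )
        subs = sf.delineate(t, focal_map(t.leaf_labels()))
        assert len(subs) == 2
        assert all(s.method == "bootstrap" for s in subs)
        members = sorted(sorted(s.members) for s in subs)
        assert members == [["F1", "F2"], ["F3", "F4"]]

    def test_low_support_without_path_raises(self, focal_map):
        t = treeio.parse_newick(
            "(((F1:1,F2:1)40:1,O1:2):1,((F3:1,F4:1)40:1,O2:2):1);"
        )
        with pytest.raises(ValueError, match="cutoff"):
            sf.delineate(t, focal_map(t.leaf_labels()))

    def test_low_support_resolved_by_cutoff(self, focal_map):
        t = treeio.parse_newick(
            "(((F1:0.1,F2:0.1)40:1,O1:2):1,((F3:0.1,F4:0.1)40:1,O2:2):1);"
        )
        subs = sf.delineate(t, focal_map(t.leaf_labels()), cutoff=0.66)
        assert all(s.method == "distance_cutoff" for s in subs)
        members = sorted(sorted(s.members) for s in subs)
        assert members == [["F1", "F2"], ["F3", "F4"]]

    def test_au_merge_when_not_rejected(self, focal_map):
        """Two focal clades split only by a weakly attached outgroup leaf:
        the merged alternative scores the data almost equally well, so the
        conservative merge wins (failure to reject => one subfamily)."""
        t = treeio.parse_newick(
            "((((F1:0.05,F2:0.05)40:0.001,O3:0.05)40:0.001,"
            "(F3:0.05,F4:0.05)40:0.001)40:0.5,(O1:0.05,O2:0.05):0.5);"
        )
        taxa = focal_map(t.leaf_labels())
        aln = sd.sim_alignment(t, 300, seed=2)
        subs = sf.delineate(
            t, taxa, merge_candidates=[[0, 1]], alignment=aln,
            replicates=500, seed=0,
        )
        merged = [s for s in subs if s.method == "au_test"]
        assert len(merged) == 1
        assert merged[0].members == frozenset({"F1", "F2", "F3", "F4"})
        assert merged[0].au_p >= 0.05

    def test_au_reject_two_origins(self, species_tree_factory):
        gt, taxa, (ma, mb) = sd.sim_two_origin_family(
            species_tree_factory(6, 4), seed=1
        )
        aln = sd.sim_alignment(gt, 1000, seed=3)
        subs = sf.delineate(
            gt, taxa, merge_candidates=[[0, 1]], alignment=aln,
            replicates=1000, seed=0,
        )
        assert len(subs) == 2
        assert {s.members for s in subs} == {ma, mb}

    def test_partition_invariant(self, focal_map):
        t = treeio.parse_newick(
            "(((F1:0.1,F2:0.1)90:1,O1:2):1,((F3:0.1,F4:0.1)40:1,O2:2):1);"
        )
        subs = sf.delineate(t, focal_map(t.leaf_labels()), cutoff=0.66)
        all_members = [m for s in subs for m in s.members]
        assert sorted(all_members) == ["F1", "F2", "F3", "F4"]
        assert len(all_members) == len(set(all_members))

    def test_output_frame(self, focal_map):
        t = treeio.parse_newick(
            "(((F1:1,F2:1)100:1,O1:2):1,((F3:1,F4:1)100:1,O2:2):1);"
        )
        subs = sf.delineate(t, focal_map(t.leaf_labels()))
        frame = sf.subfamilies_to_frame(subs)
        assert set(frame.columns) == {"leaf", "subfamily", "method", "support", "au_p"}
        assert len(frame) == 4
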