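"""Boundary-proximity analysis: grafting, predictors, discordance, and the
phylogenetic logistic regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

import statsmodels.api as sm

from nucshift.boundary import (
    PhyloLogisticModel,
    _patristic,
    discordance,
    fit_phylo_logistic,
    graft_internal_terminals,
    node_covariates,
    proximity_predictor,
)
from nucshift.simulate import generate_toy_tree
from nucshift.trees import read_newick


def toy_chronogram(n=60, seed=3, depth=90.0):
    tree = generate_toy_tree(n, seed=seed)
    tree.branch_length[:] = tree.branch_length * (
        depth / np.nanmax(tree.node_depths())
    )
    return tree


class TestGrafting:
    def test_counts_on_balanced_tree(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        g = graft_internal_terminals(t)
        assert g.tree.n_leaves == 7  # 4 original + 3 internal nodes

    def test_binary_tree_tip_count(self):
        t = toy_chronogram(50)
        g = graft_internal_terminals(t)
        # a binary rooted tree with n tips has n-1 internal nodes
        assert g.tree.n_leaves == 50 + 49

    def test_graft_then_prune_restores_topology(self):
        t = toy_chronogram(20)
        g = graft_internal_terminals(t)
        original_labels = set(t.leaf_labels)
        # pruning = restrict clades to original labels, drop trivial ones
        restored = {
            frozenset(s & original_labels)
            for s in g.tree.clades()
        }
        restored = {s for s in restored if 1 < len(s) < len(original_labels)}
        assert restored == t.clades()

    def test_grafted_tip_lengths_epsilon(self):
        t = toy_chronogram(10)
        g = graft_internal_terminals(t, epsilon=1e-6)
        for v in g.graft_label:
            i = g.graft_tip_index(v)
            assert g.tree.branch_length[i] == pytest.approx(1e-6)

    def test_non_ultrametric_warns(self):
        t = read_newick("((a:1,b:2):1,(c:1,d:1):1);")
        with pytest.warns(UserWarning):
            graft_internal_terminals(t)


class TestProximityPredictor:
    def test_values(self):
        assert proximity_predictor(67.0) == pytest.approx(0.0)
        assert proximity_predictor(76.0) == pytest.approx(
            np.log(10), abs=1e-9
        )
        assert proximity_predictor(56.0) == pytest.approx(np.log(10))

    def test_boundary_floor(self):
        assert proximity_predictor(66.0) == pytest.approx(np.log(1e-3))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            proximity_predictor(-1.0)


class TestDiscordance:
    def test_identical_gene_trees_zero(self):
        ref = read_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1);")
        gts = [read_newick(ref.to_newick(), rooted=False) for _ in range(4)]
        d = discordance(gts, ref)
        assert (d["p_discordant"].dropna() == 0).all()
        assert (d["discordance_asin_sqrt"].dropna() == 0).all()

    def test_one_third_conflict(self):
        ref = read_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1);")
        agree = "((a:1,b:1):1,((c:1,d:1):1,e:1):1);"
        conflict = "((a:1,c:1):1,((b:1,d:1):1,e:1):1);"
        gts = [
            read_newick(agree, rooted=False),
            read_newick(agree, rooted=False),
            read_newick(conflict, rooted=False),
        ]
        d = discordance(gts, ref)
        ab = ref.node_by_leafset({"a", "b"})
        assert d.loc[ab, "p_discordant"] == pytest.approx(1 / 3)
        assert d.loc[ab, "discordance_asin_sqrt"] == pytest.approx(
            np.arcsin(np.sqrt(1 / 3)), abs=1e-9
        )

    def test_full_conflict_transform_bound(self):
        ref = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        gt = read_newick("((a:1,c:1):1,(b:1,d:1):1);", rooted=False)
        d = discordance([gt], ref)
        ab = ref.node_by_leafset({"a", "b"})
        assert d.loc[ab, "discordance_asin_sqrt"] == pytest.approx(
            np.pi / 2, abs=1e-9
        )

    def test_low_support_collapses_to_nondecisive(self):
        ref = read_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1);")
        # conflicting topology but every internal node has support 40 (<95)
        weak = "((a:1,c:1)40:1,((b:1,d:1)40:1,e:1)40:1);"
        d = discordance([read_newick(weak, rooted=False)], ref)
        ab = ref.node_by_leafset({"a", "b"})
        assert d.loc[ab, "n_decisive"] == 0
        assert np.isnan(d.loc[ab, "p_discordant"])

    def test_collapsing_never_increases_discordance(self):
        ref = read_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1);")
        conflict_strong = "((a:1,c:1)99:1,((b:1,d:1)99:1,e:1):1);"
        conflict_weak = "((a:1,c:1)10:1,((b:1,d:1)10:1,e:1):1);"
        d_strong = discordance([read_newick(conflict_strong, rooted=False)], ref)
        d_weak = discordance([read_newick(conflict_weak, rooted=False)], ref)
        assert (
            d_weak["n_conflict"].fillna(0) <= d_strong["n_conflict"].fillna(0)
        ).all()


class TestNodeCovariates:
    def test_rows_and_response_coding(self):
        t = toy_chronogram(30)
        internal = t.internal_indices(include_root=False)
        shift_node = internal[2]
        covs = node_covariates(t, [t.leafset(shift_node)])
        assert len(covs) == len(internal)
        assert covs.loc[shift_node, "shift"] == 1
        assert covs["shift"].sum() == 1
        # stem age is the parent's age, hence older than the crown age
        assert (
            covs["stem_age"] >= covs["crown_age"] - 1e-9
        ).all()


class TestPhyloLogistic:
    def test_identity_limit_equals_ordinary_logistic(self):
        rng = np.random.default_rng(0)
        n = 80
        X = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 - 1.2 * X)).astype(float)
        D = np.abs(rng.normal(size=(n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        res = PhyloLogisticModel(y, X, D, names=["x"]).fit(alpha=1e9)
        ref = sm.GLM(
            y, sm.add_constant(X), family=sm.families.Binomial()
        ).fit()
        assert np.abs(res.params - ref.params).max() < 1e-4
        assert np.abs(res.naive_params - ref.params).max() < 1e-4

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError):
            PhyloLogisticModel(
                np.zeros(10), np.arange(10.0), np.zeros((10, 10))
            )

    def test_sign_recovery_on_grafted_tree(self):
        """Negative time-distance effect recovered in >=95% of simulations."""
        tree = toy_chronogram(80)
        grafted = graft_internal_terminals(tree)
        covs = node_covariates(tree, [], boundary=66.0)
        tips = [grafted.graft_tip_index(v) for v in covs.index]
        D = _patristic(grafted.tree, tips)
        R = np.exp(-0.05 * D)
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0, None))
        X = covs["time_distance"].to_numpy()
        Xc = X - X.mean()
        mu = expit(-0.5 - 1.5 * Xc)
        rng = np.random.default_rng(5)
        ok = tot = 0
        for _ in range(100):
            z = L @ rng.standard_normal(len(mu))
            y = (z < norm.ppf(mu)).astype(float)
            if y.min() == y.max():
                continue
            tot += 1
            r = PhyloLogisticModel(y, Xc, D, names=["td"]).fit()
            ok += r.params[1] < 0
        assert tot >= 90
        assert ok / tot >= 0.95

    def test_fit_invariant_to_observation_order(self):
        rng = np.random.default_rng(2)
        n = 50
        X = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 - X)).astype(float)
        D = np.abs(rng.normal(size=(n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        r1 = PhyloLogisticModel(y, X, D, names=["x"]).fit()
        perm = rng.permutation(n)
        r2 = PhyloLogisticModel(
            y[perm], X[perm], D[np.ix_(perm, perm)], names=["x"]
        ).fit()
        assert r2.params == pytest.approx(r1.params, abs=1e-5)
        assert r2.alpha == pytest.approx(r1.alpha, rel=1e-2)

    def test_bootstrap_interval_contains_point_estimate(self):
        tree = toy_chronogram(40, seed=9)
        grafted = graft_internal_terminals(tree)
        covs = node_covariates(tree, [], boundary=66.0).copy()
        rng = np.random.default_rng(9)
        covs["shift"] = (
            rng.random(len(covs)) < expit(-1 - covs["time_distance"]
                                          + covs["time_distance"].mean())
        ).astype(int)
        if covs["shift"].sum() in (0, len(covs)):
            covs.iloc[0, covs.columns.get_loc("shift")] = 1
        res = fit_phylo_logistic(grafted, covs, bootstrap=60, seed=1)
        ci = res.conf_int()
        for i in range(len(res.params)):
            assert ci[i, 0] <= res.params[i] <= ci[i, 1]

    def test_predictions_at_discordance_levels(self):
        tree = toy_chronogram(40, seed=11)
        grafted = graft_internal_terminals(tree)
        covs = node_covariates(tree, [], boundary=66.0).copy()
        rng = np.random.default_rng(11)
        covs["discordance"] = rng.uniform(0, np.pi / 2, len(covs))
        covs["shift"] = (rng.random(len(covs)) < 0.2).astype(int)
        if covs["shift"].sum() == 0:
            covs.iloc[0, covs.columns.get_loc("shift")] = 1
        res = fit_phylo_logistic(grafted, covs, bootstrap=0)
        pred = res.predictions_at_discordance(covs)
        assert set(pred.columns) >= {"time_distance", "low", "mean", "high"}
        assert ((pred[["low", "mean", "high"]] >= 0).all()).all()
        assert ((pred[["low", "mean", "high"]] <= 1).all()).all()
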