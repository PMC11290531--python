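"""Synthetic-data generator: shift sampling rules, Dirichlet compositions,
nonstationary HKY simulation, annotated export, toy trees."""

import itertools
import json

import numpy as np
import pytest
from scipy.stats import chisquare

from nucshift.simulate import (
    SimConfig,
    generate_toy_tree,
    paper_scenario_grid,
    sample_compositions,
    sample_shift_nodes,
    simulate_alignment,
    simulate_dataset,
)
from nucshift.trees import eligible_nodes, paint_regimes, read_newick


class TestSimConfig:
    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            SimConfig(scenario="weird")
        with pytest.raises(ValueError):
            SimConfig(scenario="none", n_shifts=2)
        with pytest.raises(ValueError):
            SimConfig(scenario="independent", n_shifts=0)

    def test_default_max_clade_is_three_quarters(self):
        tree = generate_toy_tree(200, seed=0)
        cfg = SimConfig(scenario="independent", n_shifts=1)
        assert cfg.resolved_max_clade(tree) == 150


class TestShiftSampling:
    def test_zero_shifts(self, balanced8):
        cfg = SimConfig(scenario="none")
        assert sample_shift_nodes(balanced8, cfg) == []

    def test_independent_pairs_within_enumerated_valid_set(self):
        nwk = ("((((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1):1,"
               "(((i:1,j:1):1,(k:1,l:1):1):1,((m:1,n:1):1,(o:1,p:1):1):1):1);")
        tree = read_newick(nwk)
        cfg = SimConfig(
            scenario="independent", n_shifts=2, min_clade=4, max_clade=12,
            buffer=2,
        )
        sizes = tree.clade_sizes()
        pool = [v for v in eligible_nodes(tree, 4) if sizes[v] <= 12]
        valid_pairs = set()
        for u, v in itertools.combinations(pool, 2):
            lineage_u = set(tree.ancestors(u)) | set(tree.descendants(u)) | {u}
            if v in lineage_u:
                continue
            if tree.path_distance(u, v) < 2:
                continue
            valid_pairs.add(frozenset((u, v)))
        rng = np.random.default_rng(0)
        for _ in range(50):
            got = frozenset(sample_shift_nodes(tree, cfg, rng=rng))
            assert got in valid_pairs

    def test_nested_shifts_share_a_lineage(self):
        tree = generate_toy_tree(64, seed=1)
        cfg = SimConfig(scenario="nested", n_shifts=2, buffer=2)
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = sample_shift_nodes(tree, cfg, rng=rng)
            lineage_a = set(tree.ancestors(a)) | set(tree.descendants(a))
            assert b in lineage_a
            assert tree.path_distance(a, b) >= 2

    def test_buffer_enforced(self):
        tree = generate_toy_tree(64, seed=2)
        cfg = SimConfig(scenario="independent", n_shifts=3, buffer=4)
        rng = np.random.default_rng(5)
        nodes = sample_shift_nodes(tree, cfg, rng=rng)
        for u, v in itertools.combinations(nodes, 2):
            assert tree.path_distance(u, v) >= 4

    def test_unsatisfiable_constraints_raise(self, balanced8):
        cfg = SimConfig(
            scenario="independent", n_shifts=4, min_clade=4,
            max_restarts=50,
        )
        with pytest.raises((RuntimeError, ValueError)):
            sample_shift_nodes(balanced8, cfg)

    def test_deterministic_under_seed(self):
        tree = generate_toy_tree(64, seed=4)
        cfg = SimConfig(scenario="independent", n_shifts=2, seed=77)
        assert sample_shift_nodes(tree, cfg) == sample_shift_nodes(tree, cfg)


class TestCompositions:
    def test_uniform_dirichlet_moments(self):
        rng = np.random.default_rng(0)
        draws = sample_compositions(100_000, (1, 1, 1, 1), rng=rng)
        se = np.sqrt(0.25 * 0.75 / 5) / np.sqrt(100_000)
        assert draws.mean(axis=0) == pytest.approx([0.25] * 4, abs=3 * se)

    def test_concentration_shrinks_variance(self):
        rng = np.random.default_rng(1)
        flat = sample_compositions(20_000, (1, 1, 1, 1), rng=rng)
        tight = sample_compositions(20_000, (100,) * 4, rng=rng)
        # Dirichlet marginal variance: a_i(a0-a_i)/(a0^2 (a0+1))
        assert tight.var(axis=0) == pytest.approx(
            np.full(4, 0.25 * 0.75 / 401), rel=0.1
        )
        assert (tight.var(axis=0) < flat.var(axis=0) / 50).all()

    def test_seeded_reproducibility(self):
        a = sample_compositions(5, rng=np.random.default_rng(9))
        b = sample_compositions(5, rng=np.random.default_rng(9))
        assert (a == b).all()


class TestSequenceSimulation:
    def test_length_zero(self, balanced8):
        aln = simulate_alignment(
            balanced8, paint_regimes(balanced8, []), [[0.25] * 4], length=0,
            rng=np.random.default_rng(0),
        )
        assert aln.length == 0

    def test_zero_branches_copy_root_state(self, balanced8):
        t = read_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = simulate_alignment(
            t, paint_regimes(t, []), [[0.25] * 4], length=50,
            rng=np.random.default_rng(1),
        )
        seqs = list(aln.to_dict().values())
        assert all(s == seqs[0] for s in seqs)

    def test_star_tree_long_branches_reach_stationarity(self):
        t = read_newick("(" + ",".join(f"t{i}:10.0" for i in range(6)) + ");",
                        rooted=False)
        pi = np.array([0.4, 0.25, 0.2, 0.15])
        aln = simulate_alignment(
            t, paint_regimes(t, []), pi[None, :], length=50_000,
            rng=np.random.default_rng(2),
        )
        joined = "".join(aln.to_dict().values())
        counts = np.array([joined.count(b) for b in "ACGT"])
        stat, p = chisquare(counts, pi * counts.sum())
        assert p > 0.01

    def test_shifted_clade_composition_converges(self):
        tree = generate_toy_tree(32, seed=8)
        cfg = SimConfig(scenario="independent", n_shifts=1, length=50_000,
                        seed=8)
        ds = simulate_dataset(tree, cfg, rng=np.random.default_rng(8))
        s = ds.shift_nodes[0]
        clade = sorted(ds.tree.leafset(s))
        from nucshift.alignment import empirical_frequencies

        # tips far from the shift point approach the regime equilibrium;
        # allow generous tolerance (finite branch lengths)
        emp = empirical_frequencies(ds.alignment, clade)
        assert np.abs(emp - ds.freqs[1]).max() < 0.12


class TestDatasetExport:
    def test_truth_sidecar_roundtrip(self, dataset16, tmp_path):
        paths = dataset16.write(tmp_path)
        truth = json.loads(open(paths["truth"]).read())
        tree = read_newick(truth["tree"])
        nodes = [tree.node_by_leafset(s) for s in truth["shift_leafsets"]]
        painting = paint_regimes(tree, nodes)
        # regime partition identical to the generating painting
        for i in range(tree.n_nodes):
            j = dataset16.tree.node_by_leafset(tree.leafset(i))
            assert painting.regime_of(i) == dataset16.painting.regime_of(j)

    def test_annotation_count_matches_regimes(self, dataset16):
        nwk = dataset16.annotated_newick()
        assert nwk.count("&model=HKY") == dataset16.painting.n_regimes

    def test_no_shift_single_root_annotation(self, balanced8):
        cfg = SimConfig(scenario="none", length=10, seed=0)
        ds = simulate_dataset(balanced8, cfg)
        assert ds.annotated_newick().count("&model=HKY") == 1


class TestToyTrees:
    def test_three_tips_unique_shape(self):
        t = generate_toy_tree(3, seed=0)
        assert t.n_leaves == 3
        assert len(t.internal_indices()) == 2

    def test_seeded_determinism(self):
        a = generate_toy_tree(25, seed=6)
        b = generate_toy_tree(25, seed=6)
        assert a.to_newick() == b.to_newick()

    def test_large_tree_contract(self):
        t = generate_toy_tree(250, seed=7)
        assert t.n_leaves == 250
        bl = t.branch_length[np.arange(t.n_nodes) != t.root]
        assert (bl > 0).all()

    def test_burst_mode_compresses_basal_internodes(self):
        t = generate_toy_tree(100, seed=3, burst=True)
        depths = t.node_depths()
        internal = [v for v in t.internal_indices() if v != t.root]
        total = depths[t.leaf_indices()].max()
        frac_early = np.mean(depths[internal] <= 0.05 * total)
        assert frac_early >= 0.2

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            generate_toy_tree(2)


def test_paper_scenario_grid_shape():
    cells = paper_scenario_grid()
    scen = {(c["scenario"], c["n_shifts"]) for c in cells}
    assert ("none", 0) in scen
    assert all(("independent", k) in scen for k in (1, 2, 3, 4))
    assert ("nested", 2) in scen
    assert all(c["replicates"] == 100 for c in cells)
    nested_lengths = {c["length"] for c in cells if c["scenario"] == "nested"}
    assert max(nested_lengths) == 100_000


def test_realized_tstv_ratio_flag():
    """With tstv_ratio set, kappa is derived so the realized
    transition:transversion ratio at the root composition hits the target."""
    from nucshift.substitution import kappa_for_tstv

    pi = np.array([0.1, 0.2, 0.3, 0.4])
    kappa = kappa_for_tstv(2.0, pi)
    a, c, g, t = pi
    realized = kappa * (a * g + c * t) / (a * c + a * t + c * g + g * t)
    assert realized == pytest.approx(2.0, abs=1e-12)
    # uniform composition: transitions/transversions frequency ratio is 1:2
    assert kappa_for_tstv(2.0, [0.25] * 4) == pytest.approx(4.0)
    tree = generate_toy_tree(12, seed=3)
    cfg = SimConfig(scenario="none", length=100, seed=3, tstv_ratio=2.0)
    ds = simulate_dataset(tree, cfg)
    assert ds.config.kappa == pytest.approx(
        kappa_for_tstv(2.0, ds.freqs[0])
    )
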