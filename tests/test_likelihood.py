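"""Pruning likelihood: closed-form and exhaustive oracles, caching
consistency, and ML estimation of compositions and nuisance parameters."""

import itertools

import numpy as np
import pytest

from nucshift.alignment import Alignment, compress_patterns
from nucshift.likelihood import (
    RegimeLikelihood,
    _outside_at,
    _subtree_lnl,
    fit_frequencies,
    fit_global_nuisance,
    log_likelihood,
)
from nucshift.simulate import SimConfig, generate_toy_tree, simulate_dataset
from nucshift.substitution import (
    Exchangeabilities,
    GammaRates,
    build_rate_matrix,
)
from nucshift.trees import eligible_nodes, paint_regimes, read_newick

JC = Exchangeabilities("HKY", kappa=1.0)
HKY2 = Exchangeabilities("HKY", kappa=2.0)


def exhaustive_lnl(tree, aln, painting, freqs, exch, gamma=None):
    """Independent oracle: sum over all internal-state assignments, per
    site, per rate category."""
    freqs = np.atleast_2d(freqs)
    er = painting.edge_regimes()
    rates = (gamma or GammaRates()).category_rates()
    Qs = [build_rate_matrix(exch, f) for f in freqs]
    internals = tree.internal_indices()
    from nucshift.alignment import _IUPAC_ROWS

    compat = {
        sym: [i for i, bit in enumerate(row) if bit]
        for sym, row in _IUPAC_ROWS.items()
    }
    total = 0.0
    for site in range(aln.length):
        obs = {
            tree.labels[i]: compat[aln.sequence(tree.labels[i])[site]]
            for i in tree.leaf_indices()
        }
        site_like = 0.0
        for r in rates:
            for states in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, states))
                pr = freqs[0][st[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    P = Qs[int(er[v])].probs(r * float(tree.branch_length[v]))
                    if v in st:
                        pr *= P[st[int(tree.parent[v])], st[v]]
                    else:
                        pr *= sum(
                            P[st[int(tree.parent[v])], sv]
                            for sv in obs[tree.labels[v]]
                        )
                site_like += pr
        total += np.log(site_like / len(rates))
    return total


class TestPruningOracles:
    def test_single_site_zero_branches(self):
        t = read_newick("(a:0.0,b:0.0);")
        aln = Alignment.from_dict({"a": "A", "b": "A"})
        pat = compress_patterns(aln, t.leaf_labels)
        lnl = log_likelihood(t, pat, paint_regimes(t, []), [[0.25] * 4], JC)
        assert lnl == pytest.approx(np.log(0.25), abs=1e-12)

    def test_two_taxon_jc_closed_form(self):
        t = read_newick("(a:0.05,b:0.15);")
        aln = Alignment.from_dict({"a": "AACG", "b": "AGCG"})
        pat = compress_patterns(aln, t.leaf_labels)
        lnl = log_likelihood(t, pat, paint_regimes(t, []), [[0.25] * 4], JC)
        tt = 0.2  # total path length
        match = 0.25 * (0.25 + 0.75 * np.exp(-4 * tt / 3))
        mismatch = 0.25 * (0.25 - 0.25 * np.exp(-4 * tt / 3))
        assert lnl == pytest.approx(
            3 * np.log(match) + np.log(mismatch), abs=1e-10
        )

    def test_four_taxon_one_shift_exhaustive(self, tree4, aln4, patterns4):
        s = eligible_nodes(tree4, 2)[0]
        painting = paint_regimes(tree4, [s])
        freqs = np.array([[0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1]])
        got = log_likelihood(tree4, patterns4, painting, freqs, HKY2)
        want = exhaustive_lnl(tree4, aln4, painting, freqs, HKY2)
        assert got == pytest.approx(want, abs=1e-8)

    def test_exhaustive_with_gamma_and_ambiguity(self, tree4):
        aln = Alignment.from_dict(
            {"a": "ACGN-", "b": "ACGTA", "c": "AYGTA", "d": "ACGTA"}
        )
        pat = compress_patterns(aln, tree4.leaf_labels)
        painting = paint_regimes(tree4, [])
        g = GammaRates(0.6, 3)
        freqs = np.array([[0.3, 0.2, 0.2, 0.3]])
        got = log_likelihood(tree4, pat, painting, freqs, HKY2, g)
        want = exhaustive_lnl(tree4, aln, painting, freqs, HKY2, g)
        assert got == pytest.approx(want, abs=1e-8)


class TestInvariants:
    def test_pattern_compression_preserves_lnl(self):
        rng = np.random.default_rng(11)
        tree = generate_toy_tree(8, seed=11)
        aln = Alignment.from_dict(
            {t: "".join(rng.choice(list("ACGT"), 1000))
             for t in tree.leaf_labels}
        )
        pat = compress_patterns(aln, tree.leaf_labels)
        # uncompressed: weight-1 patterns over every raw column
        from nucshift.alignment import SitePatterns

        raw = SitePatterns(
            tree.leaf_labels, aln.take_taxa(tree.leaf_labels),
            np.ones(aln.length, dtype=np.int64), aln.length,
        )
        painting = paint_regimes(tree, [])
        freqs = [[0.1, 0.2, 0.3, 0.4]]
        a = log_likelihood(tree, pat, painting, freqs, HKY2)
        b = log_likelihood(tree, raw, painting, freqs, HKY2)
        assert a == pytest.approx(b, abs=1e-10)

    def test_pulley_principle_reroot_along_branch(self):
        # homogeneous reversible model: sliding the root along a branch
        # leaves the likelihood unchanged
        aln = Alignment.from_dict(
            {"a": "ACGTAC", "b": "ACGTTT", "c": "AGGTAC", "d": "ACGAAC",
             "e": "CCGTAC"}
        )
        freqs = [[0.3, 0.2, 0.25, 0.25]]
        lnls = []
        for split in [0.05, 0.2, 0.35]:
            nwk = (
                f"((a:0.1,b:0.2):{split},"
                f"((c:0.15,d:0.1):0.12,e:0.3):{0.4 - split});"
            )
            t = read_newick(nwk)
            pat = compress_patterns(aln, t.leaf_labels)
            lnls.append(
                log_likelihood(t, pat, paint_regimes(t, []), freqs, HKY2)
            )
        assert lnls[0] == pytest.approx(lnls[1], abs=1e-8)
        assert lnls[0] == pytest.approx(lnls[2], abs=1e-8)

    def test_redundant_regime_leaves_lnl_unchanged(self, tree4, patterns4):
        s = eligible_nodes(tree4, 2)[0]
        pi = [0.1, 0.2, 0.3, 0.4]
        base = log_likelihood(
            tree4, patterns4, paint_regimes(tree4, []), [pi], HKY2
        )
        dup = log_likelihood(
            tree4, patterns4, paint_regimes(tree4, [s]), [pi, pi], HKY2
        )
        assert dup == pytest.approx(base, abs=1e-8)

    def test_gamma_k1_equals_no_gamma_path(self, tree4, patterns4):
        painting = paint_regimes(tree4, [])
        freqs = [[0.2, 0.3, 0.3, 0.2]]
        a = log_likelihood(tree4, patterns4, painting, freqs, HKY2, None)
        b = log_likelihood(
            tree4, patterns4, painting, freqs, HKY2, GammaRates(0.5, 1)
        )
        assert a == b

    def test_regime_update_cache_matches_fresh_engine(self):
        """Incremental partial updates equal a cold rebuild."""
        tree = generate_toy_tree(12, seed=5)
        rng = np.random.default_rng(5)
        aln = Alignment.from_dict(
            {t: "".join(rng.choice(list("ACGT"), 200))
             for t in tree.leaf_labels}
        )
        pat = compress_patterns(aln, tree.leaf_labels)
        shifts = eligible_nodes(tree, 4)[:2]
        painting = paint_regimes(tree, shifts)
        freqs = rng.dirichlet(np.ones(4), size=len(shifts) + 1)
        ctx = RegimeLikelihood(tree, pat, painting, freqs, HKY2)
        for r in range(len(shifts) + 1):
            newpi = rng.dirichlet(np.ones(4))
            lnl_inc = ctx.set_regime_frequencies(r, newpi)
            lnl_cold = log_likelihood(
                tree, pat, painting, ctx.freqs.copy(), HKY2
            )
            # incremental and cold paths accumulate per-pattern scaling in a
            # different order; allow rounding-level disagreement
            assert lnl_inc == pytest.approx(lnl_cold, abs=1e-6)

    def test_outside_partials_match_full_likelihood(self, tree4, patterns4):
        s = eligible_nodes(tree4, 2)[1]
        painting = paint_regimes(tree4, [s])
        freqs = np.array([[0.1, 0.2, 0.3, 0.4], [0.3, 0.3, 0.2, 0.2]])
        ctx = RegimeLikelihood(
            tree4, patterns4, painting, freqs, HKY2, GammaRates(0.4, 3)
        )
        O, oscale = _outside_at(ctx, s)
        assert _subtree_lnl(ctx, s, O, oscale) == pytest.approx(
            ctx.lnl(), abs=1e-9
        )


@pytest.fixture(scope="module")
def homogeneous_20k():
    tree = generate_toy_tree(24, seed=17)
    truth = np.array([0.1, 0.2, 0.3, 0.4])
    cfg = SimConfig(scenario="none", length=20_000, seed=17)
    ds = simulate_dataset(tree, cfg, rng=np.random.default_rng(17))
    # overwrite the Dirichlet composition with the fixed target
    from nucshift.simulate import simulate_alignment

    aln = simulate_alignment(
        tree, ds.painting, truth[None, :], kappa=2.0, length=20_000,
        rng=np.random.default_rng(99),
    )
    pat = compress_patterns(aln, tree.leaf_labels)
    return tree, pat, truth


class TestFitting:
    def test_root_composition_recovery(self, homogeneous_20k):
        tree, pat, truth = homogeneous_20k
        ctx = RegimeLikelihood(
            tree, pat, paint_regimes(tree, []), [[0.25] * 4], HKY2
        )
        freqs, lnl, converged = fit_frequencies(ctx, [0])
        assert converged
        assert freqs[0] == pytest.approx(truth, abs=0.01)

    def test_multistart_stability(self, homogeneous_20k):
        tree, pat, truth = homogeneous_20k
        lnls = []
        rng = np.random.default_rng(1)
        for _ in range(5):
            ctx = RegimeLikelihood(
                tree, pat, paint_regimes(tree, []),
                rng.dirichlet(np.ones(4))[None, :], HKY2,
            )
            _, lnl, _ = fit_frequencies(ctx, [0])
            lnls.append(lnl)
        assert max(lnls) - min(lnls) < 1e-6

    def test_degenerate_single_base_data(self):
        t = read_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln = Alignment.from_dict({x: "AAAA" for x in "abcd"})
        pat = compress_patterns(aln, t.leaf_labels)
        ctx = RegimeLikelihood(
            t, pat, paint_regimes(t, []), [[0.25] * 4], JC
        )
        freqs, lnl, _ = fit_frequencies(ctx, [0])
        assert np.isfinite(lnl)
        assert freqs[0][0] > 0.95  # pi_A driven toward its bound

    def test_nuisance_kappa_recovery(self):
        tree = generate_toy_tree(24, seed=23)
        from nucshift.simulate import simulate_alignment

        aln = simulate_alignment(
            tree, paint_regimes(tree, []),
            np.array([[0.3, 0.2, 0.25, 0.25]]), kappa=2.0, length=20_000,
            rng=np.random.default_rng(23),
        )
        pat = compress_patterns(aln, tree.leaf_labels)
        fit = fit_global_nuisance(tree, pat, family="HKY", k_categories=1)
        assert fit.exch.kappa == pytest.approx(2.0, rel=0.1)
        assert fit.n_free_parameters == 1  # no gamma shape at k=1

    def test_nuisance_kappa_near_one_under_jc(self):
        tree = generate_toy_tree(24, seed=29)
        from nucshift.simulate import simulate_alignment

        aln = simulate_alignment(
            tree, paint_regimes(tree, []), np.array([[0.25] * 4]),
            kappa=1.0, length=20_000, rng=np.random.default_rng(29),
        )
        pat = compress_patterns(aln, tree.leaf_labels)
        fit = fit_global_nuisance(tree, pat, family="HKY", k_categories=1)
        assert fit.exch.kappa == pytest.approx(1.0, rel=0.12)
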