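"""Felsenstein pruning likelihood over a regime-painted tree, and maximum
likelihood estimation of regime compositions and global nuisance parameters.

The model: one shared exchangeability matrix (HKY or GTR) and, per regime, a
vector of equilibrium base frequencies.  The branch into node ``x`` evolves
under Q built from the frequencies of ``x``'s regime (stem-edge convention);
the root partials are weighted by the ancestral (regime 0) frequencies.
Discrete-gamma categories are averaged with equal weights.

:class:`RegimeLikelihood` keeps per-node conditional likelihoods cached and
recomputes only the nodes whose subtree contains an edge of a regime whose
frequencies changed — the workhorse trick that makes the stepwise search and
the simulation benchmarks affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._kernels import prune
from .alignment import SitePatterns, empirical_frequencies
from .substitution import (
    Exchangeabilities,
    GammaRates,
    build_rate_matrix,
    validate_frequencies,
)
from .trees import RootedTree, RegimePainting, paint_regimes

__all__ = [
    "RegimeLikelihood",
    "log_likelihood",
    "fit_frequencies",
    "fit_global_nuisance",
    "NuisanceFit",
]

_TINY = 1e-300


def _softmax4(z3: np.ndarray) -> np.ndarray:
    z = np.concatenate([z3, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _logits(pi: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(pi, dtype=float), 1e-8, None)
    p = p / p.sum()
    return np.log(p[:3]) - np.log(p[3])


class RegimeLikelihood:
    """Pruning likelihood with cached partials for a fixed painting.

    Parameters
    ----------
    tree : RootedTree
        Rooted phylogram; branch lengths in expected substitutions/site.
    patterns : SitePatterns
        Compressed site patterns whose taxa match the tree's leaves.
    painting : RegimePainting
        Node/edge -> regime assignment (regime 0 = ancestral).
    freqs : ndarray (n_regimes, 4)
        Equilibrium frequencies per regime.
    exch, gamma
        Shared exchangeabilities and discrete-gamma settings.
    """

    def __init__(
        self,
        tree: RootedTree,
        patterns: SitePatterns,
        painting: RegimePainting,
        freqs: np.ndarray,
        exch: Exchangeabilities | None = None,
        gamma: GammaRates | None = None,
    ):
        if set(patterns.taxa) != set(tree.leaf_labels):
            raise ValueError("pattern taxa do not match tree leaves")
        self.tree = tree
        self.patterns = patterns
        self.exch = exch or Exchangeabilities()
        self.gamma = gamma or GammaRates()
        n_pat = patterns.n_patterns
        k = self.gamma.k
        self._rates = self.gamma.category_rates()
        # tip partials in node index order
        tipL = patterns.tip_partials()  # (n_taxa, n_pat, 4)
        tax_row = {t: i for i, t in enumerate(patterns.taxa)}
        self.partial = np.zeros((tree.n_nodes, k, n_pat, 4))
        self.logscale = np.zeros((tree.n_nodes, n_pat))
        for i in tree.leaf_indices():
            self.partial[i] = tipL[tax_row[tree.labels[i]]][None, :, :]
        self._internal_post = np.array(
            [i for i in tree.postorder() if not tree.is_leaf(i)], dtype=np.int64
        )
        # flattened child lists for the kernels
        flat, ptr = [], [0]
        for v in range(tree.n_nodes):
            flat.extend(tree.children[v])
            ptr.append(len(flat))
        self._child_flat = np.array(flat, dtype=np.int64)
        self._child_ptr = np.array(ptr, dtype=np.int64)
        # per-edge transition matrices, indexed by child node
        self._P = np.zeros((tree.n_nodes, k, 4, 4))
        self.set_painting(painting, freqs)

    # -- painting / parameters --------------------------------------------

    def set_painting(
        self, painting: RegimePainting, freqs: np.ndarray, recompute: bool = True
    ):
        """Switch to a new painting.

        ``recompute=False`` skips re-deriving the cached partials; it is only
        valid when every edge keeps the same frequency vector under the new
        painting (e.g. a freshly introduced regime initialized with the
        frequencies its edges had before).
        """
        if painting.tree is not self.tree:
            raise ValueError("painting refers to a different tree")
        self.painting = painting
        self.edge_regime = painting.edge_regimes()
        self.freqs = np.array(
            [validate_frequencies(f) for f in np.atleast_2d(freqs)]
        )
        if self.freqs.shape[0] != painting.n_regimes:
            raise ValueError("one frequency vector required per regime")
        self._Q = [None] * painting.n_regimes
        # which regimes occur among edges in each node's subtree (bitmask)
        below = np.zeros(self.tree.n_nodes, dtype=np.int64)
        for v in self._internal_post:
            b = 0
            for c in self.tree.children[v]:
                b |= below[c] | (1 << int(self.edge_regime[c]))
            below[v] = b
        self._regimes_below = below
        self._affected = {
            r: np.array(
                [v for v in self._internal_post if below[v] >> r & 1],
                dtype=np.int64,
            )
            for r in range(painting.n_regimes)
        }
        self._edges_of_regime = {
            r: np.flatnonzero(
                (self.edge_regime == r)
                & (np.arange(self.tree.n_nodes) != self.tree.root)
            ).astype(np.int64)
            for r in range(painting.n_regimes)
        }
        for r in range(painting.n_regimes):
            self._update_edge_probs(r)
        if recompute:
            self._recompute(self._internal_post)

    def set_exchangeabilities(self, exch: Exchangeabilities):
        self.exch = exch
        self._Q = [None] * self.painting.n_regimes
        for r in range(self.painting.n_regimes):
            self._update_edge_probs(r)
        self._recompute(self._internal_post)

    def set_gamma(self, gamma: GammaRates):
        if gamma.k != self.gamma.k:
            raise ValueError("cannot change the number of categories in place")
        self.gamma = gamma
        self._rates = gamma.category_rates()
        for r in range(self.painting.n_regimes):
            self._update_edge_probs(r)
        self._recompute(self._internal_post)

    def set_regime_frequencies(self, regime: int, pi) -> float:
        """Update one regime's frequencies, recompute only affected nodes."""
        self.freqs[regime] = validate_frequencies(pi)
        self._Q[regime] = None
        self._update_edge_probs(regime)
        self._recompute(self._affected[regime])
        return self.lnl()

    # -- computation --------------------------------------------------------

    def _rate_matrix(self, regime: int):
        if self._Q[regime] is None:
            self._Q[regime] = build_rate_matrix(self.exch, self.freqs[regime])
        return self._Q[regime]

    def _update_edge_probs(self, regime: int):
        """Refresh cached per-edge transition matrices for one regime."""
        edges = self._edges_of_regime[regime]
        if edges.size == 0:
            return
        Q = self._rate_matrix(regime)
        t = self.tree.branch_length[edges]  # (E,)
        ew = np.exp(
            np.einsum("e,k,b->ekb", t, self._rates, Q._eigval)
        )
        P = np.einsum("ib,ekb,bj->ekij", Q._left, ew, Q._right)
        P = np.clip(P, 0.0, 1.0)
        self._P[edges] = P / np.maximum(P.sum(axis=-1, keepdims=True), 1e-12)

    def _recompute(self, nodes):
        """Recompute partials at the given internal nodes (postorder subset)."""
        prune(
            self.partial, self.logscale, np.asarray(nodes, dtype=np.int64),
            self._child_flat, self._child_ptr, self._P,
        )

    def lnl(self) -> float:
        """Total log-likelihood in nats (pattern-weighted)."""
        root = self.tree.root
        site = np.einsum("kpj,j->p", self.partial[root], self.freqs[0])
        site /= self.gamma.k
        ll = float(
            np.dot(
                self.patterns.weights,
                np.log(np.maximum(site, _TINY)) + self.logscale[root],
            )
        )
        if not np.isfinite(ll):
            bad = int(np.argmin(site))
            raise FloatingPointError(
                f"non-finite log-likelihood (pattern {bad})"
            )
        return ll


def log_likelihood(
    tree: RootedTree,
    patterns: SitePatterns,
    painting: RegimePainting,
    freqs,
    exch: Exchangeabilities | None = None,
    gamma: GammaRates | None = None,
) -> float:
    """One-shot pruning log-likelihood of a regime-painted model."""
    return RegimeLikelihood(tree, patterns, painting, freqs, exch, gamma).lnl()


def _outside_at(ctx: RegimeLikelihood, node: int):
    """Outside likelihoods at ``node``: (O, oscale) where ``O[k, p, i]`` is
    the likelihood of all data outside the clade of ``node`` (excluding the
    branch into ``node``), as a function of the state ``i`` at its parent
    (at the root: the regime-0 stationary weights), under the engine's
    current parameters and cached partials."""
    tree = ctx.tree
    n_pat = ctx.patterns.n_patterns
    k = ctx.gamma.k
    path = [node]
    v = node
    while tree.parent[v] >= 0:
        v = int(tree.parent[v])
        path.append(v)
    path.reverse()  # root ... node
    O = np.broadcast_to(ctx.freqs[0], (k, n_pat, 4)).copy()
    oscale = np.zeros(n_pat)
    for depth in range(len(path) - 1):
        v, c = path[depth], path[depth + 1]
        # multiply in siblings of c below v
        for b in ctx.tree.children[v]:
            if b == c:
                continue
            for cat in range(k):
                O[cat] *= ctx.partial[b, cat] @ ctx._P[b, cat].T
            oscale = oscale + ctx.logscale[b]
        if c != node:
            # transport through the edge into c
            O = np.stack([O[cat] @ ctx._P[c, cat] for cat in range(k)])
        # rescale for stability
        mx = O.max(axis=(0, 2))
        mx = np.where(mx > 0, mx, 1.0)
        O = O / mx[None, :, None]
        oscale = oscale + np.log(mx)
    return O, oscale


def _subtree_lnl(ctx, node, O, oscale):
    """Combine cached outside likelihoods with the current inside partials
    and stem-edge transition of ``node``."""
    k = ctx.gamma.k
    stem = np.zeros(ctx.patterns.n_patterns)
    for cat in range(k):
        stem += ((ctx.partial[node, cat] @ ctx._P[node, cat].T) * O[cat]).sum(axis=1)
    site = stem / k
    ll = float(
        np.dot(
            ctx.patterns.weights,
            np.log(np.maximum(site, _TINY)) + oscale + ctx.logscale[node],
        )
    )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


def _optimize_regime(
    ctx: RegimeLikelihood,
    regime: int,
    start: np.ndarray,
    maxfun: int = 500,
    ftol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Maximize lnL over one regime's frequencies (softmax parameterized).

    For a derived regime (one founded by a shift node) each trial only
    recomputes the shift node's subtree; the likelihood of the remainder of
    the tree enters through cached outside partials.
    """
    shift_node = None
    if regime > 0:
        shift_node = int(ctx.painting.shift_nodes[regime - 1])
    if shift_node is not None:
        inside = ctx._affected[regime]
        clade = set(ctx.tree.descendants(shift_node)) | {shift_node}
        inside = np.array([v for v in inside if v in clade], dtype=np.int64)
        O, oscale = _outside_at(ctx, shift_node)

        def negll(z):
            ctx.freqs[regime] = _softmax4(z)
            ctx._Q[regime] = None
            ctx._update_edge_probs(regime)
            ctx._recompute(inside)
            return -_subtree_lnl(ctx, shift_node, O, oscale)

    else:

        def negll(z):
            return -ctx.set_regime_frequencies(regime, _softmax4(z))

    res = minimize(
        negll,
        np.clip(_logits(start), -12, 12),
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * 3,
        options={
            "maxfun": maxfun, "maxiter": 60, "ftol": ftol, "gtol": 1e-6,
            "eps": 1e-6,
        },
    )
    best = _softmax4(res.x)
    # full restore (recomputes ancestors for derived regimes)
    lnl = ctx.set_regime_frequencies(regime, best)
    return best, lnl


def fit_frequencies(
    ctx: RegimeLikelihood,
    target_regimes,
    starts: dict | None = None,
    n_starts: int = 0,
    rng=None,
    max_sweeps: int = 5,
    sweep_tol: float = 1e-6,
    maxfun: int = 500,
    ftol: float = 1e-12,
):
    """ML frequencies for the target regimes, other parameters held fixed.

    Multiple regimes are handled by coordinate ascent (up to ``max_sweeps``
    sweeps, stopping when a sweep improves lnL by less than ``sweep_tol``).
    ``starts`` may give a deterministic starting simplex per regime (defaults
    to the current values); ``n_starts`` adds seeded random restarts.

    Returns ``(freqs, lnl, converged)`` where ``freqs`` is the updated
    (n_regimes, 4) matrix held by ``ctx``.
    """
    target_regimes = list(target_regimes)
    entry = ctx.lnl()
    converged = True
    for r in target_regimes:
        if starts and r in starts:
            ctx.set_regime_frequencies(r, starts[r])
    current = ctx.lnl()
    for sweep in range(max_sweeps):
        before = current
        for r in target_regimes:
            _, current = _optimize_regime(ctx, r, ctx.freqs[r], maxfun=maxfun, ftol=ftol)
        if len(target_regimes) == 1 or current - before < sweep_tol:
            break
    else:
        converged = False
    if n_starts and rng is not None:
        best = (current, ctx.freqs.copy())
        for _ in range(n_starts):
            for r in target_regimes:
                ctx.set_regime_frequencies(r, rng.dirichlet(np.ones(4)))
            trial = ctx.lnl()
            for sweep in range(max_sweeps):
                before = trial
                for r in target_regimes:
                    _, trial = _optimize_regime(ctx, r, ctx.freqs[r], maxfun=maxfun, ftol=ftol)
                if len(target_regimes) == 1 or trial - before < sweep_tol:
                    break
            if trial > best[0]:
                best = (trial, ctx.freqs.copy())
        current = best[0]
        for r in range(ctx.freqs.shape[0]):
            ctx.set_regime_frequencies(r, best[1][r])
        current = ctx.lnl()
    if current < entry - 1e-6:
        converged = False
    return ctx.freqs.copy(), current, converged


@dataclass
class NuisanceFit:
    """Global parameters estimated once under the homogeneous model."""

    exch: Exchangeabilities
    gamma: GammaRates
    root_freqs: np.ndarray
    lnl: float
    converged: bool

    @property
    def n_free_parameters(self) -> int:
        """Exchangeability + gamma-shape parameters (frequencies counted
        per regime by the search's BIC)."""
        return self.exch.n_free_parameters + self.gamma.n_free_parameters


def fit_global_nuisance(
    tree: RootedTree,
    patterns: SitePatterns,
    family: str = "HKY",
    k_categories: int = 1,
    maxfun: int = 500,
) -> NuisanceFit:
    """Joint ML of root composition, exchangeabilities, and gamma shape under
    the homogeneous (single-regime) model.

    These values are held fixed during the shift search.
    """
    painting = paint_regimes(tree, [])
    pi0 = _pattern_frequencies(patterns)
    ctx = RegimeLikelihood(
        tree, patterns, painting, pi0[None, :],
        Exchangeabilities(family=family),
        GammaRates(shape=1.0, k=k_categories),
    )
    n_exch = 1 if family == "HKY" else 5
    with_shape = k_categories > 1

    def unpack(theta):
        pi = _softmax4(np.clip(theta[:3], -16, 16))
        pi = np.clip(pi, 1e-10, None)
        pi = pi / pi.sum()
        ex = np.exp(np.clip(theta[3:3 + n_exch], -7, 7))
        if family == "HKY":
            exch = Exchangeabilities(family="HKY", kappa=float(ex[0]))
        else:
            exch = Exchangeabilities(family="GTR", rates=(*ex, 1.0))
        shape = (
            float(np.exp(np.clip(theta[3 + n_exch], -5, 6)))
            if with_shape else 1.0
        )
        return pi, exch, GammaRates(shape=shape, k=k_categories)

    def negll(theta):
        pi, exch, gamma = unpack(theta)
        ctx.exch = exch
        ctx._rates = gamma.category_rates()
        ctx.gamma = gamma
        ctx._Q = [None]
        ctx.freqs[0] = pi
        ctx._update_edge_probs(0)
        ctx._recompute(ctx._internal_post)
        try:
            return -ctx.lnl()
        except FloatingPointError:
            return 1e12

    x0 = np.concatenate([
        _logits(pi0),
        np.zeros(n_exch) if family == "GTR" else [np.log(2.0)],
        [0.0] if with_shape else [],
    ])
    bounds = (
        [(-12.0, 12.0)] * 3
        + [(-7.0, 7.0)] * n_exch
        + ([(-5.0, 6.0)] if with_shape else [])
    )
    res = minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": maxfun, "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-6},
    )
    pi, exch, gamma = unpack(res.x)
    lnl = -negll(res.x)
    return NuisanceFit(exch, gamma, pi, lnl, bool(res.success))


def fit_exchangeabilities(
    ctx: RegimeLikelihood, maxfun: int = 200
) -> tuple[Exchangeabilities, GammaRates, float]:
    """Re-estimate the shared exchangeabilities (and gamma shape, when rate
    variation is on) under the engine's current painting and regime
    frequencies, in place.

    Used to update the global nuisance as the shift configuration grows: a
    transition:transversion rate estimated under the homogeneous model is
    biased when real compositional shifts are present, and holding the
    biased value fixed lets spurious regimes absorb the misfit.
    """
    family = ctx.exch.family
    n_exch = 1 if family == "HKY" else 5
    with_shape = ctx.gamma.k > 1

    def unpack(theta):
        ex = np.exp(np.clip(theta[:n_exch], -7, 7))
        if family == "HKY":
            exch = Exchangeabilities(family="HKY", kappa=float(ex[0]))
        else:
            exch = Exchangeabilities(family="GTR", rates=(*ex, 1.0))
        shape = (
            float(np.exp(np.clip(theta[n_exch], -5, 6))) if with_shape
            else ctx.gamma.shape
        )
        return exch, GammaRates(shape=shape, k=ctx.gamma.k)

    def negll(theta):
        exch, gamma = unpack(theta)
        ctx.exch = exch
        ctx.gamma = gamma
        ctx._rates = gamma.category_rates()
        ctx._Q = [None] * ctx.painting.n_regimes
        for r in range(ctx.painting.n_regimes):
            ctx._update_edge_probs(r)
        ctx._recompute(ctx._internal_post)
        try:
            return -ctx.lnl()
        except FloatingPointError:
            return 1e12

    x0 = np.concatenate([
        [np.log(ctx.exch.kappa)] if family == "HKY"
        else np.log(np.asarray(ctx.exch.rates[:5])),
        [np.log(ctx.gamma.shape)] if with_shape else [],
    ])
    bounds = [(-7.0, 7.0)] * n_exch + ([(-5.0, 6.0)] if with_shape else [])
    res = minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": maxfun, "ftol": 1e-12, "gtol": 1e-6, "eps": 1e-6},
    )
    exch, gamma = unpack(res.x)
    lnl = -negll(res.x)
    return exch, gamma, lnl


def _pattern_frequencies(patterns: SitePatterns) -> np.ndarray:
    """Empirical base frequencies from pattern data (weighted, unambiguous
    symbols only) — the deterministic optimizer start."""
    rows = patterns.tip_partials()  # (n_taxa, n_pat, 4)
    unambiguous = rows.sum(axis=2) == 1
    counts = np.einsum(
        "tp,tpj,p->j", unambiguous.astype(float), rows, patterns.weights.astype(float)
    )
    counts += 1e-6
    return counts / counts.sum()
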