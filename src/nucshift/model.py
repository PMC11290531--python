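"""Stepwise detection of equilibrium base-frequency shifts on a rooted tree.

The estimator: starting from a homogeneous (single-regime) reversible model
whose nuisance parameters (exchangeabilities, gamma shape, root composition)
are fitted once, every eligible internal node is scored as a candidate
two-regime model (subtree composition free, remainder at the root
composition) and ranked by BIC.  Candidates are then revisited greedily in
that order: each shift is tentatively added to the current configuration,
the regime compositions are re-optimized jointly, and the shift is kept only
if the updated BIC decreases.  Support for each accepted shift is summarized
by BIC weights for its existence (model with vs. without the shift) and its
location (focal node vs. its internal daughters).

Typical use::

    model = CompositionShiftModel(tree, alignment, min_clade=4)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, compress_patterns, empirical_frequencies
from dataclasses import replace as _dc_replace

from .likelihood import (
    NuisanceFit,
    RegimeLikelihood,
    _optimize_regime,
    fit_exchangeabilities,
    fit_frequencies,
    fit_global_nuisance,
)
from .substitution import equilibrium_gc
from .trees import RootedTree, RegimePainting, eligible_nodes, paint_regimes

__all__ = ["bic", "bic_weights", "CandidateShift", "CompositionShiftModel",
           "ShiftSearchResults"]


def bic(lnl: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: ``k * ln(n) - 2 * lnl``."""
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    if k < 0:
        raise ValueError("parameter count k must be >= 0")
    return k * np.log(n) - 2.0 * lnl


def bic_weights(scores) -> np.ndarray:
    """Normalized BIC weights exp(-dBIC/2) / sum, with dBIC from the best."""
    s = np.asarray(scores, dtype=float)
    d = s - s.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


@dataclass
class CandidateShift:
    """A single-node two-regime candidate model."""

    node: int
    leafset: frozenset
    subtree_freqs: np.ndarray
    lnl: float
    bic: float
    delta_bic: float  # vs. the root-only model


class CompositionShiftModel:
    """Model object: a rooted phylogram plus a matching alignment.

    Parameters
    ----------
    tree : RootedTree
        Rooted bifurcating phylogram, branch lengths in substitutions/site.
    alignment : Alignment
        DNA alignment whose taxa cover the tree's leaves.
    min_clade : int
        Minimum clade size (leaves) for a node to host a shift (default 4).
    family : str
        Exchangeability family, ``"HKY"`` (default) or ``"GTR"``.
    gamma_categories : int
        Discrete-gamma categories for among-site rate variation; 0 or 1
        disables it.
    stem_edge : bool
        Whether a shift applies to the branch subtending the shift node
        (default True).
    frozen : bool
        Greedy re-scoring reuses the per-candidate subtree estimates instead
        of re-optimizing all regimes jointly (the cheaper literal stepwise
        reading).
    bic_on_patterns : bool
        Use the number of unique site patterns instead of alignment sites as
        the BIC sample size.
    update_nuisance : bool
        Re-estimate the shared exchangeabilities (and gamma shape) after
        each accepted shift (default True).  A transition:transversion rate
        estimated once under the homogeneous model is biased when real
        shifts exist, and holding it fixed lets spurious regimes soak up
        the misfit.
    refit_nuisance : bool
        Re-estimate exchangeabilities/gamma once at the final configuration
        (cheaper alternative when ``update_nuisance`` is off).
    seed : int or None
        Seeds the optional multi-start composition optimizations.
    """

    def __init__(
        self,
        tree: RootedTree,
        alignment: Alignment,
        *,
        min_clade: int = 4,
        family: str = "HKY",
        gamma_categories: int = 4,
        stem_edge: bool = True,
        frozen: bool = False,
        bic_on_patterns: bool = False,
        update_nuisance: bool = True,
        refit_nuisance: bool = False,
        rescoring: str = "new_regime",
        n_starts: int = 0,
        seed: int | None = None,
    ):
        if rescoring not in ("new_regime", "joint"):
            raise ValueError("rescoring must be 'new_regime' or 'joint'")
        missing = set(tree.leaf_labels) - set(alignment.taxa)
        if missing:
            raise ValueError(f"tree leaves absent from alignment: {sorted(missing)[:5]}")
        self.tree = tree
        self.alignment = alignment
        self.min_clade = int(min_clade)
        self.family = family
        self.gamma_categories = int(gamma_categories) if gamma_categories else 1
        self.stem_edge = bool(stem_edge)
        self.frozen = bool(frozen)
        self.bic_on_patterns = bool(bic_on_patterns)
        self.update_nuisance = bool(update_nuisance)
        self.refit_nuisance = bool(refit_nuisance)
        self.rescoring = rescoring
        self.n_starts = int(n_starts)
        self.rng = np.random.default_rng(seed)
        self.patterns = compress_patterns(alignment, tree.leaf_labels)
        self.n_obs = (
            self.patterns.n_patterns if bic_on_patterns else self.patterns.n_sites
        )

    @classmethod
    def from_files(cls, tree_path, alignment_path, fmt: str = "fasta", **kwargs):
        from .trees import read_newick

        with open(tree_path) as fh:
            tree = read_newick(fh.read())
        aln = Alignment.read(alignment_path, fmt=fmt)
        return cls(tree, aln, **kwargs)

    # -- building blocks ---------------------------------------------------

    def _n_params(self, n_regimes: int, nuisance: NuisanceFit) -> int:
        return 3 * n_regimes + nuisance.n_free_parameters

    def fit_nuisance(self) -> NuisanceFit:
        """Step 1: homogeneous-model ML of root composition + nuisance."""
        return fit_global_nuisance(
            self.tree, self.patterns, family=self.family,
            k_categories=self.gamma_categories,
        )

    def score_candidates(self, nuisance: NuisanceFit) -> list[CandidateShift]:
        """Steps 2-4: score a two-regime model at every eligible node.

        The subtree composition is fitted by ML while the remainder of the
        tree keeps the root composition; candidates are returned sorted by
        BIC (ascending), ties broken by postorder index.
        """
        tree = self.tree
        cands: list[CandidateShift] = []
        nodes = eligible_nodes(tree, self.min_clade)
        if not nodes:
            return cands
        pi0 = nuisance.root_freqs
        ctx = RegimeLikelihood(
            tree, self.patterns, paint_regimes(tree, [], self.stem_edge),
            pi0[None, :], nuisance.exch, nuisance.gamma,
        )
        k2 = self._n_params(2, nuisance)
        for s in nodes:
            painting = paint_regimes(tree, [s], self.stem_edge)
            ctx.set_painting(painting, np.vstack([pi0, pi0]), recompute=False)
            start = empirical_frequencies(
                self.alignment, sorted(tree.leafset(s)), pseudo=0.5
            )
            freqs, lnl, _ = fit_frequencies(
                ctx, [1], starts={1: start}, maxfun=150, ftol=1e-10,
                n_starts=self.n_starts, rng=self.rng,
            )
            b = bic(lnl, k2, self.n_obs)
            cands.append(
                CandidateShift(
                    node=int(s),
                    leafset=tree.leafset(s),
                    subtree_freqs=freqs[1].copy(),
                    lnl=lnl,
                    bic=b,
                    delta_bic=np.nan,  # filled by caller (needs root-only BIC)
                )
            )
            # restore the homogeneous partial state for the next candidate
            ctx.set_regime_frequencies(1, pi0)
        cands.sort(key=lambda c: (c.bic, c.node))
        return cands

    # -- full search --------------------------------------------------------

    def fit(
        self,
        existence: bool = True,
        location: bool = True,
        prune_below: float | None = None,
    ) -> "ShiftSearchResults":
        """Run the stepwise search and support assessment."""
        tree = self.tree
        nuisance = self.fit_nuisance()
        n = self.n_obs
        root_bic = bic(nuisance.lnl, self._n_params(1, nuisance), n)

        candidates = self.score_candidates(nuisance)
        for c in candidates:
            c.delta_bic = c.bic - root_bic

        ctx = RegimeLikelihood(
            tree, self.patterns, paint_regimes(tree, [], self.stem_edge),
            nuisance.root_freqs[None, :], nuisance.exch, nuisance.gamma,
        )
        accepted: list[int] = []
        cand_pi = {c.node: c.subtree_freqs for c in candidates}
        current_freqs = nuisance.root_freqs[None, :].copy()
        current_lnl = nuisance.lnl
        current_bic = root_bic
        trajectory = [root_bic]
        log: list[dict] = []

        for c in candidates:
            tent = accepted + [c.node]
            new_idx = len(tent)
            q = ctx.painting.regime_of(c.node)
            tentative_deferred = False
            if not accepted and self.rescoring != "joint":
                # before the first acceptance a tentative add conditions on
                # exactly what candidate scoring conditioned on: reuse it
                lnl_new = c.lnl
                tentative_deferred = True
            else:
                painting_t = paint_regimes(tree, tent, self.stem_edge)
                ctx.set_painting(
                    painting_t, np.vstack([current_freqs, current_freqs[q]]),
                    recompute=False,
                )
                if self.frozen:
                    lnl_new = ctx.set_regime_frequencies(
                        new_idx, cand_pi[c.node]
                    )
                elif self.rescoring == "new_regime":
                    ctx.set_regime_frequencies(new_idx, cand_pi[c.node])
                    _, lnl_new = _optimize_regime(
                        ctx, new_idx, ctx.freqs[new_idx],
                        maxfun=80, ftol=1e-10,
                    )
                else:  # joint re-optimization of every regime
                    ctx.set_regime_frequencies(new_idx, cand_pi[c.node])
                    _, lnl_new, _ = fit_frequencies(
                        ctx, range(new_idx + 1), max_sweeps=5, sweep_tol=1e-6,
                        n_starts=self.n_starts, rng=self.rng,
                    )
            bic_new = bic(lnl_new, self._n_params(len(tent) + 1, nuisance), n)
            if bic_new < current_bic:
                if tentative_deferred:
                    ctx.set_painting(
                        paint_regimes(tree, tent, self.stem_edge),
                        np.vstack([current_freqs, current_freqs[q]]),
                        recompute=False,
                    )
                    ctx.set_regime_frequencies(new_idx, cand_pi[c.node])
                accepted = tent
                current_lnl = lnl_new
                current_bic = bic_new
                # polish: joint composition refit (and nuisance update)
                if not self.frozen and (
                    self.rescoring != "joint" or self.update_nuisance
                ):
                    if self.update_nuisance:
                        exch_u, gamma_u, _ = fit_exchangeabilities(ctx)
                        nuisance = _dc_replace(
                            nuisance, exch=exch_u, gamma=gamma_u
                        )
                    freqs_u, lnl_u, _ = fit_frequencies(
                        ctx, range(len(accepted) + 1),
                        max_sweeps=5, sweep_tol=1e-6,
                    )
                    b_u = bic(
                        lnl_u, self._n_params(len(accepted) + 1, nuisance), n
                    )
                    if b_u < current_bic:
                        current_lnl, current_bic = lnl_u, b_u
                current_freqs = ctx.freqs.copy()
                trajectory.append(current_bic)
                log.append(
                    {"node": c.node, "action": "accept", "bic": current_bic}
                )
            else:
                log.append({"node": c.node, "action": "reject", "bic": bic_new})
                if not tentative_deferred:
                    # restore the engine to the accepted configuration: only
                    # the tentative regime's edges moved, so resetting them
                    # to the surrounding regime's values undoes the trial
                    ctx.set_regime_frequencies(new_idx, current_freqs[q])
                    if self.rescoring == "joint" and not self.frozen:
                        for r in range(new_idx):
                            ctx.set_regime_frequencies(r, current_freqs[r])
                    ctx.set_painting(
                        paint_regimes(tree, accepted, self.stem_edge),
                        current_freqs, recompute=False,
                    )

        if self.refit_nuisance and not self.update_nuisance and accepted:
            exch_u, gamma_u, lnl_u = fit_exchangeabilities(ctx)
            nuisance = _dc_replace(nuisance, exch=exch_u, gamma=gamma_u)
            freqs_u, lnl_u, _ = fit_frequencies(
                ctx, range(len(accepted) + 1), max_sweeps=5, sweep_tol=1e-6
            )
            current_freqs, current_lnl = freqs_u, lnl_u
            current_bic = bic(
                lnl_u, self._n_params(len(accepted) + 1, nuisance), n
            )

        results = ShiftSearchResults(
            model=self,
            nuisance=nuisance,
            shift_nodes=tuple(accepted),
            freqs=current_freqs.copy(),
            lnl=current_lnl,
            bic=current_bic,
            root_bic=root_bic,
            trajectory=trajectory,
            candidates=candidates,
            decisions=log,
            n_obs=n,
        )
        if existence and accepted:
            results.existence_weights = self._existence_weights(
                ctx, accepted, current_freqs, current_bic, nuisance
            )
        if location and accepted:
            results.location_weights = self._location_weights(
                ctx, accepted, current_freqs, current_bic, nuisance
            )
        if prune_below is not None and accepted:
            keep = [
                s for s in accepted
                if results.existence_weights.get(s, 1.0) >= prune_below
            ]
            if len(keep) < len(accepted):
                lnl_p, freqs_p = self._refit_cold(
                    ctx, keep,
                    np.vstack([nuisance.root_freqs] * (len(keep) + 1)),
                    nuisance,
                )
                freqs_p = freqs_p.copy()
                results.pruned = {
                    "shift_nodes": tuple(keep),
                    "lnl": lnl_p,
                    "bic": bic(lnl_p, self._n_params(len(keep) + 1, nuisance), n),
                    "freqs": freqs_p,
                }
        # leave the engine in the final state
        ctx.set_painting(
            paint_regimes(tree, accepted, self.stem_edge), current_freqs
        )
        return results

    # -- internals -----------------------------------------------------------

    def _refit_cold(self, ctx, shifts, start_freqs, nuisance):
        """Full refit of a configuration with warm regime starts."""
        tree = self.tree
        painting = paint_regimes(tree, shifts, self.stem_edge)
        ctx.set_painting(painting, start_freqs)
        if self.frozen:
            return ctx.lnl(), ctx.freqs.copy()
        freqs, lnl, _ = fit_frequencies(
            ctx, list(range(len(shifts) + 1)), max_sweeps=5, sweep_tol=1e-6,
        )
        return lnl, freqs.copy()

    def _existence_weights(self, ctx, accepted, final_freqs, final_bic, nuisance):
        """BIC weight for each shift: final model vs. model without it."""
        weights = {}
        for i, s in enumerate(accepted):
            others = [x for x in accepted if x != s]
            # drop the removed regime's row; its edges fall back to the
            # surrounding regime, then everything is re-optimized
            keep_rows = [0] + [j + 1 for j, x in enumerate(accepted) if x != s]
            start = final_freqs[keep_rows]
            _, bic_without = self._config_bic(ctx, others, start, nuisance)
            w = bic_weights([final_bic, bic_without])
            weights[s] = float(w[0])
        return weights

    def _location_weights(self, ctx, accepted, final_freqs, final_bic, nuisance):
        """BIC weights over shift placements {focal, internal daughters}."""
        tree = self.tree
        out = {}
        for i, s in enumerate(accepted):
            placements = [s] + [
                c for c in tree.children[s] if not tree.is_leaf(c)
            ]
            if len(placements) == 1:
                out[s] = {s: 1.0}
                continue
            scores = [final_bic]
            for p in placements[1:]:
                shifts = [p if x == s else x for x in accepted]
                _, b = self._config_bic(ctx, shifts, final_freqs, nuisance)
                scores.append(b)
            w = bic_weights(scores)
            out[s] = {p: float(wi) for p, wi in zip(placements, w)}
        return out

    def _config_bic(self, ctx, shifts, start_freqs, nuisance):
        lnl, _ = self._refit_cold(ctx, shifts, start_freqs, nuisance)
        return lnl, bic(lnl, self._n_params(len(shifts) + 1, nuisance), self.n_obs)


@dataclass
class ShiftSearchResults:
    """Results of the stepwise composition-shift search."""

    model: CompositionShiftModel
    nuisance: NuisanceFit
    shift_nodes: tuple
    freqs: np.ndarray          # (n_regimes, 4), row 0 = ancestral
    lnl: float
    bic: float
    root_bic: float
    trajectory: list
    candidates: list
    decisions: list
    n_obs: int
    existence_weights: dict = field(default_factory=dict)
    location_weights: dict = field(default_factory=dict)
    pruned: dict | None = None

    # -- derived ------------------------------------------------------------

    @property
    def n_regimes(self) -> int:
        return len(self.shift_nodes) + 1

    @property
    def painting(self) -> RegimePainting:
        return paint_regimes(
            self.model.tree, self.shift_nodes, self.model.stem_edge
        )

    def shift_leafsets(self) -> list[frozenset]:
        return [self.model.tree.leafset(s) for s in self.shift_nodes]

    def regime_taxa(self) -> dict:
        """Taxa whose terminal branch sits in each regime."""
        painting = self.painting
        tree = self.model.tree
        out = {r: [] for r in range(self.n_regimes)}
        for i in tree.leaf_indices():
            out[painting.regime_of(i)].append(tree.labels[i])
        return out

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        taxa = self.regime_taxa()
        for r in range(self.n_regimes):
            node = None if r == 0 else self.shift_nodes[r - 1]
            pi = self.freqs[r]
            rows.append({
                "regime": r,
                "shift_node": node,
                "clade_size": (
                    self.model.tree.n_leaves if r == 0
                    else len(self.model.tree.leafset(node))
                ),
                "n_terminal_taxa": len(taxa[r]),
                "pi_A": pi[0], "pi_C": pi[1], "pi_G": pi[2], "pi_T": pi[3],
                "eq_GC": equilibrium_gc(pi),
                "existence_weight": (
                    np.nan if r == 0 else self.existence_weights.get(node, np.nan)
                ),
                "focal_location_weight": (
                    np.nan if r == 0
                    else self.location_weights.get(node, {}).get(node, np.nan)
                ),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Composition shift search".center(70),
            "=" * 70,
            f"Taxa: {m.tree.n_leaves}    Sites: {m.patterns.n_sites}"
            f"    Patterns: {m.patterns.n_patterns}",
            f"Family: {m.family}    Gamma categories: {m.gamma_categories}"
            f"    Min clade: {m.min_clade}",
            (
                f"Nuisance: kappa={self.nuisance.exch.kappa:.4g}"
                if self.nuisance.exch.family == "HKY"
                else f"Nuisance: GTR rates={tuple(round(r, 4) for r in self.nuisance.exch.rates)}"
            )
            + (
                f"    gamma shape={self.nuisance.gamma.shape:.4g}"
                if self.nuisance.gamma.k > 1 else ""
            ),
            f"Root-only BIC: {self.root_bic:.3f}    Final BIC: {self.bic:.3f}"
            f"    lnL: {self.lnl:.3f}",
            f"Accepted shifts: {len(self.shift_nodes)}"
            f"    Regimes: {self.n_regimes}",
            "-" * 70,
            self.summary_frame().to_string(
                index=False, float_format=lambda x: f"{x:0.4f}"
            ),
            "=" * 70,
        ]
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "tree": self.model.tree.to_newick(),
            "family": self.model.family,
            "gamma_categories": self.model.gamma_categories,
            "min_clade": self.model.min_clade,
            "stem_edge": self.model.stem_edge,
            "n_obs": self.n_obs,
            "nuisance": {
                "kappa": self.nuisance.exch.kappa,
                "gtr_rates": list(self.nuisance.exch.rates),
                "family": self.nuisance.exch.family,
                "gamma_shape": self.nuisance.gamma.shape,
                "gamma_k": self.nuisance.gamma.k,
            },
            "shifts": [
                {
                    "node": int(s),
                    "leafset": sorted(self.model.tree.leafset(s)),
                    "freqs": [float(x) for x in self.freqs[i + 1]],
                    "existence_weight": self.existence_weights.get(s),
                    "location_weights": {
                        str(k): v
                        for k, v in self.location_weights.get(s, {}).items()
                    },
                }
                for i, s in enumerate(self.shift_nodes)
            ],
            "root_freqs": [float(x) for x in self.freqs[0]],
            "lnl": self.lnl,
            "bic": self.bic,
            "root_bic": self.root_bic,
            "bic_trajectory": list(self.trajectory),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str, alignment: Alignment) -> "ShiftSearchResults":
        """Rebuild a results view from a serialized report.

        The report stores the tree, settings and estimates; the alignment
        must be supplied separately (reports do not embed sequence data).
        Search internals (candidate table, decision log) are not restored.
        """
        from .substitution import Exchangeabilities, GammaRates
        from .trees import read_newick

        doc = json.loads(text)
        tree = read_newick(doc["tree"])
        model = CompositionShiftModel(
            tree, alignment, min_clade=doc["min_clade"],
            family=doc["family"], gamma_categories=doc["gamma_categories"],
            stem_edge=doc.get("stem_edge", True),
        )
        nz = doc["nuisance"]
        nuisance = NuisanceFit(
            Exchangeabilities(
                nz["family"], kappa=nz["kappa"], rates=tuple(nz["gtr_rates"])
            ),
            GammaRates(nz["gamma_shape"], nz["gamma_k"]),
            np.asarray(doc["root_freqs"]), doc["lnl"], True,
        )
        shift_nodes = tuple(
            tree.node_by_leafset(s["leafset"]) for s in doc["shifts"]
        )
        freqs = np.vstack(
            [doc["root_freqs"]] + [s["freqs"] for s in doc["shifts"]]
        )
        existence = {
            node: s["existence_weight"]
            for node, s in zip(shift_nodes, doc["shifts"])
            if s.get("existence_weight") is not None
        }
        location = {
            node: {int(k): v for k, v in s["location_weights"].items()}
            for node, s in zip(shift_nodes, doc["shifts"])
            if s.get("location_weights")
        }
        return cls(
            model=model, nuisance=nuisance, shift_nodes=shift_nodes,
            freqs=freqs, lnl=doc["lnl"], bic=doc["bic"],
            root_bic=doc["root_bic"], trajectory=doc["bic_trajectory"],
            candidates=[], decisions=[], n_obs=doc["n_obs"],
            existence_weights=existence, location_weights=location,
        )

    def annotated_newick(self) -> str:
        """Newick with per-node regime ids as NHX comments."""
        tree = self.model.tree
        painting = self.painting
        out = RootedTree(
            tree.parent, tree.children, tree.branch_length, tree.labels,
            [f"&&NHX:regime={painting.regime_of(i)}" for i in range(tree.n_nodes)],
        )
        return out.to_newick()

    def to_tsv(self, path):
        self.summary_frame().to_csv(path, sep="\t", index=False)
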