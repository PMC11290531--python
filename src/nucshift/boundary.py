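"""Testing whether composition shifts cluster near a mass-extinction
boundary (default 66 Ma, the K-Pg horizon).

The trick that makes a regression on *internal* nodes possible: a
negligible-length terminal is grafted onto every internal node of the
chronogram, the shift indicator becomes a binary trait of those grafted
tips, and a phylogeny-aware logistic regression of shift presence on
log-absolute time distance to the boundary (optionally plus a gene-tree
discordance covariate) is fitted with the correlation among observations
derived from shared path lengths under a mean-reverting (OU-type)
transform, with the signal parameter estimated from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm

from .trees import RootedTree

__all__ = [
    "GraftedTree",
    "graft_internal_terminals",
    "proximity_predictor",
    "discordance",
    "node_covariates",
    "PhyloLogisticModel",
    "PhyloLogisticResults",
    "fit_phylo_logistic",
]

GRAFT_PREFIX = "graft_"


@dataclass
class GraftedTree:
    """A chronogram with one near-zero-length tip per internal node."""

    tree: RootedTree                 # the grafted tree
    original: RootedTree             # the input chronogram
    graft_label: dict                # original internal node -> tip label
    epsilon: float

    def graft_tip_index(self, original_node: int) -> int:
        label = self.graft_label[original_node]
        for i in self.tree.leaf_indices():
            if self.tree.labels[i] == label:
                return i
        raise KeyError(label)


def graft_internal_terminals(
    chronogram: RootedTree, epsilon: float = 1e-6
) -> GraftedTree:
    """Attach a length-``epsilon`` terminal to every internal node.

    The input should be ultrametric (a time tree); a non-ultrametric input
    is accepted with a warning.  Removing the grafted tips restores the
    original topology and node ages.
    """
    depths = chronogram.node_depths()
    leaf_depths = depths[chronogram.leaf_indices()]
    if leaf_depths.size and (leaf_depths.max() - leaf_depths.min()) > 1e-6 * max(
        leaf_depths.max(), 1.0
    ):
        warnings.warn("input chronogram is not ultrametric", stacklevel=2)
    dtree = chronogram._to_dendropy()
    # dendropy postorder over a tree we built node-by-node follows our index
    # order, so enumerate gives original node indices
    import dendropy

    labels = {}
    for idx, nd in enumerate(dtree.postorder_node_iter()):
        if nd.is_leaf():
            continue
        label = f"{GRAFT_PREFIX}{idx}"
        child = dendropy.Node()
        child.taxon = dtree.taxon_namespace.require_taxon(label=label)
        child.edge.length = epsilon
        nd.add_child(child)
        labels[idx] = label
    grafted = RootedTree._from_dendropy(dtree)
    return GraftedTree(grafted, chronogram, labels, epsilon)


def proximity_predictor(
    stem_age: float, boundary: float = 66.0, floor: float = 1e-3
) -> float:
    """log-absolute time distance to the boundary: ln(max(|age - b|, floor)).

    Ages in Ma; the floor guards nodes sitting exactly on the boundary.
    """
    if stem_age < 0:
        raise ValueError("stem age must be non-negative")
    return float(np.log(max(abs(stem_age - boundary), floor)))


# -- gene-tree discordance ---------------------------------------------------


def _collapsed_splits(tree: RootedTree, support_cut: float) -> list[tuple]:
    """Nontrivial bipartitions of a gene tree after collapsing nodes whose
    support label is below ``support_cut`` (unlabeled nodes are kept)."""
    taxa = frozenset(tree.leaf_labels)
    splits = []
    for v in tree.internal_indices(include_root=False):
        label = tree.labels[v]
        if label is not None:
            try:
                if float(label) < support_cut:
                    continue
            except ValueError:
                pass
        side = tree.leafset(v)
        if 2 <= len(side) <= len(taxa) - 2:
            splits.append((side, taxa - side))
    return splits


def _split_relation(gene_splits, side_a: frozenset, side_b: frozenset) -> str:
    """Relation of a reference bipartition (restricted sides) to a gene
    tree's splits: 'concordant', 'conflict', or 'undecided'."""
    conflict = False
    for x, xc in gene_splits:
        xa, xb = x & (side_a | side_b), xc & (side_a | side_b)
        # restrict the gene split to the shared taxa
        if not (
            side_a == xa or side_a == xb or side_b == xa or side_b == xb
        ):
            # compatibility: one of the four pairwise intersections empty
            if (
                side_a & xa and side_a & xb and side_b & xa and side_b & xb
            ):
                conflict = True
            continue
        return "concordant"
    return "conflict" if conflict else "undecided"


def discordance(
    gene_trees: list[RootedTree],
    reference: RootedTree,
    support_cut: float = 95.0,
) -> pd.DataFrame:
    """Per-node gene-tree discordance against a reference topology.

    For each non-root internal node of the reference, the proportion ``p``
    of gene trees whose collapsed topology conflicts with the node's
    bipartition (restricted to shared taxa), over gene trees decisive for
    that node; gene trees that neither contain nor conflict with the split
    (collapsed polytomies, insufficient taxon overlap) are non-decisive.
    Returns a frame with raw proportions, the arcsine-square-root transform,
    counts, and a total-gene-tree variant of the proportion.
    """
    ref_taxa = frozenset(reference.leaf_labels)
    gene_data = []
    for g in gene_trees:
        gtaxa = frozenset(g.leaf_labels)
        gene_data.append((gtaxa, _collapsed_splits(g, support_cut)))
    rows = []
    for v in reference.internal_indices(include_root=False):
        clade = reference.leafset(v)
        other = ref_taxa - clade
        n_conc = n_conf = 0
        for gtaxa, gsplits in gene_data:
            a = clade & gtaxa
            b = other & gtaxa
            if len(a) < 2 or len(b) < 2:
                continue
            rel = _split_relation(gsplits, a, b)
            if rel == "concordant":
                n_conc += 1
            elif rel == "conflict":
                n_conf += 1
        decisive = n_conc + n_conf
        p = n_conf / decisive if decisive else np.nan
        rows.append({
            "node": v,
            "n_decisive": decisive,
            "n_conflict": n_conf,
            "p_discordant": p,
            "discordance_asin_sqrt": (
                float(np.arcsin(np.sqrt(p))) if decisive else np.nan
            ),
            "p_discordant_total": n_conf / len(gene_trees) if gene_trees else np.nan,
        })
    return pd.DataFrame(rows).set_index("node")


# -- covariate assembly ------------------------------------------------------


def node_covariates(
    chronogram: RootedTree,
    shift_leafsets: list,
    boundary: float = 66.0,
    discordance_table: pd.DataFrame | None = None,
    use_crown_age: bool = False,
) -> pd.DataFrame:
    """Build the regression table for non-root internal nodes.

    ``shift_leafsets`` are canonical clades (from any number of data types);
    a node's response is 1 if any shift names its clade.  The time-distance
    predictor uses stem ages (the age of the parent split) by default.
    The root is excluded (it has no stem age), as are extant terminals.
    """
    depths = chronogram.node_depths()
    total = depths[chronogram.leaf_indices()].max()
    age = total - depths  # time before present
    shift_sets = {frozenset(s) for s in shift_leafsets}
    rows = []
    for v in chronogram.internal_indices(include_root=False):
        stem_age = float(age[chronogram.parent[v]])
        crown_age = float(age[v])
        used = crown_age if use_crown_age else stem_age
        row = {
            "node": v,
            "shift": int(chronogram.leafset(v) in shift_sets),
            "stem_age": stem_age,
            "crown_age": crown_age,
            "time_distance": proximity_predictor(used, boundary),
        }
        if discordance_table is not None and v in discordance_table.index:
            row["discordance"] = discordance_table.loc[
                v, "discordance_asin_sqrt"
            ]
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")


# -- phylogenetic logistic regression ---------------------------------------


class PhyloLogisticModel:
    """Logistic regression of a binary node trait with phylogenetic
    correlation among observations.

    Observations correspond to internal nodes (via their grafted tips); the
    working correlation is ``exp(-alpha * D)`` where ``D`` holds patristic
    distances between grafted tips and ``alpha`` (the mean-reversion /
    signal parameter, units 1/Ma) is profiled from the data.  As
    ``alpha -> inf`` the correlation vanishes and the estimator reduces to
    ordinary logistic maximum likelihood.
    """

    def __init__(self, y, X, distance: np.ndarray, names=None):
        self.y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.allclose(X[:, 0], 1.0):
            X = np.column_stack([np.ones(len(X)), X])
            if names is not None:
                names = ["intercept", *names]
        self.X = X
        self.names = names or ["intercept"] + [
            f"x{i}" for i in range(1, X.shape[1])
        ]
        self.D = np.asarray(distance, dtype=float)
        if self.D.shape != (len(self.y),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if self.y.min() == self.y.max():
            raise ValueError(
                "response is constant; need at least one 0 and one 1"
            )

    @classmethod
    def from_grafted(
        cls, grafted: GraftedTree, covariates: pd.DataFrame, columns=None
    ) -> "PhyloLogisticModel":
        """Assemble from a grafted chronogram and a node-covariate table."""
        cols = columns or [
            c for c in ("time_distance", "discordance") if c in covariates
        ]
        d = covariates.dropna(subset=cols)
        tips = [grafted.graft_tip_index(v) for v in d.index]
        D = _patristic(grafted.tree, tips)
        return cls(d["shift"].to_numpy(), d[cols].to_numpy(), D, names=cols)

    def fit(
        self,
        alpha: float | None = None,
        bootstrap: int = 0,
        seed: int | None = None,
        ridge: float = 1e-8,
        max_rounds: int = 6,
    ) -> "PhyloLogisticResults":
        dbar = np.mean(self.D[np.triu_indices_from(self.D, 1)])
        alpha_hi = 50.0 / max(dbar, 1e-12)  # effectively independent
        fixed_alpha = alpha
        a = alpha if alpha is not None else 1.0 / max(dbar, 1e-12)
        beta = np.zeros(self.X.shape[1])
        separated = False
        for _ in range(max_rounds):
            beta, separated, _ = self._gee_beta(a, beta, ridge)
            if fixed_alpha is not None:
                break
            a_new = self._profile_alpha(beta, alpha_hi)
            if abs(np.log(a_new) - np.log(a)) < 1e-4:
                a = a_new
                break
            a = a_new
        beta, separated, converged = self._gee_beta(
            a, beta, ridge if not separated else 1e-2
        )
        naive, _, _ = self._gee_beta(alpha_hi * 1e3, np.zeros_like(beta), ridge)
        boot = None
        if bootstrap:
            boot = self._parametric_bootstrap(beta, a, bootstrap, seed, ridge)
        return PhyloLogisticResults(
            model=self,
            params=beta,
            alpha=float(a),
            converged=converged,
            separation=separated,
            naive_params=naive,
            bootstrap_params=boot,
            names=list(self.names),
        )

    # -- internals --------------------------------------------------------

    #: nugget blended into the working correlation; keeps R invertible when
    #: grafted tips sit almost on top of each other.  Vanishes in the
    #: identity (no-signal) limit, so the ordinary-logistic reduction is
    #: exact.
    NUGGET = 0.01

    def _corr(self, alpha: float) -> np.ndarray:
        R = np.exp(-alpha * self.D)
        np.fill_diagonal(R, 1.0)
        nu = self.NUGGET
        R = (1 - nu) * R + nu * np.eye(len(R))
        return R

    def _gee_beta(self, alpha, beta0, ridge):
        """Fisher scoring on the GEE estimating equations; with identity
        working correlation this is exactly logistic ML.  Steps are halved
        until the score norm decreases (monotone safeguard)."""
        R = self._corr(alpha)
        Rinv = np.linalg.pinv(R)
        beta = beta0.copy()
        separated = False
        converged = False

        def score(b):
            mu = expit(np.clip(self.X @ b, -30, 30))
            s = np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
            U = self.X.T @ (s[:, None] * Rinv @ ((self.y - mu) / s))
            info = (self.X * s[:, None]).T @ Rinv @ (self.X * s[:, None])
            return U - ridge * b, info + ridge * np.eye(len(b))

        U, info = score(beta)
        for _ in range(100):
            try:
                step = np.linalg.solve(info, U)
            except np.linalg.LinAlgError:
                separated = True
                break
            if not np.isfinite(step).all():
                separated = True
                break
            nrm = np.linalg.norm(step)
            if nrm > 5:
                step *= 5 / nrm
                nrm = 5.0
            # step halving against the score norm
            u0 = np.linalg.norm(U)
            for half in range(12):
                trial = beta + step
                U_t, info_t = score(trial)
                if np.linalg.norm(U_t) < u0 or half == 11:
                    break
                step = step / 2
            beta, U, info = trial, U_t, info_t
            if np.abs(beta).max() > 30:
                separated = True
                break
            if np.linalg.norm(step) < 1e-9:
                converged = True
                break
        return beta, separated, converged

    def _profile_alpha(self, beta, alpha_hi):
        """Choose alpha maximizing the Gaussian quasi-likelihood of the
        Pearson residuals under correlation exp(-alpha D)."""
        eta = self.X @ beta
        mu = expit(np.clip(eta, -30, 30))
        s = np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
        r = (self.y - mu) / s

        def nll(log_a):
            R = self._corr(np.exp(log_a))
            sign, logdet = np.linalg.slogdet(R + 1e-10 * np.eye(len(R)))
            if sign <= 0:
                return 1e12
            q = r @ np.linalg.solve(R + 1e-10 * np.eye(len(R)), r)
            return 0.5 * (logdet + q)

        res = minimize_scalar(
            nll,
            bounds=(np.log(1e-4 / self.D.max()), np.log(alpha_hi)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        return float(np.exp(res.x))

    def _parametric_bootstrap(self, beta, alpha, n, seed, ridge):
        rng = np.random.default_rng(seed)
        R = self._corr(alpha)
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0, None))
        mu = expit(np.clip(self.X @ beta, -30, 30))
        thresh = norm.ppf(mu)
        out = np.empty((n, len(beta)))
        for b in range(n):
            z = L @ rng.standard_normal(len(mu))
            yb = (z < thresh).astype(float)
            if yb.min() == yb.max():  # degenerate draw: resample
                yb[rng.integers(len(yb))] = 1 - yb[0]
            mdl = PhyloLogisticModel(yb, self.X, self.D, names=self.names)
            bb, _, _ = mdl._gee_beta(alpha, beta.copy(), ridge)
            out[b] = bb
        return out


@dataclass
class PhyloLogisticResults:
    """Fitted phylogenetic logistic regression."""

    model: PhyloLogisticModel
    params: np.ndarray
    alpha: float
    converged: bool
    separation: bool
    naive_params: np.ndarray
    bootstrap_params: np.ndarray | None
    names: list

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        if self.bootstrap_params is None:
            raise ValueError("fit with bootstrap > 0 for intervals")
        lo = (1 - level) / 2 * 100
        return np.percentile(self.bootstrap_params, [lo, 100 - lo], axis=0).T

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] == len(self.params) - 1:
            X = np.column_stack([np.ones(len(X)), X])
        return expit(X @ self.params)

    def predictions_at_discordance(self, covariates: pd.DataFrame, grid=None):
        """Predicted shift probability vs. time distance at low / mean /
        high discordance (mean -/+ 1 s.d.)."""
        if "discordance" not in self.names:
            raise ValueError("model has no discordance covariate")
        d = covariates["discordance"].dropna()
        levels = {
            "low": d.mean() - d.std(),
            "mean": d.mean(),
            "high": d.mean() + d.std(),
        }
        td = covariates["time_distance"].dropna()
        grid = np.linspace(td.min(), td.max(), 25) if grid is None else grid
        out = {}
        for name, lvl in levels.items():
            X = np.column_stack([grid, np.full_like(grid, lvl)])
            out[name] = self.predict(X)
        return pd.DataFrame({"time_distance": grid, **out})

    def summary(self) -> str:
        lines = [
            "Phylogenetic logistic regression".center(60),
            "=" * 60,
            f"Observations: {len(self.model.y)}"
            f"    Positives: {int(self.model.y.sum())}",
            f"Signal parameter alpha: {self.alpha:.4g} (1/time)",
            f"Converged: {self.converged}    Separation: {self.separation}",
            "-" * 60,
        ]
        ci = None
        if self.bootstrap_params is not None:
            ci = self.conf_int()
        for i, nm in enumerate(self.names):
            row = f"{nm:>16}  {self.params[i]: .4f}"
            row += f"   (naive {self.naive_params[i]: .4f})"
            if ci is not None:
                row += f"   [{ci[i, 0]: .4f}, {ci[i, 1]: .4f}]"
            lines.append(row)
        lines.append("=" * 60)
        return "\n".join(lines)


def fit_phylo_logistic(
    grafted: GraftedTree,
    covariates: pd.DataFrame,
    bootstrap: int = 1000,
    seed: int | None = None,
    columns=None,
) -> PhyloLogisticResults:
    """Convenience wrapper: build the model from a grafted chronogram and
    covariate table and fit with a parametric bootstrap."""
    model = PhyloLogisticModel.from_grafted(grafted, covariates, columns=columns)
    return model.fit(bootstrap=bootstrap, seed=seed)


def _patristic(tree: RootedTree, tips: list[int]) -> np.ndarray:
    depths = tree.node_depths()
    n = len(tips)
    # ancestor chains
    anc = []
    for t in tips:
        chain = {t}
        v = t
        while tree.parent[v] >= 0:
            v = int(tree.parent[v])
            chain.add(v)
        anc.append(chain)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = anc[i] & anc[j]
            mrca_depth = max(depths[v] for v in common)
            D[i, j] = D[j, i] = depths[tips[i]] + depths[tips[j]] - 2 * mrca_depth
    return D
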