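"""Synthetic data with known compositional shifts.

This is the package's validation engine: it samples shift configurations on
a tree under nested/independent placement rules with clade-size and
path-distance ("buffer") constraints, draws regime compositions from a
Dirichlet, and evolves nonstationary HKY sequences down the tree.  A
pure-birth toy-tree generator (with an optional early-burst transform that
compresses basal internodes) removes any dependence on external tree files.

Defaults mirror the benchmark conditions used throughout the package's
acceptance suite: HKY with transition:transversion rate 2:1 (kappa = 2),
uniform Dirichlet compositions, uniform site rates, minimum clade size 4,
maximum clade size ~3/4 of the tips, and a buffer of two edges between
sampled shift nodes.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import asdict, dataclass
from dataclasses import replace as _dc_replace
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .substitution import Exchangeabilities, build_rate_matrix
from .trees import (
    RootedTree,
    RegimePainting,
    eligible_nodes,
    paint_regimes,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "sample_shift_nodes",
    "sample_compositions",
    "simulate_alignment",
    "simulate_dataset",
    "generate_toy_tree",
    "paper_scenario_grid",
]


@dataclass
class SimConfig:
    """Settings for one simulated dataset.

    ``scenario`` is ``"none"`` (no shifts), ``"independent"`` (disjoint
    lineages) or ``"nested"`` (shifts along one lineage).  ``max_clade``
    defaults to ~3/4 of the number of tips; ``buffer`` is the minimum
    node-path distance (edges) between sampled shift nodes.
    """

    scenario: str = "none"
    n_shifts: int = 0
    length: int = 10_000
    min_clade: int = 4
    max_clade: int | None = None
    buffer: int = 2
    kappa: float = 2.0
    #: when set, kappa is instead derived so the *realized* ts/tv ratio at
    #: the root composition equals this value
    tstv_ratio: float | None = None
    concentration: tuple = (1.0, 1.0, 1.0, 1.0)
    gamma_shape: float | None = None
    gamma_categories: int = 8
    seed: int | None = None
    max_restarts: int = 1000

    def __post_init__(self):
        if self.scenario not in ("none", "independent", "nested"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "none" and self.n_shifts:
            raise ValueError("scenario 'none' implies n_shifts = 0")
        if self.scenario != "none" and self.n_shifts < 1:
            raise ValueError("shift scenarios need n_shifts >= 1")
        if self.length < 0 or self.buffer < 0:
            raise ValueError("length and buffer must be non-negative")

    def resolved_max_clade(self, tree: RootedTree) -> int:
        if self.max_clade is not None:
            if self.max_clade < self.min_clade:
                raise ValueError("max_clade < min_clade")
            return self.max_clade
        return max(self.min_clade, int(round(tree.n_leaves * 0.75)))


@dataclass
class SimulatedDataset:
    """A simulated alignment plus its generating truth."""

    tree: RootedTree
    painting: RegimePainting
    freqs: np.ndarray           # (n_regimes, 4); row 0 = root composition
    alignment: Alignment
    config: SimConfig
    seed: int | None

    @property
    def shift_nodes(self) -> tuple:
        return self.painting.shift_nodes

    def shift_leafsets(self) -> list[frozenset]:
        return [self.tree.leafset(s) for s in self.shift_nodes]

    def annotated_newick(self) -> str:
        """Newick with per-regime HKY model annotations at regime roots
        (the mixture-annotation style used by tree-aware sequence
        simulators); the JSON sidecar is the authoritative truth format."""
        tree = self.tree
        comments = [None] * tree.n_nodes

        def model_str(r):
            f = "/".join(f"{x:.6f}" for x in self.freqs[r])
            return f"&model=HKY{{{self.config.kappa}}}+F{{{f}}}"

        comments[tree.root] = model_str(0)
        for k, s in enumerate(self.shift_nodes):
            comments[s] = model_str(k + 1)
        out = RootedTree(
            tree.parent, tree.children, tree.branch_length, tree.labels, comments
        )
        return out.to_newick()

    def sidecar(self) -> dict:
        return {
            "scenario": self.config.scenario,
            "seed": self.seed,
            "length": self.alignment.length,
            "kappa": self.config.kappa,
            "tree": self.tree.to_newick(),
            "shift_nodes": [int(s) for s in self.shift_nodes],
            "shift_leafsets": [sorted(s) for s in self.shift_leafsets()],
            "root_freqs": [float(x) for x in self.freqs[0]],
            "regime_freqs": [
                [float(x) for x in row] for row in self.freqs[1:]
            ],
            "config": asdict(self.config),
        }

    def write(self, outdir, prefix: str = "sim"):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.alignment.write(str(outdir / f"{prefix}.fasta"), "fasta")
        (outdir / f"{prefix}.nwk").write_text(self.tree.to_newick() + "\n")
        (outdir / f"{prefix}.annotated.nwk").write_text(
            self.annotated_newick() + "\n"
        )
        (outdir / f"{prefix}.truth.json").write_text(
            json.dumps(self.sidecar(), indent=2)
        )
        return {
            "fasta": str(outdir / f"{prefix}.fasta"),
            "tree": str(outdir / f"{prefix}.nwk"),
            "annotated": str(outdir / f"{prefix}.annotated.nwk"),
            "truth": str(outdir / f"{prefix}.truth.json"),
        }


def sample_shift_nodes(tree: RootedTree, cfg: SimConfig, rng=None) -> list[int]:
    """Sample shift nodes under the scenario's placement rules.

    Every selected node's clade size lies in ``[min_clade, max_clade]`` and
    all pairwise node-path distances are at least ``buffer``.  In nested
    mode, nodes after the first are drawn from the first node's lineage
    (ancestors and descendants); in independent mode a selected node's whole
    lineage is excluded from later draws.  Restarts with a fresh initial
    node on dead ends, raising after ``cfg.max_restarts`` failures.
    """
    if cfg.n_shifts == 0:
        return []
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sizes = tree.clade_sizes()
    max_clade = cfg.resolved_max_clade(tree)
    pool = [
        v for v in eligible_nodes(tree, cfg.min_clade)
        if sizes[v] <= max_clade
    ]
    if len(pool) < cfg.n_shifts:
        raise ValueError("not enough eligible nodes for requested shifts")

    for _ in range(cfg.max_restarts):
        chosen = [int(rng.choice(pool))]
        if cfg.scenario == "nested":
            lineage = set(tree.ancestors(chosen[0])) | set(
                tree.descendants(chosen[0])
            )
            avail = [v for v in pool if v in lineage]
        else:
            lineage = set(tree.ancestors(chosen[0])) | set(
                tree.descendants(chosen[0])
            ) | {chosen[0]}
            avail = [v for v in pool if v not in lineage]
        ok = True
        while len(chosen) < cfg.n_shifts:
            valid = [
                v for v in avail
                if all(tree.path_distance(v, c) >= cfg.buffer for c in chosen)
            ]
            if not valid:
                ok = False
                break
            nxt = int(rng.choice(valid))
            chosen.append(nxt)
            if cfg.scenario == "nested":
                avail = [v for v in avail if v != nxt]
            else:
                excl = set(tree.ancestors(nxt)) | set(tree.descendants(nxt)) | {nxt}
                avail = [v for v in avail if v not in excl]
        if ok:
            return chosen
    raise RuntimeError(
        f"could not satisfy shift-sampling constraints after "
        f"{cfg.max_restarts} restarts"
    )


def sample_compositions(n_regimes: int, concentration=(1, 1, 1, 1), rng=None):
    """I.i.d. Dirichlet draws of base frequencies, one per regime (row 0 is
    the root/ancestral composition)."""
    if n_regimes < 1:
        raise ValueError("need at least one regime")
    rng = np.random.default_rng() if rng is None else rng
    return rng.dirichlet(np.asarray(concentration, dtype=float), size=n_regimes)


def simulate_alignment(
    tree: RootedTree,
    painting: RegimePainting,
    freqs: np.ndarray,
    kappa: float = 2.0,
    length: int = 10_000,
    gamma_shape: float | None = None,
    gamma_categories: int = 8,
    rng=None,
) -> Alignment:
    """Evolve sequences down the tree under regime-painted HKY.

    Root states are i.i.d. draws from the root (regime 0) composition; each
    branch evolves under the frequencies of the child's regime (stem-edge
    convention, matching the search).  Sites are independent with uniform
    rates unless ``gamma_shape`` enables discrete-gamma rate multipliers.
    """
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.atleast_2d(freqs)
    exch = Exchangeabilities(family="HKY", kappa=kappa)
    n = tree.n_nodes
    if length == 0:
        return Alignment.from_dict({t: "" for t in tree.leaf_labels})
    if gamma_shape is None:
        site_cat = np.zeros(length, dtype=np.int64)
        cat_rates = np.ones(1)
    else:
        from .substitution import GammaRates

        cat_rates = GammaRates(gamma_shape, gamma_categories).category_rates()
        site_cat = rng.integers(0, gamma_categories, size=length)

    edge_regime = painting.edge_regimes()
    Qs = [build_rate_matrix(exch, freqs[r]) for r in range(freqs.shape[0])]
    states = np.empty((n, length), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=length, p=freqs[0])
    for v in tree.preorder():
        if v == tree.root:
            continue
        r = int(edge_regime[v])
        t = float(tree.branch_length[v])
        P = Qs[r].probs(cat_rates * t)  # (k, 4, 4)
        P = P / P.sum(axis=2, keepdims=True)
        parent_states = states[tree.parent[v]]
        cum = P.cumsum(axis=2)  # (k, 4, 4)
        u = rng.random(length)
        states[v] = np.minimum(
            (u[:, None] > cum[site_cat, parent_states]).sum(axis=1), 3
        )
    bases = np.array(list("ACGT"))
    seqs = {
        tree.labels[i]: "".join(bases[states[i]]) for i in tree.leaf_indices()
    }
    return Alignment.from_dict(seqs)


def simulate_dataset(
    tree: RootedTree, cfg: SimConfig, rng=None
) -> SimulatedDataset:
    """Sample shifts + compositions, then simulate the alignment."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    shifts = sample_shift_nodes(tree, cfg, rng=rng)
    freqs = sample_compositions(len(shifts) + 1, cfg.concentration, rng=rng)
    painting = paint_regimes(tree, shifts)
    kappa = cfg.kappa
    if cfg.tstv_ratio is not None:
        from .substitution import kappa_for_tstv

        kappa = kappa_for_tstv(cfg.tstv_ratio, freqs[0])
        cfg = _dc_replace(cfg, kappa=kappa)
    aln = simulate_alignment(
        tree, painting, freqs, kappa=kappa, length=cfg.length,
        gamma_shape=cfg.gamma_shape, gamma_categories=cfg.gamma_categories,
        rng=rng,
    )
    return SimulatedDataset(tree, painting, freqs, aln, cfg, cfg.seed)


def generate_toy_tree(
    n_tips: int, seed: int | None = None, burst: bool = False
) -> RootedTree:
    """Pure-birth (Yule) toy tree with ``n_tips`` extant leaves.

    Branch lengths are in expected substitutions/site with birth rate 1, so
    tree height grows like ln(n).  ``burst=True`` emulates a rapid early
    radiation by rescaling node depths so the oldest 20% of splits occupy
    the first 5% of total depth (many short basal internodes).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    import dendropy
    from dendropy.model import birthdeath

    taxa = dendropy.TaxonNamespace([f"t{i+1}" for i in range(n_tips)])
    dtree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=_random.Random(None if seed is None else seed),
    )
    tree = RootedTree._from_dendropy(dtree)
    if burst:
        tree = _early_burst_transform(tree)
    # guard against zero-length edges from the generator
    bl = tree.branch_length
    depth = np.nanmax(tree.node_depths())
    bl[~np.isnan(bl)] = np.maximum(bl[~np.isnan(bl)], 1e-6 * depth)
    return tree


def _early_burst_transform(tree: RootedTree) -> RootedTree:
    """Monotone depth transform: oldest 20% of splits -> first 5% of depth."""
    depths = tree.node_depths()
    internal = [i for i in tree.internal_indices() if i != tree.root]
    total = depths[tree.leaf_indices()].max()
    split_depths = np.sort(depths[internal])
    q = split_depths[max(0, int(np.ceil(0.2 * len(split_depths))) - 1)]
    if q <= 0 or q >= total:
        return tree

    def warp(d):
        if d <= q:
            return d * (0.05 * total / q)
        return 0.05 * total + (d - q) * (0.95 * total / (total - q))

    new_depths = np.array([warp(d) for d in depths])
    bl = tree.branch_length.copy()
    for i in range(tree.n_nodes):
        if i != tree.root:
            bl[i] = new_depths[i] - new_depths[tree.parent[i]]
    return RootedTree(tree.parent, tree.children, bl, tree.labels, tree.comments)


def paper_scenario_grid(
    lengths_independent=(2000, 10_000, 50_000),
    lengths_nested=(2000, 10_000, 100_000),
    replicates: int = 100,
) -> list[dict]:
    """The benchmark scenario grid: no shifts, 1-4 independent shifts
    (alignments 2-50 kbp) and 2 nested shifts (2-100 kbp), 100 replicates
    per cell.  Returns cell descriptors (scenario, n_shifts, length, n_reps);
    all values overridable."""
    cells = []
    for length in lengths_independent:
        cells.append({"scenario": "none", "n_shifts": 0, "length": length,
                      "replicates": replicates})
    for k in (1, 2, 3, 4):
        for length in lengths_independent:
            cells.append({"scenario": "independent", "n_shifts": k,
                          "length": length, "replicates": replicates})
    for length in lengths_nested:
        cells.append({"scenario": "nested", "n_shifts": 2, "length": length,
                      "replicates": replicates})
    return cells
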