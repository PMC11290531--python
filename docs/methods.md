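# Methods

## The model

`nucshift` detects *macroevolutionary shifts in equilibrium base
composition* on a fixed, rooted phylogram. The substitution process is a
reversible nucleotide model (HKY by default, GTR optionally) in which one
symmetric exchangeability matrix is shared across the whole tree while the
equilibrium frequency vector π = (π_A, π_C, π_G, π_T) is allowed to differ
among *regimes* — contiguous sets of branches. A regime is founded by a
*shift* on an edge: under the stem-edge convention (default, configurable)
a shift at node *s* governs the branch subtending *s* and everything below
it, until overridden by a nested shift. Regime 0 is the ancestral process;
its frequencies also weight the root state distribution.

Each regime's rate matrix is built as Q_ij = s_ij π_j and normalized to one
expected substitution per unit branch length *under its own frequencies*,
so input branch lengths keep their substitutions/site meaning in every
regime. Branch lengths are taken from the input phylogram and never
re-optimized (and therefore never counted as free parameters). Among-site
rate variation uses a discrete-gamma mixture with equal category weights
and mean-per-category discretization (each category's rate is the
conditional mean of the gamma within its probability bin, renormalized to
mean 1); `k = 1` disables it exactly.

The likelihood is computed by Felsenstein pruning on compressed unique site
patterns, with per-pattern rescaling for underflow protection. Gaps, `N`/`?`
and IUPAC ambiguity codes contribute partial-likelihood rows with ones for
every compatible state (partially missing data).

## The stepwise search

1. **Global nuisance.** Under the homogeneous single-regime model, the root
   composition, exchangeabilities (κ for HKY, five free rates for GTR) and
   the gamma shape are estimated jointly by maximum likelihood.
2. **Candidate scoring.** Every non-root internal node whose clade holds at
   least `min_clade` leaves (default 4) is scored as a two-regime model:
   the subtree composition is fitted by ML while the remainder of the tree
   keeps the step-1 root composition. Candidates are ranked by BIC
   (`k·ln(n) − 2·lnL`, `n` = alignment sites by default; a flag switches to
   unique patterns), ties broken by postorder index.
3. **Greedy acceptance.** Starting from the root-only configuration,
   candidates are revisited in BIC order. Each is tentatively added, the
   model is re-scored, and the shift is kept only if the configuration BIC
   strictly decreases. The parameter count is 3 per regime (frequencies)
   plus the shared nuisance parameters.
4. **Support.** For every accepted shift the package reports an *existence*
   BIC weight (final configuration vs. the re-optimized configuration with
   that shift removed) and *location* BIC weights over the focal node and
   its internal daughters (leaf daughters cannot host a two-regime
   submodel and are excluded, with weights renormalized — a shift whose
   daughters are both leaves gets focal weight 1). Weights are reported,
   never used to delete shifts automatically; an optional
   `prune_below` post-filter re-fits the configuration without weakly
   supported shifts.

### Tentative re-scoring policy

How much to re-optimize when a candidate is tentatively added is genuinely
open. The package exposes three policies:

- `rescoring="new_regime"` (default): only the new regime's composition is
  optimized against the current configuration; the accepted configuration
  is then *polished* by joint coordinate ascent over all regimes. The
  tentative score is a lower bound on the jointly optimized likelihood, so
  acceptance decisions err on the conservative side — in line with the
  method's intended low false-positive character — at a fraction of the
  cost.
- `rescoring="joint"`: every regime is re-optimized for every tentative
  candidate (coordinate ascent, ≤ 5 sweeps, 1e-6 lnL sweep tolerance).
- `frozen=True`: the literal stepwise reading — per-candidate subtree
  estimates are reused unchanged and only the BIC is recomputed.

Before the first acceptance the `new_regime` tentative model conditions on
exactly what candidate scoring conditioned on, so those scores are reused
rather than recomputed.

### Updating the nuisance as shifts accumulate

By default (`update_nuisance=True`) the shared exchangeabilities and gamma
shape are re-estimated after every accepted shift, and the regime
compositions are then re-polished. The alternative — estimating κ once
under the homogeneous model and freezing it — is available
(`update_nuisance=False`, optionally with `refit_nuisance=True` for one
final re-estimate) but is not the default for a measured reason: when a
real composition shift is present, the homogeneous-model κ estimate is
biased (on a 64-tip, 10 kbp single-shift simulation with true κ = 2 the
homogeneous fit gave κ̂ = 2.84, costing ~1.4 × 10³ lnL units at the true
configuration), and a frozen, biased κ lets the greedy step "explain" the
misfit by accepting many spurious regimes. Under the null the two settings
behave identically, because nothing is ever accepted.

## Numerical choices

- Compositions are optimized on softmax-transformed logits (3 free
  parameters per regime, bounded to ±12) with L-BFGS-B, finite-difference
  step 1e-6, `ftol` 1e-12 (relative) for definitive fits and 1e-10 with a
  capped evaluation budget inside candidate scoring and tentative adds;
  the deterministic default start is the empirical composition of the
  relevant taxa (with a 0.5 pseudocount per base). Optional seeded
  multi-starts (`n_starts`) guard against rare local optima.
- Transition probabilities come from the symmetric eigendecomposition of
  D^{1/2} Q D^{-1/2}; eigenvalues are clamped to ≤ 0 and the reconstructed
  matrix is clipped to [0, 1] and row-renormalized, so extreme frequency
  proposals during optimization cannot produce invalid probabilities.
- When a derived regime's composition is optimized, only its founding
  subtree is recomputed; the rest of the tree enters through cached
  "outside" partial likelihoods. A numba-compiled fused pruning kernel
  (with a pure-numpy fallback) does the per-node work; incremental and
  cold evaluations agree to rounding (~1e-7 on |lnL| ≈ 10⁴).
- Degenerate inputs: an all-one-base partition drives its π toward the
  simplex boundary without numerical failure (bounded logits); an empty
  candidate list returns the root-only configuration; a site pattern with
  zero likelihood raises a flagged error naming the pattern.

## The synthetic-data generator

The generator emulates the benchmark conditions used to validate the
search: a pure-birth (Yule, rate 1) tree — optionally with an early-burst
transform that maps the oldest 20% of splits into the first 5% of total
depth, imitating a rapid post-extinction radiation — regime compositions
drawn i.i.d. from a uniform Dirichlet (concentration 1,1,1,1, including the
root state), HKY evolution with the transition:transversion rate parameter
κ = 2 (the "2:1" convention of the rate parameterization; a flag can
instead target a realized ts/tv ratio), uniform site rates by default, and
alignment lengths of 2–100 kbp. Shift placements follow three scenarios:
*none*; *independent* (after each draw the node's ancestors and descendants
are excluded); and *nested* (subsequent draws come from the first node's
lineage). All draws respect a minimum clade size (4), a maximum clade size
(~3/4 of the tips), and a minimum pairwise node-path distance ("buffer",
2 edges), restarting from a fresh initial node on dead ends (bounded at
1000 restarts). The preset grid mirrors the benchmark design: 0 shifts and
1–4 independent shifts at 2–50 kbp, 2 nested shifts at 2–100 kbp, 100
replicates per cell.

What the generator does *not* emulate: indels and alignment error,
recombination and within-locus tree heterogeneity, selection and codon
structure, heterotachy beyond regime frequency shifts, and branch-length
estimation error. Passing benchmarks therefore demonstrate statistical
behavior under the model's own assumptions, not robustness to real-data
artifacts.

## Benchmark definitions

A detected shift matches a simulated one when it names exactly the same
clade (canonical identity = the set of descendant leaf labels); an optional
path-distance tolerance allows near-miss matching, greedily one-to-one and
closest-first. Per dataset, the false-negative rate is |missed| / |true
shifts| (0 when nothing was simulated) and the false-positive rate is
|spurious| / (eligible nodes − |true shifts|); because that normalization
is a choice, the per-replicate binary "any spurious shift" proportion is
always reported alongside. Rates are aggregated as mean ± s.d. across
replicates and tested with one-sided one-sample t and Z statistics against
mean > 0 (all-zero sample ⇒ p = 1 by convention; zero-variance positive
sample ⇒ p → 0, flagged), with Benjamini–Hochberg adjustment across the
family of tests.

Benchmark problem sizes used by the acceptance suite, chosen as desk-scale
versions of the validation design: null calibration on 100 replicates of
10 kbp alignments on 64-tip trees; the false-negative check on 30
replicates of 1 kbp alignments on 250-tip trees with two independent
shifts; composition recovery on one 50 kbp two-shift dataset.

## Boundary-proximity analysis

To ask whether shifts cluster near a mass-extinction horizon (66 Ma by
default), a negligible-length terminal (ε = 1e-6 Ma, configurable) is
grafted onto every internal node of a time-calibrated chronogram, turning
node properties into tip traits. The response is 1 if any data type placed
a shift on the node's clade. The predictor is ln |stem age − 66| (floored
at 1e-3 Ma); stem ages are the default (crown ages by flag — the choice
has little impact since parent and child ages differ by one internode).
The root is excluded (it has no stem age), as are extant terminals.

An optional covariate is per-node gene-tree discordance: the proportion of
gene trees whose topology — after collapsing nodes below 95% support —
contains a bipartition incompatible with the node's bipartition restricted
to shared taxa, among gene trees decisive for that node (a collapsed
polytomy is neither concordant nor conflicting and counts as non-decisive;
a total-gene-trees variant is also emitted), transformed as asin(√p).

The regression itself is a logistic model with phylogenetically correlated
observations: working correlation exp(−α·d_ij) over patristic distances
between grafted tips, with the mean-reversion/signal parameter α profiled
by Gaussian quasi-likelihood of the Pearson residuals, and coefficients
solved by GEE-type Fisher scoring with a monotone (score-norm) safeguard.
A 1% nugget keeps the working correlation invertible when grafted tips sit
almost on top of each other; it vanishes in the no-signal limit, so with
independent observations the estimator reduces *exactly* to ordinary
logistic maximum likelihood (verified to 1e-4 against an independent GLM
fit). Ridge penalization is escalated and flagged when separation is
detected. Uncertainty comes from a parametric bootstrap (default 1000
refits on data simulated from the fitted model via a thresholded latent
Gaussian with correlation exp(−α̂ D)). Predictions are reported at low /
mean / high discordance (mean ∓ 1 s.d.).

## Known limitations

- The search explores single-node moves only; configurations reachable
  only by simultaneous multi-shift proposals can be missed.
- Rate-matrix (exchangeability) shifts are out of scope by design; only
  the shared exchangeabilities adapt, not per-regime ones.
- The FP/FN normalizations are stated conventions, not the only possible
  ones; both per-node and per-replicate variants are emitted.
- The boundary regression's working-correlation estimator is a
  quasi-likelihood approximation, not the exact likelihood of a
  phylogenetic threshold model; its contract is the identity-limit
  reduction and simulation-calibrated sign recovery, not coefficient-level
  equality with any particular mixed-model implementation.
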