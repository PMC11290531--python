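"""Reversible nucleotide substitution models (HKY / GTR) with regime-specific
equilibrium frequencies and discrete-gamma rate variation across sites.

The instantaneous rate matrix uses the standard reversible construction
``Q_ij = s_ij * pi_j`` (i != j) where ``s`` is the symmetric exchangeability
matrix; each regime's Q is normalized to one expected substitution per unit
branch length under its own frequencies, so input branch lengths keep their
substitutions/site interpretation in every regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaincinv

__all__ = [
    "validate_frequencies",
    "Exchangeabilities",
    "GammaRates",
    "RateMatrix",
    "build_rate_matrix",
    "transition_probs",
    "equilibrium_gc",
]

#: index order of nucleotide states everywhere in the package
STATES = "ACGT"


def validate_frequencies(pi, tol: float = 1e-12) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,):
        raise ValueError("base frequencies must have 4 entries (A, C, G, T)")
    if (pi <= 0).any():
        raise ValueError("base frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"base frequencies sum to {pi.sum()}, not 1")
    return pi / pi.sum()


@dataclass(frozen=True)
class Exchangeabilities:
    """Symmetric exchangeability rates shared across regimes.

    ``family`` is ``"HKY"`` (one transition:transversion rate ``kappa``) or
    ``"GTR"`` (six symmetric rates, G<->T conventionally fixed to 1).
    GTR rate order: AC, AG, AT, CG, CT, GT.
    """

    family: str = "HKY"
    kappa: float = 2.0
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.family not in ("HKY", "GTR"):
            raise ValueError("family must be HKY or GTR")
        if self.family == "HKY" and not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.family == "GTR" and any(r <= 0 for r in self.rates):
            raise ValueError("GTR rates must be positive")

    def matrix(self) -> np.ndarray:
        """Symmetric 4x4 matrix of s_ij (diagonal zero)."""
        s = np.zeros((4, 4))
        if self.family == "HKY":
            s[:] = 1.0
            s[0, 2] = s[2, 0] = self.kappa  # A<->G
            s[1, 3] = s[3, 1] = self.kappa  # C<->T
        else:
            ac, ag, at, cg, ct, gt = self.rates
            s[0, 1] = s[1, 0] = ac
            s[0, 2] = s[2, 0] = ag
            s[0, 3] = s[3, 0] = at
            s[1, 2] = s[2, 1] = cg
            s[1, 3] = s[3, 1] = ct
            s[2, 3] = s[3, 2] = gt
        np.fill_diagonal(s, 0.0)
        return s

    @property
    def n_free_parameters(self) -> int:
        return 1 if self.family == "HKY" else 5


@dataclass(frozen=True)
class GammaRates:
    """Discrete-gamma rate heterogeneity across sites.

    ``k`` equal-probability categories, each represented by its conditional
    mean rate (mean-per-category discretization); the category rates average
    to exactly 1.  ``k = 1`` means uniform rates and contributes no free
    parameter.
    """

    shape: float = 1.0
    k: int = 1

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("number of rate categories must be >= 1")
        if self.k > 1 and not self.shape > 0:
            raise ValueError("gamma shape must be positive")

    def category_rates(self) -> np.ndarray:
        if self.k == 1:
            return np.ones(1)
        a = self.shape
        # category boundaries at quantiles i/k of Gamma(a, scale=1/a)
        edges = gammaincinv(a, np.arange(1, self.k) / self.k) / a
        edges = np.concatenate([[0.0], edges, [np.inf]])
        # conditional mean of Gamma(a, 1/a) on each bin:
        #   k * [ P(a+1, a*upper) - P(a+1, a*lower) ]   (regularized gamma P)
        upper = gammainc(a + 1, a * edges[1:])
        lower = gammainc(a + 1, a * edges[:-1])
        rates = self.k * (upper - lower)
        return rates / rates.mean()

    @property
    def n_free_parameters(self) -> int:
        return 0 if self.k == 1 else 1


class RateMatrix:
    """A normalized reversible rate matrix with its stationary frequencies.

    Caches the symmetric eigendecomposition so that transition probabilities
    for many branch lengths are cheap:  P(t) = U exp(L t) U^{-1}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.pi = validate_frequencies(pi)
        sqrt_pi = np.sqrt(self.pi)
        # similarity transform S = D^{1/2} Q D^{-1/2} (D = diag(pi)) is
        # symmetric for a reversible Q; eigh is stable and fast
        S = self.Q * sqrt_pi[:, None] / sqrt_pi[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        # eigenvalues of a generator are <= 0; clamp numerical noise so the
        # exponential cannot blow up on long branches
        self._eigval = np.minimum(w, 0.0)
        self._left = V / sqrt_pi[:, None]       # rows scaled: diag(1/sqrt pi) V
        self._right = (V * sqrt_pi[:, None]).T  # V^T diag(sqrt pi)

    def probs(self, t) -> np.ndarray:
        """Transition probabilities for branch length(s) ``t``.

        Scalar ``t`` gives a (4, 4) stochastic matrix; an array of lengths
        gives (len(t), 4, 4).
        """
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("negative branch length")
        ew = np.exp(np.multiply.outer(t, self._eigval))  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self._left, ew, self._right)
        # guard reconstruction noise: a transition matrix is stochastic
        P = np.clip(P, 0.0, 1.0)
        return P / np.maximum(P.sum(axis=-1, keepdims=True), 1e-12)


def build_rate_matrix(
    exch: Exchangeabilities, pi, normalize: bool = True
) -> RateMatrix:
    """Assemble Q from exchangeabilities and equilibrium frequencies.

    When ``normalize`` the matrix is rescaled so the expected substitution
    rate at stationarity, ``-sum_i pi_i Q_ii``, equals 1.
    """
    pi = validate_frequencies(pi)
    s = exch.matrix()
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        Q = Q / mu
    return RateMatrix(Q, pi)


def transition_probs(
    Q: RateMatrix, t: float, gamma: GammaRates | None = None
) -> np.ndarray:
    """Per-category transition matrices: (k, 4, 4), one per gamma category."""
    if t < 0:
        raise ValueError("negative branch length")
    rates = (gamma or GammaRates()).category_rates()
    return Q.probs(rates * t)


def kappa_for_tstv(ratio: float, pi) -> float:
    """HKY rate parameter kappa giving a realized transition:transversion
    *ratio* at stationarity under frequencies ``pi``.

    The realized ratio is kappa * (pi_A pi_G + pi_C pi_T) / (sum of
    transversion frequency products); "2:1" as a rate parameter and as a
    realized ratio are different conventions.
    """
    pi = validate_frequencies(pi)
    a, c, g, t = pi
    transitions = a * g + c * t
    transversions = a * c + a * t + c * g + g * t
    if transitions <= 0:
        raise ValueError("degenerate frequencies: no transition pairs")
    return float(ratio * transversions / transitions)


def equilibrium_gc(pi) -> float:
    """GC content implied by equilibrium frequencies: pi_G + pi_C."""
    pi = validate_frequencies(pi)
    return float(pi[1] + pi[2])
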