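"""Regime-level descriptive summaries: empirical vs. fitted equilibrium
frequencies, GC content, and the GC vs. body-mass regression.

The deviation between a regime's fitted equilibrium composition and the
empirical composition of its taxa is reported primarily as total-variation
distance (bounded on [0, 1]); Euclidean distance and per-base deltas are
always emitted alongside.  The GC-mass regression is the package's check of
the GC-biased gene-conversion expectation: clades with larger bodies (hence
smaller effective population sizes) should show lower equilibrium GC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alignment import Alignment, empirical_frequencies
from .substitution import equilibrium_gc, validate_frequencies

__all__ = [
    "frequency_deviation",
    "regime_summaries",
    "gc_mass_regression",
]


def frequency_deviation(pi_eq, pi_emp, metric: str = "tv"):
    """Magnitude of the shift between two composition vectors.

    ``tv``   total variation, 0.5 * sum |a - b|  (default; bounded [0, 1])
    ``l2``   Euclidean distance
    ``delta`` signed per-base differences (eq - emp), a length-4 array
    """
    a = validate_frequencies(pi_eq)
    b = validate_frequencies(pi_emp)
    if metric == "tv":
        return float(0.5 * np.abs(a - b).sum())
    if metric == "l2":
        return float(np.linalg.norm(a - b))
    if metric == "delta":
        return a - b
    raise ValueError(f"unknown metric {metric!r}")


def regime_summaries(
    results,
    masses: dict | None = None,
) -> pd.DataFrame:
    """Per-regime table of empirical vs. equilibrium composition and GC.

    Parameters
    ----------
    results : ShiftSearchResults
        A fitted shift search.
    masses : dict, optional
        Taxon -> body mass (g); regime mass is the mean of log10 masses over
        the regime's terminal taxa.
    """
    aln = results.model.alignment
    taxa_by_regime = results.regime_taxa()
    rows = []
    for r in range(results.n_regimes):
        taxa = taxa_by_regime[r]
        if not taxa:
            continue
        emp = empirical_frequencies(aln, taxa, pseudo=0.5)
        eq = results.freqs[r]
        row = {
            "regime": r,
            "n_taxa": len(taxa),
            "emp_A": emp[0], "emp_C": emp[1], "emp_G": emp[2], "emp_T": emp[3],
            "eq_A": eq[0], "eq_C": eq[1], "eq_G": eq[2], "eq_T": eq[3],
            "deviation_tv": frequency_deviation(eq, emp, "tv"),
            "deviation_l2": frequency_deviation(eq, emp, "l2"),
            "delta_A": eq[0] - emp[0], "delta_C": eq[1] - emp[1],
            "delta_G": eq[2] - emp[2], "delta_T": eq[3] - emp[3],
            "empirical_GC": float(emp[1] + emp[2]),
            "equilibrium_GC": equilibrium_gc(eq),
        }
        if masses:
            logm = [
                np.log10(masses[t]) for t in taxa if t in masses
            ]
            row["mean_log10_mass_g"] = float(np.mean(logm)) if logm else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def gc_mass_regression(summaries: pd.DataFrame, response: str = "equilibrium_GC"):
    """OLS of regime GC content on regime mean log10 body mass.

    Needs at least 3 regimes with mass data.  Returns a dict with slope,
    intercept, R^2, p-value of the slope, and the fitted statsmodels
    results object.
    """
    if "mean_log10_mass_g" not in summaries:
        raise ValueError("summaries lack mass data")
    d = summaries.dropna(subset=["mean_log10_mass_g", response])
    if len(d) < 3:
        raise ValueError("need at least 3 regimes with mass data")
    X = sm.add_constant(d["mean_log10_mass_g"].to_numpy())
    fit = sm.OLS(d[response].to_numpy(), X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "slope_p": float(fit.pvalues[1]),
        "n": int(len(d)),
        "fit": fit,
    }
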