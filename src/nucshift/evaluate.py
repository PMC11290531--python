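"""Scoring detection output against simulation truth, and the benchmark's
one-sample t/Z tests with false-discovery-rate control.

Shift nodes are matched by canonical identity (the leaf set of the clade);
an optional path-distance tolerance allows near-miss matching.  False
negatives are counted against the number of simulated shifts; false
positives against the number of eligible non-truth nodes (a per-node rate),
with a per-replicate binary variant ("any spurious shift") also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trees import RootedTree

__all__ = [
    "DetectionOutcome",
    "match_shifts",
    "fp_fn_rates",
    "TestResult",
    "test_rates",
    "bh_adjust",
]


@dataclass
class DetectionOutcome:
    """Per-dataset confusion sets for detected vs. true shift nodes."""

    true_nodes: frozenset
    detected_nodes: frozenset
    tp: frozenset
    fp: frozenset
    fn: frozenset
    tolerance: int = 0

    @property
    def n_tp(self):
        return len(self.tp)

    @property
    def n_fp(self):
        return len(self.fp)

    @property
    def n_fn(self):
        return len(self.fn)


def match_shifts(
    tree: RootedTree, truth, detected, tolerance: int = 0
) -> DetectionOutcome:
    """Match detected shift nodes to true ones on a common tree.

    With ``tolerance=0`` a detection counts as a true positive only if it
    names exactly the true clade.  With tolerance ``d``, detected nodes are
    greedily matched one-to-one to the nearest unmatched truth node within
    ``d`` edges (closest pairs first, ties broken by postorder index).
    """
    truth = [int(t) for t in truth]
    detected = [int(x) for x in detected]
    for v in truth + detected:
        if not 0 <= v < tree.n_nodes:
            raise ValueError(f"node {v} not on tree")
    if tolerance == 0:
        tset, dset = set(truth), set(detected)
        tp = tset & dset
        return DetectionOutcome(
            frozenset(truth), frozenset(detected),
            frozenset(tp), frozenset(dset - tp), frozenset(tset - tp), 0,
        )
    pairs = sorted(
        (tree.path_distance(d, t), d, t)
        for d in detected for t in truth
    )
    matched_d, matched_t = set(), set()
    for dist, d, t in pairs:
        if dist > tolerance:
            break
        if d in matched_d or t in matched_t:
            continue
        matched_d.add(d)
        matched_t.add(t)
    return DetectionOutcome(
        frozenset(truth), frozenset(detected),
        frozenset(matched_d), frozenset(set(detected) - matched_d),
        frozenset(set(truth) - matched_t), tolerance,
    )


def fp_fn_rates(outcomes, eligible_count: int) -> dict:
    """Aggregate per-dataset FP/FN rates into a benchmark-table row.

    Per dataset the FN rate is ``|FN| / |truth|`` (0 when no shift was
    simulated) and the FP rate is ``|FP| / (eligible - |truth|)``; the row
    carries the mean and s.d. across replicates plus the per-replicate
    binary spurious-shift proportion.
    """
    if not outcomes:
        raise ValueError("need at least one outcome")
    fn_rates, fp_rates, any_fp = [], [], []
    for o in outcomes:
        n_truth = len(o.true_nodes)
        if eligible_count <= n_truth:
            raise ValueError("eligible_count must exceed number of true shifts")
        fn_rates.append(o.n_fn / n_truth if n_truth else 0.0)
        fp_rates.append(o.n_fp / (eligible_count - n_truth))
        any_fp.append(1.0 if o.n_fp else 0.0)
    fn = np.array(fn_rates)
    fp = np.array(fp_rates)
    return {
        "n_replicates": len(outcomes),
        "fn_mean": float(fn.mean()),
        "fn_sd": float(fn.std(ddof=1)) if len(fn) > 1 else 0.0,
        "fp_mean": float(fp.mean()),
        "fp_sd": float(fp.std(ddof=1)) if len(fp) > 1 else 0.0,
        "fp_any_mean": float(np.mean(any_fp)),
        "fn_rates": fn,
        "fp_rates": fp,
    }


@dataclass
class TestResult:
    """A one-sided, one-sample location test of mean rate > 0."""

    kind: str                # "t" or "Z"
    statistic: float
    p: float
    p_adjusted: float | None = None
    flag: str | None = None


def test_rates(rates) -> tuple[TestResult, TestResult]:
    """One-sided one-sample t and Z tests of the null that the mean rate is
    not greater than zero.

    Conventions for degenerate samples: an all-zero sample gives p = 1 for
    both tests; a constant positive sample has zero s.d., giving p -> 0
    (flagged).
    """
    x = np.asarray(rates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicates")
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    if np.all(x == 0):
        return (
            TestResult("t", 0.0, 1.0, flag="all-zero"),
            TestResult("Z", 0.0, 1.0, flag="all-zero"),
        )
    if sd == 0:
        return (
            TestResult("t", np.inf, 0.0, flag="zero-variance"),
            TestResult("Z", np.inf, 0.0, flag="zero-variance"),
        )
    stat = mean / (sd / np.sqrt(n))
    pt = float(stats.t.sf(stat, df=n - 1))
    pz = float(stats.norm.sf(stat))
    return TestResult("t", float(stat), pt), TestResult("Z", float(stat), pz)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment across a family of tests."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def adjust_test_family(results: list[TestResult]) -> list[TestResult]:
    """Apply BH adjustment in place across a family of TestResults."""
    padj = bh_adjust([r.p for r in results])
    for r, a in zip(results, padj):
        r.p_adjusted = float(a)
    return results


def rate_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble benchmark rows (scenario/length cells) into a tidy table."""
    recs = []
    for row in rows:
        rec = {k: v for k, v in row.items() if not isinstance(v, np.ndarray)}
        recs.append(rec)
    return pd.DataFrame(recs)
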