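"""End-to-end benchmark: simulate -> detect -> score, over a scenario grid.

Mirrors the validation design used for the detection method: per cell
(scenario x alignment length) a number of replicate datasets are simulated
on pure-birth trees, the stepwise search is run with among-site rate
variation and the post-hoc support steps disabled (as in the large-scale
simulation study), and false-positive / false-negative rates are aggregated
with one-sample t and Z tests under FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import (
    adjust_test_family,
    fp_fn_rates,
    match_shifts,
    test_rates,
)
from .model import CompositionShiftModel
from .simulate import SimConfig, generate_toy_tree, simulate_dataset
from .trees import RootedTree, eligible_nodes

__all__ = ["run_cell", "run_benchmark", "detect_on_dataset"]


def detect_on_dataset(dataset, min_clade=4, **fit_kwargs):
    """Run the shift search on a simulated dataset with the benchmark's
    detection settings (HKY, uniform rates, no support weights)."""
    model = CompositionShiftModel(
        dataset.tree, dataset.alignment, min_clade=min_clade,
        family="HKY", gamma_categories=1,
    )
    return model.fit(existence=False, location=False, **fit_kwargs)


def run_cell(
    scenario: str,
    n_shifts: int,
    length: int,
    replicates: int,
    n_tips: int = 64,
    min_clade: int = 4,
    buffer: int = 2,
    burst: bool = False,
    tolerance: int = 0,
    seed: int | None = None,
    threads: int = 1,
    keep_outcomes: bool = False,
) -> dict:
    """Simulate/detect/score one grid cell; returns a rate-table row."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]

    def one(rep_seed):
        rng = np.random.default_rng(rep_seed)
        tree = generate_toy_tree(n_tips, seed=rep_seed, burst=burst)
        cfg = SimConfig(
            scenario=scenario, n_shifts=n_shifts, length=length,
            min_clade=min_clade, buffer=buffer, seed=rep_seed,
        )
        ds = simulate_dataset(tree, cfg, rng=rng)
        res = detect_on_dataset(ds, min_clade=min_clade)
        outcome = match_shifts(
            tree, ds.shift_nodes, res.shift_nodes, tolerance=tolerance
        )
        return outcome, len(eligible_nodes(tree, min_clade))

    if threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=threads)(
            delayed(one)(s) for s in child_seeds
        )
    else:
        results = [one(s) for s in child_seeds]
    outcomes = [r[0] for r in results]
    eligible_mean = int(round(np.mean([r[1] for r in results])))
    row = fp_fn_rates(outcomes, eligible_mean)
    row.update({
        "scenario": scenario, "n_shifts": n_shifts, "length": length,
        "n_tips": n_tips, "eligible_nodes": eligible_mean,
    })
    if keep_outcomes:
        row["outcomes"] = outcomes
    return row


def run_benchmark(
    cells: list[dict],
    n_tips: int = 64,
    seed: int | None = None,
    threads: int = 1,
    **cell_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every grid cell and aggregate rate and test tables.

    Returns ``(rates, tests)`` DataFrames: one row per cell, and one row per
    (cell, rate-kind, test-kind) with BH-adjusted one-sided p-values across
    the whole family of tests.
    """
    ss = np.random.SeedSequence(seed)
    cell_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cells))]
    rows = []
    for cell, cs in zip(cells, cell_seeds):
        row = run_cell(
            cell["scenario"], cell["n_shifts"], cell["length"],
            cell.get("replicates", 100), n_tips=cell.get("n_tips", n_tips),
            seed=cs, threads=threads, **cell_kwargs,
        )
        rows.append(row)
    test_rows = []
    family = []
    for row in rows:
        for kind in ("fp", "fn"):
            rates = row[f"{kind}_rates"]
            if len(rates) < 2:
                continue
            t_res, z_res = test_rates(rates)
            for res in (t_res, z_res):
                family.append(res)
                test_rows.append({
                    "scenario": row["scenario"], "n_shifts": row["n_shifts"],
                    "length": row["length"], "rate": kind,
                    "test": res.kind, "statistic": res.statistic,
                    "p": res.p, "flag": res.flag,
                })
    adjust_test_family(family)
    for rec, res in zip(test_rows, family):
        rec["p_adjusted"] = res.p_adjusted
    rates_df = pd.DataFrame([
        {k: v for k, v in row.items()
         if not isinstance(v, (np.ndarray, list))}
        for row in rows
    ])
    return rates_df, pd.DataFrame(test_rows)
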