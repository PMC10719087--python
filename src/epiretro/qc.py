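"""The four-step cell/experiment QC ladder.

Step 1 keeps cells from well-converted experiments with sane read counts
(experiment median mCCC < 0.025, 500,000 < nonclonal reads < 10,000,000, cell
mCCC < 0.05; mCCC is a bisulfite non-conversion proxy; all bounds strict).
Step 2 is doublet removal (:func:`epiretro.transfer.remove_doublets`).
Step 3 drops experiments with fewer than 20 neurons.
Step 4 tests each FANS run for contamination: observed on-/off-target neuron
counts (O_on, O_off) are compared to expected counts from an unbiased
reference (E_on, E_off) via

    fold enrichment FE = (O_on * E_off) / (O_off * E_on)
    p = Pr(X >= O_on),  X ~ Binomial(n = O_on + O_off, p = E_on / (E_on + E_off))

A run passes when FE >= its threshold (8 for ET targets, 3 for IT targets)
and the BH-adjusted p across runs of the same target class is < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContaminationTest",
    "filter_cells_basic",
    "filter_experiments_min_cells",
    "contamination_test",
    "contamination_test_batch",
]


@dataclass
class ContaminationTest:
    run_id: str
    o_on: int
    o_off: int
    e_on: float
    e_off: float
    fold_enrichment: float
    p_value: float
    fdr: float | None = None
    passed: bool | None = None


def filter_cells_basic(records: pd.DataFrame) -> pd.Series:
    """QC step 1 pass flags.

    ``records`` columns: cell_id, experiment, mccc_level, nonclonal_reads.
    A cell passes iff its experiment's median mCCC < 0.025, its nonclonal read
    count lies strictly inside (500,000, 10,000,000), and its own mCCC < 0.05.
    """
    for col in ("cell_id", "experiment", "mccc_level", "nonclonal_reads"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    exp_median = records.groupby("experiment")["mccc_level"].transform("median")
    passed = (
        (exp_median < 0.025)
        & (records["nonclonal_reads"] > 500_000)
        & (records["nonclonal_reads"] < 10_000_000)
        & (records["mccc_level"] < 0.05)
    )
    return pd.Series(passed.to_numpy(), index=records["cell_id"].to_numpy(), name="pass_qc1")


def filter_experiments_min_cells(
    neurons_per_experiment: pd.Series | dict, min_cells: int = 20
) -> set:
    """QC step 3: experiments with >= ``min_cells`` neurons."""
    s = pd.Series(neurons_per_experiment)
    return set(s.index[s >= min_cells])


def _fold_enrichment(o_on: int, o_off: int, e_on: float, e_off: float) -> float:
    if o_on == 0:
        return 0.0
    if o_off == 0 or e_on == 0:
        return np.inf
    return (o_on * e_off) / (o_off * e_on)


def contamination_test(
    run_id: str,
    o_on: int,
    o_off: int,
    e_on: float,
    e_off: float,
) -> ContaminationTest:
    """One-sided exact binomial goodness-of-fit test for one FANS run.

    FE and p as defined in the module docstring; with O_off = 0 or E_on = 0
    the FE is infinite (reported as such) and p is still computed.
    """
    if min(o_on, o_off) < 0 or min(e_on, e_off) < 0:
        raise ValueError("counts must be non-negative")
    if e_on + e_off <= 0:
        raise ValueError("expected counts must sum to > 0")
    n = o_on + o_off
    p_exp = e_on / (e_on + e_off)
    # upper tail Pr(X >= o_on)
    p_value = 1.0 if o_on == 0 else float(stats.binom.sf(o_on - 1, n, p_exp))
    fe = _fold_enrichment(o_on, o_off, e_on, e_off)
    return ContaminationTest(run_id, o_on, o_off, e_on, e_off, fe, p_value)


def contamination_test_batch(
    runs: pd.DataFrame,
    fe_threshold: float,
    fdr_threshold: float = 0.001,
    family_column: str | None = None,
) -> pd.DataFrame:
    """Test every FANS run and apply BH within target-class families.

    ``runs`` columns: run_id, o_on, o_off, e_on, e_off, and optionally a
    family column (e.g. the ET/IT target class) named by ``family_column``;
    with no family column all runs form one BH family.  A run passes iff
    FE >= ``fe_threshold`` and adjusted p < ``fdr_threshold``.
    """
    out = runs.copy().reset_index(drop=True)
    results = [
        contamination_test(r.run_id, int(r.o_on), int(r.o_off), r.e_on, r.e_off)
        for r in out.itertuples()
    ]
    out["fold_enrichment"] = [t.fold_enrichment for t in results]
    out["p_value"] = [t.p_value for t in results]
    out["fdr"] = np.nan
    groups = (
        out.groupby(family_column).groups.values()
        if family_column
        else [out.index]
    )
    for idx in groups:
        idx = list(idx)
        out.loc[idx, "fdr"] = multipletests(out.loc[idx, "p_value"], method="fdr_bh")[1]
    out["passed"] = (out["fold_enrichment"] >= fe_threshold) & (out["fdr"] < fdr_threshold)
    return out
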