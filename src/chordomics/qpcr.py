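"""Relative qPCR quantification by the 2^-ddCt method with dual
housekeeping normalization.

Per housekeeping gene h: dCt = Ct_target - Ct_h (condition means of
technical triplicates), ddCt = dCt_condition - dCt_reference, fold change
FC_h = 2^-ddCt.  Fold changes are then averaged across the housekeeping
genes (mean +- sample sd), matching dual-reference reporting with HPRT1
and TBP.  Amplification efficiency is fixed at 2 per cycle.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["condition_means", "delta_delta_ct", "housekeeping_stability"]

_REP_COLS = ["rep1", "rep2", "rep3"]


def condition_means(ct: pd.DataFrame) -> pd.DataFrame:
    """Average Ct of technical replicates per (gene, condition); warns when
    a triplet is incomplete and uses the available replicates."""
    reps = ct[_REP_COLS]
    if reps.isna().any(axis=None):
        warnings.warn("incomplete replicate triplets; averaging available wells")
    if reps.isna().all(axis=1).any():
        raise ValueError("a (gene, condition) row has no replicate values")
    out = ct[["gene", "condition"]].copy()
    out["ct"] = reps.mean(axis=1, skipna=True)
    return out.set_index(["gene", "condition"])["ct"].unstack("condition")


def delta_delta_ct(
    ct: pd.DataFrame,
    housekeeping: list[str] = ("HPRT1", "TBP"),
    reference_condition: str = "mock",
) -> pd.DataFrame:
    """Fold-change table for every non-housekeeping gene and condition.

    Returns a DataFrame with one row per (gene, condition) carrying the
    per-housekeeping fold changes (columns ``fc_<hk>``), their mean and
    sample sd.  The reference condition's fold change is exactly 1 for
    every gene and housekeeping choice.
    """
    means = condition_means(ct)
    if reference_condition not in means.columns:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    for hk in housekeeping:
        if hk not in means.index:
            raise ValueError(f"housekeeping gene {hk!r} missing from the table")
        if means.loc[hk].isna().any():
            raise ValueError(f"housekeeping gene {hk!r} missing a condition value")

    targets = [g for g in means.index if g not in set(housekeeping)]
    rows = []
    for gene in targets:
        for cond in means.columns:
            fcs = {}
            for hk in housekeeping:
                dct = means.loc[gene, cond] - means.loc[hk, cond]
                dct_ref = means.loc[gene, reference_condition] - means.loc[hk, reference_condition]
                fcs[hk] = 2.0 ** -(dct - dct_ref)
            vals = np.array(list(fcs.values()))
            rows.append(
                dict(gene=gene, condition=cond,
                     **{f"fc_{hk}": fcs[hk] for hk in housekeeping},
                     mean_fc=vals.mean(),
                     sd_fc=vals.std(ddof=1) if vals.size > 1 else 0.0)
            )
    out = pd.DataFrame(rows)
    if (out["mean_fc"] <= 0).any():
        raise ValueError("fold changes must be positive")
    return out


def housekeeping_stability(
    ct: pd.DataFrame, housekeeping: list[str] = ("HPRT1", "TBP"), bound: float = 1.0
) -> pd.DataFrame:
    """Range (max - min) and sd of condition-mean Ct per housekeeping gene,
    flagged when the range exceeds ``bound`` cycles."""
    means = condition_means(ct)
    if means.shape[1] < 2:
        raise ValueError("need >=2 conditions to assess stability")
    rows = []
    for hk in housekeeping:
        vals = means.loc[hk].values.astype(float)
        rng = float(vals.max() - vals.min())
        rows.append(dict(gene=hk, ct_range=rng, ct_sd=float(vals.std(ddof=1)),
                         flagged=rng > bound))
    return pd.DataFrame(rows)
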