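"""Relative quantification of qPCR expression by the 2^-ddCt method.

Input is a tidy Ct table (sample, group, gene, ct, replicate). Technical
replicates are averaged in Ct space; dCt = Ct(target) - Ct(reference) per
sample; ddCt subtracts the control-group mean dCt, so the geometric mean of
control-group folds is exactly 1. The same arithmetic with two isoforms of
one gene (a as target, b as reference) yields an isoform a/b ratio index.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _sample_ct(ct: pd.DataFrame, gene: str) -> pd.Series:
    sub = ct[ct["gene"] == gene]
    return sub.groupby("sample")["ct"].mean()


def ddct_fold(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample fold change 2^-ddCt plus dCt bookkeeping.

    Returns a DataFrame indexed by sample with columns group, dct, ddct,
    fold. Samples lacking a reference (or target) Ct are excluded with a
    warning. Requires >= 1 sample in the control group.
    """
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]
    tgt = _sample_ct(ct, target)
    ref = _sample_ct(ct, reference)
    complete = tgt.index.intersection(ref.index)
    dropped = groups.index.difference(complete)
    if len(dropped):
        warnings.warn(f"samples missing target or reference Ct: {list(dropped)}")
    dct = (tgt - ref).loc[complete]
    grp = groups.loc[complete]
    control = dct[grp == control_group]
    if control.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    ddct = dct - control.mean()
    return pd.DataFrame(
        {"group": grp, "dct": dct, "ddct": ddct, "fold": 2.0 ** (-ddct)}
    )


def isoform_ratio(
    ct: pd.DataFrame,
    isoform_a: str = "isoform_a",
    isoform_b: str = "isoform_b",
    control_group: str = "control",
) -> pd.DataFrame:
    """Isoform a/b ratio index: ddCt arithmetic with a as target, b as reference."""
    return ddct_fold(ct, target=isoform_a, reference=isoform_b, control_group=control_group)


def group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean, geometric mean and SEM of fold per group."""
    def geo(x):
        return float(np.exp(np.log(x).mean()))

    return folds.groupby("group")["fold"].agg(
        mean="mean", geometric_mean=geo, sem=lambda x: x.sem() if len(x) > 1 else 0.0,
        n="count",
    )
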