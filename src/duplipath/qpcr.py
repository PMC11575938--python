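"""Relative quantification of qPCR data by the 2^-ΔΔCt (Livak) method.

ΔCt = Ct_target - Ct_reference per replicate; ΔΔCt subtracts the mean
control-condition ΔCt; fold change = 2^-ΔΔCt.  Control-condition folds keep
their per-replicate spread (their geometric mean is 1 by construction), and
a two-sided Welch t-test compares conditions on the ΔCt scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DdctResult", "ddct_relative_expression", "significance_stars"]


@dataclass
class DdctResult:
    gene_id: str
    per_replicate: pd.DataFrame  # condition, replicate, dct, ddct, fold
    summary: pd.DataFrame  # per condition: mean_fold, se, n
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Figure-style significance marks: * p < 0.05, ** p < 0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str = "CK",
) -> DdctResult:
    """Livak relative expression of ``target`` against ``reference``.

    ``ct_table`` columns: gene_id, condition, replicate, ct.  Requires a
    reference Ct for every (condition, replicate) the target appears in, and
    at least 3 replicates per condition.
    """
    t = ct_table[ct_table["gene_id"] == target]
    r = ct_table[ct_table["gene_id"] == reference]
    if t.empty:
        raise ValueError(f"no Ct rows for target {target}")
    if r.empty:
        raise ValueError(f"no Ct rows for reference gene {reference}")
    ref_ct = r.set_index(["condition", "replicate"])["ct"]
    rows = []
    for row in t.itertuples(index=False):
        key = (row.condition, row.replicate)
        if key not in ref_ct.index:
            raise ValueError(f"missing reference Ct for condition={key[0]} replicate={key[1]}")
        rows.append(
            {
                "condition": row.condition,
                "replicate": row.replicate,
                "dct": row.ct - float(ref_ct.loc[key]),
            }
        )
    per_rep = pd.DataFrame(rows)
    counts = per_rep.groupby("condition").size()
    if (counts < 3).any():
        raise ValueError("need at least 3 replicates per condition")
    if control_condition not in counts.index:
        raise ValueError(f"control condition {control_condition!r} absent from table")

    control_mean_dct = per_rep.loc[per_rep["condition"] == control_condition, "dct"].mean()
    per_rep["ddct"] = per_rep["dct"] - control_mean_dct
    per_rep["fold"] = 2.0 ** (-per_rep["ddct"])

    summary = (
        per_rep.groupby("condition")["fold"]
        .agg(mean_fold="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
        .reset_index()
    )
    conds = [c for c in per_rep["condition"].unique() if c != control_condition]
    if conds:
        a = per_rep.loc[per_rep["condition"] == control_condition, "dct"]
        b = per_rep.loc[per_rep["condition"] == conds[0], "dct"]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 0.0 if not np.isclose(a.mean(), b.mean()) else 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = 1.0
    return DdctResult(gene_id=target, per_replicate=per_rep, summary=summary, p_value=p)
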