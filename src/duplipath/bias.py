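"""Six-category homoeolog expression-bias classification.

For every homoeologous (At, Dt) gene pair expressed under both conditions,
the At/Dt expression ratio is tested for departure from 1 separately under
control (CK) and UV-B stress (UV).  A ratio whose test is not significant
(p >= 0.05) is recorded as 1.  The pair of per-condition verdicts then maps
onto six categories:

====================  =================  ==============
CK direction          UV direction       category
====================  =================  ==============
equal                 equal              no_bias
biased                equal              lost_bias
equal                 At dominant        get_At_bias
equal                 Dt dominant        get_Dt_bias
biased                At dominant        At_bias
biased                Dt dominant        Dt_bias
====================  =================  ==============

A pair whose dominant subgenome flips between conditions (CK At-dominant,
UV Dt-dominant or vice versa) is labeled by the UV-dominant homoeolog with
``switched_dominance`` set — the taxonomy above does not name that case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioStatus",
    "BiasCall",
    "UnexpressedPairError",
    "CATEGORIES",
    "ratio_test",
    "classify_pair",
    "classify_all",
]

CATEGORIES = ("no_bias", "lost_bias", "At_bias", "Dt_bias", "get_At_bias", "get_Dt_bias")

BIAS_ALPHA = 0.05
EXPRESSED_MIN_MEAN = 1.0  # mean expression floor for "simultaneously expressed"


class UnexpressedPairError(ValueError):
    """Raised when classifying a pair with both homoeologs silent."""


@dataclass(frozen=True)
class RatioStatus:
    """Per-condition verdict on the At/Dt expression ratio."""

    condition: str
    raw_ratio: float
    p_value: float
    direction: str  # equal | At_dominant | Dt_dominant

    @property
    def effective_ratio(self) -> float:
        """The ratio used downstream: 1 when not significant."""
        return 1.0 if self.direction == "equal" else self.raw_ratio


@dataclass(frozen=True)
class BiasCall:
    pair_id: str
    ck: RatioStatus
    uv: RatioStatus
    category: str
    switched_dominance: bool = False


def ratio_test(
    at_values: np.ndarray,
    dt_values: np.ndarray,
    condition: str = "",
    alpha: float = BIAS_ALPHA,
) -> RatioStatus:
    """Test At vs Dt expression equality within one condition.

    Welch's two-sample t-test on log2(x+1)-transformed replicate values; the
    raw ratio is mean(At)/mean(Dt) on the original scale.  With p >= alpha
    the direction is ``equal`` and the effective ratio is 1.  Degenerate
    zero-variance inputs are called significant iff the means differ.
    """
    at = np.asarray(at_values, dtype=float)
    dt = np.asarray(dt_values, dtype=float)
    if at.size < 2 or dt.size < 2:
        raise ValueError("need at least 2 replicates per homoeolog")
    if (at < 0).any() or (dt < 0).any():
        raise ValueError("expression values must be nonnegative")
    if not (at.any() or dt.any()):
        raise UnexpressedPairError("both homoeologs unexpressed in all replicates")

    at_log = np.log2(at + 1.0)
    dt_log = np.log2(dt + 1.0)
    mean_at, mean_dt = at.mean(), dt.mean()
    raw_ratio = mean_at / mean_dt if mean_dt > 0 else np.inf

    if at_log.std(ddof=1) == 0.0 and dt_log.std(ddof=1) == 0.0:
        p = 0.0 if not np.isclose(at_log.mean(), dt_log.mean()) else 1.0
    else:
        p = stats.ttest_ind(at_log, dt_log, equal_var=False).pvalue
        if not np.isfinite(p):
            p = 1.0

    if p >= alpha:
        direction = "equal"
    elif mean_at > mean_dt:
        direction = "At_dominant"
    else:
        direction = "Dt_dominant"
    return RatioStatus(condition=condition, raw_ratio=raw_ratio, p_value=float(p), direction=direction)


def classify_pair(ck: RatioStatus, uv: RatioStatus, pair_id: str = "") -> BiasCall:
    """Map the (CK, UV) ratio verdicts onto the six bias categories."""
    switched = (
        ck.direction != "equal"
        and uv.direction != "equal"
        and ck.direction != uv.direction
    )
    if ck.direction == "equal" and uv.direction == "equal":
        category = "no_bias"
    elif uv.direction == "equal":
        category = "lost_bias"
    elif ck.direction == "equal":
        category = "get_At_bias" if uv.direction == "At_dominant" else "get_Dt_bias"
    else:
        # biased in both conditions: labeled by the UV-dominant homoeolog
        category = "At_bias" if uv.direction == "At_dominant" else "Dt_bias"
    return BiasCall(pair_id=pair_id, ck=ck, uv=uv, category=category, switched_dominance=switched)


def classify_all(
    expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    metadata: pd.DataFrame,
    alpha: float = BIAS_ALPHA,
    expressed_min_mean: float = EXPRESSED_MIN_MEAN,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Classify every simultaneously expressed homoeolog pair.

    ``expr`` is an expression matrix (FPKM or normalized counts) with genes as
    rows; ``metadata`` maps sample columns to ``condition`` CK/UV.  A pair
    enters classification only when both homoeologs have mean expression at or
    above ``expressed_min_mean`` under both conditions; the rest are reported
    as unexpressed.

    Returns ``(bias_table, census, unexpressed_pair_ids)``; the census counts
    pairs and genes (2x pairs) per category over all six categories.
    """
    cond = metadata.loc[expr.columns, "condition"]
    ck_cols = list(expr.columns[cond == "CK"])
    uv_cols = list(expr.columns[cond == "UV"])
    rows = []
    unexpressed: list[str] = []
    for at_id, dt_id in pairs:
        pair_id = f"{at_id}|{dt_id}"
        at_ck = expr.loc[at_id, ck_cols].to_numpy(dtype=float)
        dt_ck = expr.loc[dt_id, ck_cols].to_numpy(dtype=float)
        at_uv = expr.loc[at_id, uv_cols].to_numpy(dtype=float)
        dt_uv = expr.loc[dt_id, uv_cols].to_numpy(dtype=float)
        expressed = (
            at_ck.mean() >= expressed_min_mean
            and dt_ck.mean() >= expressed_min_mean
            and at_uv.mean() >= expressed_min_mean
            and dt_uv.mean() >= expressed_min_mean
        )
        if not expressed:
            unexpressed.append(pair_id)
            continue
        ck = ratio_test(at_ck, dt_ck, "CK", alpha)
        uv = ratio_test(at_uv, dt_uv, "UV", alpha)
        call = classify_pair(ck, uv, pair_id)
        rows.append(
            {
                "pair_id": pair_id,
                "at_id": at_id,
                "dt_id": dt_id,
                "ck_ratio": ck.effective_ratio,
                "ck_raw_ratio": ck.raw_ratio,
                "ck_p": ck.p_value,
                "uv_ratio": uv.effective_ratio,
                "uv_raw_ratio": uv.raw_ratio,
                "uv_p": uv.p_value,
                "category": call.category,
                "switched": call.switched_dominance,
            }
        )
    bias_table = pd.DataFrame(
        rows,
        columns=[
            "pair_id", "at_id", "dt_id", "ck_ratio", "ck_raw_ratio", "ck_p",
            "uv_ratio", "uv_raw_ratio", "uv_p", "category", "switched",
        ],
    )
    census = pd.DataFrame(
        {
            "category": CATEGORIES,
            "n_pairs": [int((bias_table["category"] == c).sum()) for c in CATEGORIES],
        }
    )
    census["n_genes"] = census["n_pairs"] * 2
    return bias_table, census, unexpressed
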