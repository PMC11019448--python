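"""Reporting layer: rounding rules, tidy analysis tables, forest features.

Percentages are rounded half-away-from-zero at a caller-chosen precision, so
printed proportions match the usual clinical-journal convention (e.g.
633/1361 prints as 47% at integer precision and 1282/1361 as 94.2% at one
decimal).  Scores are carried at full precision internally and printed at
one decimal.

``heterogeneity_table`` reproduces the shape of a clinicopathologic
comparison table: Spearman rho for continuous covariates against the CLix
score, and median (IQR) by group with a Wilcoxon rank-sum p for binary ones.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CaseRecord, cohort_frame
from .errors import InsufficientDataError, ValidationError
from .stats import mmse_decline, spearman, wilcoxon_rank_sum

#: Continuous covariates correlated with the score, in reporting order.
CONTINUOUS_VARS = (
    "education_y",
    "age_onset_y",
    "duration_y",
    "mmse_decline",
    "age_death_y",
    "brain_weight_g",
    "braak",
    "thal",
    "kalaria",
)
#: Binary covariates compared by group medians.
BINARY_VARS = ("sex_male", "apoe_e4", "atypical_syndrome", "trem2_r47h", "tdp43_positive")

#: Default predictor set for the importance forest.  Age at death is left
#: out (collinear with age at onset) and MMSE decline is left out (too much
#: missingness); both can be re-added explicitly by the caller.
FOREST_VARS = (
    "education_y",
    "age_onset_y",
    "duration_y",
    "brain_weight_g",
    "braak",
    "thal",
    "kalaria",
    "sex_male",
    "apoe_e4",
    "atypical_syndrome",
)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ValidationError("zero denominator")
    raw = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(numerator: float, denominator: float, decimals: int = 0) -> str:
    return f"{percent(numerator, denominator, decimals):.{decimals}f}%"


def format_score(score: float) -> str:
    """Scores are printed at one decimal."""
    return f"{score:.1f}"


def analysis_frame(
    records: Sequence[CaseRecord], scored: pd.DataFrame
) -> pd.DataFrame:
    """Merge covariates (plus the derived MMSE slope) with the scores.

    Booleans become 0/1 floats with NaN for absent values; sex becomes the
    indicator ``sex_male``.
    """
    cov = cohort_frame(records)
    declines = []
    for rec in records:
        try:
            declines.append(mmse_decline(rec.mmse))
        except InsufficientDataError:
            declines.append(np.nan)
    cov["mmse_decline"] = declines
    cov["sex_male"] = cov["sex"].map({"male": 1.0, "female": 0.0})
    for col in ("apoe_e4", "trem2_r47h", "atypical_syndrome", "tdp43_positive"):
        cov[col] = cov[col].map({True: 1.0, False: 0.0})
    merged = scored.merge(cov, on="case_id", how="left", suffixes=("", "_cov"))
    return merged


def heterogeneity_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-covariate association table against the CLix score.

    One row per covariate with the test used, the estimate (rho for
    continuous, difference in group medians for binary), the two-sided p,
    the n analysed, and median (IQR) summaries for the binary groups.
    """
    rows = []
    for var in CONTINUOUS_VARS:
        if var not in frame.columns:
            continue
        sub = frame[["score", var]].dropna()
        if len(sub) < 3 or sub[var].nunique() < 2:
            continue
        res = spearman(sub[var], sub["score"])
        rows.append(
            {
                "variable": var,
                "test": "spearman",
                "estimate": res.estimate,
                "p_value": res.p_value,
                "n": res.n,
                "group_summary": "",
            }
        )
    for var in BINARY_VARS:
        if var not in frame.columns:
            continue
        sub = frame[["score", var]].dropna()
        pos = sub.loc[sub[var] == 1.0, "score"]
        neg = sub.loc[sub[var] == 0.0, "score"]
        if len(pos) == 0 or len(neg) == 0:
            continue
        res = wilcoxon_rank_sum(pos, neg)
        summ = (
            f"{var}+: {_median_iqr(pos)}; {var}-: {_median_iqr(neg)}"
        )
        rows.append(
            {
                "variable": var,
                "test": "wilcoxon_rank_sum",
                "estimate": float(pos.median() - neg.median()),
                "p_value": res.p_value,
                "n": res.n,
                "group_summary": summ,
            }
        )
    return pd.DataFrame(rows)


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.0f} ({q1:.0f}-{q3:.0f})"


def forest_features(
    frame: pd.DataFrame, variables: Sequence[str] = FOREST_VARS
) -> tuple[pd.DataFrame, np.ndarray]:
    """Predictor matrix and target for :func:`clix.importance.rf_importance`."""
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValidationError(f"missing forest variables: {missing}")
    return frame[list(variables)].astype(float), frame["score"].to_numpy(float)
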