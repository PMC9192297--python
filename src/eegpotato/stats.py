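"""One-way ANOVA significance machinery for feature comparisons.

Used to ask whether a feature (per-channel mean PSD or sample entropy)
differs between groups of epochs — e.g. normal vs abnormal epochs of the
potato partition, or features before vs after a denoising step.  All
comparisons, including two-group ones, go through the same one-way
F test; no multiple-testing correction is applied, and results are
reported per channel and per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["AnovaResult", "one_way_anova", "compare_feature_sets"]


@dataclass(frozen=True)
class AnovaResult:
    """F statistic, tail probability and degrees of freedom of one test."""

    F: float
    p: float
    df_between: int
    df_within: int


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA over k groups.

    Between/within variance decomposition with p from the F distribution
    on (k-1, N-k) degrees of freedom.  The degenerate case of zero
    within- and between-group variance (all values identical) returns
    F=0, p=1 rather than NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two values")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df_b, df_w = k - 1, n_total - k
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return AnovaResult(F=0.0, p=1.0, df_between=df_b, df_within=df_w)
    f, p = sst.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-variance but distinct means
        f, p = float("inf"), 0.0
    return AnovaResult(F=float(f), p=float(p), df_between=df_b, df_within=df_w)


def compare_feature_sets(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    alpha: float = 0.05,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-column two-group ANOVA between two feature tables.

    Both tables must share the feature columns being compared (by
    default, all numeric columns present in both).  Returns a
    SignificanceReport frame with one row per feature column:
    ``feature, F, p, significant`` where significant means p < alpha.
    """
    if features_a.empty or features_b.empty:
        raise ValueError("feature tables must be non-empty")
    if columns is None:
        num_a = features_a.select_dtypes("number").columns
        columns = [c for c in num_a if c in features_b.columns]
    missing = [c for c in columns if c not in features_a.columns
               or c not in features_b.columns]
    if missing:
        raise KeyError(f"columns missing from one table: {missing}")
    rows = []
    for col in columns:
        res = one_way_anova(
            [features_a[col].to_numpy(), features_b[col].to_numpy()]
        )
        rows.append((col, res.F, res.p, bool(res.p < alpha)))
    return pd.DataFrame(rows, columns=["feature", "F", "p", "significant"])
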