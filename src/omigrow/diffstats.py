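"""Aerobic vs anaerobic differential abundance and CV ranking.

Differential testing uses Welch's unequal-variance two-sample t-test on
raw (unstandardized) abundances, with Benjamini-Hochberg FDR control
across the analyzed feature subset at level alpha. Features where
either oxygen group has zero variance are flagged untestable and
excluded from the FDR adjustment rather than given a fabricated
p-value.

The coefficient of variation (CV) of a feature is its sample (n-1)
standard deviation divided by its mean across all conditions — a
scale-free dispersion measure. Two rankings are emitted, because
"important" is direction-dependent: ``cv_rank`` puts the most variable
feature first (rank 1 = largest oxygen-driven swing), while
``consistency_rank`` puts the most stable feature first.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, InsufficientGroupError, MetricDomainError
from .preprocess import OmicsMatrix
from .synthetic import ConditionDesign


def _oxygen_groups(
    design: Sequence[ConditionDesign], condition_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    oxy = {c.condition_id: c.oxygen for c in design}
    missing = [c for c in condition_ids if c not in oxy]
    if missing:
        raise InputError(f"conditions absent from design: {missing}")
    aer = [c for c in condition_ids if oxy[c] == "aerobic"]
    ana = [c for c in condition_ids if oxy[c] == "anaerobic"]
    return aer, ana


def coefficient_of_variation(
    m: OmicsMatrix, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-feature CV across all conditions, with both rankings.

    Raises
    ------
    MetricDomainError
        If any analyzed feature has a non-positive mean (CV undefined).
    """
    mat = m.subset(subset) if subset is not None else m
    X = mat.values()
    means = X.mean(axis=0)
    bad = [f for f, mu in zip(mat.feature_ids, means) if mu <= 0]
    if bad:
        raise MetricDomainError(f"CV undefined for non-positive means: {bad[:5]}")
    cv = X.std(axis=0, ddof=1) / means
    df = pd.DataFrame({"cv": cv}, index=pd.Index(mat.feature_ids, name="feature_id"))
    df = df.sort_index()
    by_desc = df.sort_values("cv", ascending=False, kind="mergesort")
    df["cv_rank"] = pd.Series(
        np.arange(1, len(df) + 1), index=by_desc.index
    ).reindex(df.index)
    by_asc = df.sort_values("cv", ascending=True, kind="mergesort")
    df["consistency_rank"] = pd.Series(
        np.arange(1, len(df) + 1), index=by_asc.index
    ).reindex(df.index)
    return df


def diff_abundance(
    m: OmicsMatrix,
    design: Sequence[ConditionDesign],
    alpha: float = 0.05,
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Welch t-test per feature between oxygen groups, BH-adjusted.

    Parameters
    ----------
    m
        Raw (unstandardized) abundance matrix.
    design
        Condition metadata assigning each condition an oxygen level;
        both groups need >= 2 conditions.
    alpha
        FDR level for the significance flag.
    subset
        Features to analyze (default: all of `m`); FDR adjustment runs
        across exactly this subset.

    Returns
    -------
    DataFrame indexed by feature ID with columns ``mean_aerobic``,
    ``mean_anaerobic``, ``t_stat``, ``p_value``, ``q_value``,
    ``significant``, ``untestable``, ``cv``, ``cv_rank``,
    ``consistency_rank``. Untestable features carry NaN statistics and
    ``significant=False``.
    """
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")
    if m.standardized:
        raise InputError("differential testing expects raw, unstandardized abundances")
    mat = m.subset(subset) if subset is not None else m
    aer, ana = _oxygen_groups(design, mat.condition_ids)
    if len(aer) < 2 or len(ana) < 2:
        raise InsufficientGroupError(
            f"need >= 2 conditions per oxygen group, got {len(aer)} aerobic / "
            f"{len(ana)} anaerobic"
        )
    A = mat.data.loc[aer].to_numpy(dtype=float)
    B = mat.data.loc[ana].to_numpy(dtype=float)

    var_a = A.var(axis=0, ddof=1)
    var_b = B.var(axis=0, ddof=1)
    untestable = (var_a == 0.0) | (var_b == 0.0)

    t_stat = np.full(mat.n_features, np.nan)
    p_val = np.full(mat.n_features, np.nan)
    ok = ~untestable
    if ok.any():
        res = stats.ttest_ind(A[:, ok], B[:, ok], axis=0, equal_var=False)
        t_stat[ok] = res.statistic
        p_val[ok] = res.pvalue

    q_val = np.full(mat.n_features, np.nan)
    significant = np.zeros(mat.n_features, dtype=bool)
    if ok.any():
        reject, qvals, _, _ = multipletests(p_val[ok], alpha=alpha, method="fdr_bh")
        q_val[ok] = qvals
        significant[ok] = reject

    cv_df = coefficient_of_variation(mat)
    out = pd.DataFrame(
        {
            "mean_aerobic": A.mean(axis=0),
            "mean_anaerobic": B.mean(axis=0),
            "t_stat": t_stat,
            "p_value": p_val,
            "q_value": q_val,
            "significant": significant,
            "untestable": untestable,
        },
        index=pd.Index(mat.feature_ids, name="feature_id"),
    )
    return out.join(cv_df)
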