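"""Behavioral analysis: validity filtering, miss rates, repeated-measures
ANOVA with partial eta squared, and Bonferroni planned comparisons.

A trial counts as a miss when no response was made or the reaction time
falls outside the 100-800 ms validity window (the boundary values are
valid).  Mean valid RTs per subject and deviant condition enter a classical
within-subject one-way ANOVA — F is the condition mean square over the
condition-by-subject interaction mean square, df (k-1, (k-1)(n-1)) — and
the six condition pairs are compared with paired t-tests under Bonferroni
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .norms import BIN_LABELS

logger = logging.getLogger(__name__)


@dataclass
class RTValidityRule:
    lower_ms: float = 100.0
    upper_ms: float = 800.0

    def __post_init__(self) -> None:
        if self.lower_ms >= self.upper_ms:
            raise ValueError("validity window lower bound must be below upper bound")


@dataclass
class ConditionMeans:
    """Subjects x 4 conditions matrix of mean valid RTs, plus miss percentages."""

    rt: np.ndarray        # (n_subjects, 4) ordered SC, C, D, SD
    miss_pct: np.ndarray  # (n_subjects, 4)
    subjects: list

    def __post_init__(self) -> None:
        if np.isnan(self.rt).any():
            bad = [self.subjects[i] for i in np.flatnonzero(np.isnan(self.rt).any(axis=1))]
            raise ValueError(f"subject(s) {bad} have a condition with no valid trials")


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def filter_valid(rt_table: pd.DataFrame,
                 rule: RTValidityRule | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trials into valid responses and misses.

    A trial is a miss iff there was no response or the RT lies strictly
    outside [lower_ms, upper_ms].  Returns the valid-trial table and a
    subject x condition table of miss percentages.
    """
    rule = rule or RTValidityRule()
    unknown = set(rt_table["condition"]) - set(BIN_LABELS)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    responded = rt_table["responded"].astype(bool) & rt_table["rt_ms"].notna()
    in_window = rt_table["rt_ms"].between(rule.lower_ms, rule.upper_ms, inclusive="both")
    valid = responded & in_window
    miss_pct = (
        rt_table.assign(miss=~valid)
        .groupby(["subject", "condition"], sort=True)["miss"]
        .mean()
        .mul(100.0)
        .unstack("condition")
        .reindex(columns=list(BIN_LABELS))
    )
    return rt_table[valid].copy(), miss_pct


def condition_means(valid: pd.DataFrame, miss_pct: pd.DataFrame) -> ConditionMeans:
    rt = (
        valid.groupby(["subject", "condition"])["rt_ms"].mean()
        .unstack("condition").reindex(columns=list(BIN_LABELS))
    )
    rt = rt.reindex(index=miss_pct.index)
    return ConditionMeans(rt=rt.to_numpy(), miss_pct=miss_pct.to_numpy(),
                          subjects=list(rt.index))


def rm_anova_oneway(means: np.ndarray) -> AnovaResult:
    """Within-subject one-way ANOVA on a subjects x conditions matrix.

    F = MS_condition / MS_(condition x subject); partial eta squared is
    SS_condition / (SS_condition + SS_error).
    """
    X = np.asarray(means, dtype=float)
    n, k = X.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = np.inf if ms_err == 0 and ms_cond > 0 else (0.0 if ms_cond == 0 else ms_cond / ms_err)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    peta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p, partial_eta_sq=float(peta))


def planned_pairwise(means: np.ndarray, correction: str = "bonferroni",
                     m: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests for all condition pairs with Bonferroni adjustment.

    p_adj = min(1, m * p_raw) with the family size m defaulting to the six
    pairwise tests; an m smaller than the number of tests is raised to it
    (with a logged warning).
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    X = np.asarray(means, dtype=float)
    pairs = list(combinations(range(X.shape[1]), 2))
    if m is None:
        m = len(pairs)
    elif m < len(pairs):
        logger.warning("Bonferroni family size %d < %d tests; raising to %d",
                       m, len(pairs), len(pairs))
        m = len(pairs)
    n = X.shape[0]
    rows = []
    for i, j in pairs:
        diff = X[:, i] - X[:, j]
        sd = diff.std(ddof=1)
        if sd == 0:
            t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            p_raw = 1.0 if t == 0 else 0.0
        else:
            t = diff.mean() / (sd / np.sqrt(n))
            p_raw = float(2 * stats.t.sf(abs(t), n - 1))
        p_adj = min(1.0, m * p_raw)
        rows.append({
            "pair": f"{BIN_LABELS[i]}-{BIN_LABELS[j]}",
            "t": float(t), "df": n - 1, "p_raw": p_raw, "p_adj": p_adj,
            "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


def behavioral_report(rt_table: pd.DataFrame,
                      rule: RTValidityRule | None = None) -> dict:
    """Full behavioral stage: filtering, condition means, ANOVA, pairwise."""
    valid, miss_pct = filter_valid(rt_table, rule)
    cm = condition_means(valid, miss_pct)
    anova_rt = rm_anova_oneway(cm.rt)
    anova_miss = rm_anova_oneway(cm.miss_pct)
    pairwise = planned_pairwise(cm.rt)
    return {
        "condition_means_rt": {c: float(v) for c, v in zip(BIN_LABELS, cm.rt.mean(axis=0))},
        "condition_means_miss_pct": {
            c: float(v) for c, v in zip(BIN_LABELS, cm.miss_pct.mean(axis=0))
        },
        "anova_rt": anova_rt.__dict__,
        "anova_miss": anova_miss.__dict__,
        "pairwise_rt": pairwise.to_dict(orient="records"),
        "n_subjects": len(cm.subjects),
    }
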