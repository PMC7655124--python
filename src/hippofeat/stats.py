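"""Statistical battery for per-channel iEEG features.

For each feature: paired t-tests for the rest-vs-task change within each
hippocampus group (EH, NEH); Mann-Whitney U tests for the EH-vs-NEH
difference within each condition; ROC analysis (EH coded positive) of the
rest values, task values and rest-minus-task differences, with the
Hanley-McNeil closed-form test against chance (AUC = 0.5). Tests run per
channel and, as an outlier-robustness check, per hippocampus (on channel
medians). No multiple-testing correction is applied by default; an
optional Benjamini-Hochberg flag is available.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES
from .filtering import ParameterError


class InsufficientDataError(ValueError):
    """Not enough complete observations for the requested test."""


@dataclass(frozen=True)
class StatResult:
    feature: str
    comparison: str  # e.g. 'rest-vs-task within EH', 'EH-vs-NEH at rest'
    statistic: float
    p_value: float
    n: int
    level: str = "channel"  # or 'hippocampus'
    task_scope: str = "grouped"


@dataclass(frozen=True)
class RocResult:
    feature: str
    scope: str  # 'rest', 'task' or 'diff'
    auc: float
    n_pos: int
    n_neg: int
    p_vs_chance: float
    level: str = "channel"


# ---------------------------------------------------------------------------
# elementary tests


def paired_rest_task_test(
    features: pd.DataFrame, feature: str, label_group: str, level: str = "channel"
) -> StatResult:
    """Two-sided paired t-test of rest vs task values across channels.

    Channels missing either condition's value are dropped (and counted in
    ``n`` only if complete).
    """
    sub = features[features["label"] == label_group]
    wide = sub.pivot_table(index="channel_id", columns="condition", values=feature)
    if "rest" not in wide or "task" not in wide:
        raise InsufficientDataError(f"need both conditions for {feature} in {label_group}")
    wide = wide.dropna(subset=["rest", "task"])
    if len(wide) < 2:
        raise InsufficientDataError(
            f"<2 complete rest/task pairs for {feature} in {label_group}"
        )
    t, p = sps.ttest_rel(wide["rest"], wide["task"])
    if np.isnan(p):  # identical pairs: zero variance of differences
        t, p = 0.0, 1.0
    return StatResult(
        feature, f"rest-vs-task within {label_group}", float(t), float(p), len(wide), level
    )


def group_test_eh_vs_neh(
    features: pd.DataFrame, feature: str, condition: str, level: str = "channel"
) -> StatResult:
    """Two-sided Mann-Whitney U test of EH vs NEH channels in one condition."""
    sub = features[features["condition"] == condition]
    x = sub.loc[sub["label"] == "EH", feature].dropna()
    y = sub.loc[sub["label"] == "NEH", feature].dropna()
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError(f"empty group for {feature} at {condition}")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        feature, f"EH-vs-NEH at {condition}", float(u), float(p), len(x) + len(y), level
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), positives coded 1 (EH).

    Computed from the rank-sum (Mann-Whitney) identity, which handles
    ties exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InsufficientDataError("both classes required for ROC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def hanley_mcneil_p(auc: float, n_pos: int, n_neg: int) -> float:
    """Two-sided normal p-value for H0: AUC = 0.5 (Hanley-McNeil SE).

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A), evaluated at the observed AUC.
    """
    if not 0.0 <= auc <= 1.0:
        raise ParameterError(f"auc {auc} outside [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("need n_pos, n_neg >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    if var <= 0:
        return 0.0 if a != 0.5 else 1.0
    z = (a - 0.5) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def roc_result(
    features: pd.DataFrame, feature: str, scope: str, level: str = "channel"
) -> RocResult:
    """ROC of one feature for one scope: rest, task or rest-minus-task diff."""
    wide = features.pivot_table(index="channel_id", columns="condition", values=feature)
    labels = features.drop_duplicates("channel_id").set_index("channel_id")["label"]
    if scope in ("rest", "task"):
        if scope not in wide:
            raise InsufficientDataError(f"no {scope} values for {feature}")
        vals = wide[scope]
    elif scope == "diff":
        if "rest" not in wide or "task" not in wide:
            raise InsufficientDataError(f"need both conditions for {feature} diff")
        vals = wide["rest"] - wide["task"]
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    vals = vals.dropna()
    lab = labels.loc[vals.index]
    y = (lab == "EH").astype(int).values
    auc = roc_auc(vals.values, y)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    return RocResult(feature, scope, auc, n_pos, n_neg, hanley_mcneil_p(auc, n_pos, n_neg), level)


# ---------------------------------------------------------------------------
# battery


def run_battery(
    features: pd.DataFrame,
    feature_names: list[str] | None = None,
    level: str = "channel",
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full test battery on a (grouped-task) feature table.

    Returns ``(tests, rocs)``: paired t and Mann-Whitney results in
    ``tests``, ROC/Hanley-McNeil results in ``rocs``. Tests that cannot
    run (insufficient data) are skipped.
    """
    feature_names = feature_names or FEATURE_NAMES
    tests: list[StatResult] = []
    rocs: list[RocResult] = []
    for feat in feature_names:
        for label in ("EH", "NEH"):
            try:
                tests.append(paired_rest_task_test(features, feat, label, level))
            except InsufficientDataError:
                pass
        for condition in ("rest", "task"):
            try:
                tests.append(group_test_eh_vs_neh(features, feat, condition, level))
            except InsufficientDataError:
                pass
        for scope in ("rest", "task", "diff"):
            try:
                rocs.append(roc_result(features, feat, scope, level))
            except InsufficientDataError:
                pass
    tests_df = pd.DataFrame([asdict(t) for t in tests])
    rocs_df = pd.DataFrame([asdict(r) for r in rocs])
    if bh_correction and len(tests_df):
        from statsmodels.stats.multitest import multipletests

        tests_df["p_adjusted"] = multipletests(tests_df["p_value"], method="fdr_bh")[1]
        if len(rocs_df):
            rocs_df["p_adjusted"] = multipletests(rocs_df["p_vs_chance"], method="fdr_bh")[1]
    return tests_df, rocs_df
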