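"""Group-comparison statistics on individual mean probabilities.

All inference is at the individual level (n = people, not cells): each
individual contributes one number — the mean probability score of their
cells — and groups are compared by Student's t-test, individual-level
ROC/AUC, and the fold difference between group mean probabilities.  A
conventional single-feature baseline (per-individual mean of one named
feature) is included for comparison with the multi-feature scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import ProbabilityScores, aggregate_individual_means

P_FLOOR = 1e-300  # underflow-safe minimum for degenerate separations


@dataclass
class TTestResult:
    t: float
    p: float
    mean_group0: float
    mean_group1: float


def compare_groups_ttest(means_g0, means_g1,
                         equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test on individual mean probabilities.

    Student's (equal-variance) test by default; Welch via
    ``equal_var=False``.  Degenerate zero-variance inputs are guarded:
    equal means give t=0, p=1, disjoint constant groups give the
    underflow-safe minimum p.
    """
    g0 = np.asarray(means_g0, dtype=float)
    g1 = np.asarray(means_g1, dtype=float)
    if min(len(g0), len(g1)) < 2:
        raise ValueError("need >= 2 individuals per group")
    if g0.var() == 0 and g1.var() == 0:
        if g0.mean() == g1.mean():
            return TTestResult(0.0, 1.0, float(g0.mean()), float(g1.mean()))
        return TTestResult(np.inf if g1.mean() > g0.mean() else -np.inf,
                           P_FLOOR, float(g0.mean()), float(g1.mean()))
    t, p = sps.ttest_ind(g0, g1, equal_var=equal_var)
    return TTestResult(float(t), float(max(p, P_FLOOR)),
                       float(g0.mean()), float(g1.mean()))


@dataclass
class ROCResult:
    """ROC curve over individuals plus its AUC.

    ``fpr``/``tpr`` run monotonically from (0, 0) to (1, 1); ``auc`` is
    computed by the Mann-Whitney identity (ties counted half) and equals
    the trapezoidal integral of the curve.
    """

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    positive_label: object

    @property
    def trapezoid_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_individuals(individual_means, labels,
                    positive_label=None) -> ROCResult:
    """ROC analysis of per-individual mean probabilities.

    Sensitivity is plotted against 1-specificity over a sweep of score
    thresholds; AUC is the probability that a randomly chosen positive
    individual outscores a randomly chosen negative one (Mann-Whitney,
    ties = 1/2).  1.0 means a threshold exists with 100% sensitivity and
    100% specificity; 0.5 is chance.
    """
    scores = np.asarray(individual_means, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_label is None:
        positive_label = classes[-1]
    y = labels == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class is absent")

    ranks = sps.rankdata(scores)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores, sorted_y = scores[order], y[order]
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cut = np.r_[distinct, len(sorted_scores) - 1]
    tps = np.cumsum(sorted_y)[cut]
    fps = np.cumsum(~sorted_y)[cut]
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    return ROCResult(auc=float(auc), fpr=fpr, tpr=tpr,
                     positive_label=positive_label)


def fold_difference(scores: ProbabilityScores) -> float:
    """Ratio of group mean probabilities (group 1 over group 0)."""
    means = scores.cells.groupby("group")["probability"].mean()
    if len(means) != 2:
        raise ValueError("need both groups present")
    g0, g1 = means.sort_index().to_numpy()
    if g0 == 0:
        raise ValueError("group-0 mean probability is zero")
    return float(g1 / g0)


@dataclass
class FeatureComparison:
    feature: str
    mean_group0: float
    mean_group1: float
    t: float
    p: float
    fold: float


def conventional_feature_analysis(table: pd.DataFrame,
                                  feature_name: str) -> FeatureComparison:
    """Single-feature baseline: per-individual means of one raw feature.

    Aggregates the named feature to per-individual means, runs the
    Student's t-test between groups and reports the group-mean ratio —
    the conventional analysis a multi-feature probability score is
    benchmarked against.
    """
    feature_cols = [c for c in table.columns if "." in c]
    if feature_name not in table.columns:
        close = [c for c in feature_cols if feature_name in c][:10]
        raise KeyError(f"unknown feature {feature_name!r}; "
                       f"similar available: {close or feature_cols[:10]}")
    per_ind = (table.groupby("individual_id")
               .agg(value=(feature_name, "mean"), group=("group", "first")))
    g0 = per_ind.loc[per_ind["group"] == 0, "value"].to_numpy()
    g1 = per_ind.loc[per_ind["group"] == 1, "value"].to_numpy()
    res = compare_groups_ttest(g0, g1)
    if res.mean_group0 == 0:
        raise ValueError("group-0 mean is zero; fold undefined")
    return FeatureComparison(feature=feature_name,
                             mean_group0=res.mean_group0,
                             mean_group1=res.mean_group1,
                             t=res.t, p=res.p,
                             fold=res.mean_group1 / res.mean_group0)


def marker_set_report(scores: ProbabilityScores) -> dict:
    """Summary block for one marker set: t-test, ROC, fold, group means."""
    means = aggregate_individual_means(scores)
    g0 = means.loc[means["group"] == 0, "mean_probability"].to_numpy()
    g1 = means.loc[means["group"] == 1, "mean_probability"].to_numpy()
    ttest = compare_groups_ttest(g0, g1)
    roc = roc_individuals(means["mean_probability"].to_numpy(),
                          means["group"].to_numpy(), positive_label=1)
    return {
        "marker_set": scores.marker_set,
        "n_individuals": {"group0": len(g0), "group1": len(g1)},
        "mean_probability": {"group0": ttest.mean_group0,
                             "group1": ttest.mean_group1},
        "t": ttest.t, "p": ttest.p,
        "auc": roc.auc,
        "fold": fold_difference(scores),
    }
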