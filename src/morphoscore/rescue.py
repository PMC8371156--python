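"""Classifier transfer to drug-treated cells and rescue classification.

A scoring model frozen on untreated case-vs-control cells is applied,
unchanged, to drug-treated patient cells; if treatment reverts the
disease morphology, treated cells score like controls.  Per marker set,
the three groups of individual mean probabilities — untreated control,
untreated patient, treated patient — are compared by one-way ANOVA with
Tukey's HSD, and the treated group is called:

* ``rescued`` — significantly different from untreated patients AND not
  significantly different from controls;
* ``partial`` — different from neither, but its mean lies strictly
  between the patient and control means (shifted towards control);
* ``not_rescued`` — otherwise.

Both Tukey p-values are reported verbatim: near the significance
threshold the call is sensitive to alpha and should be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import (
    ProbabilityScores,
    ScoringModel,
    cross_validated_scores,
    score_cells,
)

DEFAULT_ALPHA = 0.05


@dataclass
class RescueEntry:
    """ANOVA + Tukey results for one marker set's three-group comparison."""

    marker_set: str
    f: float
    p: float
    group_means: dict  # control / patient / treated
    tukey_p: dict  # treated_vs_control / treated_vs_patient / patient_vs_control
    rescue_status: str = ""


@dataclass
class RescueReport:
    entries: dict = field(default_factory=dict)  # marker_set -> RescueEntry

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.entries.values():
            rows.append({
                "marker_set": entry.marker_set, "F": entry.f, "p": entry.p,
                **{f"mean_{k}": v for k, v in entry.group_means.items()},
                **{f"p_{k}": v for k, v in entry.tukey_p.items()},
                "rescue_status": entry.rescue_status,
            })
        return pd.DataFrame(rows)


def score_treated(model: ScoringModel,
                  treated_table: pd.DataFrame) -> ProbabilityScores:
    """Score treated cells with a frozen model (no refitting).

    Guards against leakage: refuses to score a table whose
    (individual, treatment) cells were part of the model's training data.
    """
    treated_keys = {
        (str(i), str(t)) for i, t in
        zip(treated_table["individual_id"], treated_table["treatment"])}
    overlap = treated_keys & set(model.training_keys)
    if overlap:
        raise ValueError(
            "model was trained on cells it is asked to score: "
            f"{sorted(overlap)[:5]} — refit on untreated cells only")
    return score_cells(model, treated_table)


def rescue_anova(control_means, patient_means, treated_means,
                 marker_set: str = "combined") -> RescueEntry:
    """One-way ANOVA + Tukey HSD over the three groups of individual means."""
    groups = [np.asarray(g, dtype=float)
              for g in (control_means, patient_means, treated_means)]
    if min(map(len, groups)) < 2:
        raise ValueError("need >= 2 individuals per group")
    names = ("control", "patient", "treated")
    means = {n: float(g.mean()) for n, g in zip(names, groups)}
    if all(g.var() == 0 for g in groups) and len({*map(float, np.concatenate(groups))}) == 1:
        return RescueEntry(marker_set=marker_set, f=0.0, p=1.0,
                           group_means=means,
                           tukey_p={"treated_vs_control": 1.0,
                                    "treated_vs_patient": 1.0,
                                    "patient_vs_control": 1.0})
    f, p = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    pv = tukey.pvalue  # index order: control=0, patient=1, treated=2
    return RescueEntry(
        marker_set=marker_set, f=float(f), p=float(p), group_means=means,
        tukey_p={"treated_vs_control": float(pv[2, 0]),
                 "treated_vs_patient": float(pv[2, 1]),
                 "patient_vs_control": float(pv[1, 0])})


def classify_rescue(entry: RescueEntry,
                    alpha: float = DEFAULT_ALPHA) -> str:
    """Call rescued / partial / not_rescued from the Tukey contrasts."""
    p_tc = entry.tukey_p["treated_vs_control"]
    p_tp = entry.tukey_p["treated_vs_patient"]
    m = entry.group_means
    if p_tp < alpha and p_tc >= alpha:
        status = "rescued"
    elif p_tp >= alpha and p_tc >= alpha and (
            min(m["control"], m["patient"]) < m["treated"]
            < max(m["control"], m["patient"])):
        status = "partial"
    else:
        status = "not_rescued"
    entry.rescue_status = status
    return status


def rescue_analysis(model: ScoringModel, untreated_table: pd.DataFrame,
                    treated_table: pd.DataFrame,
                    alpha: float = DEFAULT_ALPHA,
                    untreated_scoring: str = "cv") -> RescueEntry:
    """End-to-end rescue call for one marker set.

    Treated patient cells are always scored by the frozen ``model``
    (classifier transfer).  The untreated control/patient means entering
    the ANOVA are, by default, held-out cross-validated scores
    (``untreated_scoring='cv'``): scoring the training cells in-sample
    depresses the class-0 means slightly relative to transferred cells,
    a systematic offset that Tukey would misread as a treatment
    difference.  ``untreated_scoring='insample'`` reproduces the naive
    workflow.
    """
    if untreated_scoring == "cv":
        untreated = cross_validated_scores(
            untreated_table, marker_set=model.marker_set,
            n_folds=5, fold_by="individual", seed=0).individual_means
    elif untreated_scoring == "insample":
        untreated = score_cells(model, untreated_table).individual_means
    else:
        raise ValueError("untreated_scoring must be 'cv' or 'insample'")
    treated = score_treated(model, treated_table).individual_means
    control = untreated.loc[untreated["group"] == 0, "mean_probability"]
    patient = untreated.loc[untreated["group"] == 1, "mean_probability"]
    entry = rescue_anova(control.to_numpy(), patient.to_numpy(),
                         treated["mean_probability"].to_numpy(),
                         marker_set=model.marker_set)
    classify_rescue(entry, alpha)
    return entry
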