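"""Control-based feature normalization and cross-run reproducibility.

Feature values are z-scored against negative-control (healthy-control,
untreated) cells separately for every acquisition run: for feature j in
run r, x' = (x - mu_ctrl[r, j]) / sd_ctrl[r, j].  This removes per-run
affine batch effects while expressing every cell relative to the control
phenotype of its own run.  Near-zero-variance features are flagged and
passed through unscaled so the 124-column contract is preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .classify import cross_validated_scores
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

MIN_CONTROL_CELLS = 30
SD_FLOOR = 1e-12


def default_control_selector(table: pd.DataFrame) -> pd.Series:
    """Negative controls: group-0 individuals, untreated."""
    sel = table["group"] == 0
    if "treatment" in table:
        sel &= table["treatment"] == "untreated"
    return sel


@dataclass
class NormalizationParams:
    """Per (run, feature) control mean/SD; flagged where SD ~ 0."""

    stats: pd.DataFrame  # MultiIndex (run, feature) -> mean, sd, flagged

    @property
    def runs(self) -> list[str]:
        return sorted(self.stats.index.get_level_values("run").unique())

    def to_json(self, path) -> None:
        payload = [
            {"run": run, "feature": feat, "mean": row["mean"],
             "sd": row["sd"], "flagged": bool(row["flagged"])}
            for (run, feat), row in self.stats.iterrows()
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload).set_index(["run", "feature"])
        return cls(stats=df)


def fit_control_normalizer(table: pd.DataFrame,
                           control_selector: Callable[[pd.DataFrame], pd.Series]
                           = default_control_selector,
                           min_control_cells: int = MIN_CONTROL_CELLS,
                           ) -> NormalizationParams:
    """Per-run, per-feature mean/SD over negative-control cells."""
    controls = table[control_selector(table)]
    rows = []
    for run in sorted(table["run"].unique()):
        sub = controls[controls["run"] == run]
        if len(sub) == 0:
            raise ValueError(f"run {run!r} has no control cells")
        if len(sub) < min_control_cells:
            raise ValueError(
                f"run {run!r} has only {len(sub)} control cells "
                f"(< {min_control_cells})")
        x = sub[list(FEATURE_NAMES)].to_numpy(dtype=float)
        mean, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
        for feat, m, s in zip(FEATURE_NAMES, mean, sd):
            rows.append({"run": run, "feature": feat, "mean": m, "sd": s,
                         "flagged": s < SD_FLOOR})
    stats = pd.DataFrame(rows).set_index(["run", "feature"])
    n_flagged = int(stats["flagged"].sum())
    if n_flagged:
        logger.warning("%d (run, feature) pairs have near-zero control SD; "
                       "these will pass through unscaled", n_flagged)
    return NormalizationParams(stats=stats)


def apply_normalizer(table: pd.DataFrame,
                     params: NormalizationParams) -> pd.DataFrame:
    """Z-score every feature against its run's control moments."""
    missing = set(table["run"].unique()) - set(params.runs)
    if missing:
        raise ValueError(f"normalizer has no parameters for runs: {sorted(missing)}")
    out = table.copy()
    for run, sub_idx in table.groupby("run").groups.items():
        stats = params.stats.loc[run].reindex(list(FEATURE_NAMES))
        mean = stats["mean"].to_numpy()
        sd = stats["sd"].to_numpy().copy()
        flagged = stats["flagged"].to_numpy(dtype=bool)
        sd[flagged] = 1.0
        mean = np.where(flagged, 0.0, mean)
        x = out.loc[sub_idx, list(FEATURE_NAMES)].to_numpy(dtype=float)
        out.loc[sub_idx, list(FEATURE_NAMES)] = (x - mean) / sd
    return out


@dataclass
class ReproducibilityReport:
    """Per-individual mean run-discrimination probabilities and verdict."""

    per_individual: pd.DataFrame  # individual_id, mean_run_a, mean_run_b, diff
    max_difference: float
    margin: float
    reproducible: bool


def run_reproducibility_check(table_a: pd.DataFrame, table_b: pd.DataFrame,
                              margin: float = 0.05) -> ReproducibilityReport:
    """Can a classifier tell two acquisition runs of the same lines apart?

    Fits run-A-vs-run-B logistic regression on the combined features and
    reports each individual's mean probability in each run.  Cells are
    scored held-out (cell-level cross-validation), since in-sample fitted
    probabilities always separate the two coded classes a little even
    when the runs are exchangeable.  If the runs are exchangeable the
    held-out scores hover near 0.5 in both runs and the per-individual
    run difference stays under ``margin`` (reproducible); a batch shift
    drives the runs to opposite ends of the scale.
    """
    shared = set(table_a["individual_id"]) & set(table_b["individual_id"])
    if not shared:
        raise ValueError("runs share no individuals")
    a = table_a[table_a["individual_id"].isin(shared)].copy()
    b = table_b[table_b["individual_id"].isin(shared)].copy()
    a["group"], b["group"] = 0, 1  # run coded as the class to discriminate
    combined = pd.concat([a, b], ignore_index=True)
    scores = cross_validated_scores(combined, group_coding={0: 0, 1: 1},
                                    marker_set="combined", n_folds=5,
                                    fold_by="cell", seed=0)
    per_run = []
    for code, name in ((0, "mean_run_a"), (1, "mean_run_b")):
        sub = scores.cells[scores.cells["group"] == code]
        means = (sub.groupby("individual_id")["probability"].mean()
                 .rename(name))
        per_run.append(means)
    report = pd.concat(per_run, axis=1).reset_index()
    report["diff"] = (report["mean_run_a"] - report["mean_run_b"]).abs()
    max_diff = float(report["diff"].max())
    return ReproducibilityReport(per_individual=report,
                                 max_difference=max_diff, margin=margin,
                                 reproducible=max_diff < margin)
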