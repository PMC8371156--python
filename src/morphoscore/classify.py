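"""Per-cell binary logistic-regression scoring.

The central statistic of the pipeline: a maximum-likelihood logistic
regression fitted on standardized per-cell features of a chosen marker
subset, with the two groups coded 0/1.  Every cell receives a probability
score in [0, 1] — its resemblance to the group coded 1 — and individuals
are summarised by the arithmetic mean of their cells' scores, which is
the unit of all downstream group statistics and ROC analysis.

Fitting is unpenalized ML by default (Newton-Raphson via statsmodels);
on quasi-separation or a singular Hessian the fit falls back to a tiny
ridge penalty (1e-6) and logs a warning.  Standardization constants are
stored inside the model so that a frozen model can be transferred to new
(e.g. drug-treated) cells unchanged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .features import marker_columns

logger = logging.getLogger(__name__)

RIDGE_ALPHA = 1e-6  # fallback penalty under separation
MIN_CELLS_PER_CLASS = 10


@dataclass
class ScoringModel:
    """A fitted logistic scorer: weights + standardization + group coding."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    std_mean: np.ndarray
    std_sd: np.ndarray
    marker_set: str
    coding: dict  # group label -> 0/1
    penalized: bool = False
    training_keys: frozenset = dc_field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.std_mean = np.asarray(self.std_mean, dtype=float)
        self.std_sd = np.asarray(self.std_sd, dtype=float)
        if len(self.coef) != len(self.feature_names):
            raise ValueError("coefficient/feature-name length mismatch")
        if np.any(self.std_sd <= 0):
            raise ValueError("standardization SDs must be > 0")

    def decision(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.std_mean) / self.std_sd
        return self.intercept + z @ self.coef

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "std_mean": self.std_mean.tolist(),
            "std_sd": self.std_sd.tolist(),
            "marker_set": self.marker_set,
            "coding": {str(k): v for k, v in self.coding.items()},
            "penalized": self.penalized,
            "training_keys": sorted(map(list, self.training_keys)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScoringModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload["training_keys"] = frozenset(
            tuple(k) for k in payload.pop("training_keys"))
        return cls(**payload)


@dataclass
class ProbabilityScores:
    """Per-cell probabilities plus metadata; individual means on demand."""

    cells: pd.DataFrame  # columns: probability, individual_id, group, treatment
    marker_set: str

    def __post_init__(self) -> None:
        p = self.cells["probability"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def individual_means(self) -> pd.DataFrame:
        return aggregate_individual_means(self)


def _design(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks feature columns: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    x = table[columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = [c for c in columns
               if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite feature values in columns: {bad[:5]}")
    return x


def fit_cell_classifier(table: pd.DataFrame, group_coding: dict | None = None,
                        marker_set: str = "combined",
                        group_column: str = "group") -> ScoringModel:
    """Fit the per-cell logistic scorer on one marker subset.

    ``group_coding`` maps the two group labels to {0, 1}; by default the
    two sorted unique labels are coded 0 and 1 respectively.  Features are
    standardized to the training cells' mean/SD inside the model.
    """
    columns = marker_columns(marker_set)
    x = _design(table, columns)
    groups = table[group_column]
    if group_coding is None:
        levels = sorted(pd.unique(groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {levels}")
        group_coding = {levels[0]: 0, levels[1]: 1}
    y = groups.map(group_coding).to_numpy()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both coded classes must be present")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n0, n1) < MIN_CELLS_PER_CLASS:
        raise ValueError(f"need >= {MIN_CELLS_PER_CLASS} cells per class "
                         f"(got {n0} vs {n1})")

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    flat = sd <= 0
    if flat.any():
        logger.warning("%d zero-variance features passed through unscaled",
                       int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
    z = (x - mean) / sd

    coef, intercept, penalized = _ml_logistic(z, y)
    keys = frozenset(
        (str(i), str(t)) for i, t in
        zip(table.get("individual_id", pd.Series(["?"] * len(table))),
            table.get("treatment", pd.Series(["untreated"] * len(table)))))
    return ScoringModel(feature_names=columns, coef=coef,
                        intercept=float(intercept), std_mean=mean, std_sd=sd,
                        marker_set=marker_set,
                        coding={k: int(v) for k, v in group_coding.items()},
                        penalized=penalized, training_keys=keys)


def _ml_logistic(z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Unpenalized ML fit; tiny-ridge fallback on separation/singularity."""
    design = sm.add_constant(z, has_constant="add")
    try:
        with warnings.catch_warnings():
            for category in (RuntimeWarning, ConvergenceWarning,
                             PerfectSeparationWarning):
                warnings.simplefilter("error", category=category)
            res = sm.Logit(y, design).fit(disp=0, method="newton",
                                          maxiter=100, tol=1e-12)
        params = np.asarray(res.params)
        if np.all(np.isfinite(params)) and res.mle_retvals.get("converged", True):
            return params[1:], params[0], False
        raise np.linalg.LinAlgError("non-finite or unconverged ML fit")
    except Exception as exc:  # PerfectSeparation, LinAlgError, overflow
        logger.warning("ML logistic fit failed (%s); refitting with ridge "
                       "penalty %.0e", type(exc).__name__, RIDGE_ALPHA)
        clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="newton-cholesky",
                                 max_iter=200, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(z, y)
        return clf.coef_[0], float(clf.intercept_[0]), True


def cross_validated_scores(table: pd.DataFrame, group_coding: dict | None = None,
                           marker_set: str = "combined", n_folds: int = 5,
                           fold_by: str = "individual",
                           seed: int = 0) -> ProbabilityScores:
    """Held-out per-cell probability scores via k-fold cross-validation.

    The default in-sample workflow (fit on all cells, score the same
    cells) is optimistically biased at the individual level: fitted
    class-1 cells always average above class-0 in-sample, and per-person
    averaging removes the noise, so even a signal-free cohort separates
    perfectly.  Honest individual-level inference needs each cell scored
    by a model that never saw it — and, because cells of one person share
    that person's random effect, folds must hold out whole individuals
    (``fold_by='individual'``); ``fold_by='cell'`` folds at the cell
    level instead.
    """
    if n_folds < 2:
        raise ValueError("need >= 2 folds")
    rng = np.random.default_rng(seed)
    if fold_by == "individual":
        units = table["individual_id"].to_numpy()
    elif fold_by == "cell":
        units = np.arange(len(table))
    else:
        raise ValueError("fold_by must be 'individual' or 'cell'")
    # stratify folds by group: otherwise a fold rich in one class leaves
    # a class-poor training set whose intercept shifts every score in the
    # fold, biasing the individual-level AUC below 0.5 under the null
    group_of_unit = (table.groupby(table["individual_id"] if fold_by == "individual"
                                   else units)["group"].first())
    fold_of_unit: dict = {}
    for _, members in group_of_unit.groupby(group_of_unit):
        ids = rng.permutation(np.asarray(members.index, dtype=object))
        for pos, unit in enumerate(ids):
            fold_of_unit[unit] = pos % n_folds
    folds = np.array([fold_of_unit[u] for u in units])

    pieces = []
    for fold in range(n_folds):
        train, test = table[folds != fold], table[folds == fold]
        if len(test) == 0:
            continue
        model = fit_cell_classifier(train, group_coding=group_coding,
                                    marker_set=marker_set)
        scored = score_cells(model, test).cells
        scored.index = test.index
        pieces.append(scored)
    cells = pd.concat(pieces).sort_index()
    return ProbabilityScores(cells=cells, marker_set=marker_set)


def score_cells(model: ScoringModel, table: pd.DataFrame) -> ProbabilityScores:
    """Score cells with a fitted model (stored standardization, no refit)."""
    x = _design(table, model.feature_names)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-model.decision(x)))
    cells = pd.DataFrame({
        "probability": p,
        "individual_id": table.get("individual_id", "unknown"),
        "group": table.get("group", -1),
        "treatment": table.get("treatment", "untreated"),
    })
    return ProbabilityScores(cells=cells, marker_set=model.marker_set)


def aggregate_individual_means(scores: ProbabilityScores) -> pd.DataFrame:
    """One row per individual: mean probability, cell count, group label."""
    cells = scores.cells
    if cells["individual_id"].isna().any():
        raise ValueError("every cell needs an individual_id")
    agg = (cells.groupby("individual_id", sort=True)
           .agg(mean_probability=("probability", "mean"),
                n_cells=("probability", "size"),
                group=("group", "first"),
                treatment=("treatment", "first"))
           .reset_index())
    return agg


def probability_histogram(scores: ProbabilityScores,
                          bins: int = 50) -> dict:
    """Per-group histogram of cell scores over [0, 1] plus group means.

    Returns ``{"edges": ..., "counts": {group: ...}, "means": {group: ...}}``
    — the counts draw the histogram, the means are the dotted-line markers.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, means = {}, {}
    for group, sub in scores.cells.groupby("group"):
        p = sub["probability"].to_numpy()
        counts[group] = np.histogram(p, bins=edges)[0]
        means[group] = float(p.mean())
    return {"edges": edges, "counts": counts, "means": means}
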