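"""Boosted-tree behaviour-probability models.

Two binary gradient-boosted tree (BRT) classifiers drive the movement
simulator:

* the **follow-the-flow** model — probability that a smolt's next step is
  flow-aligned, given the departure cell's (u, v, w, TKE);
* the **swim-direction** model — given a non-flow-aligned step, probability
  that the fish picks a fresh random heading (searching) rather than keeping
  its previous heading (directional burst).

Hyperparameters (shrinkage/learning rate, tree complexity/interaction depth,
number of boosting trees) are tuned by stratified k-fold cross-validation
over a grid of learning rates × depths, choosing the number of trees by
early stopping on held-out Bernoulli deviance.  The tuning loss (mean
Bernoulli deviance) and the discrimination statistic (AUC) are implemented
here and cross-checked against brute-force oracles in the test suite.

The boosting engine is scikit-learn's ``GradientBoostingClassifier``;
per-predictor *relative influence* is its impurity-based split-gain
attribution normalised to percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .hydraulic_field import PREDICTOR_NAMES, HydraulicCell

#: learning-rate grid spanning the conventional shrinkage range
DEFAULT_LEARNING_RATES: tuple[float, ...] = (0.01, 0.025, 0.005, 0.0025, 0.001)
#: tree complexities (interaction depths) 1..9
DEFAULT_TREE_COMPLEXITIES: tuple[int, ...] = tuple(range(1, 10))

PROB_CLIP = 1e-12
PRED_CLIP = 1e-9  # predictions are reported strictly inside (0, 1)


class ModelFitError(ValueError):
    """Raised when a training table cannot support a fit (empty/single-class)."""


@dataclass(frozen=True)
class BRTHyperparams:
    """One boosted-tree configuration.

    ``learning_rate`` is the per-tree shrinkage, ``tree_complexity`` the
    maximum depth of each tree (interaction order), ``n_trees`` the number
    of boosting iterations.
    """

    learning_rate: float
    tree_complexity: int
    n_trees: int

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class CVRecord:
    hyperparams: BRTHyperparams
    cv_deviance: float
    cv_auc: float
    train_deviance: float
    train_auc: float


@dataclass
class CVResult:
    """All grid evaluations plus the selected configuration.

    ``best`` minimises cross-validated deviance; ties break towards higher
    cross-validated AUC, then fewer trees.
    """

    records: list[CVRecord]
    best: BRTHyperparams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "learning_rate": [r.hyperparams.learning_rate for r in self.records],
                "tree_complexity": [r.hyperparams.tree_complexity for r in self.records],
                "n_trees": [r.hyperparams.n_trees for r in self.records],
                "cv_deviance": [r.cv_deviance for r in self.records],
                "cv_auc": [r.cv_auc for r in self.records],
                "train_deviance": [r.train_deviance for r in self.records],
                "train_auc": [r.train_auc for r in self.records],
            }
        )


@dataclass
class FittedBehaviorModel:
    """A tuned boosted-tree behaviour classifier.

    ``influence`` maps each predictor to its percent contribution
    (non-negative, summing to 100).
    """

    model_kind: str  # "follow_the_flow" | "swim_direction"
    hyperparams: BRTHyperparams
    estimator: GradientBoostingClassifier
    influence: dict[str, float]
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    seed: int | None = None
    training_fingerprint: str | None = None

    def predict_prob(self, hydraulics: HydraulicCell | Sequence[float]) -> float:
        """Behaviour probability for one cell's (u, v, w, tke)."""
        x = np.asarray(hydraulics, dtype=float).reshape(1, -1)
        if not np.all(np.isfinite(x)):
            raise ValueError("hydraulics contain absent/non-finite predictors")
        p = self.estimator.predict_proba(x)[0, 1]
        return float(np.clip(p, PRED_CLIP, 1.0 - PRED_CLIP))

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        """Vectorised probabilities for a frame with u, v, w, tke columns."""
        x = table[list(self.predictor_names)].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("hydraulics contain absent/non-finite predictors")
        p = self.estimator.predict_proba(x)[:, 1]
        return np.clip(p, PRED_CLIP, 1.0 - PRED_CLIP)


# -- performance metrics ----------------------------------------------------


def bernoulli_deviance(y: Sequence[int], p: Sequence[float]) -> float:
    """Mean Bernoulli deviance, −2·mean(y·ln p + (1−y)·ln(1−p)).

    Probabilities are clipped to [1e-12, 1−1e-12] for numeric safety.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("y and p must be non-empty vectors of equal length")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def auc(y: Sequence[int], p: Sequence[float]) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half.  Requires both classes present.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(p)  # average ranks handle ties as 1/2
    u_stat = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u_stat / (n1 * n0)


def overfitting_gap(cv_deviance: float, train_deviance: float) -> float:
    """Percent excess of cross-validated over training deviance.

    ``100 · (cv_deviance / train_deviance − 1)``; the standard summary of
    how much a boosted model overfits its training data.
    """
    if train_deviance <= 0:
        raise ValueError("train_deviance must be positive")
    return 100.0 * (cv_deviance / train_deviance - 1.0)


# -- tuning and fitting -----------------------------------------------------


def _split_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, str]:
    response = [c for c in table.columns if c not in PREDICTOR_NAMES]
    if len(response) != 1:
        raise ModelFitError(f"expected predictors {PREDICTOR_NAMES} plus one response column")
    y = table[response[0]].to_numpy(dtype=int)
    x = table[list(PREDICTOR_NAMES)].to_numpy(dtype=float)
    return x, y, response[0]


def _check_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if table is None or len(table) == 0:
        raise ModelFitError("training table is empty (no steps of this kind observed)")
    x, y, _ = _split_table(table)
    if len(np.unique(y)) < 2:
        raise ModelFitError("training table is single-class; cannot fit a classifier")
    return x, y


def tune_brt(
    table: pd.DataFrame,
    lr_grid: Sequence[float] = DEFAULT_LEARNING_RATES,
    depth_grid: Sequence[int] = DEFAULT_TREE_COMPLEXITIES,
    k: int = 10,
    seed: int | None = None,
    max_trees: int = 10_000,
    patience: int = 50,
) -> CVResult:
    """Grid search over (learning rate, tree complexity) with k-fold CV.

    For each grid point the boosting ensembles of all folds are grown in
    lock-step increments of ``patience`` trees; the held-out deviance
    (averaged over folds) is evaluated at each increment and growth stops
    once it fails to improve for a full increment, up to ``max_trees``.
    The tree count at the minimum mean held-out deviance becomes that grid
    point's ``n_trees``.  With the default grids, 5 learning rates × 9
    depths = 45 combinations are evaluated.

    Returns every grid record plus the best configuration (minimum CV
    deviance; ties towards higher CV AUC, then fewer trees).
    """
    x, y = _check_table(table)
    if len(y) < k:
        raise ModelFitError(f"need at least k={k} rows for {k}-fold CV, got {len(y)}")
    patience = max(1, int(patience))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))

    records: list[CVRecord] = []
    for lr in lr_grid:
        for depth in depth_grid:
            records.append(
                _evaluate_combo(x, y, folds, float(lr), int(depth), seed, max_trees, patience)
            )

    best = min(
        records,
        key=lambda r: (r.cv_deviance, -r.cv_auc, r.hyperparams.n_trees),
    ).hyperparams
    return CVResult(records=records, best=best)


def _evaluate_combo(
    x: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    lr: float,
    depth: int,
    seed: int | None,
    max_trees: int,
    step: int,
) -> CVRecord:
    """Grow all folds of one (lr, depth) combination with early stopping."""
    clfs = []
    for tr, _ in folds:
        clf = GradientBoostingClassifier(
            learning_rate=lr,
            max_depth=depth,
            n_estimators=0,
            warm_start=True,
            random_state=seed,
        )
        clfs.append(clf)

    # per checkpoint: mean over folds of (val dev, val auc, train dev, train auc)
    checkpoints: list[tuple[int, float, float, float, float]] = []
    best_dev = np.inf
    n = 0
    while n < max_trees:
        n = min(n + step, max_trees)
        stats = np.zeros(4)
        for clf, (tr, va) in zip(clfs, folds):
            clf.n_estimators = n
            clf.fit(x[tr], y[tr])
            p_va = clf.predict_proba(x[va])[:, 1]
            p_tr = clf.predict_proba(x[tr])[:, 1]
            stats += [
                bernoulli_deviance(y[va], p_va),
                _safe_auc(y[va], p_va),
                bernoulli_deviance(y[tr], p_tr),
                _safe_auc(y[tr], p_tr),
            ]
        stats /= len(folds)
        checkpoints.append((n, *stats))
        if stats[0] < best_dev - 1e-12:
            best_dev = stats[0]
        else:  # no improvement over a full increment: stop growing
            break

    n_best, cv_dev, cv_auc, tr_dev, tr_auc = min(checkpoints, key=lambda c: (c[1], c[0]))
    return CVRecord(
        hyperparams=BRTHyperparams(learning_rate=lr, tree_complexity=depth, n_trees=n_best),
        cv_deviance=float(cv_dev),
        cv_auc=float(cv_auc),
        train_deviance=float(tr_dev),
        train_auc=float(tr_auc),
    )


def _safe_auc(y: np.ndarray, p: np.ndarray) -> float:
    try:
        return auc(y, p)
    except ValueError:  # a fold may be single-class at extreme imbalance
        return np.nan


def fit_brt(
    table: pd.DataFrame,
    hyperparams: BRTHyperparams,
    seed: int | None = None,
    model_kind: str = "follow_the_flow",
) -> FittedBehaviorModel:
    """Fit the final boosted-tree model on all rows of a training table.

    Deterministic for a fixed seed.  Relative influence is the ensemble's
    split-gain importance normalised to percent (uniform 25% per predictor
    when no split carries any gain).
    """
    x, y = _check_table(table)
    clf = GradientBoostingClassifier(
        learning_rate=hyperparams.learning_rate,
        max_depth=hyperparams.tree_complexity,
        n_estimators=hyperparams.n_trees,
        random_state=seed,
    )
    clf.fit(x, y)
    raw = np.asarray(clf.feature_importances_, dtype=float)
    total = raw.sum()
    if total > 0:
        influence = 100.0 * raw / total
    else:
        influence = np.full(len(PREDICTOR_NAMES), 100.0 / len(PREDICTOR_NAMES))
    fingerprint = f"n={len(y)};pos={int(y.sum())};xsum={float(np.sum(x)):.6g}"
    return FittedBehaviorModel(
        model_kind=model_kind,
        hyperparams=hyperparams,
        estimator=clf,
        influence={name: float(v) for name, v in zip(PREDICTOR_NAMES, influence)},
        seed=seed,
        training_fingerprint=fingerprint,
    )


def predict_prob(model: FittedBehaviorModel, hydraulics: HydraulicCell) -> float:
    """Functional form of :meth:`FittedBehaviorModel.predict_prob`."""
    return model.predict_prob(hydraulics)


def relative_influence(model: FittedBehaviorModel) -> list[tuple[str, float]]:
    """Predictors ranked by percent influence, descending; sums to 100."""
    return sorted(model.influence.items(), key=lambda kv: -kv[1])


# -- serialisation ----------------------------------------------------------


def save_model(model: FittedBehaviorModel, path: str | Path) -> None:
    """Serialise a fitted model; a JSON sidecar carries the metadata."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "model_kind": model.model_kind,
        "hyperparams": {
            "learning_rate": model.hyperparams.learning_rate,
            "tree_complexity": model.hyperparams.tree_complexity,
            "n_trees": model.hyperparams.n_trees,
        },
        "influence": model.influence,
        "predictor_names": list(model.predictor_names),
        "seed": model.seed,
        "training_fingerprint": model.training_fingerprint,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path: str | Path) -> FittedBehaviorModel:
    path = Path(path)
    estimator = joblib.load(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    hp = sidecar["hyperparams"]
    return FittedBehaviorModel(
        model_kind=sidecar["model_kind"],
        hyperparams=BRTHyperparams(
            learning_rate=hp["learning_rate"],
            tree_complexity=hp["tree_complexity"],
            n_trees=hp["n_trees"],
        ),
        estimator=estimator,
        influence=sidecar["influence"],
        predictor_names=tuple(sidecar["predictor_names"]),
        seed=sidecar.get("seed"),
        training_fingerprint=sidecar.get("training_fingerprint"),
    )
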