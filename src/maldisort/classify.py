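"""Gradient-boosted tree training and the hyperparameter trial grid.

A trial is one (n_trees, n_feature_bins, learning_rate) configuration:
train on the training feature table, predict the held-out scoring table,
and report sens/spc/J.  The default grid is the full cross product
{50, 101, 401, 701} x {20, 40} x {0.01, 1e-4, 1e-5} (24 trials); a 12-trial
preset restricts to n_feature_bins = 20.

The backend is sklearn's histogram gradient-boosted trees, whose max_bins
parameter is exactly the "number of bins" knob (histogram discretization
granularity of feature values during tree construction); for binary feature
tables it is a no-op, which is logged.  Training rows are canonically sorted
by spot_id before fitting so predictions are invariant to row order.
"""

from __future__ import annotations

import itertools
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .binning import FeatureTable
from .evaluate import EvalResult, confusion, sens_spc_j

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "positive"

GRID_N_TREES = (50, 101, 401, 701)
GRID_N_FEATURE_BINS = (20, 40)
GRID_LEARNING_RATES = (0.01, 0.0001, 0.00001)


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int
    learning_rate: float
    n_feature_bins: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.n_feature_bins < 2:
            raise ValueError("n_feature_bins must be >= 2")


@dataclass
class TrainedModel:
    estimator: HistGradientBoostingClassifier
    columns: tuple[str, ...]
    config: ClassifierConfig
    positive_label: str = POSITIVE_LABEL

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train(table: FeatureTable, config: ClassifierConfig) -> TrainedModel:
    """Fit a gradient-boosted ensemble on a feature table.

    Deterministic: the same table, config and seed give identical
    predictions.  Requires at least one spot per class and no missing values.
    """
    classes = set(table.labels.unique())
    if len(classes) < 2:
        raise ValueError(f"training table has a single class {classes}; need two")
    if table.data.isna().any().any():
        raise ValueError("training table contains missing values")
    # canonical row order -> row-order invariance regardless of backend details
    order = table.data.index.argsort(kind="stable")
    X = table.data.iloc[order].to_numpy(dtype=float)
    y = (table.labels.iloc[order] == POSITIVE_LABEL).to_numpy(dtype=int)
    if table.encoding == "binary":
        logger.debug("binary features: n_feature_bins=%d is a no-op", config.n_feature_bins)
    est = HistGradientBoostingClassifier(
        max_iter=config.n_trees,
        learning_rate=config.learning_rate,
        max_bins=config.n_feature_bins,
        early_stopping=False,
        random_state=config.seed,
        # spot datasets are small (tens of rows per class); the backend's
        # big-data default of 20 rows per leaf would forbid any split on
        # small training tables
        min_samples_leaf=5,
    )
    est.fit(X, y)
    return TrainedModel(estimator=est, columns=tuple(table.data.columns), config=config)


def predict(model: TrainedModel, table: FeatureTable) -> pd.DataFrame:
    """Per-spot dichotomous prediction and positive-class score.

    Score-table columns may be reordered; missing bins are filled with 0
    (warned); columns absent from the training space are an error.  The
    predicted label is 'positive' iff the positive-class score is >= 0.5.
    """
    want = list(model.columns)
    have = list(table.data.columns)
    extra = sorted(set(have) - set(want))
    if extra:
        raise ValueError(
            f"score table has {len(extra)} column(s) unknown to the model, "
            f"e.g. {extra[:3]}"
        )
    missing = [c for c in want if c not in set(have)]
    data = table.data
    if missing:
        logger.warning("score table missing %d training bin(s); filling with 0",
                       len(missing))
        data = data.reindex(columns=want, fill_value=0.0)
    else:
        data = data[want]
    proba = model.estimator.predict_proba(data.to_numpy(dtype=float))
    pos_idx = list(model.estimator.classes_).index(1)
    score = proba[:, pos_idx]
    label = np.where(score >= 0.5, POSITIVE_LABEL, "negative")
    return pd.DataFrame({"predicted": label, "score": score}, index=data.index)


def default_grid(preset: str = "full24", seed: int = 0) -> list[ClassifierConfig]:
    """The hyperparameter grid.

    'full24' is the complete 4x2x3 cross product; 'bins20x12' restricts to
    n_feature_bins = 20 (all tree counts x all learning rates, 12 trials).
    """
    if preset == "full24":
        bins = GRID_N_FEATURE_BINS
    elif preset == "bins20x12":
        bins = (20,)
    else:
        raise ValueError(f"unknown grid preset {preset!r}")
    return [
        ClassifierConfig(n_trees=t, learning_rate=lr, n_feature_bins=b, seed=seed)
        for t, b, lr in itertools.product(GRID_N_TREES, bins, GRID_LEARNING_RATES)
    ]


@dataclass(frozen=True)
class TrialOutcome:
    config: ClassifierConfig
    result: EvalResult | None
    error: str | None = None


@dataclass
class TrialGridResult:
    trials: tuple[TrialOutcome, ...]

    @property
    def results(self) -> list[EvalResult]:
        return [t.result for t in self.trials if t.result is not None]

    @property
    def js(self) -> list[float]:
        return [r.j for r in self.results]

    def __len__(self) -> int:
        return len(self.trials)


def run_grid(train_table: FeatureTable, score_table: FeatureTable,
             grid: Sequence[ClassifierConfig] | None = None,
             seed: int = 0) -> TrialGridResult:
    """Train and score one trial per config; a failed trial is recorded,
    not fatal."""
    if grid is None:
        grid = default_grid(seed=seed)
    outcomes = []
    for cfg in grid:
        try:
            model = train(train_table, cfg)
            pred = predict(model, score_table)
            c = confusion(pred["predicted"], score_table.labels)
            outcomes.append(TrialOutcome(config=cfg, result=sens_spc_j(c, config=cfg)))
        except Exception as exc:  # noqa: BLE001 - per-trial isolation
            logger.warning("trial %s failed: %s", cfg, exc)
            outcomes.append(TrialOutcome(config=cfg, result=None, error=str(exc)))
    return TrialGridResult(trials=tuple(outcomes))
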