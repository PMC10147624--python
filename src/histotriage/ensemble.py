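"""Tile-level classifier ensemble and percentile slide aggregation.

Slide-level mutation risk is predicted in three steps: (1) an ensemble of
three small feed-forward networks scores every tile, (2) member outputs are
averaged per tile, (3) the slide score is the 99th percentile of its tile
scores.  The high percentile reflects the assumption that mutation-related
morphology shows in a minority of tiles: a slide is suspicious if its most
suspicious tiles are, not if its average tile is.

Every tile inherits the label of its slide during training.  The
classifier is pluggable: the default is the multilayer perceptron
(hidden layers 64 and 16, ReLU, sigmoid output, Adam at 1e-4, binary
cross-entropy, 5 epochs, batches of 32); a logistic-regression base is
provided for fast tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cohort import Cohort

__all__ = ["MLPConfig", "TileEnsembleClassifier", "train_ensemble",
           "predict_tiles", "aggregate_slide", "score_slides_by_model"]

SLIDE_PERCENTILE = 99.0


@dataclass
class MLPConfig:
    """Hyper-parameters of the tile ensemble (defaults as used throughout)."""

    hidden_sizes: tuple[int, int] = (64, 16)
    epochs: int = 5
    learning_rate: float = 1e-4
    ensemble_size: int = 3
    batch_size: int = 32
    base: str = "mlp"  # "mlp" | "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_sizes) <= 0 or self.epochs <= 0 \
                or self.ensemble_size <= 0 or self.batch_size <= 0:
            raise ValueError("all counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.base not in {"mlp", "logistic"}:
            raise ValueError(f"unknown base classifier {self.base!r}")


class TileEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Seeded ensemble of tile classifiers with averaged probabilities.

    scikit-learn estimator: ``fit(X, y)`` trains ``ensemble_size``
    independently initialized members on the same tiles;
    ``predict_proba(X)[:, 1]`` is the arithmetic mean of member
    probabilities, bounded in (0, 1).

    Parameters
    ----------
    hidden_sizes : tuple of int
        Widths of the two hidden ReLU layers (MLP base only).
    epochs : int
        Training epochs per member.
    learning_rate : float
        Adam step size.
    ensemble_size : int
        Number of members (3 by default).
    batch_size : int
    base : {"mlp", "logistic"}
        Member architecture; logistic regression is a fast stand-in
        honouring the same contract (scores in (0, 1)).
    random_state : int, RandomState or None
        Seeds member initialization and batch shuffling.

    Attributes
    ----------
    estimators_ : list
        The fitted ensemble members.
    classes_ : ndarray of shape (2,)
    """

    def __init__(self, hidden_sizes=(64, 16), epochs=5, learning_rate=1e-4,
                 ensemble_size=3, batch_size=32, base="mlp",
                 random_state=None):
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.ensemble_size = ensemble_size
        self.batch_size = batch_size
        self.base = base
        self.random_state = random_state

    def _member(self, seed: int):
        if self.base == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=tuple(self.hidden_sizes),
                activation="relu", solver="adam",
                learning_rate_init=self.learning_rate,
                batch_size=self.batch_size, max_iter=self.epochs,
                shuffle=True, random_state=seed)
        if self.base == "logistic":
            return LogisticRegression(max_iter=200, random_state=seed)
        raise ValueError(f"unknown base classifier {self.base!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training tiles contain a single class; "
                             "both labels are required")
        if self.ensemble_size <= 0 or self.epochs <= 0:
            raise ValueError("ensemble_size and epochs must be positive")
        rng = check_random_state(self.random_state)
        seeds = rng.randint(np.iinfo(np.int32).max, size=self.ensemble_size)
        self.estimators_ = []
        with warnings.catch_warnings():
            # few epochs by design; the optimizer is not expected to converge
            warnings.simplefilter("ignore", ConvergenceWarning)
            for s in seeds:
                self.estimators_.append(self._member(int(s)).fit(X, y))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        probs = np.mean([m.predict_proba(X) for m in self.estimators_], axis=0)
        return probs

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def train_ensemble(X, y, config: MLPConfig | None = None) -> TileEnsembleClassifier:
    """Fit a :class:`TileEnsembleClassifier` from an :class:`MLPConfig`."""
    config = config or MLPConfig()
    model = TileEnsembleClassifier(
        hidden_sizes=config.hidden_sizes, epochs=config.epochs,
        learning_rate=config.learning_rate, ensemble_size=config.ensemble_size,
        batch_size=config.batch_size, base=config.base,
        random_state=config.seed)
    return model.fit(X, y)


def predict_tiles(model: TileEnsembleClassifier, X) -> np.ndarray:
    """Per-tile risk score: ensemble-averaged positive-class probability."""
    return model.predict_proba(X)[:, 1]


def aggregate_slide(tile_scores, percentile: float = SLIDE_PERCENTILE) -> float:
    """Slide score: the 99th percentile of its tile scores.

    Linear interpolation between closest ranks (position ``(n-1) * 0.99``
    between order statistics); a single tile returns its own score.
    """
    tile_scores = np.asarray(tile_scores, dtype=float)
    if tile_scores.size == 0:
        raise ValueError("cannot aggregate an empty tile list")
    return float(np.percentile(tile_scores, percentile))


def _tile_matrix(tiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    feature_cols = [c for c in tiles.columns if c.startswith("f")
                    and c[1:].isdigit()]
    if not feature_cols:
        raise ValueError("tile table carries no feature columns (f0..fd)")
    return tiles[feature_cols].to_numpy(dtype=float), feature_cols


def score_slides_by_model(cohort: Cohort, gene: str, train_mask: np.ndarray,
                          config: MLPConfig | None = None,
                          percentile: float = SLIDE_PERCENTILE) -> pd.Series:
    """Train the ensemble on the train-side tiles, score every slide.

    Tiles inherit their slide's label for training.  Returns a Series of
    slide scores (percentile-aggregated tile predictions) indexed by
    ``slide_id``, covering all slides of the cohort.
    """
    if cohort.tiles is None:
        raise ValueError("cohort has no tile table")
    labels = pd.Series(cohort.labels(gene), index=cohort.slide_ids())
    train_ids = set(cohort.slide_ids()[np.asarray(train_mask)])

    X_all, _ = _tile_matrix(cohort.tiles)
    tile_slide = cohort.tiles["slide_id"].to_numpy()
    in_train = np.isin(tile_slide, list(train_ids))
    y_train = labels.loc[tile_slide[in_train]].to_numpy()

    model = train_ensemble(X_all[in_train], y_train, config)
    tile_pred = predict_tiles(model, X_all)
    return (pd.Series(tile_pred)
            .groupby(tile_slide)
            .apply(lambda s: aggregate_slide(s.to_numpy(), percentile))
            .reindex(cohort.slide_ids()))
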