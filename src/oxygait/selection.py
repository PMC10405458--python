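"""Hybrid filter/embedded feature selection and autoencoder reduction.

Stage 1 (filter): each feature's absolute Pearson correlation p with the
staircase target; only features with p strictly greater than the threshold
(default 0.3) survive.  Stage 2 (embedded): a gradient-boosted regression
tree ensemble is fitted on the retained features and its per-feature
importances serve as the embedded coefficients c.  The two are combined by
the harmonic-mean score

    f_score = 2 p |c| / (p + |c|)

and the top-k features by f_score form the new feature space, which an
autoencoder then compresses to latent_dim columns.

The whole selector is fitted on training rows only and applied frozen to
validation/test rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .core import ConfigurationError, InputError
from .nn import Autoencoder

logger = logging.getLogger(__name__)

PEARSON_THRESHOLD = 0.3


@dataclass
class SelectionConfig:
    pearson_threshold: float = PEARSON_THRESHOLD
    top_k: int = 100
    latent_dim: int = 20
    gbt_n_estimators: int = 100
    gbt_max_depth: int = 3
    gbt_learning_rate: float = 0.1
    ae_max_epochs: int = 200
    ae_patience: int = 8
    seed: int = 0


def pearson_screen(
    features: pd.DataFrame, target: np.ndarray, threshold: float = PEARSON_THRESHOLD
) -> pd.Series:
    """Absolute Pearson correlation of every feature column with the target.

    Returns the p values of the retained columns (p > threshold, strictly).
    Zero-variance features get p = 0 and are dropped with a logged warning.
    """
    y = np.asarray(target, dtype=float)
    if len(features) != y.size:
        raise InputError("features and target must be row-aligned")
    X = features.to_numpy()
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise InputError("target has zero variance")
    degenerate = sx == 0
    sx_safe = np.where(degenerate, 1.0, sx)
    p = np.abs(xc.T @ yc) / (sx_safe * sy)
    p[degenerate] = 0.0
    if degenerate.any():
        logger.warning(
            "%d zero-variance feature(s) dropped from the Pearson screen",
            int(degenerate.sum()),
        )
    p_series = pd.Series(p, index=features.columns, name="p")
    return p_series[p_series > threshold]


def embedded_coefficients(
    features: pd.DataFrame,
    target: np.ndarray,
    seed: int = 0,
    n_estimators: int = 100,
    max_depth: int = 3,
    learning_rate: float = 0.1,
) -> pd.Series:
    """Per-feature importances c from a seeded gradient-boosted tree regressor."""
    y = np.asarray(target, dtype=float)
    if len(features) < 10:
        raise InputError("need at least 10 rows to fit the embedded model")
    gbt = GradientBoostingRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        random_state=seed,
    )
    gbt.fit(features.to_numpy(), y)
    return pd.Series(gbt.feature_importances_, index=features.columns, name="c")


def f_score(p, c):
    """Harmonic-mean combination 2 p |c| / (p + |c|); 0 when both are 0."""
    p = np.asarray(p, dtype=float)
    c = np.abs(np.asarray(c, dtype=float))
    denom = p + c
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 2.0 * p * c / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def select_top(scores: pd.Series, k: int) -> pd.Series:
    """Top-k features by f_score; ties broken by earlier position for determinism."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k >= len(scores):
        if k > len(scores):
            logger.info("k=%d exceeds %d available features; keeping all", k, len(scores))
        return scores.copy()
    order = np.lexsort((np.arange(len(scores)), -scores.to_numpy()))
    return scores.iloc[np.sort(order[:k])]


def fit_autoencoder(
    features: np.ndarray | pd.DataFrame,
    latent_dim: int,
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 8,
) -> Autoencoder:
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    model = Autoencoder(input_dim=X.shape[1], latent_dim=latent_dim, seed=seed)
    return model.fit(X, max_epochs=max_epochs, patience=patience)


def encode(model: Autoencoder, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    X = features.to_numpy() if isinstance(features, pd.DataFrame) else np.asarray(features)
    return model.encode(X)


@dataclass
class FeatureSelector:
    """Fitted screen -> embedded -> f_score -> top-k -> autoencoder pipeline.

    fit() learns everything from training rows; transform() applies the frozen
    selector to any row-aligned feature matrix.
    """

    config: SelectionConfig = field(default_factory=SelectionConfig)
    score_table: pd.DataFrame | None = None
    selected: pd.Index | None = None
    reducer: Autoencoder | None = None

    def fit(self, features: pd.DataFrame, target: np.ndarray) -> "FeatureSelector":
        cfg = self.config
        p = pearson_screen(features, target, cfg.pearson_threshold)
        if len(p) == 0:
            raise InputError("no feature survived the Pearson screen")
        retained = features[p.index]
        c = embedded_coefficients(
            retained,
            target,
            seed=cfg.seed,
            n_estimators=cfg.gbt_n_estimators,
            max_depth=cfg.gbt_max_depth,
            learning_rate=cfg.gbt_learning_rate,
        )
        scores = pd.Series(f_score(p.to_numpy(), c.to_numpy()), index=p.index, name="f_score")
        top = select_top(scores, cfg.top_k)
        self.selected = top.index
        self.score_table = pd.DataFrame({"p": p, "c": c, "f_score": scores})
        self.score_table["retained"] = self.score_table.index.isin(set(top.index))
        latent = min(cfg.latent_dim, len(top) - 1)
        if latent < 1:
            raise InputError("too few selected features for autoencoder reduction")
        self.reducer = fit_autoencoder(
            features[top.index],
            latent_dim=latent,
            seed=cfg.seed,
            max_epochs=cfg.ae_max_epochs,
            patience=cfg.ae_patience,
        )
        return self

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        if self.reducer is None or self.selected is None:
            raise InputError("selector is not fitted")
        return self.reducer.encode(features[self.selected].to_numpy())

    def export_scores(self, path) -> None:
        """Score table as CSV: structured index columns + p, c, f_score, retained."""
        table = self.score_table.copy()
        table.index = ["|".join(t) for t in table.index]
        table.index.name = "feature_id"
        table.to_csv(path)
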