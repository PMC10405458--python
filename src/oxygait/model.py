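"""LSTM regression of gait-parameter staircases with R²-gated adaptation.

Rows are per-window observations (reduced feature vector, staircase target,
subject id, target time).  Features and targets are Z-score normalized with
training-set statistics; each network input is the sequence of the last
`sequence_length` consecutive window vectors of the same subject, ending at
the target window (the first windows of a subject are padded by repeating the
earliest row).  Training uses subject-level 4-fold cross-validation with
early stopping on validation RMSE (patience 8, max 200 iterations) and
restores the best checkpoint; the returned model is refitted on all
cross-validation subjects.

Individual adaptive enhancement briefly continues training on a new subject's
adaptation rows at a reduced learning rate and keeps the updated parameters
only if R² on the subject's held-out gating rows strictly improves; otherwise
the original parameters are returned untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, InputError
from .evaluation import EvaluationResult, adaptation_report, r_squared
from .nn import Adam, LSTMRegressor, TrainingHistory, train_lstm


@dataclass
class TrainingConfig:
    folds: int = 4
    split_ratio: float = 0.8  # train share of the train:test subject split
    max_iterations: int = 200
    patience: int = 8
    forgetting_rate: float = 0.2  # dropout probability on the LSTM output
    l2_strength: float = 1e-4
    sequence_length: int = 10
    hidden_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 64
    adapt_iterations: int = 20
    adapt_learning_rate: float = 3e-4
    adapt_holdout: float = 0.3  # share of new-subject rows held out for gating
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if not 0 <= self.forgetting_rate < 1:
            raise ConfigurationError("forgetting_rate must be in [0, 1)")
        if self.patience >= self.max_iterations:
            raise ConfigurationError("patience must be below max_iterations")


@dataclass
class ModelState:
    """Trained network plus the statistics needed to apply it to raw rows."""

    network: LSTMRegressor
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    target_mean: float
    target_sd: float
    config: TrainingConfig
    histories: list = field(default_factory=list)

    def normalize_features(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_sd

    def denormalize_target(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_sd + self.target_mean


def zscore_fit_apply(train_rows: np.ndarray, *other_rows: np.ndarray):
    """Column-wise Z-score using training statistics; zero-sd columns map to 0.

    Returns (normalized_train, [normalized_others...], mean, sd).
    """
    train_rows = np.asarray(train_rows, dtype=float)
    if train_rows.shape[0] < 2:
        raise InputError("need at least 2 training rows for Z-score statistics")
    mean = train_rows.mean(axis=0)
    sd = train_rows.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    normed = [(np.asarray(r, dtype=float) - mean) / sd for r in (train_rows, *other_rows)]
    return (*normed, mean, sd)


def build_sequences(X: np.ndarray, subject_ids: np.ndarray, sequence_length: int) -> np.ndarray:
    """Per-row sequences of the last `sequence_length` rows of the same subject.

    Rows must be time-ordered within each subject; the first rows of a subject
    are front-padded by repeating that subject's earliest row.
    """
    X = np.asarray(X, dtype=float)
    subject_ids = np.asarray(subject_ids)
    out = np.empty((X.shape[0], sequence_length, X.shape[1]))
    for sid in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == sid)
        Xs = X[idx]
        padded = np.vstack([np.repeat(Xs[:1], sequence_length - 1, axis=0), Xs])
        for j in range(len(idx)):
            out[idx[j]] = padded[j : j + sequence_length]
    return out


def assign_folds(subject_ids: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Partition unique subjects into folds (every subject in exactly one)."""
    subjects = np.unique(subject_ids)
    if len(subjects) < folds:
        raise ConfigurationError(
            f"need at least {folds} subjects for {folds}-fold cross-validation, "
            f"got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    return [np.sort(part) for part in np.array_split(rng.permutation(subjects), folds)]


def split_subjects(subject_ids: np.ndarray, ratio: float, seed: int):
    """Subject-level train:test split (default 8:2)."""
    subjects = np.unique(subject_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_train = max(1, int(round(ratio * len(subjects))))
    n_train = min(n_train, len(subjects) - 1) if len(subjects) > 1 else n_train
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _fit_one(X_tr, y_tr, X_val, y_val, config: TrainingConfig, seed: int):
    model = LSTMRegressor(
        input_dim=X_tr.shape[2],
        hidden_units=config.hidden_units,
        l2=config.l2_strength,
        dropout=config.forgetting_rate,
        seed=seed,
    )
    hist = train_lstm(
        model, X_tr, y_tr, X_val, y_val,
        max_iterations=config.max_iterations,
        patience=config.patience,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        seed=seed,
    )
    return model, hist


def train_cv(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: np.ndarray,
    config: TrainingConfig,
) -> tuple[ModelState, list[dict]]:
    """Subject-level K-fold cross-validated training plus an all-subject refit.

    Returns (state, fold_metrics).  Each fold entry reports validation
    relative RMSE (percent), R², iterations run and the stop reason.  The
    refit model is trained on every cross-validation subject, with a
    deterministic 1-in-10 row slice held out for early stopping only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    subject_ids = np.asarray(subject_ids)
    fold_subjects = assign_folds(subject_ids, config.folds, config.seed)

    from .evaluation import rmse_relative  # local to avoid cycle at import time

    fold_metrics = []
    histories = []
    for k, val_subj in enumerate(fold_subjects):
        val_mask = np.isin(subject_ids, val_subj)
        Xn_tr, Xn_val, f_mu, f_sd = zscore_fit_apply(X[~val_mask], X[val_mask])
        yn_tr, yn_val, t_mu, t_sd = zscore_fit_apply(
            y[~val_mask, None], y[val_mask, None]
        )
        seq_tr = build_sequences(Xn_tr, subject_ids[~val_mask], config.sequence_length)
        seq_val = build_sequences(Xn_val, subject_ids[val_mask], config.sequence_length)
        model, hist = _fit_one(
            seq_tr, yn_tr[:, 0], seq_val, yn_val[:, 0], config, config.seed + 1000 + k
        )
        pred_val = model.predict(seq_val) * float(t_sd[0]) + float(t_mu[0])
        fold_metrics.append(
            {
                "fold": k,
                "val_subjects": val_subj.tolist(),
                "rmse_relative": rmse_relative(pred_val, y[val_mask]),
                "r_squared": r_squared(pred_val, y[val_mask]),
                "iterations": hist.n_iterations,
                "stop_reason": hist.stop_reason,
            }
        )
        histories.append(hist)

    # refit on all cross-validation subjects
    Xn, f_mu, f_sd = zscore_fit_apply(X)
    yn, t_mu, t_sd = zscore_fit_apply(y[:, None])
    seq = build_sequences(Xn, subject_ids, config.sequence_length)
    holdout = np.zeros(len(y), dtype=bool)
    holdout[::10] = True
    model, hist = _fit_one(
        seq[~holdout], yn[~holdout, 0], seq[holdout], yn[holdout, 0],
        config, config.seed + 2000,
    )
    histories.append(hist)
    state = ModelState(
        network=model,
        feat_mean=f_mu,
        feat_sd=f_sd,
        target_mean=float(t_mu[0]),
        target_sd=float(t_sd[0]),
        config=config,
        histories=histories,
    )
    return state, fold_metrics


def predict(state: ModelState, X: np.ndarray, subject_ids: np.ndarray) -> np.ndarray:
    """Per-row staircase predictions in physical units."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.feat_mean.size:
        raise InputError(
            f"expected {state.feat_mean.size} feature columns, got "
            f"{X.shape[1] if X.ndim == 2 else X.shape}"
        )
    seq = build_sequences(
        state.normalize_features(X), subject_ids, state.config.sequence_length
    )
    return state.denormalize_target(state.network.predict(seq))


def gating_split(n_rows: int, holdout: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic interleaved adaptation/evaluation split of a subject's rows.

    Every round(1/holdout)-th row goes to the gating evaluation set, so both
    sets cover the whole ramp of gait intensities.
    """
    if n_rows < 10:
        raise InputError("too few new-subject rows to split for adaptation")
    every = max(2, int(round(1.0 / holdout)))
    idx = np.arange(n_rows)
    eval_mask = (idx % every) == (every - 1)
    return idx[~eval_mask], idx[eval_mask]


def adaptive_update(
    state: ModelState,
    X_new: np.ndarray,
    y_new: np.ndarray,
    config: TrainingConfig | None = None,
) -> tuple[ModelState, dict]:
    """Incremental adaptation to one new subject, gated by held-out R².

    Fine-tunes a copy of the network on the subject's adaptation rows for a few
    iterations at a reduced learning rate, evaluates R² on the held-out gating
    rows before and after, and keeps the update only if R² strictly improved.
    Returns (state, report); when the update is rejected the returned state is
    the original object, unchanged.
    """
    config = config or state.config
    X_new = np.asarray(X_new, dtype=float)
    y_new = np.asarray(y_new, dtype=float)
    if len(X_new) != len(y_new):
        raise InputError("features and targets must be row-aligned")
    adapt_idx, eval_idx = gating_split(len(y_new), config.adapt_holdout)

    sid = np.zeros(len(y_new), dtype=int)
    seq = build_sequences(state.normalize_features(X_new), sid, config.sequence_length)
    yn = (y_new - state.target_mean) / state.target_sd

    before_pred = state.denormalize_target(state.network.predict(seq[eval_idx]))
    before = EvaluationResult.from_series(before_pred, y_new[eval_idx])

    candidate = state.network.clone()
    if config.adapt_iterations > 0:
        rng = np.random.default_rng(config.seed + 3000)
        opt = Adam(candidate.params, lr=config.adapt_learning_rate)
        for _ in range(config.adapt_iterations):
            _, grads = candidate.loss_and_grads(seq[adapt_idx], yn[adapt_idx], rng=rng)
            opt.step(candidate.params, grads)

    after_pred = state.denormalize_target(candidate.predict(seq[eval_idx]))
    after = EvaluationResult.from_series(after_pred, y_new[eval_idx])

    kept = after.r_squared > before.r_squared
    report = adaptation_report(before, after if kept else before)
    report.update(
        {
            "candidate_r2": after.r_squared,
            "kept": bool(kept),
            "n_adapt_rows": int(len(adapt_idx)),
            "n_eval_rows": int(len(eval_idx)),
        }
    )
    if not kept:
        return state, report
    new_state = ModelState(
        network=candidate,
        feat_mean=state.feat_mean,
        feat_sd=state.feat_sd,
        target_mean=state.target_mean,
        target_sd=state.target_sd,
        config=state.config,
        histories=state.histories,
    )
    return new_state, report
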