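"""End-to-end orchestration: cohort -> preprocessing -> features -> selection
-> LSTM training -> evaluation -> individual adaptation.

All learned transforms (Pearson screen, gradient boosting, autoencoder,
Z-score statistics, network weights) are fitted on training subjects only and
applied frozen everywhere else.  Windows whose target falls in a flagged
partial edge cycle, or beyond the end of the last complete gait cycle, are
excluded from the row set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess
from .core import InputError, SyntheticSubject
from .evaluation import EvaluationResult, cohort_adaptation_report
from .features import WindowingPlan, build_feature_matrix, feature_count
from .model import (
    ModelState,
    TrainingConfig,
    adaptive_update,
    predict,
    split_subjects,
    train_cv,
)
from .selection import FeatureSelector, SelectionConfig
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    windowing: WindowingPlan = field(default_factory=WindowingPlan)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lowpass_cutoff: float = preprocess.DEFAULT_LOWPASS_HZ
    smooth_window_s: float = preprocess.DEFAULT_SMOOTH_WINDOW_S
    min_cycle_s: float = preprocess.DEFAULT_MIN_CYCLE_S
    n_adapt_subjects: int = 8  # held entirely out of cross-validation

    def reseed(self, seed: int) -> "PipelineConfig":
        """Propagate one master seed to every stage."""
        self.simulation.seed = seed
        self.selection.seed = seed
        self.training.seed = seed
        return self


@dataclass
class SubjectRows:
    """Per-window rows for one subject after preprocessing and extraction."""

    subject_id: int
    features: pd.DataFrame  # windows x feature columns (structured index)
    target_speed: np.ndarray
    target_step: np.ndarray
    times: np.ndarray


def extract_subject_rows(subject: SyntheticSubject, config: PipelineConfig) -> SubjectRows:
    """Preprocess one subject and align feature windows with staircase targets."""
    cleaned = {name: preprocess.remove_baseline(rec) for name, rec in subject.recordings.items()}
    decomp = preprocess.bandpass_decompose(cleaned, config.simulation.bands)
    X = build_feature_matrix(decomp, config.windowing)

    gait = preprocess.process_gait(
        subject.gait,
        cutoff=config.lowpass_cutoff,
        window_s=config.smooth_window_s,
        min_cycle_s=config.min_cycle_s,
    )
    fs = gait.sampling_rate
    samples = np.minimum((X.index.to_numpy() * fs).round().astype(int) - 1, gait.n_samples)
    in_range = (samples >= 0) & (samples < gait.n_samples)
    cycles = np.searchsorted(gait.cycle_boundaries, samples.clip(0, gait.n_samples - 1), side="right") - 1
    cycles = cycles.clip(0, gait.n_cycles - 1)
    keep = in_range & ~gait.partial_cycles[cycles]
    if not keep.any():
        raise InputError("no usable windows for subject (all in partial edge cycles)")
    return SubjectRows(
        subject_id=subject.subject_id,
        features=X.loc[keep],
        target_speed=gait.staircase_speed[samples[keep]],
        target_step=gait.staircase_step[samples[keep]],
        times=X.index.to_numpy()[keep],
    )


def stack_rows(rows: list[SubjectRows]):
    """Concatenate per-subject rows into cohort-level arrays."""
    X = pd.concat([r.features for r in rows], axis=0, ignore_index=True)
    y_speed = np.concatenate([r.target_speed for r in rows])
    y_step = np.concatenate([r.target_step for r in rows])
    sids = np.concatenate([np.full(len(r.features), r.subject_id) for r in rows])
    times = np.concatenate([r.times for r in rows])
    return X, y_speed, y_step, sids, times


@dataclass
class FittedTarget:
    """Everything needed to predict and adapt one gait parameter."""

    target: str  # "speed" | "step"
    selector: FeatureSelector
    state: ModelState
    fold_metrics: list
    test_eval: EvaluationResult | None
    test_subjects: np.ndarray


def fit_target(
    X: pd.DataFrame,
    y: np.ndarray,
    subject_ids: np.ndarray,
    config: PipelineConfig,
    target: str,
) -> FittedTarget:
    """8:2 subject split, train-only selection fit, 4-fold CV training, test eval."""
    train_subj, test_subj = split_subjects(
        subject_ids, config.training.split_ratio, config.training.seed
    )
    train_mask = np.isin(subject_ids, train_subj)
    selector = FeatureSelector(config=config.selection).fit(X[train_mask], y[train_mask])
    logger.info(
        "[%s] %d/%d features survive the Pearson screen; %d selected, latent dim %d",
        target,
        int((selector.score_table["p"].notna()).sum()),
        X.shape[1],
        len(selector.selected),
        selector.reducer.latent_dim,
    )
    Z = selector.transform(X)
    state, fold_metrics = train_cv(
        Z[train_mask], y[train_mask], subject_ids[train_mask], config.training
    )
    test_eval = None
    if len(test_subj):
        test_mask = np.isin(subject_ids, test_subj)
        pred = predict(state, Z[test_mask], subject_ids[test_mask])
        test_eval = EvaluationResult.from_series(pred, y[test_mask])
    return FittedTarget(
        target=target,
        selector=selector,
        state=state,
        fold_metrics=fold_metrics,
        test_eval=test_eval,
        test_subjects=test_subj,
    )


def run_fit(subjects: list[SyntheticSubject], config: PipelineConfig) -> dict:
    """Fit both gait parameters on a cohort; returns {"speed": ..., "step": ...}.

    The varied parameter of each subject's trial mode is the fitted target, so
    a speed-mode cohort trains the speed model and a stride-mode cohort the
    step model; passing a mixed list fits each model on its matching subset.
    """
    fitted = {}
    for target, mode in (("speed", "speed"), ("step", "stride")):
        subset = [s for s in subjects if s.latent.mode == mode]
        if not subset:
            continue
        rows = [extract_subject_rows(s, config) for s in subset]
        X, y_speed, y_step, sids, _ = stack_rows(rows)
        y = y_speed if target == "speed" else y_step
        logger.info("[%s] %d subjects, %d rows, %d feature columns", target, len(subset), len(y), X.shape[1])
        fitted[target] = fit_target(X, y, sids, config, target)
    return fitted


def adapt_cohort(
    fitted: FittedTarget,
    new_subjects: list[SyntheticSubject],
    config: PipelineConfig,
) -> dict:
    """R²-gated adaptation of the fitted model to each new subject separately."""
    reports = []
    for subject in new_subjects:
        rows = extract_subject_rows(subject, config)
        y = rows.target_speed if fitted.target == "speed" else rows.target_step
        Z = fitted.selector.transform(rows.features)
        _, report = adaptive_update(fitted.state, Z, y, config.training)
        report["subject_id"] = subject.subject_id
        reports.append(report)
    out = cohort_adaptation_report(reports)
    out["per_subject"] = reports
    return out


def metrics_dict(fitted: dict, adaptation: dict | None = None) -> dict:
    """JSON-serializable metrics summary of a full run."""
    out = {}
    for target, ft in fitted.items():
        entry = {
            "fold_metrics": ft.fold_metrics,
            "n_selected_features": int(len(ft.selector.selected)),
            "latent_dim": int(ft.selector.reducer.latent_dim),
            "test_subjects": ft.test_subjects.tolist(),
        }
        if ft.test_eval is not None:
            entry["test_rmse_relative"] = ft.test_eval.rmse_relative
            entry["test_r_squared"] = ft.test_eval.r_squared
        out[target] = entry
    if adaptation is not None:
        out["adaptation"] = adaptation
    return out


def run_experiment(config: PipelineConfig) -> dict:
    """Full study surrogate: simulate, fit both targets, adapt held-out subjects.

    The last n_adapt_subjects of the cohort never enter cross-validation or
    the selection fit; they are used only for individual adaptive enhancement.
    """
    results = {}
    n_cv = config.simulation.n_subjects - config.n_adapt_subjects
    if n_cv < config.training.folds:
        raise InputError("not enough cross-validation subjects for the configured folds")
    for target, mode in (("speed", "speed"), ("step", "stride")):
        cohort = generate_cohort(config.simulation, mode)
        cv_cohort, adapt_pool = cohort[:n_cv], cohort[n_cv:]
        fitted = run_fit(cv_cohort, config)[target]
        adaptation = adapt_cohort(fitted, adapt_pool, config) if adapt_pool else None
        results[target] = {"fitted": fitted, "metrics": metrics_dict({target: fitted}, adaptation)[target]}
        if adaptation is not None:
            results[target]["adaptation"] = adaptation
    return results
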