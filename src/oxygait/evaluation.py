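"""Fit-quality metrics: relative RMSE (percent) and the coefficient of determination.

relative RMSE = sqrt( mean_i ( (pred_i - real_i) / real_i )^2 ) * 100
R^2           = 1 - SS_res / SS_tot

The relative form divides each residual by the true value, so it is invariant
to a common positive rescaling of both series; the staircase targets are
strictly positive by construction, and an epsilon guard turns a violation of
that assumption into a loud error rather than a silent blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InputError

EPSILON = 1e-9


def _check_pair(y_pred, y_real) -> tuple[np.ndarray, np.ndarray]:
    y_pred = np.asarray(y_pred, dtype=float)
    y_real = np.asarray(y_real, dtype=float)
    if y_pred.shape != y_real.shape:
        raise InputError("predicted and true series must have equal length")
    if y_pred.size < 2:
        raise InputError("need at least 2 samples")
    return y_pred, y_real


def rmse_relative(y_pred, y_real) -> float:
    """Root mean square of per-point relative errors, in percent."""
    y_pred, y_real = _check_pair(y_pred, y_real)
    if np.any(np.abs(y_real) <= EPSILON):
        raise InputError("true series contains (near-)zero values; relative error undefined")
    rel = (y_pred - y_real) / y_real
    return float(np.sqrt(np.mean(rel**2)) * 100.0)


def r_squared(y_pred, y_real) -> float:
    """1 - SS_res/SS_tot; 1 is a perfect fit, 0 matches the mean-only model."""
    y_pred, y_real = _check_pair(y_pred, y_real)
    ss_tot = float(np.sum((y_real - y_real.mean()) ** 2))
    if ss_tot <= 0:
        raise InputError("true series is constant; R^2 undefined")
    ss_res = float(np.sum((y_pred - y_real) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class EvaluationResult:
    """Paired prediction/truth series with both metrics."""

    y_pred: np.ndarray
    y_real: np.ndarray
    rmse_relative: float
    r_squared: float

    @classmethod
    def from_series(cls, y_pred, y_real) -> "EvaluationResult":
        y_pred, y_real = _check_pair(y_pred, y_real)
        return cls(
            y_pred=y_pred,
            y_real=y_real,
            rmse_relative=rmse_relative(y_pred, y_real),
            r_squared=r_squared(y_pred, y_real),
        )

    @property
    def m(self) -> int:
        return self.y_real.size

    @property
    def y_mean_real(self) -> float:
        return float(self.y_real.mean())


def adaptation_report(before: EvaluationResult, after: EvaluationResult) -> dict:
    """Per-subject adaptation deltas on the same evaluation rows.

    delta_rmse = before - after (positive means the error decreased);
    delta_r_squared = after - before (positive means the fit improved).
    """
    if before.m != after.m or not np.allclose(before.y_real, after.y_real):
        raise InputError("before/after must be evaluated on the same rows")
    return {
        "rmse_before": before.rmse_relative,
        "rmse_after": after.rmse_relative,
        "delta_rmse": before.rmse_relative - after.rmse_relative,
        "r2_before": before.r_squared,
        "r2_after": after.r_squared,
        "delta_r2": after.r_squared - before.r_squared,
    }


def cohort_adaptation_report(reports: list[dict]) -> dict:
    """Average the per-subject deltas over a cohort of adapted subjects."""
    if not reports:
        return {"n_subjects": 0}
    keys = ("rmse_before", "rmse_after", "delta_rmse", "r2_before", "r2_after", "delta_r2")
    out = {f"mean_{k}": float(np.mean([r[k] for r in reports])) for k in keys}
    out["n_subjects"] = len(reports)
    return out


def plot_staircase_overlay(times, y_real, y_pred_before, y_pred_after=None, ax=None,
                           title: str = "", ylabel: str = ""):
    """True-vs-predicted staircase overlay (before/after adaptation)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.step(times, y_real, where="post", label="true", color="black")
    ax.step(times, y_pred_before, where="post", label="predicted", color="tab:blue")
    if y_pred_after is not None:
        ax.step(times, y_pred_after, where="post", label="adapted", color="tab:red")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
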