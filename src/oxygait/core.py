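"""Shared data containers and error types.

The pipeline moves three kinds of objects between stages: hemoglobin
concentration recordings (one matrix per species: HbO, HbR, HbT), knee-joint
gait traces (angular velocity and angle), and the slow latent gait-intensity
profile the synthetic generator couples them through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SPECIES = ("HbO", "HbR", "HbT")


class ConfigurationError(ValueError):
    """Invalid configuration (bad band edges, degenerate ranges, ...)."""


class InputError(ValueError):
    """Invalid data passed to an operation (empty channel, length mismatch, ...)."""


@dataclass
class HemodynamicRecording:
    """Multichannel concentration time series for one hemoglobin species.

    data is (channels, samples) in concentration units (uM), uniformly sampled.
    """

    sampling_rate: float
    species: str
    data: np.ndarray
    channel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.species not in SPECIES:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if self.data.ndim != 2:
            raise InputError("data must be a (channels, samples) matrix")
        if self.data.shape[1] == 0:
            raise InputError("recording has empty channels")
        if not np.all(np.isfinite(self.data)):
            raise InputError("recording contains non-finite values")
        if not self.channel_ids:
            self.channel_ids = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_ids) != self.data.shape[0]:
            raise InputError("channel_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "HemodynamicRecording":
        return HemodynamicRecording(
            sampling_rate=self.sampling_rate,
            species=self.species,
            data=np.asarray(data, dtype=float),
            channel_ids=self.channel_ids,
        )


@dataclass
class BandDefinition:
    """One physiological frequency band, edges in Hz."""

    name: str
    low_edge: float
    high_edge: float

    def __post_init__(self) -> None:
        if not 0 < self.low_edge < self.high_edge:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low ({self.low_edge}) < high ({self.high_edge})"
            )

    @property
    def center(self) -> float:
        """Geometric-mean center frequency."""
        return float(np.sqrt(self.low_edge * self.high_edge))


@dataclass
class GaitTrace:
    """Knee angular velocity (deg/s) and angle (deg), plus derived cycle structure.

    cycle_boundaries delimit gait cycles as sample indices b_0 < ... < b_K; cycle k
    spans [b_k, b_{k+1}).  staircase_speed / staircase_step are the per-cycle-maximum
    (piecewise-constant) series produced by digital step processing.  partial_cycles
    flags cycles not delimited by true interior minima on both sides (the first and
    last cycle of a trace); these are excluded from training targets by default.
    """

    sampling_rate: float
    angular_velocity: np.ndarray
    angle: np.ndarray
    cycle_boundaries: np.ndarray | None = None
    staircase_speed: np.ndarray | None = None
    staircase_step: np.ndarray | None = None
    partial_cycles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.angular_velocity.shape != self.angle.shape:
            raise InputError("angular_velocity and angle must have equal length")
        if self.angular_velocity.size == 0:
            raise InputError("empty gait trace")
        if self.cycle_boundaries is not None:
            b = np.asarray(self.cycle_boundaries)
            if np.any(np.diff(b) <= 0):
                raise InputError("cycle_boundaries must be strictly increasing")
            self.cycle_boundaries = b

    @property
    def n_samples(self) -> int:
        return self.angular_velocity.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def n_cycles(self) -> int:
        if self.cycle_boundaries is None:
            return 0
        return len(self.cycle_boundaries) - 1

    def copy_with(self, **kw) -> "GaitTrace":
        base = dict(
            sampling_rate=self.sampling_rate,
            angular_velocity=self.angular_velocity,
            angle=self.angle,
            cycle_boundaries=self.cycle_boundaries,
            staircase_speed=self.staircase_speed,
            staircase_step=self.staircase_step,
            partial_cycles=self.partial_cycles,
        )
        base.update(kw)
        return GaitTrace(**base)


@dataclass
class LatentGaitProfile:
    """Slow latent gait-intensity profile driving both fNIRS and gait synthesis.

    speed_intensity and stride_intensity are dimensionless in (0, 1], sampled on
    `time`; `mode` records which parameter is varied (ramped) in this trial.
    """

    time: np.ndarray
    speed_intensity: np.ndarray
    stride_intensity: np.ndarray
    mode: str = "speed"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed_intensity = np.asarray(self.speed_intensity, dtype=float)
        self.stride_intensity = np.asarray(self.stride_intensity, dtype=float)
        for name in ("speed_intensity", "stride_intensity"):
            v = getattr(self, name)
            if v.shape != self.time.shape:
                raise InputError(f"{name} must match the time grid")
            if np.any(v <= 0) or np.any(v > 1):
                raise InputError(f"{name} must lie in (0, 1]")

    def varied(self) -> np.ndarray:
        return self.speed_intensity if self.mode == "speed" else self.stride_intensity

    def speed_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.time, self.speed_intensity)

    def stride_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.time, self.stride_intensity)

    def varied_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.time, self.varied())


@dataclass
class SyntheticSubject:
    """One simulated subject-trial: coupled recordings, gait, and ground truth.

    truth carries generator-side quantities the pipeline must recover: cycle
    boundary indices, per-cycle maxima of the noiseless velocity/angle, and the
    cycle midpoint times.
    """

    subject_id: int
    recordings: dict  # species -> HemodynamicRecording
    gait: GaitTrace
    latent: LatentGaitProfile
    subject_gain: float
    subject_offset: float
    truth: dict = field(default_factory=dict)
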