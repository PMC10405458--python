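"""Synthetic coupled fNIRS/gait cohort generator.

Emulates a treadmill-style protocol in which a subject either ramps walking
speed at constant stride length, or ramps stride length at constant speed.  A
slow latent gait-intensity profile drives both sides of the simulation:

* cortical hemoglobin channels are sums of narrowband amplitude-modulated
  oscillators, one per physiological band (cardiac, respiratory, myogenic,
  neurogenic, endothelial); in *informative* channels the oscillator envelope
  follows ``offset + coupling_gain * intensity``, elsewhere it is constant.
  HbR mirrors HbO with opposite sign and reduced magnitude; HbT = HbO + HbR by
  construction.  Linear drift and white measurement noise are added per channel.
* the knee angular-velocity trace is a train of half-sine bursts, one per gait
  cycle, whose per-cycle peak is an affine function of the speed intensity at
  the cycle midpoint; the knee angle is the analogous burst train driven by the
  stride intensity.

Everything is a pure function of (config, seed): per-subject random streams are
derived with ``numpy.random.SeedSequence([seed, subject_id, stream_tag])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    GaitTrace,
    HemodynamicRecording,
    LatentGaitProfile,
    SyntheticSubject,
)
from .preprocess import DEFAULT_BANDS

# Affine map from latent intensity in (0,1] to physical per-cycle peaks.
SPEED_PEAK_BASE = 100.0  # deg/s at intensity 0
SPEED_PEAK_SPAN = 200.0  # deg/s per unit intensity
STEP_PEAK_BASE = 30.0  # deg at intensity 0
STEP_PEAK_SPAN = 40.0  # deg per unit intensity

# Base oscillator amplitude per band (uM); low-frequency vasomotion dominates,
# mirroring the 1/f-like shape of resting hemodynamics.
BAND_BASE_AMPLITUDE = {
    "endothelial": 1.0,
    "neurogenic": 0.8,
    "myogenic": 0.6,
    "respiratory": 0.5,
    "cardiac": 0.4,
}

_STREAMS = {"latent": 11, "fnirs": 23, "gait": 37, "subject": 53}


def _rng(seed: int, subject_id: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject_id), _STREAMS[stream]])
    )


@dataclass
class SimulationConfig:
    """Cohort generator configuration; defaults define the study conditions."""

    n_subjects: int = 38
    trial_duration: float = 60.0  # s
    fnirs_rate: float = 10.0  # Hz
    imu_rate: float = 100.0  # Hz
    n_channels: int = 6
    informative_channels: tuple[int, ...] = (0, 1, 2)
    coupling_gain: float = 1.0  # envelope units per unit latent intensity
    amplitude_offset: float = 0.2  # envelope floor, fraction of band base amplitude
    drift_slope: float = 0.001  # uM/s linear baseline drift
    noise_sd: float = 0.05  # uM white measurement noise
    hbr_ratio: float = 0.4  # |HbR| / |HbO| anticoupling magnitude
    subject_gain_sd: float = 0.1  # sd of per-subject multiplicative gain
    subject_offset_sd: float = 0.05  # sd of per-subject additive offset (uM)
    latent_jitter: float = 0.02  # amplitude of smooth jitter on the latent ramp
    gait_noise_sd: float = 1.0  # deg/s (and deg) sensor noise on gait traces
    cycle_duration_range: tuple[float, float] = (0.9, 1.3)  # s
    bands: tuple = tuple(DEFAULT_BANDS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if self.fnirs_rate <= 0 or self.imu_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        top = max(b.high_edge for b in self.bands)
        if self.fnirs_rate <= 2 * top:
            raise ConfigurationError(
                f"fnirs_rate {self.fnirs_rate} Hz cannot represent the top band edge {top} Hz"
            )
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be positive")
        bad = set(self.informative_channels) - set(range(self.n_channels))
        if bad:
            raise ConfigurationError(f"informative_channels out of range: {sorted(bad)}")
        lo, hi = self.cycle_duration_range
        if lo > hi or lo <= 0:
            raise ConfigurationError("cycle_duration_range must satisfy 0 < min <= max")


def generate_latent_profile(
    config: SimulationConfig, subject_id: int, mode: str = "speed"
) -> LatentGaitProfile:
    """Latent intensity profile: the varied parameter ramps 0.3 -> 1.0 with small
    smooth jitter; the held parameter stays at 0.6."""
    if mode not in ("speed", "stride"):
        raise ConfigurationError(f"mode must be 'speed' or 'stride', got {mode!r}")
    rng = _rng(config.seed, subject_id, "latent")
    n = int(round(config.trial_duration * config.imu_rate))
    t = np.arange(n) / config.imu_rate
    ramp = 0.3 + 0.7 * t / config.trial_duration
    if config.latent_jitter > 0:
        # two random low-frequency sinusoids: smooth, slower than a gait cycle
        jitter = np.zeros(n)
        for _ in range(2):
            f = rng.uniform(0.02, 0.08)
            phi = rng.uniform(0, 2 * np.pi)
            jitter += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t + phi)
        ramp = ramp + config.latent_jitter * jitter / 2.0
    varied = np.clip(ramp, 1e-3, 1.0)
    held = np.full(n, 0.6)
    speed, stride = (varied, held) if mode == "speed" else (held, varied)
    return LatentGaitProfile(time=t, speed_intensity=speed, stride_intensity=stride, mode=mode)


def synthesize_fnirs(
    config: SimulationConfig,
    latent: LatentGaitProfile,
    subject_gain: float = 1.0,
    subject_offset: float = 0.0,
    subject_id: int = 0,
) -> dict:
    """Synthesize HbO/HbR/HbT recordings coupled to the latent intensity.

    Returns a dict species -> HemodynamicRecording.
    """
    n = int(round(config.trial_duration * config.fnirs_rate))
    t = np.arange(n) / config.fnirs_rate
    if latent.time[-1] < t[-1] - 1.0 / config.fnirs_rate:
        raise ConfigurationError("latent profile does not cover the trial duration")
    intensity = latent.varied_at(t)
    rng = _rng(config.seed, subject_id, "fnirs")
    informative = set(config.informative_channels)

    hbo = np.zeros((config.n_channels, n))
    for band in config.bands:
        base = BAND_BASE_AMPLITUDE.get(band.name, 0.5)
        env_info = base * (config.amplitude_offset + config.coupling_gain * intensity)
        env_flat = base * (
            config.amplitude_offset + config.coupling_gain * float(np.mean(intensity))
        )
        for ch in range(config.n_channels):
            phase0 = rng.uniform(0, 2 * np.pi)
            # slow random phase drift keeps carriers incoherent across channels
            drift = np.cumsum(rng.normal(0.0, 0.01, n))
            carrier = np.sin(2 * np.pi * band.center * t + phase0 + drift)
            env = env_info if ch in informative else env_flat
            hbo[ch] += env * carrier

    hbr = -config.hbr_ratio * hbo
    drift_term = config.drift_slope * t
    hbo = hbo + drift_term + rng.normal(0.0, config.noise_sd, hbo.shape)
    hbr = hbr - drift_term * config.hbr_ratio + rng.normal(0.0, config.noise_sd, hbr.shape)
    hbo = subject_gain * hbo + subject_offset
    hbr = subject_gain * hbr - subject_offset * config.hbr_ratio
    hbt = hbo + hbr

    return {
        name: HemodynamicRecording(sampling_rate=config.fnirs_rate, species=name, data=data)
        for name, data in (("HbO", hbo), ("HbR", hbr), ("HbT", hbt))
    }


def synthesize_gait(
    config: SimulationConfig, latent: LatentGaitProfile, subject_id: int = 0
) -> tuple[GaitTrace, dict]:
    """Synthesize the knee trace as a half-sine burst train, one burst per cycle.

    Returns (trace, truth) where truth holds cycle boundary indices and the
    per-cycle maxima of the noiseless series (the generator's ground truth).
    """
    rng = _rng(config.seed, subject_id, "gait")
    lo, hi = config.cycle_duration_range
    durations = []
    total = 0.0
    while True:
        d = rng.uniform(lo, hi)
        if total + d > config.trial_duration + 1e-12:
            break
        durations.append(d)
        total += d
    if not durations:
        raise ConfigurationError("trial_duration shorter than one gait cycle")

    fs = config.imu_rate
    boundaries_t = np.concatenate([[0.0], np.cumsum(durations)])
    boundaries = np.round(boundaries_t * fs).astype(int)
    n = boundaries[-1]
    t = np.arange(n) / fs

    velocity = np.zeros(n)
    angle = np.zeros(n)
    peaks_speed, peaks_step, midpoints = [], [], []
    for k in range(len(durations)):
        i0, i1 = boundaries[k], boundaries[k + 1]
        seg_t = t[i0:i1]
        T = boundaries_t[k + 1] - boundaries_t[k]
        mid = 0.5 * (boundaries_t[k] + boundaries_t[k + 1])
        v_pk = SPEED_PEAK_BASE + SPEED_PEAK_SPAN * float(latent.speed_at(mid))
        a_pk = STEP_PEAK_BASE + STEP_PEAK_SPAN * float(latent.stride_at(mid))
        shape = np.sin(np.pi * (seg_t - boundaries_t[k]) / T)
        velocity[i0:i1] = v_pk * shape
        angle[i0:i1] = a_pk * shape
        peaks_speed.append(float(velocity[i0:i1].max()))
        peaks_step.append(float(angle[i0:i1].max()))
        midpoints.append(mid)

    truth = {
        "cycle_boundaries": boundaries,
        "cycle_midpoints": np.asarray(midpoints),
        "peak_speed": np.asarray(peaks_speed),
        "peak_step": np.asarray(peaks_step),
    }
    if config.gait_noise_sd > 0:
        velocity = velocity + rng.normal(0.0, config.gait_noise_sd, n)
        angle = angle + rng.normal(0.0, config.gait_noise_sd, n)
    trace = GaitTrace(sampling_rate=fs, angular_velocity=velocity, angle=angle)
    return trace, truth


def generate_subject(config: SimulationConfig, subject_id: int, mode: str = "speed") -> SyntheticSubject:
    srng = _rng(config.seed, subject_id, "subject")
    gain = float(1.0 + srng.normal(0.0, config.subject_gain_sd))
    offset = float(srng.normal(0.0, config.subject_offset_sd))
    latent = generate_latent_profile(config, subject_id, mode)
    recordings = synthesize_fnirs(config, latent, gain, offset, subject_id)
    gait, truth = synthesize_gait(config, latent, subject_id)
    return SyntheticSubject(
        subject_id=subject_id,
        recordings=recordings,
        gait=gait,
        latent=latent,
        subject_gain=gain,
        subject_offset=offset,
        truth=truth,
    )


def generate_cohort(config: SimulationConfig, mode: str = "speed") -> list[SyntheticSubject]:
    """Generate n_subjects coupled subject-trials, reproducible from config.seed."""
    if config.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    return [generate_subject(config, sid, mode) for sid in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# Disk layout: one CSV per species, one gait CSV, one JSON ground-truth sidecar.


def write_subject(subject: SyntheticSubject, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, rec in subject.recordings.items():
        df = pd.DataFrame(rec.data.T, columns=list(rec.channel_ids))
        df.insert(0, "time", rec.times)
        p = outdir / f"subject{subject.subject_id:03d}_{name.lower()}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    g = subject.gait
    gdf = pd.DataFrame(
        {"time": g.times, "angular_velocity": g.angular_velocity, "angle": g.angle}
    )
    p = outdir / f"subject{subject.subject_id:03d}_gait.csv"
    gdf.to_csv(p, index=False)
    written.append(p)

    sidecar = {
        "subject_id": subject.subject_id,
        "mode": subject.latent.mode,
        "subject_gain": subject.subject_gain,
        "subject_offset": subject.subject_offset,
        "fnirs_rate": subject.recordings["HbO"].sampling_rate,
        "imu_rate": g.sampling_rate,
        "latent": {
            "time": subject.latent.time.tolist(),
            "speed_intensity": subject.latent.speed_intensity.tolist(),
            "stride_intensity": subject.latent.stride_intensity.tolist(),
        },
        "truth": {k: np.asarray(v).tolist() for k, v in subject.truth.items()},
    }
    p = outdir / f"subject{subject.subject_id:03d}_truth.json"
    p.write_text(json.dumps(sidecar))
    written.append(p)
    return written


def read_subject(outdir: str | Path, subject_id: int) -> SyntheticSubject:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"subject{subject_id:03d}_truth.json").read_text())
    recordings = {}
    for name in ("HbO", "HbR", "HbT"):
        df = pd.read_csv(outdir / f"subject{subject_id:03d}_{name.lower()}.csv")
        chans = [c for c in df.columns if c != "time"]
        recordings[name] = HemodynamicRecording(
            sampling_rate=sidecar["fnirs_rate"],
            species=name,
            data=df[chans].to_numpy().T,
            channel_ids=tuple(chans),
        )
    gdf = pd.read_csv(outdir / f"subject{subject_id:03d}_gait.csv")
    gait = GaitTrace(
        sampling_rate=sidecar["imu_rate"],
        angular_velocity=gdf["angular_velocity"].to_numpy(),
        angle=gdf["angle"].to_numpy(),
    )
    lat = sidecar["latent"]
    latent = LatentGaitProfile(
        time=np.asarray(lat["time"]),
        speed_intensity=np.asarray(lat["speed_intensity"]),
        stride_intensity=np.asarray(lat["stride_intensity"]),
        mode=sidecar["mode"],
    )
    truth = {k: np.asarray(v) for k, v in sidecar["truth"].items()}
    return SyntheticSubject(
        subject_id=subject_id,
        recordings=recordings,
        gait=gait,
        latent=latent,
        subject_gain=sidecar["subject_gain"],
        subject_offset=sidecar["subject_offset"],
        truth=truth,
    )
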