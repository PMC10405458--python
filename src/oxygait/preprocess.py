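"""Signal conditioning for hemoglobin and gait traces.

Hemoglobin side: per-channel baseline removal (subtract the first sample) and
zero-phase second-order Chebyshev type-I band-pass decomposition into the five
physiological bands (cardiac, respiratory, myogenic, neurogenic, endothelial).

Gait side: zero-phase second-order Butterworth 6 Hz low-pass, rectification,
centered moving-average smoothing, gait-cycle segmentation at local minima of
the smoothed envelope, and "digital step" (staircase) processing that replaces
each cycle by its within-cycle maximum — the per-cycle gait parameter targets.

All filters are applied forward-backward (zero phase) so that features and
targets remain time-aligned; the effective filter order is therefore doubled.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import BandDefinition, ConfigurationError, GaitTrace, HemodynamicRecording, InputError

#: The five physiological bands (Hz).
DEFAULT_BANDS = (
    BandDefinition("cardiac", 0.6, 2.0),
    BandDefinition("respiratory", 0.145, 0.6),
    BandDefinition("myogenic", 0.052, 0.145),
    BandDefinition("neurogenic", 0.021, 0.052),
    BandDefinition("endothelial", 0.0095, 0.021),
)

CHEBY_ORDER = 2
CHEBY_RIPPLE_DB = 0.5
BUTTER_ORDER = 2
DEFAULT_LOWPASS_HZ = 6.0
DEFAULT_SMOOTH_WINDOW_S = 0.25
DEFAULT_MIN_CYCLE_S = 0.4


def remove_baseline(recording: HemodynamicRecording) -> HemodynamicRecording:
    """Subtract each channel's first sample, shifting the series to start at 0."""
    if recording.n_samples < 1:
        raise InputError("cannot remove baseline from an empty channel")
    return recording.copy_with(recording.data - recording.data[:, :1])


def design_bandpass(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    """Second-order Chebyshev type-I band-pass as second-order sections."""
    nyq = sampling_rate / 2.0
    if band.high_edge >= nyq:
        raise ConfigurationError(
            f"band {band.name!r} upper edge {band.high_edge} Hz is not below "
            f"the Nyquist frequency {nyq} Hz"
        )
    return signal.cheby1(
        CHEBY_ORDER,
        CHEBY_RIPPLE_DB,
        [band.low_edge, band.high_edge],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def _zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    padlen = min(n - 1, 3 * (2 * sos.shape[0] + 1) * 10)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


class BandDecomposition(dict):
    """Mapping (band_name, species) -> band-limited HemodynamicRecording."""

    @property
    def band_names(self) -> tuple[str, ...]:
        seen = []
        for b, _ in self.keys():
            if b not in seen:
                seen.append(b)
        return tuple(seen)

    @property
    def species_names(self) -> tuple[str, ...]:
        seen = []
        for _, s in self.keys():
            if s not in seen:
                seen.append(s)
        return tuple(seen)


def bandpass_decompose(
    recordings: dict | HemodynamicRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> BandDecomposition:
    """Band-limit each species' channels into the physiological bands.

    Accepts a single recording or a dict species -> recording; returns a
    BandDecomposition keyed by (band_name, species).
    """
    if isinstance(recordings, HemodynamicRecording):
        recordings = {recordings.species: recordings}
    out = BandDecomposition()
    for species, rec in recordings.items():
        for band in bands:
            sos = design_bandpass(band, rec.sampling_rate)
            out[(band.name, species)] = rec.copy_with(_zero_phase(sos, rec.data))
    return out


def lowpass_gait(trace: GaitTrace, cutoff: float = DEFAULT_LOWPASS_HZ) -> GaitTrace:
    """Zero-phase second-order Butterworth low-pass on both gait series."""
    nyq = trace.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ConfigurationError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(BUTTER_ORDER, cutoff, btype="lowpass", fs=trace.sampling_rate, output="sos")
    return trace.copy_with(
        angular_velocity=_zero_phase(sos, trace.angular_velocity),
        angle=_zero_phase(sos, trace.angle),
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges average over the available samples only."""
    if window < 1:
        raise InputError("window must be >= 1 sample")
    if window > x.size:
        raise InputError(f"window ({window}) longer than trace ({x.size})")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def rectify_smooth(trace: GaitTrace, window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> GaitTrace:
    """Absolute value, then centered moving average of window_s seconds."""
    if window_s <= 0:
        raise InputError("window_s must be positive")
    w = max(1, int(round(window_s * trace.sampling_rate)))
    return trace.copy_with(
        angular_velocity=moving_average(np.abs(trace.angular_velocity), w),
        angle=moving_average(np.abs(trace.angle), w),
    )


def segment_cycles(
    trace: GaitTrace, min_cycle_s: float = DEFAULT_MIN_CYCLE_S
) -> tuple[np.ndarray, np.ndarray]:
    """Find gait-cycle boundaries at local minima of the smoothed velocity envelope.

    Minima closer together than min_cycle_s are pruned (the deeper one wins via
    peak-distance enforcement).  The trace start and end close the first and
    last cycle; those two edge cycles are flagged partial.

    Returns (boundaries, partial_flags): boundaries are K+1 strictly increasing
    sample indices delimiting K cycles; partial_flags is a boolean array of
    length K marking cycles not bounded by interior minima on both sides.
    """
    env = trace.angular_velocity
    distance = max(1, int(round(min_cycle_s * trace.sampling_rate)))
    minima, _ = signal.find_peaks(-env, distance=distance)
    minima = minima[(minima > 0) & (minima < env.size - 1)]
    boundaries = np.concatenate([[0], minima, [env.size]])
    boundaries = np.unique(boundaries)
    n_cycles = len(boundaries) - 1
    partial = np.zeros(n_cycles, dtype=bool)
    if n_cycles > 0:
        partial[0] = True
        partial[-1] = True
    return boundaries.astype(int), partial


def staircase(series: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Digital step processing: within each cycle [b_k, b_{k+1}) every sample is
    replaced by the cycle's maximum, yielding a piecewise-constant series."""
    series = np.asarray(series, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries[0] != 0 or boundaries[-1] != series.size:
        raise InputError("boundaries must start at 0 and end at the series length")
    out = np.empty_like(series)
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        out[b0:b1] = series[b0:b1].max()
    return out


def process_gait(
    trace: GaitTrace,
    cutoff: float = DEFAULT_LOWPASS_HZ,
    window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
) -> GaitTrace:
    """Full gait chain: low-pass, rectify+smooth, segment, staircase both series.

    Cycle boundaries come from the velocity envelope and are shared by the angle
    series (one gait cycle delimits both parameters).
    """
    smoothed = rectify_smooth(lowpass_gait(trace, cutoff), window_s)
    boundaries, partial = segment_cycles(smoothed, min_cycle_s)
    return smoothed.copy_with(
        cycle_boundaries=boundaries,
        partial_cycles=partial,
        staircase_speed=staircase(smoothed.angular_velocity, boundaries),
        staircase_step=staircase(smoothed.angle, boundaries),
    )
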