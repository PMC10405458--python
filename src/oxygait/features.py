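"""Windowed time-domain and spatial (Pearson) feature extraction.

Per analysis window, per band, per hemoglobin species, nine time-domain
features are computed for every channel — energy, mean, standard deviation,
peak (max absolute value), range, kurtosis, skewness, zero-crossing count and
Shannon information entropy — plus one Pearson correlation coefficient per
unordered channel pair.  For C channels the full battery has

    n_features = 5 bands x 3 species x (9*C + C*(C-1)/2)

columns, i.e. 1,035 for the default 6-channel montage.

Moment conventions: population (1/n) normalization; skewness is the third
standardized moment, kurtosis the plain fourth standardized moment (a Gaussian
scores ~3); on a constant window both are defined as 0, as is entropy.
Zero crossings count strict adjacent sign changes, with zero samples
inheriting the previous sign.  Entropy uses a 16-equal-width-bin histogram
over the window's own min-max range, in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, InputError
from .preprocess import BandDecomposition

TIME_DOMAIN_NAMES = (
    "energy",
    "mean",
    "std",
    "peak",
    "range",
    "kurtosis",
    "skewness",
    "zero_crossings",
    "entropy",
)
ENTROPY_BINS = 16
INDEX_NAMES = ("band", "species", "channel", "feature")


@dataclass
class WindowingPlan:
    """Sliding analysis windows, end-aligned to their target sample."""

    window_s: float = 5.0
    stride_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.stride_s <= self.window_s:
            raise ConfigurationError("need 0 < stride_s <= window_s")


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    # zeros inherit the previous sign; leading zeros take the first nonzero sign
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return 0
    s[: nz[0]] = s[nz[0]]
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _entropy(x: np.ndarray) -> float:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def time_domain_features(window: np.ndarray) -> dict[str, float]:
    """The nine time-domain features of a single-channel window."""
    x = np.asarray(window, dtype=float)
    if x.size < 4:
        raise InputError("window must have at least 4 samples")
    mean = float(x.mean())
    std = float(x.std())  # population
    centered = x - mean
    if std > 0:
        skew = float((centered**3).mean() / std**3)
        kurt = float((centered**4).mean() / std**4)
    else:
        skew = kurt = 0.0
    return {
        "energy": float((x**2).sum()),
        "mean": mean,
        "std": std,
        "peak": float(np.abs(x).max()),
        "range": float(x.max() - x.min()),
        "kurtosis": kurt,
        "skewness": skew,
        "zero_crossings": float(_zero_crossings(x)),
        "entropy": _entropy(x),
    }


def spatial_features(windows: np.ndarray) -> np.ndarray:
    """Pearson coefficients for all unordered channel pairs, lexicographic order.

    windows is (channels, samples); a zero-variance channel contributes 0 to
    every pair it appears in, with a warning.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise InputError("need a (channels, samples) matrix with >= 2 channels")
    if w.shape[1] < 3:
        raise InputError("need at least 3 samples per window")
    sd = w.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance channel(s) {np.flatnonzero(degenerate).tolist()}: "
            "their Pearson coefficients are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(w)
    corr = np.nan_to_num(corr, nan=0.0)
    iu, ju = np.triu_indices(w.shape[0], k=1)
    return corr[iu, ju]


def pair_labels(channel_ids: tuple[str, ...]) -> list[str]:
    iu, ju = np.triu_indices(len(channel_ids), k=1)
    return [f"{channel_ids[i]}-{channel_ids[j]}" for i, j in zip(iu, ju)]


def feature_count(n_channels: int, n_bands: int = 5, n_species: int = 3) -> int:
    """Total feature-column count for a C-channel montage."""
    c = n_channels
    return n_bands * n_species * (len(TIME_DOMAIN_NAMES) * c + c * (c - 1) // 2)


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    if n_samples < win:
        raise InputError(
            f"trial of {n_samples} samples is shorter than one window ({win} samples)"
        )
    return np.arange(0, n_samples - win + 1, step)


def build_feature_matrix(
    decomposition: BandDecomposition, plan: WindowingPlan | None = None
) -> pd.DataFrame:
    """Extract the full battery for every window position.

    Returns a DataFrame with a 4-level column MultiIndex
    (band, species, channel, feature) and the window end times (seconds) as a
    float index named "time".  Spatial rows use the pair label "chI-chJ" as the
    channel level and "pearson" as the feature name.
    """
    plan = plan or WindowingPlan()
    first = next(iter(decomposition.values()))
    fs = first.sampling_rate
    win = int(round(plan.window_s * fs))
    step = max(1, int(round(plan.stride_s * fs)))
    starts = _window_starts(first.n_samples, win, step)
    end_times = (starts + win) / fs

    columns: list[tuple[str, str, str, str]] = []
    blocks: list[np.ndarray] = []
    for (band, species), rec in decomposition.items():
        data = rec.data
        n_ch = rec.n_channels
        td = np.empty((len(starts), n_ch * len(TIME_DOMAIN_NAMES)))
        sp = np.empty((len(starts), n_ch * (n_ch - 1) // 2))
        for wi, s0 in enumerate(starts):
            block = data[:, s0 : s0 + win]
            for ci in range(n_ch):
                feats = time_domain_features(block[ci])
                td[wi, ci * 9 : ci * 9 + 9] = [feats[k] for k in TIME_DOMAIN_NAMES]
            sp[wi] = spatial_features(block)
        for ci in range(n_ch):
            for name in TIME_DOMAIN_NAMES:
                columns.append((band, species, rec.channel_ids[ci], name))
        for pair in pair_labels(rec.channel_ids):
            columns.append((band, species, pair, "pearson"))
        blocks.append(td)
        blocks.append(sp)

    values = np.hstack(blocks)
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite feature values extracted")
    idx = pd.MultiIndex.from_tuples(columns, names=INDEX_NAMES)
    return pd.DataFrame(values, columns=idx, index=pd.Index(end_times, name="time"))


def flatten_index(columns: pd.MultiIndex) -> list[str]:
    """Serialize the structured feature index to 'band|species|channel|feature'."""
    return ["|".join(tup) for tup in columns]


def parse_index(names: list[str]) -> pd.MultiIndex:
    """Inverse of flatten_index."""
    return pd.MultiIndex.from_tuples(
        [tuple(n.split("|")) for n in names], names=INDEX_NAMES
    )


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    flat = features.copy()
    flat.columns = flatten_index(features.columns)
    flat.to_csv(path, index=True)


def read_feature_matrix(path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col=0)
    flat.columns = parse_index(list(flat.columns))
    return flat
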