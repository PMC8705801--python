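"""Signal conditioning: offset trim, median filter, scaling, power transform,
and block-median downsampling.

The median-filter kernel follows the rule ``w = round(n / (4 * fs))`` with an
even-to-odd correction of +1, so a 10-minute 256-Hz channel gets w = 151.
Standardization uses the population (N-divisor) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .signal_io import Recording

__all__ = [
    "PreprocessConfig",
    "ChannelStats",
    "PreprocessError",
    "median_kernel_size",
    "trim_offset",
    "median_filter",
    "standardize",
    "yeo_johnson",
    "downsample_median",
    "preprocess_recording",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for the conditioning stage.

    ``kernel_override`` replaces the kernel-size rule when set (must be odd).
    ``aggregator`` selects the 1-Hz block statistic (median by default; mean
    is used by the phase-1-vs-phase-5 validation analysis).
    """

    trim_seconds: float = 0.5
    kernel_override: int | None = None
    downsample_hz: float = 1.0
    aggregator: str = "median"

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise PreprocessError("trim_seconds must be >= 0")
        if self.kernel_override is not None and self.kernel_override % 2 == 0:
            raise PreprocessError("kernel_override must be odd")
        if self.aggregator not in ("median", "mean"):
            raise PreprocessError(f"unknown aggregator {self.aggregator!r}")


@dataclass(frozen=True)
class ChannelStats:
    """Fitted per-channel scaling parameters."""

    mean: dict[str, float]
    sd: dict[str, float]
    lmbda: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, s in self.sd.items():
            if s <= 0:
                raise PreprocessError(f"channel {ch}: sd must be positive")


def median_kernel_size(fs: float, n: int) -> int:
    """Median-filter window: ``round(n / (4 fs))``, bumped to odd, min 1."""
    if fs <= 0 or n <= 0:
        raise PreprocessError("fs and n must be positive")
    w = int(round(n / (4.0 * fs)))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def trim_offset(rec: Recording, seconds: float) -> Recording:
    """Drop the first ``floor(seconds * fs)`` samples from every channel."""
    if seconds < 0:
        raise PreprocessError("trim seconds must be >= 0")
    n_drop = int(np.floor(seconds * rec.fs))
    if n_drop >= rec.n_samples:
        raise PreprocessError(
            f"cannot trim {seconds} s ({n_drop} samples) from a "
            f"{rec.n_samples}-sample recording"
        )
    if n_drop == 0:
        return rec
    data = rec.data.iloc[n_drop:].reset_index(drop=True)
    return rec.with_data(data, t0_offset=rec.t0_offset + n_drop / rec.fs)


def median_filter(series: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window median with edge-inclusive reflected padding.

    Output has the same length as the input; element k is the median of the
    w-window centred at k.
    """
    series = np.asarray(series, dtype=float)
    if w % 2 == 0:
        raise PreprocessError(f"kernel size must be odd, got {w}")
    if w > series.size:
        raise PreprocessError(f"kernel {w} exceeds series length {series.size}")
    # scipy's 'reflect' mode duplicates the edge sample: (a b c) -> b a | a b c | c b
    return ndimage.median_filter(series, size=w, mode="reflect")


def standardize(series: np.ndarray) -> tuple[np.ndarray, float, float]:
    """z = (x - mean) / sd with the population (divide-by-N) sd.

    Returns ``(z, mean, sd)``.  Raises on constant input.
    """
    series = np.asarray(series, dtype=float)
    a = float(series.mean())
    s = float(series.std(ddof=0))
    if s == 0.0:
        raise PreprocessError("cannot standardize a constant series")
    return (series - a) / s, a, s


def yeo_johnson(series: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-likelihood power transform followed by re-standardization.

    Returns the transformed-and-standardized series and the fitted lambda.
    """
    series = np.asarray(series, dtype=float)
    if np.ptp(series) == 0.0:
        raise PreprocessError("cannot power-transform a constant series")
    transformed, lmbda = stats.yeojohnson(series)
    z, _, _ = standardize(transformed)
    return z, float(lmbda)


def downsample_median(
    matrix: np.ndarray, fs: float, target_hz: float = 1.0, aggregator: str = "median"
) -> np.ndarray:
    """Aggregate consecutive blocks of ``fs / target_hz`` rows to one row each.

    A trailing partial block is aggregated over the samples it has.
    """
    if fs <= 0 or target_hz <= 0:
        raise PreprocessError("rates must be positive")
    ratio = fs / target_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise PreprocessError(f"fs {fs} not divisible by target rate {target_hz}")
    block = int(round(ratio))
    matrix = np.asarray(matrix, dtype=float)
    squeeze = matrix.ndim == 1
    if squeeze:
        matrix = matrix[:, None]
    agg = np.median if aggregator == "median" else np.mean
    if aggregator not in ("median", "mean"):
        raise PreprocessError(f"unknown aggregator {aggregator!r}")
    n_blocks = int(np.ceil(matrix.shape[0] / block))
    out = np.empty((n_blocks, matrix.shape[1]))
    for b in range(n_blocks):
        out[b] = agg(matrix[b * block : (b + 1) * block], axis=0)
    return out[:, 0] if squeeze else out


def preprocess_recording(
    rec: Recording,
    config: PreprocessConfig | None = None,
    power_transform: bool = False,
) -> tuple[Recording, ChannelStats]:
    """Run trim -> median filter -> standardize (-> power transform) per channel.

    The power transform (used only by the linear-PCA distance path) is fitted
    per subject over the whole recording, then re-standardized.  Returns the
    conditioned recording plus the fitted channel statistics.
    """
    config = config or PreprocessConfig()
    trimmed = trim_offset(rec, config.trim_seconds)
    w = config.kernel_override or median_kernel_size(trimmed.fs, trimmed.n_samples)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    lmbdas: dict[str, float] = {}
    out = {}
    for ch in trimmed.data.columns:
        filtered = median_filter(trimmed.channel(ch), w)
        z, a, s = standardize(filtered)
        means[ch], sds[ch] = a, s
        if power_transform:
            z, lmbdas[ch] = yeo_johnson(z)
        out[ch] = z
    data = pd.DataFrame(out, columns=trimmed.data.columns)
    stats_ = ChannelStats(mean=means, sd=sds, lmbda=lmbdas)
    return trimmed.with_data(data), stats_
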