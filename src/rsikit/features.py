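"""Feature construction: first/second-order differencing and phase labelling.

Each of the five conditioned channels is augmented with x(t) - x(t-1) and
x(t) - x(t-2) columns, giving a 15-column matrix.  The first two rows are
dropped so every column is defined on every remaining row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import downsample_median
from .signal_io import PhaseProtocol, Recording

__all__ = [
    "FeatureMatrix",
    "FeatureError",
    "difference_features",
    "segment_phases",
    "build_feature_matrix",
    "downsample_feature_matrix",
]


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-sample feature rows with 1-based phase labels.

    ``start_sample`` is the index of row 0 on the recording's original
    (pre-trim) sample grid; it anchors downsampling blocks and phase windows.
    ``rate`` is "full" or "1hz".
    """

    subject_id: str
    data: np.ndarray
    columns: tuple[str, ...]
    phases: np.ndarray
    fs: float
    start_sample: int = 0
    rate: str = "full"

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise FeatureError("feature data must be 2-D")
        if self.data.shape[1] != len(self.columns):
            raise FeatureError("column names do not match data width")
        if self.data.shape[0] != self.phases.shape[0]:
            raise FeatureError("phase labels do not match row count")
        if np.isnan(self.data).any():
            raise FeatureError("feature matrix contains missing cells")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def phase_ids(self) -> np.ndarray:
        return np.unique(self.phases)

    def phase_rows(self, phase: int) -> np.ndarray:
        """Rows belonging to a 1-based phase index."""
        return self.data[self.phases == phase]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df["phase"] = self.phases
        return df


def difference_features(
    matrix: np.ndarray, columns: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Augment columns with t-1 and t-2 differences; drop the first two rows.

    A c-column input yields a 3c-column output aligned at t = 2.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 3:
        raise FeatureError("differencing needs a 2-D matrix with >= 3 rows")
    if columns is None:
        columns = tuple(f"c{k}" for k in range(matrix.shape[1]))
    d1 = matrix[1:] - matrix[:-1]  # defined from t=1
    d2 = matrix[2:] - matrix[:-2]  # defined from t=2
    out = np.hstack([matrix[2:], d1[1:], d2])
    names = (
        tuple(columns)
        + tuple(f"{c}_d1" for c in columns)
        + tuple(f"{c}_d2" for c in columns)
    )
    return out, names


def segment_phases(
    n_samples: int,
    protocol: PhaseProtocol,
    fs: float,
    t0_offset: float = 0.0,
    start_sample: int | None = None,
) -> np.ndarray:
    """1-based phase label per sample; boundaries are half-open in samples.

    The sample grid is anchored at the original t = 0, so samples trimmed
    from the start are deducted from phase 1 only.  ``start_sample``
    overrides the offset-derived grid origin (used for differenced rows).
    """
    if start_sample is None:
        start_sample = int(np.floor(t0_offset * fs))
    if n_samples <= 0:
        raise FeatureError("need at least one sample to label")
    global_idx = np.arange(n_samples) + start_sample
    end_sample = int(np.floor(protocol.end_s * fs))
    if global_idx[-1] >= end_sample:
        raise FeatureError(
            f"recording extends to sample {global_idx[-1]} beyond the protocol "
            f"end (sample {end_sample})"
        )
    labels = np.empty(n_samples, dtype=np.int64)
    windows = protocol.sample_windows(fs)
    for k, (lo, hi) in enumerate(windows, start=1):
        labels[(global_idx >= lo) & (global_idx < hi)] = k
    if global_idx.size and global_idx[0] < windows[0][0]:
        raise FeatureError("samples precede the protocol start")
    return labels


def build_feature_matrix(rec: Recording, protocol: PhaseProtocol) -> FeatureMatrix:
    """Difference a conditioned recording and attach phase labels."""
    base_cols = tuple(rec.data.columns)
    data, names = difference_features(rec.data.to_numpy(), base_cols)
    start = int(np.floor(rec.t0_offset * rec.fs)) + 2  # two rows lost to differencing
    phases = segment_phases(
        data.shape[0], protocol, rec.fs, start_sample=start
    )
    return FeatureMatrix(
        subject_id=rec.subject_id,
        data=data,
        columns=names,
        phases=phases,
        fs=rec.fs,
        start_sample=start,
        rate="full",
    )


def downsample_feature_matrix(
    fm: FeatureMatrix, target_hz: float = 1.0, aggregator: str = "median"
) -> FeatureMatrix:
    """Aggregate rows into blocks aligned to the original 1-s grid.

    Each output row is the block median (or mean) of the samples falling in
    one second of the original timeline; its phase label is taken at the
    block's position in the protocol.  Blocks straddling a phase boundary do
    not occur with integer-second protocols at integer fs.
    """
    if fm.rate != "full":
        raise FeatureError("feature matrix is already downsampled")
    block = fm.fs / target_hz
    if abs(block - round(block)) > 1e-9:
        raise FeatureError(f"fs {fm.fs} not divisible by {target_hz} Hz")
    block = int(round(block))
    global_idx = np.arange(fm.n_rows) + fm.start_sample
    sec = global_idx // block
    uniq = np.unique(sec)
    agg = np.median if aggregator == "median" else np.mean
    data = np.empty((uniq.size, fm.n_features))
    phases = np.empty(uniq.size, dtype=np.int64)
    for k, s in enumerate(uniq):
        mask = sec == s
        data[k] = agg(fm.data[mask], axis=0)
        # label by the block's first sample present (phase windows are
        # aligned to whole seconds, so all samples in a block agree)
        phases[k] = fm.phases[mask][0]
    return replace(
        fm,
        data=data,
        phases=phases,
        fs=target_hz,
        start_sample=int(uniq[0]),
        rate="1hz",
    )
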