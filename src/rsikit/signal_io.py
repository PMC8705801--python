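"""Reading and writing of recordings, phase protocols and questionnaire scores.

A recording is a uniformly sampled five-channel block (EMG, BVP, BR, SC, PT)
stored as plain CSV with a mandatory header.  Protocols are ordered lists of
contiguous phase windows with roles; the default is five two-minute phases
(baseline, stressor, recovery, stressor, recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CHANNELS",
    "Recording",
    "Phase",
    "PhaseProtocol",
    "SignalIOError",
    "MissingChannelError",
    "NonNumericDataError",
    "RaggedRowsError",
    "ProtocolError",
    "ScoreRangeError",
    "read_recording",
    "write_recording",
    "default_protocol",
    "load_protocol",
    "read_scores",
    "write_scores",
]

#: Canonical channel order used throughout the package.
CHANNELS: tuple[str, ...] = ("EMG", "BVP", "BR", "SC", "PT")

#: Case-insensitive header aliases accepted on input.
_ALIASES: dict[str, str] = {
    "emg": "EMG",
    "bvp": "BVP",
    "br": "BR",
    "resp": "BR",
    "breathing": "BR",
    "sc": "SC",
    "gsr": "SC",
    "eda": "SC",
    "pt": "PT",
    "temp": "PT",
    "temperature": "PT",
}

#: Valid questionnaire total range (inclusive).
SCORE_RANGE: tuple[int, int] = (43, 172)

PHASE_ROLES = ("baseline", "stressor", "recovery")


class SignalIOError(ValueError):
    """Base class for recording/protocol input errors."""


class MissingChannelError(SignalIOError):
    """A required channel column is absent from the input file."""


class NonNumericDataError(SignalIOError):
    """A channel contains a missing or non-numeric cell."""


class RaggedRowsError(SignalIOError):
    """Rows of the input file do not all have the same number of fields."""


class ProtocolError(SignalIOError):
    """Phase protocol is malformed (overlap, gap, bad role, ...)."""


class ScoreRangeError(SignalIOError):
    """Questionnaire total outside the instrument's valid range."""


@dataclass(frozen=True)
class Recording:
    """One subject's five-channel, uniformly sampled signal block.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    fs : float
        Sampling rate in Hz (> 0).
    data : pandas.DataFrame
        One column per channel in canonical order, one row per sample.
    t0_offset : float
        Seconds already trimmed from the start of the recording.
    """

    subject_id: str
    fs: float
    data: pd.DataFrame
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SignalIOError(f"sampling rate must be positive, got {self.fs}")
        if tuple(self.data.columns) != CHANNELS:
            missing = [c for c in CHANNELS if c not in self.data.columns]
            if missing:
                raise MissingChannelError(f"missing channel(s): {missing}")
            object.__setattr__(self, "data", self.data.loc[:, list(CHANNELS)])
        if self.data.isna().any().any():
            raise NonNumericDataError("recording contains missing values")
        for col in CHANNELS:
            if not np.issubdtype(self.data[col].dtype, np.number):
                raise NonNumericDataError(f"channel {col} is not numeric")
        if self.t0_offset < 0:
            raise SignalIOError("t0_offset must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        """Remaining duration in seconds (after any trim)."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def with_data(self, data: pd.DataFrame, **changes) -> "Recording":
        return replace(self, data=data, **changes)


@dataclass(frozen=True)
class Phase:
    name: str
    start_s: float
    end_s: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in PHASE_ROLES:
            raise ProtocolError(f"unknown phase role {self.role!r}")
        if not self.start_s < self.end_s:
            raise ProtocolError(
                f"phase {self.name!r}: start {self.start_s} must precede end {self.end_s}"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseProtocol:
    """Ordered, contiguous, non-overlapping phase schedule."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError("protocol must contain at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))
        prev_end = self.phases[0].start_s
        for ph in self.phases:
            if ph.start_s < prev_end:
                raise ProtocolError(f"phase {ph.name!r} overlaps the previous phase")
            if ph.start_s > prev_end:
                raise ProtocolError(f"gap before phase {ph.name!r}")
            prev_end = ph.end_s
        n_base = sum(1 for ph in self.phases if ph.role == "baseline")
        if n_base != 1:
            raise ProtocolError(f"exactly one baseline phase required, got {n_base}")

    def __len__(self) -> int:
        return len(self.phases)

    def __iter__(self):
        return iter(self.phases)

    @property
    def baseline_index(self) -> int:
        """1-based index of the baseline phase."""
        for k, ph in enumerate(self.phases, start=1):
            if ph.role == "baseline":
                return k
        raise ProtocolError("no baseline phase")  # unreachable

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def sample_windows(self, fs: float) -> list[tuple[int, int]]:
        """Half-open sample windows ``[floor(start*fs), floor(end*fs))``."""
        return [
            (int(np.floor(ph.start_s * fs)), int(np.floor(ph.end_s * fs)))
            for ph in self.phases
        ]

    def phase_at(self, t: float) -> int:
        """1-based phase index containing time ``t`` (half-open windows)."""
        for k, ph in enumerate(self.phases, start=1):
            if ph.start_s <= t < ph.end_s:
                return k
        raise ProtocolError(f"time {t} s is outside the protocol [{self.start_s}, {self.end_s})")


def default_protocol() -> PhaseProtocol:
    """Five 120-s phases: baseline, stressor, recovery, stressor, recovery."""
    roles = ("baseline", "stressor", "recovery", "stressor", "recovery")
    phases = tuple(
        Phase(name=f"phase{k + 1}", start_s=120.0 * k, end_s=120.0 * (k + 1), role=roles[k])
        for k in range(5)
    )
    return PhaseProtocol(phases)


def load_protocol(path: str | Path | None = None) -> PhaseProtocol:
    """Load a phase protocol from a YAML file, or return the default.

    The file holds a ``phases`` list of mappings with keys ``name``,
    ``start_s``, ``end_s`` and ``role``.
    """
    if path is None:
        return default_protocol()
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "phases" not in cfg:
        raise ProtocolError("protocol config must contain a 'phases' list")
    phases = []
    for entry in cfg["phases"]:
        try:
            phases.append(
                Phase(
                    name=str(entry["name"]),
                    start_s=float(entry["start_s"]),
                    end_s=float(entry["end_s"]),
                    role=str(entry["role"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ProtocolError(f"malformed phase entry {entry!r}") from exc
    return PhaseProtocol(tuple(phases))


def _canonical_columns(columns: Sequence[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        canon = _ALIASES.get(str(col).strip().lower())
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    missing = [c for c in CHANNELS if c not in mapping.values()]
    if missing:
        raise MissingChannelError(
            f"input lacks channel column(s) {missing}; found {list(columns)}"
        )
    return mapping


def read_recording(
    path: str | Path,
    fs: float = 256.0,
    subject_id: str | None = None,
    t0_offset: float = 0.0,
) -> Recording:
    """Read a five-channel CSV recording.

    The header must name all five channels (case-insensitive aliases are
    accepted, e.g. ``gsr`` for SC).  Missing columns, non-numeric cells and
    ragged rows each raise a distinct error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0)
    except pd.errors.ParserError as exc:
        raise RaggedRowsError(f"{path}: {exc}") from exc
    mapping = _canonical_columns(df.columns)
    df = df.rename(columns=mapping).loc[:, list(CHANNELS)]
    for col in CHANNELS:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            bad = int(series.isna().idxmax())
            raise NonNumericDataError(f"{path}: non-numeric value in {col} at row {bad}")
        df[col] = series.astype(float)
    if subject_id is None:
        subject_id = path.stem
    return Recording(subject_id=subject_id, fs=fs, data=df, t0_offset=t0_offset)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV at full floating-point precision."""
    rec.data.to_csv(path, index=False, float_format="%.17g")


def read_scores(path: str | Path) -> dict[str, int]:
    """Read questionnaire totals from a two-column CSV (subject_id, score)."""
    df = pd.read_csv(path, header=0)
    if df.shape[1] < 2:
        raise SignalIOError("scores file needs two columns: subject_id, score")
    out: dict[str, int] = {}
    lo, hi = SCORE_RANGE
    for _, row in df.iterrows():
        sid, score = str(row.iloc[0]), row.iloc[1]
        try:
            score = int(score)
        except (TypeError, ValueError) as exc:
            raise NonNumericDataError(f"non-integer score for subject {sid}") from exc
        if not lo <= score <= hi:
            raise ScoreRangeError(f"score {score} for {sid} outside [{lo}, {hi}]")
        out[sid] = score
    return out


def write_scores(scores: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"subject_id": list(scores), "score": list(scores.values())}
    ).to_csv(path, index=False)
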