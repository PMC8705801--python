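"""Cohort-relative indices.

For each subject and method, the signed recovery delta is
``delta_r = D(4) - D(5)`` (distance to baseline at the last stressor minus at
the last recovery): positive means phase 5 ended nearer the baseline.  The
resilience index normalizes by the cohort maximum delta, so the best
recoverer scores exactly 1 and non-recoverers score negative.

The alteration factor min-max normalizes each subject's maximum
baseline-relative stretch over the cohort, landing in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase_distances import PhaseDistanceProfile

__all__ = [
    "SubjectRecovery",
    "CohortIndices",
    "CohortError",
    "recovery_delta",
    "subject_max_stretch",
    "compute_rsi",
    "compute_af",
    "cohort_indices",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectRecovery:
    subject_id: str
    method: str
    delta_r: float
    sub_max_s: float


@dataclass(frozen=True)
class CohortIndices:
    """Per-subject indices plus the cohort normalizers that produced them."""

    table: pd.DataFrame  # subject_id, method, D2..D5, delta_r, sub_max_s, rsi, af
    normalizers: dict  # method -> {delta_s, sam_min_s, delta_sam_st}

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()


def recovery_delta(
    profile: PhaseDistanceProfile, stressor: int = 4, recovery: int = 5
) -> float:
    """Signed recovery: D(last stressor) - D(last recovery)."""
    try:
        return float(profile[stressor] - profile[recovery])
    except KeyError as exc:
        raise CohortError(
            f"profile for {profile.subject_id} lacks phase {exc.args[0]}"
        ) from exc


def subject_max_stretch(profile: PhaseDistanceProfile) -> float:
    """Maximum baseline-relative distance over the non-baseline phases."""
    if not profile.distances:
        raise CohortError("empty distance profile")
    return float(max(profile.distances.values()))


def compute_rsi(deltas: np.ndarray) -> np.ndarray:
    """Normalize recovery deltas by the cohort maximum.

    Requires at least two subjects and a strictly positive maximum (someone
    must have recovered, or the normalizer is meaningless).
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 2:
        raise CohortError("cohort indices need at least two subjects")
    delta_s = deltas.max()
    if delta_s <= 0:
        raise CohortError("no subject recovered (max delta <= 0); RSI undefined")
    return deltas / delta_s


def compute_af(stretches: np.ndarray) -> np.ndarray:
    """Min-max normalize maximum stretches over the cohort."""
    stretches = np.asarray(stretches, dtype=float)
    if stretches.size < 2:
        raise CohortError("cohort indices need at least two subjects")
    span = stretches.max() - stretches.min()
    if span <= 0:
        raise CohortError("all stretches equal; alteration factor undefined")
    return (stretches - stretches.min()) / span


def cohort_indices(
    profiles: list[PhaseDistanceProfile],
    stressor: int = 4,
    recovery: int = 5,
) -> CohortIndices:
    """Assemble the per-subject index table for one or more methods.

    Normalizers are computed per method, never pooled across methods.
    """
    if not profiles:
        raise CohortError("no distance profiles supplied")
    rows = []
    for pr in profiles:
        rows.append(
            {
                "subject_id": pr.subject_id,
                "method": pr.method,
                **{f"D{i}": pr.distances[i] for i in sorted(pr.distances)},
                "delta_r": recovery_delta(pr, stressor, recovery),
                "sub_max_s": subject_max_stretch(pr),
            }
        )
    df = pd.DataFrame(rows)
    normalizers: dict[str, dict[str, float]] = {}
    df["rsi"] = np.nan
    df["af"] = np.nan
    for method, grp in df.groupby("method"):
        if grp["subject_id"].duplicated().any():
            raise CohortError(f"duplicate subject ids for method {method}")
        rsi = compute_rsi(grp["delta_r"].to_numpy())
        af = compute_af(grp["sub_max_s"].to_numpy())
        df.loc[grp.index, "rsi"] = rsi
        df.loc[grp.index, "af"] = af
        stretches = grp["sub_max_s"].to_numpy()
        normalizers[method] = {
            "delta_s": float(grp["delta_r"].max()),
            "sam_min_s": float(stretches.min()),
            "delta_sam_st": float(stretches.max() - stretches.min()),
        }
    return CohortIndices(table=df, normalizers=normalizers)
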