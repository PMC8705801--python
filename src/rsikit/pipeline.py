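"""End-to-end orchestration: conditioning -> features -> distances -> indices."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .features import build_feature_matrix, downsample_feature_matrix
from .indices import CohortIndices, cohort_indices
from .phase_distances import (
    METHODS,
    PhaseDistanceProfile,
    cvid_scores,
    edpca_distances,
    kpca_distances,
    mahalanobis_distances,
)
from .preprocess import PreprocessConfig, preprocess_recording
from .signal_io import PhaseProtocol, Recording, default_protocol

__all__ = ["SubjectResult", "analyze_subject", "analyze_cohort", "build_manifest"]

logger = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    subject_id: str
    profiles: dict[str, PhaseDistanceProfile]
    kernel_size: int | None = None


def analyze_subject(
    rec: Recording,
    protocol: PhaseProtocol | None = None,
    methods: tuple[str, ...] = METHODS,
    config: PreprocessConfig | None = None,
    kpca_kwargs: dict | None = None,
) -> SubjectResult:
    """Run the selected distance methods for one subject.

    The linear-PCA path gets power-transformed features; the Mahalanobis and
    silhouette paths use plain standardized features; the kernel-PCA and
    silhouette paths run on 1-Hz block medians.
    """
    protocol = protocol or default_protocol()
    config = config or PreprocessConfig()
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown method(s): {sorted(bad)}")
    baseline = protocol.baseline_index
    profiles: dict[str, PhaseDistanceProfile] = {}

    need_plain = {"md", "cvid", "edkpca"} & set(methods)
    plain_fm = None
    if need_plain:
        plain_rec, _ = preprocess_recording(rec, config, power_transform=False)
        plain_fm = build_feature_matrix(plain_rec, protocol)
    low_fm = None
    if {"cvid", "edkpca"} & set(methods):
        low_fm = downsample_feature_matrix(
            plain_fm, target_hz=config.downsample_hz, aggregator=config.aggregator
        )

    if "edpca" in methods:
        pt_rec, _ = preprocess_recording(rec, config, power_transform=True)
        pt_fm = build_feature_matrix(pt_rec, protocol)
        profiles["edpca"] = edpca_distances(pt_fm, baseline=baseline)
    if "md" in methods:
        profiles["md"] = mahalanobis_distances(plain_fm, baseline=baseline)
    if "cvid" in methods:
        profiles["cvid"] = cvid_scores(low_fm, baseline=baseline)
    if "edkpca" in methods:
        profiles["edkpca"] = kpca_distances(low_fm, baseline=baseline, **(kpca_kwargs or {}))
    return SubjectResult(rec.subject_id, profiles)


def analyze_cohort(
    recordings: list[Recording],
    protocol: PhaseProtocol | None = None,
    methods: tuple[str, ...] = METHODS,
    config: PreprocessConfig | None = None,
    stressor: int | None = None,
    recovery: int | None = None,
    kpca_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, CohortIndices]:
    """Distances and cohort indices for every subject and method.

    Returns the tidy distance table (subject_id, method, phase, value) and
    the cohort index table.  The recovery delta uses the last stressor and
    last recovery phases of the protocol by default.
    """
    protocol = protocol or default_protocol()
    if len(recordings) < 2:
        raise ValueError("cohort analysis needs at least two subjects")
    if stressor is None:
        stressor = max(
            k for k, ph in enumerate(protocol, start=1) if ph.role == "stressor"
        )
    if recovery is None:
        recovery = max(
            k for k, ph in enumerate(protocol, start=1) if ph.role == "recovery"
        )
    all_profiles: list[PhaseDistanceProfile] = []
    for rec in recordings:
        logger.info("analyzing subject %s", rec.subject_id)
        res = analyze_subject(rec, protocol, methods, config, kpca_kwargs)
        all_profiles.extend(res.profiles.values())
    rows = [
        {"subject_id": pr.subject_id, "method": pr.method, "phase": i, "value": d}
        for pr in all_profiles
        for i, d in sorted(pr.distances.items())
    ]
    distances = pd.DataFrame(rows)
    indices = cohort_indices(all_profiles, stressor=stressor, recovery=recovery)
    return distances, indices


def build_manifest(
    config: PreprocessConfig,
    methods: tuple[str, ...],
    protocol: PhaseProtocol,
    seeds: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """JSON-serializable record of every parameter that shaped a run."""
    return {
        "rsikit_version": __version__,
        "preprocess": {
            "trim_seconds": config.trim_seconds,
            "kernel_override": config.kernel_override,
            "downsample_hz": config.downsample_hz,
            "aggregator": config.aggregator,
        },
        "methods": list(methods),
        "protocol": [
            {"name": ph.name, "start_s": ph.start_s, "end_s": ph.end_s, "role": ph.role}
            for ph in protocol
        ],
        "seeds": seeds or {},
        **(extra or {}),
    }
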