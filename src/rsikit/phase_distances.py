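"""Baseline-relative phase separation, four ways.

Each method treats a phase's feature rows as a cluster and reports, per
phase i, the separation of (baseline, phase i):

* ``edpca``   — Euclidean distance between centroids in full PCA space;
* ``md``      — mean Mahalanobis distance of phase-i rows to the baseline
  centroid, under the pooled covariance of the pair;
* ``cvid``    — mean silhouette of the two-cluster labelling, Mahalanobis
  metric under the pooled-pair covariance;
* ``edkpca``  — Euclidean distance between centroids in kernel-PCA space,
  computed on 1-Hz downsampled rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA, KernelPCA
from sklearn.metrics import silhouette_score

from .features import FeatureMatrix

__all__ = [
    "METHODS",
    "PhaseDistanceProfile",
    "DistanceError",
    "edpca_distances",
    "mahalanobis_distance",
    "mahalanobis_distances",
    "cvid_score",
    "cvid_scores",
    "kpca_distances",
    "median_heuristic_gamma",
    "regularized_inverse",
]

#: Canonical method keys, in reporting order.
METHODS: tuple[str, ...] = ("edpca", "md", "cvid", "edkpca")

#: Ridge engages when the covariance condition number exceeds this.
COND_THRESHOLD = 1e10
RIDGE_SCALE = 1e-6


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseDistanceProfile:
    """Per-subject, per-method separation of each phase from the baseline.

    ``distances`` maps 1-based phase index -> distance (or silhouette score
    for ``cvid``).  ``diagnostics`` records fit details (explained variance,
    covariance condition numbers, whether a ridge was applied, kernel
    settings...).
    """

    subject_id: str
    method: str
    distances: dict[int, float]
    baseline: int = 1
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DistanceError(f"unknown method {self.method!r}")
        for i, d in self.distances.items():
            if self.method in ("edpca", "md", "edkpca") and d < 0:
                raise DistanceError(f"{self.method} distance for phase {i} is negative")
            if self.method == "cvid" and not -1.0 <= d <= 1.0:
                raise DistanceError(f"silhouette for phase {i} outside [-1, 1]")

    def __getitem__(self, phase: int) -> float:
        return self.distances[phase]

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(sorted(self.distances))


def _nonbaseline_phases(fm: FeatureMatrix, baseline: int) -> list[int]:
    ids = [int(p) for p in fm.phase_ids]
    if baseline not in ids:
        raise DistanceError(f"baseline phase {baseline} absent from feature matrix")
    others = [p for p in ids if p != baseline]
    if not others:
        raise DistanceError("need at least one non-baseline phase")
    return others


def regularized_inverse(cov: np.ndarray) -> tuple[np.ndarray, bool, float]:
    """Invert a covariance matrix, adding a scaled ridge if ill-conditioned.

    Returns ``(inverse, ridge_applied, condition_number)``.
    """
    cond = float(np.linalg.cond(cov))
    ridged = False
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        eps = RIDGE_SCALE * np.trace(cov) / cov.shape[0]
        if eps <= 0:
            eps = RIDGE_SCALE
        cov = cov + eps * np.eye(cov.shape[0])
        ridged = True
        cond = float(np.linalg.cond(cov))
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise DistanceError("covariance singular even after ridge") from exc
    return inv, ridged, cond


def edpca_distances(
    fm: FeatureMatrix, baseline: int = 1, n_components: int | None = None
) -> PhaseDistanceProfile:
    """Centroid-to-centroid Euclidean distances in full PCA space.

    The PCA is fitted on the subject's pooled rows with all components
    retained (an orthogonal map), so distances equal those measured
    directly in the transformed feature space.
    """
    others = _nonbaseline_phases(fm, baseline)
    n_comp = n_components or fm.n_features
    if fm.n_rows < fm.n_features:
        raise DistanceError(
            f"rank-deficient input: {fm.n_rows} rows < {fm.n_features} features"
        )
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(fm.data)
    centroids = {
        p: scores[fm.phases == p].mean(axis=0) for p in [baseline, *others]
    }
    dists = {
        p: float(np.linalg.norm(centroids[p] - centroids[baseline])) for p in others
    }
    diag = {
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "n_components": n_comp,
    }
    return PhaseDistanceProfile(fm.subject_id, "edpca", dists, baseline, diag)


def mahalanobis_distance(
    fm: FeatureMatrix,
    phase: int,
    baseline: int = 1,
    instances: str = "target",
    vi: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Mean Mahalanobis distance of phase rows to the baseline centroid.

    The metric is the inverse covariance of the pooled (baseline, phase)
    rows.  ``instances`` selects which rows are averaged: the target phase's
    ("target", default) or the pooled pair's ("pooled").  ``vi`` overrides
    the inverse covariance (used by identity-metric oracles).
    """
    if instances not in ("target", "pooled"):
        raise DistanceError(f"unknown instances mode {instances!r}")
    base_rows = fm.phase_rows(baseline)
    phase_rows = fm.phase_rows(phase)
    if phase_rows.size == 0:
        raise DistanceError(f"phase {phase} has no rows")
    pooled = np.vstack([base_rows, phase_rows])
    diag: dict = {}
    if vi is None:
        if pooled.shape[0] <= pooled.shape[1]:
            raise DistanceError("phase pair has fewer rows than features")
        cov = np.cov(pooled, rowvar=False)
        vi, ridged, cond = regularized_inverse(cov)
        diag = {"ridge_applied": ridged, "cov_condition": cond}
    centroid = base_rows.mean(axis=0)
    pts = phase_rows if instances == "target" else pooled
    d = cdist(pts, centroid[None, :], metric="mahalanobis", VI=vi)
    return float(d.mean()), diag


def mahalanobis_distances(
    fm: FeatureMatrix, baseline: int = 1, instances: str = "target"
) -> PhaseDistanceProfile:
    others = _nonbaseline_phases(fm, baseline)
    dists: dict[int, float] = {}
    diag: dict = {"per_phase": {}}
    for p in others:
        dists[p], diag["per_phase"][p] = mahalanobis_distance(
            fm, p, baseline=baseline, instances=instances
        )
    return PhaseDistanceProfile(fm.subject_id, "md", dists, baseline, diag)


def cvid_score(
    fm: FeatureMatrix,
    pair: tuple[int, int],
    vi: np.ndarray | None = None,
) -> float:
    """Mean silhouette of a two-phase labelling under a Mahalanobis metric.

    The metric's covariance is estimated from the pooled rows of the pair
    unless ``vi`` supplies an inverse covariance directly.
    """
    i, j = pair
    a = fm.phase_rows(i)
    b = fm.phase_rows(j)
    if len(a) < 2 or len(b) < 2:
        raise DistanceError("each phase needs at least two points for a silhouette")
    x = np.vstack([a, b])
    labels = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    if vi is None:
        cov = np.cov(x, rowvar=False)
        cov = np.atleast_2d(cov)
        vi, _, _ = regularized_inverse(cov)
    return float(silhouette_score(x, labels, metric="mahalanobis", VI=vi))


def cvid_scores(fm: FeatureMatrix, baseline: int = 1) -> PhaseDistanceProfile:
    """Silhouette of each (baseline, phase) pair; full pairwise map in diagnostics."""
    others = _nonbaseline_phases(fm, baseline)
    scores = {p: cvid_score(fm, (baseline, p)) for p in others}
    all_ids = [baseline, *others]
    pairwise = {
        f"{i}-{j}": cvid_score(fm, (i, j))
        for k, i in enumerate(all_ids)
        for j in all_ids[k + 1 :]
    }
    return PhaseDistanceProfile(
        fm.subject_id, "cvid", scores, baseline, {"pairwise": pairwise}
    )


def median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise Euclidean distance."""
    d = cdist(x, x)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med <= 0:
        raise DistanceError("degenerate data: zero median pairwise distance")
    return 1.0 / (2.0 * med**2)


def kpca_distances(
    fm: FeatureMatrix,
    baseline: int = 1,
    kernel: str = "rbf",
    gamma: float | None = None,
    n_components: int = 15,
) -> PhaseDistanceProfile:
    """Centroid distances in kernel-PCA space on downsampled rows.

    Defaults: RBF kernel with a median-heuristic bandwidth, 15 retained
    components.  Intended for 1-Hz inputs (~120 rows per phase).
    """
    others = _nonbaseline_phases(fm, baseline)
    if fm.n_rows < n_components + 1:
        raise DistanceError(
            f"too few rows ({fm.n_rows}) for {n_components} kernel components"
        )
    if kernel == "rbf" and gamma is None:
        gamma = median_heuristic_gamma(fm.data)
    kp = KernelPCA(n_components=n_components, kernel=kernel, gamma=gamma)
    scores = kp.fit_transform(fm.data)
    if not np.isfinite(scores).all():
        raise DistanceError("degenerate kernel matrix")
    centroids = {p: scores[fm.phases == p].mean(axis=0) for p in [baseline, *others]}
    dists = {
        p: float(np.linalg.norm(centroids[p] - centroids[baseline])) for p in others
    }
    diag = {"kernel": kernel, "gamma": gamma, "n_components": n_components}
    return PhaseDistanceProfile(fm.subject_id, "edkpca", dists, baseline, diag)
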