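"""Statistical validation machinery.

Covers the normality-gated correlation of per-method index vectors against
questionnaire totals, the Friedman comparison across methods, and the
per-channel baseline-vs-final-recovery rank correlations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

from .features import segment_phases
from .preprocess import downsample_median
from .signal_io import CHANNELS, PhaseProtocol, Recording

__all__ = [
    "StatsError",
    "MethodComparison",
    "ValidationReport",
    "spearman",
    "pearson",
    "anderson_darling",
    "friedman",
    "phase15_feature_correlations",
    "resim_validation",
]

logger = logging.getLogger(__name__)

#: Exact permutation p-values are used for rank correlations up to this n.
EXACT_SPEARMAN_N = 8


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class MethodComparison:
    """Friedman comparison across methods (columns) over subjects (rows)."""

    statistic: float
    pvalue: float
    mean_ranks: pd.Series  # per method, rank 1 = smallest value
    summary: pd.DataFrame  # per method: median, mad, mean_rank


@dataclass(frozen=True)
class ValidationReport:
    """Per-method normality gate + correlation against questionnaire totals."""

    table: pd.DataFrame  # method, ad_stat_*, normal_*, coefficient, r, p
    alpha: float
    notes: list = field(default_factory=list)


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("inputs must be 1-D and of equal length")
    if x.size < min_n:
        raise StatsError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    return x, y


def _exact_spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided permutation p for a tie-free rank correlation, |rho'| >= |rho|."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(base):
        d2 = int(np.sum((np.asarray(perm) - base) ** 2))
        r = 1.0 - 6.0 * d2 / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank correlation with average ranks on ties.

    For tie-free samples with n <= 8 the p-value is the exact two-sided
    permutation probability; otherwise the large-sample t approximation.
    """
    x, y = _check_pair(x, y)
    rho, p_approx = stats.spearmanr(x, y)
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if tie_free and n <= EXACT_SPEARMAN_N:
        return float(rho), _exact_spearman_pvalue(float(rho), n)
    return float(rho), float(p_approx)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation; p from the t distribution on n-2 dof."""
    x, y = _check_pair(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def anderson_darling(x: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Normality test with mean/variance estimated from the sample.

    Applies the (1 + 0.75/n + 2.25/n^2) small-sample adjustment and the
    standard p interpolation.  Returns ``(statistic, p, normal?)`` where
    ``normal?`` is True when the null of normality is retained at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise StatsError(f"normality test needs >= 5 points, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("normality test undefined for a constant vector")
    a2, p = normal_ad(x)
    return float(a2), float(p), bool(p > alpha)


def friedman(values: np.ndarray | pd.DataFrame) -> MethodComparison:
    """Within-subject rank comparison across methods, with tie correction.

    ``values`` is subjects x methods.  Also emits a per-method summary of the
    median, the median absolute deviation and the mean rank (rank 1 =
    smallest value within a subject).
    """
    if isinstance(values, pd.DataFrame):
        methods = list(values.columns)
        mat = values.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
        methods = [f"m{k}" for k in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise StatsError("need >= 2 subjects and >= 2 methods")
    if np.isnan(mat).any():
        raise StatsError("missing method value for some subject")
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=methods, name="mean_rank")
    if np.allclose(mat, mat[:, [0]]):
        statistic, p = 0.0, 1.0  # degenerate: all methods identical
    else:
        statistic, p = stats.friedmanchisquare(*mat.T)
    med = np.median(mat, axis=0)
    mad = stats.median_abs_deviation(mat, axis=0)
    summary = pd.DataFrame(
        {"median": med, "mad": mad, "mean_rank": mean_ranks.to_numpy()},
        index=methods,
    )
    return MethodComparison(float(statistic), float(p), mean_ranks, summary)


def phase15_feature_correlations(
    rec: Recording,
    protocol: PhaseProtocol,
    baseline: int = 1,
    recovery: int = 5,
    aggregator: str = "mean",
) -> dict[str, float]:
    """Per-channel rank correlation between the baseline and final phases.

    The conditioned channels are aggregated to 1 Hz (mean per second by
    default), split into the two phases, paired by within-phase position
    (truncating to the shorter series with a logged warning) and correlated.
    Returns channel -> rho plus the unweighted ``"mean"`` across channels.
    """
    labels = segment_phases(
        rec.n_samples, protocol, rec.fs, t0_offset=rec.t0_offset
    )
    out: dict[str, float] = {}
    for ch in rec.data.columns:
        series = {}
        for ph in (baseline, recovery):
            raw = rec.channel(ch)[labels == ph]
            if raw.size == 0:
                raise StatsError(f"phase {ph} has no samples")
            series[ph] = downsample_median(
                raw, rec.fs, target_hz=1.0, aggregator=aggregator
            )
        a, b = series[baseline], series[recovery]
        if a.size != b.size:
            n = min(a.size, b.size)
            logger.warning(
                "phase %d/%d lengths differ after aggregation (%d vs %d); "
                "truncating to %d",
                baseline, recovery, a.size, b.size, n,
            )
            a, b = a[:n], b[:n]
        out[ch] = spearman(a, b)[0]
    out["mean"] = float(np.mean([out[ch] for ch in rec.data.columns]))
    return out


def resim_validation(
    rsi_by_method: pd.DataFrame,
    scores: dict[str, int] | pd.Series,
    alpha: float = 0.05,
    force: dict[str, str] | None = None,
) -> ValidationReport:
    """Normality-gated correlation of each method's index against totals.

    ``rsi_by_method`` is subjects x methods, indexed by subject id.  Both
    the method vector and the score vector must pass the normality gate for
    the product-moment coefficient to be used; otherwise the rank
    coefficient is taken.  With fewer than 5 subjects the gate cannot run
    and the rank coefficient is used with a logged warning.  ``force`` maps
    method -> "pearson" | "spearman" to bypass the gate (for replaying a
    published assignment).
    """
    scores = pd.Series(scores)
    missing = set(rsi_by_method.index) ^ set(scores.index)
    if missing:
        raise StatsError(f"subject sets differ: {sorted(missing)}")
    scores = scores.loc[rsi_by_method.index].astype(float)
    force = force or {}
    notes: list[str] = []
    n = len(scores)
    gate_possible = n >= 5
    if gate_possible:
        ad_scores = anderson_darling(scores.to_numpy(), alpha)
    rows = []
    for method in rsi_by_method.columns:
        vec = rsi_by_method[method].to_numpy(dtype=float)
        row: dict = {"method": method}
        if method in force:
            choice = force[method]
            if choice not in ("pearson", "spearman"):
                raise StatsError(f"force[{method}] must be pearson or spearman")
            row.update(ad_stat=np.nan, ad_p=np.nan, normal=np.nan)
        elif not gate_possible:
            choice = "spearman"
            row.update(ad_stat=np.nan, ad_p=np.nan, normal=np.nan)
            msg = f"{method}: n={n} < 5, normality gate skipped; using spearman"
            logger.warning(msg)
            notes.append(msg)
        else:
            ad_v = anderson_darling(vec, alpha)
            both_normal = ad_v[2] and ad_scores[2]
            choice = "pearson" if both_normal else "spearman"
            row.update(ad_stat=ad_v[0], ad_p=ad_v[1], normal=ad_v[2])
        r, p = (pearson if choice == "pearson" else spearman)(vec, scores.to_numpy())
        row.update(coefficient=choice, r=r, p=p)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("method")
    # rank table in the published layout: rank 1 = smallest value
    ranks = rsi_by_method.rank(axis=0, method="average")
    table["mean_rank"] = ranks.mean(axis=0)
    return ValidationReport(table=table, alpha=alpha, notes=notes)
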