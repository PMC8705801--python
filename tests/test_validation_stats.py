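import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rsikit.datasets import (
    RSI_EXAMPLE_ASSIGNMENT,
    load_phase_correlation_example,
    load_rsi_example,
)
from rsikit.signal_io import CHANNELS, Phase, PhaseProtocol, Recording
from rsikit.validation_stats import (
    StatsError,
    anderson_darling,
    friedman,
    pearson,
    phase15_feature_correlations,
    resim_validation,
    spearman,
)


class TestSpearman:
    def test_example_md_column(self):
        rsi, scores = load_rsi_example()
        rho, p = spearman(rsi["md"].to_numpy(), scores.to_numpy())
        # exact rational: d^2 = 96 -> 1 - 576/336
        assert rho == pytest.approx(-0.714286, abs=1e-6)
        assert 0.0 < p < 0.15  # exact permutation p for n=7

    def test_example_kpca_column(self):
        rsi, scores = load_rsi_example()
        rho, _ = spearman(rsi["edkpca"].to_numpy(), scores.to_numpy())
        # exact rational: d^2 = 58 -> 1 - 348/336
        assert rho == pytest.approx(-0.035714, abs=1e-6)

    def test_monotone_gives_one(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_raises(self):
        with pytest.raises(StatsError):
            spearman(np.ones(5), np.arange(5.0))

    def test_exact_p_matches_enumeration_for_perfect_rank(self):
        # n=4, perfect agreement: only 1 of 24 permutations reaches |rho|=1
        # in each direction -> two-sided p = 2/24
        rho, p = spearman(np.arange(4.0), np.array([1.0, 2.0, 3.0, 4.0]))
        assert rho == 1.0
        assert p == pytest.approx(2.0 / 24.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equals_pearson_on_ranks(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(20).astype(float)
        y = rng.normal(size=20)
        rho, _ = spearman(x, y)
        r, _ = pearson(stats.rankdata(x), stats.rankdata(y))
        assert rho == pytest.approx(r, abs=1e-12)


class TestPearson:
    def test_example_edpca_column(self):
        rsi, scores = load_rsi_example()
        r, p = pearson(rsi["edpca"].to_numpy(), scores.to_numpy())
        assert r == pytest.approx(-0.1149, abs=5e-5)
        assert p == pytest.approx(0.801, abs=0.01)

    def test_example_cvid_column(self):
        rsi, scores = load_rsi_example()
        r, _ = pearson(rsi["cvid"].to_numpy(), scores.to_numpy())
        assert round(r, 2) == -0.04

    def test_affine_relation_gives_one(self):
        x = np.arange(8.0)
        r, p = pearson(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(StatsError):
            pearson(np.arange(5.0), np.full(5, 2.0))


class TestAndersonDarling:
    def test_size_on_normal_samples(self):
        # retain the null in >= 95% of replicates at alpha = 0.05
        keep = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            keep += anderson_darling(x, alpha=0.05)[2]
        assert keep >= 90  # binomial slack around the nominal 95

    def test_power_on_exponential_samples(self):
        # Monte-Carlo oracle: n=200 exponential draws are rejected
        # essentially always
        reject = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=200)
            reject += not anderson_darling(x, alpha=0.05)[2]
        assert reject == 50

    def test_constant_raises(self):
        with pytest.raises(StatsError):
            anderson_darling(np.full(10, 1.0))

    def test_too_few_points_raises(self):
        with pytest.raises(StatsError):
            anderson_darling(np.arange(4.0))


class TestFriedman:
    def test_identical_methods_give_zero(self):
        mat = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 4))
        cmp_ = friedman(mat)
        assert cmp_.statistic == 0.0
        assert cmp_.pvalue == 1.0

    def test_worked_four_by_three(self):
        # brute-force rank arithmetic: ranks (1,2,3) in every row,
        # chi2 = 12*4/(3*4) * sum((rbar - 2)^2) = 8
        mat = np.array([[1, 2, 3]] * 4, dtype=float)
        cmp_ = friedman(mat)
        np.testing.assert_allclose(cmp_.mean_ranks.to_numpy(), [1.0, 2.0, 3.0])
        assert cmp_.statistic == pytest.approx(8.0)
        assert cmp_.pvalue == pytest.approx(stats.chi2.sf(8.0, 2), abs=1e-10)

    def test_column_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(10, 4))
        perm = [2, 0, 3, 1]
        a = friedman(mat)
        b = friedman(mat[:, perm])
        assert a.statistic == pytest.approx(b.statistic)
        np.testing.assert_allclose(
            a.mean_ranks.to_numpy()[perm], b.mean_ranks.to_numpy()
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_invariant_to_monotone_within_subject_transform(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.normal(size=(8, 3))
        transformed = np.exp(mat)  # strictly monotone
        assert friedman(mat).statistic == pytest.approx(
            friedman(transformed).statistic
        )

    def test_mean_ranks_average_to_center(self):
        mat = np.random.default_rng(5).normal(size=(12, 5))
        assert friedman(mat).mean_ranks.mean() == pytest.approx(3.0)

    def test_missing_value_raises(self):
        mat = np.random.default_rng(6).normal(size=(5, 3))
        mat[2, 1] = np.nan
        with pytest.raises(StatsError):
            friedman(mat)

    def test_summary_structure(self):
        mat = np.random.default_rng(7).normal(size=(9, 4))
        summary = friedman(mat).summary
        assert list(summary.columns) == ["median", "mad", "mean_rank"]
        assert len(summary) == 4


class TestPhase15Correlations:
    def _recording(self, phase5_equals_phase1=True, seed=0):
        fs = 16.0
        rng = np.random.default_rng(seed)
        n_phase = int(10 * fs)
        cols = {}
        for ch in CHANNELS:
            p1 = rng.normal(size=n_phase)
            mid = rng.normal(size=3 * n_phase)
            p5 = p1.copy() if phase5_equals_phase1 else rng.normal(size=n_phase)
            cols[ch] = np.concatenate([p1, mid, p5])
        df = pd.DataFrame(cols, columns=list(CHANNELS))
        roles = ("baseline", "stressor", "recovery", "stressor", "recovery")
        proto = PhaseProtocol(
            tuple(Phase(f"p{k}", 10.0 * k, 10.0 * (k + 1), roles[k]) for k in range(5))
        )
        return Recording("c", fs, df), proto

    def test_identical_phases_give_unit_correlations(self):
        rec, proto = self._recording(True)
        out = phase15_feature_correlations(rec, proto)
        for ch in CHANNELS:
            assert out[ch] == pytest.approx(1.0)
        assert out["mean"] == pytest.approx(1.0)

    def test_independent_phases_give_small_mean(self):
        rec, proto = self._recording(False, seed=3)
        out = phase15_feature_correlations(rec, proto)
        assert abs(out["mean"]) < 0.5

    def test_example_row_means(self):
        table = load_phase_correlation_example()
        feats = ["EMG", "HR", "BR", "SC", "PT"]
        means = table[feats].mean(axis=1)
        # printed row means are the rounded averages of the printed entries
        np.testing.assert_allclose(
            means.round(2).to_numpy(), table["mean"].to_numpy(), atol=5e-3
        )
        assert means.iloc[0] == pytest.approx(-0.108)
        assert round(means.iloc[0], 2) == -0.11

    def test_example_means_vs_scores(self):
        table = load_phase_correlation_example()
        rho, p = spearman(table["mean"].to_numpy(), table["score"].to_numpy())
        # exact rational: d^2 = 84 -> 1 - 504/336 = -0.5
        assert rho == pytest.approx(-0.5, abs=1e-12)


class TestResimValidation:
    def test_example_with_published_assignment(self):
        rsi, scores = load_rsi_example()
        report = resim_validation(rsi, scores, force=RSI_EXAMPLE_ASSIGNMENT)
        t = report.table
        assert t.loc["edpca", "coefficient"] == "pearson"
        assert t.loc["md", "coefficient"] == "spearman"
        assert t.loc["edpca", "r"] == pytest.approx(-0.1149, abs=5e-5)
        assert t.loc["md", "r"] == pytest.approx(-0.7143, abs=5e-5)
        assert round(t.loc["cvid", "r"], 2) == -0.04
        assert t.loc["edkpca", "r"] == pytest.approx(-0.03571, abs=5e-6)

    def test_gate_runs_without_force(self):
        rsi, scores = load_rsi_example()
        report = resim_validation(rsi, scores)
        assert set(report.table["coefficient"]) <= {"pearson", "spearman"}
        assert report.table["r"].between(-1, 1).all()

    def test_perfect_rank_agreement(self):
        idx = pd.Index([f"s{k}" for k in range(7)], name="subject_id")
        scores = pd.Series([50, 60, 70, 80, 90, 100, 110], index=idx)
        rsi = pd.DataFrame({"md": np.arange(7.0)}, index=idx)
        report = resim_validation(rsi, scores, force={"md": "spearman"})
        assert report.table.loc["md", "r"] == pytest.approx(1.0)

    def test_small_cohort_falls_back_to_spearman(self):
        idx = pd.Index(["a", "b", "c"], name="subject_id")
        rsi = pd.DataFrame({"md": [0.1, 0.5, 0.3]}, index=idx)
        scores = pd.Series([50, 80, 65], index=idx)
        report = resim_validation(rsi, scores)
        assert report.table.loc["md", "coefficient"] == "spearman"
        assert report.notes  # warning recorded

    def test_mismatched_subjects_raise(self):
        rsi = pd.DataFrame({"md": [0.1, 0.2]}, index=pd.Index(["a", "b"]))
        with pytest.raises(StatsError):
            resim_validation(rsi, pd.Series({"a": 50, "c": 60}))

    def test_rank_direction_smallest_is_one(self):
        rsi, scores = load_rsi_example()
        report = resim_validation(rsi, scores, force=RSI_EXAMPLE_ASSIGNMENT)
        ranks = rsi.rank(axis=0)
        assert ranks.loc[rsi["md"].idxmin(), "md"] == 1.0
        assert report.table.loc["md", "mean_rank"] == pytest.approx(4.0)
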