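import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from surfage.clinstats import (
    association_table,
    dichotomize,
    fdr_adjust,
    mixed_assoc,
    outcome_correlation,
)


class TestDichotomize:
    def test_birthweight_threshold(self):
        out = dichotomize([800, 1000, 1200], rule="threshold", threshold=1000)
        assert out.tolist() == [1, 1, 0]

    def test_already_binary_unchanged(self):
        out = dichotomize([0, 1, 1, 0])
        assert out.tolist() == [0, 1, 1, 0]

    def test_median_split_ties_low(self):
        assert dichotomize([1, 2, 3, 4], rule="median").tolist() == [1, 1, 0, 0]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize([2.0, 2.0, 2.0], rule="median")

    def test_threshold_requires_value(self):
        with pytest.raises(ValueError):
            dichotomize([1, 2, 3], rule="threshold")


def _longitudinal_null(rng, n_subjects=150, subject_sd=0.5, resid_sd=0.5, effect=0.0):
    subj = np.repeat([f"s{i}" for i in range(n_subjects)], 2)
    factor = np.repeat((rng.random(n_subjects) < 0.4).astype(float), 2)
    u = np.repeat(rng.normal(0.0, subject_sd, n_subjects), 2)
    pma = rng.uniform(28, 44, 2 * n_subjects)
    bai = effect * factor + u + rng.normal(0.0, resid_sd, 2 * n_subjects)
    return bai, factor, subj, pd.DataFrame({"pma_scan": pma})


def test_mixed_model_recovers_injected_effect(rng):
    bai, factor, subj, cov = _longitudinal_null(rng, effect=-1.0)
    res = mixed_assoc(bai, factor, subj, cov)
    assert abs(res.estimate - (-1.0)) < 3 * res.se
    assert res.p < 0.001


def test_single_scan_per_subject_collapses_to_ols(rng):
    n = 120
    subj = np.array([f"s{i}" for i in range(n)])
    factor = (rng.random(n) < 0.5).astype(float)
    bai = 0.6 * factor + rng.normal(0, 1, n)
    res = mixed_assoc(bai, factor, subj)
    ols = sm.OLS(bai, np.column_stack([np.ones(n), factor])).fit()
    assert abs(res.estimate - ols.params[1]) < 1e-6


def test_factor_level_guard(rng):
    with pytest.raises(ValueError, match="at least 2"):
        mixed_assoc(rng.standard_normal(5), np.array([1, 0, 0, 0, 0.0]),
                    np.arange(5))


def test_collinear_covariate_dropped_with_warning(rng):
    bai, factor, subj, cov = _longitudinal_null(rng)
    cov = cov.assign(pma_copy=cov["pma_scan"])
    with pytest.warns(UserWarning, match="collinear"):
        res = mixed_assoc(bai, factor, subj, cov)
    assert res.dropped_covariates == ["pma_copy"]


class TestFDR:
    def test_hand_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert fdr_adjust([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    @staticmethod
    def _brute_force_bh(p):
        """Step-up definition: q_i = min over ranks k >= rank(i) of m p_(k)/k."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            q[order[i]] = min(m * sorted_p[k] / (k + 1) for k in range(i, m))
        return np.minimum(q, 1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_brute_force(self, p):
        assert np.allclose(fdr_adjust(p), self._brute_force_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_q_at_least_p_and_monotone(self, p):
        q = fdr_adjust(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestOutcomeCorrelation:
    def _frame(self, bai, scores, subjects=None):
        n = len(bai)
        return pd.DataFrame(
            {
                "subject_id": subjects if subjects is not None else [f"s{i}" for i in range(n)],
                "pma_scan": np.linspace(28, 40, n),
                "bai": bai,
                "cognitive": scores,
            }
        )

    def test_collinear_scores_give_r_one(self):
        frame = self._frame([0.0, 1.0, 2.0, 3.0], [100.0, 101.0, 102.0, 103.0])
        out = outcome_correlation(frame, ["cognitive"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_null_loading_uncorrelated(self, rng):
        n = 400
        frame = self._frame(rng.standard_normal(n), 100 + 15 * rng.standard_normal(n))
        out = outcome_correlation(frame, ["cognitive"])
        assert abs(out.loc[0, "r"]) < 3 / np.sqrt(n)

    def test_generative_correlation_recovered(self, rng):
        """Scores built as intercept - lambda*shift + noise must show the
        closed-form correlation with BAI = -shift + small noise."""
        n = 200
        lam, shift_sd, resid_sd = 9.0, 0.67, 13.0
        shift = rng.normal(0, shift_sd, n)
        bai = -shift + rng.normal(0, 0.1, n)
        score = 103.0 - lam * shift + rng.normal(0, resid_sd, n)
        rho = lam * shift_sd / np.sqrt(lam**2 * shift_sd**2 + resid_sd**2)
        frame = self._frame(bai, score)
        out = outcome_correlation(frame, ["cognitive"])
        se = (1 - rho**2) / np.sqrt(n - 3)
        assert abs(out.loc[0, "r"] - rho) < 3 * se

    def test_latest_scan_used_for_longitudinal(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "c", "d"],
                "pma_scan": [30.0, 35.0, 31.0, 32.0, 33.0],
                "bai": [9.9, 1.0, 2.0, 3.0, 4.0],
                "cognitive": [np.nan, 101.0, 102.0, 103.0, 104.0],
            }
        )
        out = outcome_correlation(frame, ["cognitive"])
        assert out.loc[0, "n"] == 4
        assert out.loc[0, "r"] == pytest.approx(1.0)  # late scan (bai=1) used

    def test_too_few_pairs_rejected(self):
        frame = self._frame([1.0, 2.0, 3.0], [100.0, 101.0, 102.0])
        with pytest.raises(ValueError, match="fewer than 4"):
            outcome_correlation(frame, ["cognitive"])


def test_association_table_excludes_small_factors(rng):
    n = 80
    subj = [f"s{i}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "subject_id": subj,
            "pma_scan": rng.uniform(28, 44, n),
            "bai": rng.standard_normal(n),
            "cld": (rng.random(n) < 0.4).astype(int),
            "steroids": (rng.random(n) < 0.3).astype(int),
            "nec": np.r_[np.ones(3), np.zeros(n - 3)].astype(int),  # tiny group
        }
    )
    out = association_table(frame, ["cld", "steroids", "nec"])
    assert set(out["factor"]) == {"cld", "steroids"}
    assert "q" in out.columns
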