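"""Peak scores, rank-accuracy association, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taskcpca.behavior import (
    extract_peak_scores,
    fdr_adjust,
    rank_accuracy_regression,
)
from taskcpca.curves import ResponseCurveSet
from taskcpca.datatypes import ValidationError


def curveset_from_curves(per_subject_curves, subject_ids=None):
    """(S, K, E, L) array -> ResponseCurveSet."""
    est = np.asarray(per_subject_curves, dtype=float)
    return ResponseCurveSet(
        estimates=est,
        lag_times=(np.arange(est.shape[3]) + 0.5) * 3.0,
        subject_ids=subject_ids or [f"s{i}" for i in range(est.shape[0])],
        component_labels=[f"PC{k + 1}" for k in range(est.shape[1])],
    )


class TestExtractPeakScores:
    def _single_curve_set(self, curve):
        est = np.full((1, 1, 6, 6), np.nan)
        est[0, 0, 0] = curve  # threat:correct only
        est[0, 0, 1] = curve
        est[0, 0, 3] = curve
        est[0, 0, 4] = curve
        return curveset_from_curves(est)

    def test_positive_peak(self):
        peaks = extract_peak_scores(
            self._single_curve_set([0.1, 0.5, 0.3, -0.2, -0.1, 0.0])
        )
        row = peaks.iloc[0]
        assert row["peak"] == 0.5
        assert row["peak_lag_s"] == 4.5  # lag index 1

    def test_negative_peak_under_max_abs(self):
        peaks = extract_peak_scores(
            self._single_curve_set([0.1, 0.2, -0.6, 0.1, 0.0, 0.0])
        )
        assert peaks.iloc[0]["peak"] == -0.6

    def test_signed_max_convention(self):
        peaks = extract_peak_scores(
            self._single_curve_set([0.1, 0.2, -0.6, 0.1, 0.0, 0.0]),
            convention="signed_max",
        )
        assert peaks.iloc[0]["peak"] == 0.2

    def test_tie_broken_to_earliest_lag(self):
        peaks = extract_peak_scores(
            self._single_curve_set([0.0, 0.5, 0.5, 0.0, 0.0, 0.0])
        )
        assert peaks.iloc[0]["peak_lag_s"] == 4.5

    def test_absent_event_types_absent_in_table(self):
        est = np.full((1, 1, 6, 6), np.nan)
        est[0, 0, 0] = np.linspace(0, 1, 6)
        peaks = extract_peak_scores(curveset_from_curves(est))
        assert len(peaks) == 1
        assert peaks.iloc[0]["event_type"] == "threat:correct"

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValidationError):
            extract_peak_scores(
                self._single_curve_set([0, 1, 0, 0, 0, 0]), convention="area"
            )


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = m - rank_from_end  # 1-based rank of this p-value
        val = min(prev, p[idx] * m / i)
        q[idx] = val
        prev = val
    return q


class TestFdrAdjust:
    def test_reference_example(self):
        q = fdr_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], atol=1e-12)
        np.testing.assert_allclose(q, brute_force_bh([0.01, 0.02, 0.04, 0.5]))

    def test_all_equal(self):
        q = fdr_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, [0.2, 0.2, 0.2])

    def test_single_p(self):
        np.testing.assert_allclose(fdr_adjust([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_dominates_p(self, p):
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)


def make_peak_cohort(n=46, coupling=0.8, seed=0):
    rng = np.random.default_rng(seed)
    est = rng.standard_normal((n, 2, 6, 6)) * 0.2
    # component 2, threat:incorrect (event index 1) carries the signal
    strength = rng.standard_normal(n)
    est[:, 1, 1, 2] = 2.0 + strength
    cov = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["case"] * n,
            "age": rng.normal(20, 4, n),
            "sex": rng.integers(0, 2, n),
            "total_brain_volume": rng.normal(1150, 100, n),
            "mean_framewise_displacement": np.abs(rng.normal(0.1, 0.05, n)),
            "handedness": rng.integers(0, 2, n),
            "accuracy": np.clip(
                0.75 + coupling * 0.1 * strength + rng.normal(0, 0.03, n), 0, 1
            ),
        }
    )
    return curveset_from_curves(est, [f"s{i}" for i in range(n)]), cov


class TestRankAccuracyRegression:
    def test_planted_association_detected(self):
        curves, cov = make_peak_cohort(coupling=1.0)
        peaks = extract_peak_scores(curves)
        res = rank_accuracy_regression(peaks, cov, group="case")
        assert len(res) == 2 * 4
        hit = res[(res["component"] == "PC2") & (res["event_type"] == "threat:incorrect")]
        assert hit.iloc[0]["beta"] > 0
        assert hit.iloc[0]["q"] < 0.05
        others = res[~((res["component"] == "PC2") & (res["event_type"] == "threat:incorrect"))]
        assert (others["q"] > 0.05).mean() > 0.8

    def test_beta_invariant_to_accuracy_rescaling(self):
        curves, cov = make_peak_cohort(coupling=1.0, seed=1)
        peaks = extract_peak_scores(curves)
        res1 = rank_accuracy_regression(peaks, cov, group="case")
        cov2 = cov.copy()
        cov2["accuracy"] = 3.0 + 17.0 * cov2["accuracy"]  # affine rescale
        res2 = rank_accuracy_regression(peaks, cov2, group="case")
        np.testing.assert_allclose(
            res1["beta"].to_numpy(), res2["beta"].to_numpy(), atol=1e-12
        )

    def test_constant_accuracy_rejected(self):
        curves, cov = make_peak_cohort(seed=2)
        cov["accuracy"] = 0.8
        peaks = extract_peak_scores(curves)
        with pytest.raises(ValidationError, match="zero variance"):
            rank_accuracy_regression(peaks, cov, group="case")

    def test_rank_deficient_covariates_named(self):
        curves, cov = make_peak_cohort(seed=3)
        cov["total_brain_volume"] = 2.0 * cov["age"]  # exact collinearity
        cov["sex"] = cov["handedness"]
        cov.loc[:, "age"] = cov["handedness"]
        peaks = extract_peak_scores(curves)
        with pytest.raises(ValidationError, match="rank-deficient"):
            rank_accuracy_regression(peaks, cov, group="case")

    def test_too_few_subjects_rejected(self):
        curves, cov = make_peak_cohort(n=5, seed=4)
        peaks = extract_peak_scores(curves)
        with pytest.raises(ValidationError, match="at least 10"):
            rank_accuracy_regression(peaks, cov, group="case")

    def test_interaction_model_reports_interaction_term(self):
        curves, cov = make_peak_cohort(n=40, seed=5)
        cov.loc[20:, "group"] = "control"
        peaks = extract_peak_scores(curves)
        res = rank_accuracy_regression(peaks, cov, group=None, interaction=True)
        assert len(res) == 8
        assert res["n"].iloc[0] == 40
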