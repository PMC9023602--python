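"""Multilevel growth models: term algebra, fitting, selection."""

import numpy as np
import pandas as pd
import pytest

from taskcpca.curves import ResponseCurveSet
from taskcpca.datatypes import ValidationError
from taskcpca.growth import (
    GrowthModelSpec,
    _design,
    build_growth_frame,
    canonical_term,
    default_candidate_ladder,
    fit_growth_model,
    required_main_effects,
    select_growth_model,
    validate_ladder,
)

LAGS = np.array([-7.5, -4.5, -1.5, 1.5, 4.5, 7.5])


def make_frame(
    n_sub=30,
    subj_sd=0.5,
    beta_t=0.1,
    beta_t2=0.04,
    beta_t3=0.0,
    beta_g_t2=0.0,
    beta_group=0.0,
    noise=0.3,
    seed=0,
):
    """Balanced 4-event x 6-lag frame simulated directly from a known
    mixed model (the test oracle for fitting)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        cov = dict(
            age=rng.normal(),
            sex=int(rng.integers(2)),
            total_brain_volume=rng.normal(),
            mean_framewise_displacement=abs(rng.normal()) * 0.1,
            handedness=int(rng.random() < 0.9),
            group=float(s < n_sub // 2),
        )
        b0 = rng.normal() * subj_sd
        for thr in (0, 1):
            for corr in (0, 1):
                for t in LAGS:
                    y = (
                        0.5
                        + b0
                        + beta_t * t
                        + beta_t2 * t**2
                        + beta_t3 * t**3
                        + beta_g_t2 * cov["group"] * t**2
                        + beta_group * cov["group"]
                        + rng.normal() * noise
                    )
                    rows.append(
                        dict(subject=f"s{s}", score=y, t=t, lag_time_s=t + 9,
                             threat=thr, correct=corr, **cov)
                    )
    return pd.DataFrame(rows)


class TestTermAlgebra:
    @pytest.mark.parametrize(
        "term,mains",
        [
            ("t3", ["t", "t2"]),
            ("t2:correct", ["t", "t2", "correct"]),
            ("t2:group", ["t", "t2"]),
            ("threat", []),
            ("t:threat:correct:group", ["t", "threat", "correct"]),
        ],
    )
    def test_required_main_effects(self, term, mains):
        assert required_main_effects(term) == mains

    def test_canonical_order(self):
        assert canonical_term(2, True, True, True) == "t2:threat:correct:group"
        with pytest.raises(ValidationError):
            canonical_term(0, False, False, False)

    def test_ladder_hierarchy_validation(self):
        validate_ladder(default_candidate_ladder(4))
        with pytest.raises(ValidationError, match="before its main effect"):
            validate_ladder(["t:threat", "t", "threat"])


class TestBuildGrowthFrame:
    def test_observation_count_at_reference_scale(self):
        # 116 subjects x 4 response events x 6 lags = 2784 rows
        rng = np.random.default_rng(0)
        est = rng.standard_normal((116, 1, 6, 6))
        curves = ResponseCurveSet(
            estimates=est,
            lag_times=(np.arange(6) + 0.5) * 3.0,
            subject_ids=[f"sub-{i:03d}" for i in range(116)],
            component_labels=["PC1"],
        )
        cov = pd.DataFrame(
            {
                "subject_id": [f"sub-{i:03d}" for i in range(116)],
                "group": ["case"] * 58 + ["control"] * 58,
                "age": rng.normal(20, 4, 116),
                "sex": rng.integers(0, 2, 116),
                "total_brain_volume": rng.normal(1150, 100, 116),
                "mean_framewise_displacement": np.abs(rng.normal(0.1, 0.05, 116)),
                "handedness": rng.integers(0, 2, 116),
                "accuracy": rng.uniform(0.4, 1.0, 116),
            }
        )
        frame = build_growth_frame(curves, cov, component=0)
        assert len(frame) == 116 * 4 * 6
        # non-response events are excluded by construction
        assert set(frame["lag_time_s"]) == {1.5, 4.5, 7.5, 10.5, 13.5, 16.5}

    def test_incomplete_covariates_dropped(self):
        rng = np.random.default_rng(1)
        est = rng.standard_normal((3, 1, 6, 6))
        curves = ResponseCurveSet(
            estimates=est,
            lag_times=(np.arange(6) + 0.5) * 3.0,
            subject_ids=["a", "b", "c"],
            component_labels=["PC1"],
        )
        cov = pd.DataFrame(
            {
                "subject_id": ["a", "b"],  # subject c missing entirely
                "group": ["case", "control"],
                "age": [20, np.nan],  # subject b incomplete
                "sex": [0, 1],
                "total_brain_volume": [1100, 1200],
                "mean_framewise_displacement": [0.1, 0.1],
                "handedness": [1, 1],
                "accuracy": [0.8, 0.9],
            }
        )
        frame = build_growth_frame(curves, cov, component=0)
        assert set(frame["subject"]) == {"a"}


class TestFitGrowthModel:
    def test_known_quadratic_recovered(self):
        frame = make_frame(n_sub=40, beta_t2=0.04, seed=2)
        fit = fit_growth_model(frame, GrowthModelSpec(fixed_terms=["t", "t2"]))
        row = fit.term("t2")
        assert abs(row["beta"] - 0.04) < 2.0 * row["se"]
        assert fit.n_obs == 40 * 4 * 6
        assert fit.random_effects["subject_intercept_var"] > 0.05

    def test_permuted_group_centers_on_zero(self):
        frame = make_frame(n_sub=40, beta_group=0.0, seed=3)
        rng = np.random.default_rng(0)
        # permute group labels across subjects
        groups = frame.groupby("subject")["group"].first()
        permuted = pd.Series(
            rng.permutation(groups.to_numpy()), index=groups.index
        )
        frame["group"] = frame["subject"].map(permuted)
        fit = fit_growth_model(frame, GrowthModelSpec(fixed_terms=["t", "t2"]))
        row = fit.term("group")
        assert abs(row["beta"]) < 3.0 * row["se"]

    def test_zero_random_variance_equals_pooled_ols(self):
        frame = make_frame(n_sub=30, subj_sd=0.0, beta_t3=0.003, seed=4)
        spec = GrowthModelSpec(fixed_terms=["t", "t2", "t3"])
        fit = fit_growth_model(frame, spec, reml=False)
        X = _design(frame, spec).to_numpy()
        beta = np.linalg.lstsq(X, frame["score"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(
            fit.params["beta"].to_numpy(), beta, atol=1e-6
        )

    def test_single_timepoint_rejected(self):
        frame = make_frame(n_sub=4, seed=5)
        frame = frame[frame["t"] == LAGS[0]]
        with pytest.raises(ValidationError, match="2 time points"):
            fit_growth_model(frame, GrowthModelSpec())

    def test_singular_random_slope_dropped(self):
        # no between-subject slope variance: the random slope must be
        # dropped rather than reported as a singular covariance
        frame = make_frame(n_sub=20, subj_sd=0.3, seed=6)
        spec = GrowthModelSpec(fixed_terms=["t", "t2"], random_slope=True)
        fit = fit_growth_model(frame, spec)
        assert not fit.spec.random_slope

    def test_fitted_trajectories_shape(self):
        frame = make_frame(n_sub=12, seed=7)
        fit = fit_growth_model(frame, GrowthModelSpec(fixed_terms=["t", "t2"]))
        traj = fit.fitted_trajectories()
        assert len(traj) == 2 * 4 * 6  # groups x event types x lags
        assert {"case", "control"} == set(traj["group"])


class TestSelection:
    def test_recovers_generating_terms(self):
        frame = make_frame(
            n_sub=30, beta_t3=0.003, beta_g_t2=0.02, subj_sd=0.5, seed=8
        )
        spec, fit, trace = select_growth_model(frame, max_degree=4)
        assert {"t", "t2", "t3", "t2:group"} <= set(spec.fixed_terms)
        assert "t4" not in spec.fixed_terms
        assert (trace["decision"] == "added").sum() >= 4
        assert fit.reml

    def test_pure_noise_adds_few_terms(self):
        frame = make_frame(
            n_sub=25, subj_sd=0.3, beta_t=0.0, beta_t2=0.0, seed=9
        )
        spec, _, trace = select_growth_model(frame, max_degree=3)
        tested = trace[trace["decision"].isin(["added", "rejected"])]
        added = (tested["decision"] == "added").sum()
        # each candidate is admitted with probability ~ alpha under the null
        assert added <= max(2, int(0.3 * len(tested)))

    def test_trace_deterministic(self):
        frame = make_frame(n_sub=15, seed=10)
        _, _, t1 = select_growth_model(frame, max_degree=2)
        _, _, t2 = select_growth_model(frame, max_degree=2)
        pd.testing.assert_frame_equal(t1, t2)
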