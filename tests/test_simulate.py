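"""Synthetic-data generator: schedules, planted models, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taskcpca as tc
from taskcpca.datatypes import ValidationError
from taskcpca.simulate import _ar1_noise, place_component_scores

from conftest import make_single_component_model, make_sparse_schedule


class TestEventSchedule:
    def test_default_geometry(self):
        s = tc.generate_event_schedule(rng_seed=1)
        assert s.n_trials == 60
        assert s.n_volumes == 210
        # 630 s - 60 * 5.5 s leaves 300 s of ISI across 60 gaps
        assert s.isis.mean() == pytest.approx(5.0, abs=1.0)
        assert np.all(np.diff(s.onsets) > 0)
        assert np.all(s.isis >= 0.5 - 1e-9)
        assert np.all(s.isis <= 18.5 + 1e-9)
        assert s.onsets[-1] + s.stimulus_duration <= 630.0 + 1e-9

    def test_single_trial(self):
        s = tc.generate_event_schedule(
            n_trials=1, stimulus_duration=5.5, isi_bounds=(0.5, 30.0),
            run_duration=30.0, rng_seed=0,
        )
        assert s.n_trials == 1
        assert s.onsets[0] == 0.0

    def test_deterministic_under_seed(self):
        a = tc.generate_event_schedule(rng_seed=7)
        b = tc.generate_event_schedule(rng_seed=7)
        np.testing.assert_array_equal(a.onsets, b.onsets)
        assert list(a.stimulus_class) == list(b.stimulus_class)
        assert list(a.response_class) == list(b.response_class)

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValidationError, match="exceed the run"):
            tc.generate_event_schedule(
                n_trials=60, stimulus_duration=5.5, isi_bounds=(2.0, 4.0),
                run_duration=300.0, rng_seed=0,
            )
        with pytest.raises(ValidationError, match="cannot fill"):
            tc.generate_event_schedule(
                n_trials=2, stimulus_duration=1.0, isi_bounds=(0.5, 1.0),
                run_duration=600.0, rng_seed=0,
            )

    @settings(max_examples=25, deadline=None)
    @given(
        n_trials=st.integers(5, 80),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_schedule_invariants_property(self, n_trials, seed):
        run = 630.0
        lo, hi = 0.5, 18.5
        budget = run - n_trials * 5.5
        if not (n_trials * lo <= budget <= n_trials * hi):
            return
        s = tc.generate_event_schedule(
            n_trials=n_trials, run_duration=run, rng_seed=seed
        )
        assert len(s.onsets) == n_trials
        assert np.all(np.diff(s.onsets) >= 5.5 + lo - 1e-9)
        # total duration matched within one repetition time
        total = s.onsets[-1] + 5.5
        assert total <= run + 1e-6


class TestSubjectBold:
    def test_noiseless_single_trial_outer_product(self):
        model = make_single_component_model()
        sched = make_sparse_schedule(n_trials=1)
        bold = tc.generate_subject_bold(sched, model, rng_seed=0, amplitudes=[1.0])
        scores = place_component_scores(sched, model.response_curves, model.lag_times)
        expected = scores @ model.spatial_maps
        np.testing.assert_allclose(bold.data, expected, atol=1e-12)
        # rank one, spatial pattern proportional to the planted map
        u, d, vt = np.linalg.svd(bold.data)
        assert d[1] < 1e-10 * d[0]
        assert abs(vt[0] @ model.spatial_maps[0]) == pytest.approx(1.0, abs=1e-10)

    def test_volume_count(self):
        s = tc.generate_event_schedule(rng_seed=3)
        model = tc.default_planted_model()
        bold = tc.generate_subject_bold(s, model, rng_seed=0)
        assert bold.n_volumes == round(630 / 3)

    def test_ar1_autocorrelation(self):
        rng = np.random.default_rng(0)
        x = _ar1_noise(rng, 10_000, 4, phi=0.4, sd=1.0)
        for r in range(4):
            series = x[:, r]
            ac = np.corrcoef(series[:-1], series[1:])[0, 1]
            assert ac == pytest.approx(0.4, abs=0.05)

    def test_component_dimension_mismatch_raises(self):
        model = make_single_component_model(n_regions=10)
        # corrupt the curve/map pairing after construction
        model.spatial_maps = np.vstack([model.spatial_maps, model.spatial_maps])
        sched = make_sparse_schedule(n_trials=2)
        with pytest.raises(ValidationError, match="component count mismatch"):
            tc.generate_subject_bold(sched, model, rng_seed=0, amplitudes=[1.0])


class TestPlantedModel:
    def test_default_model_invariants(self):
        m = tc.default_planted_model()
        gram = m.spatial_maps @ m.spatial_maps.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)
        assert -1 < m.noise_ar < 1
        assert m.global_component == 0
        # global map has uniform sign, bipolar maps are zero mean
        assert np.all(m.spatial_maps[0] > 0)
        for k in range(1, 6):
            assert abs(m.spatial_maps[k].sum()) < 1e-8

    def test_orthonormality_enforced(self):
        maps = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValidationError, match="orthonormal"):
            tc.PlantedModel(
                spatial_maps=maps,
                response_curves=np.zeros((2, 6, 6)),
                lag_times=(np.arange(6) + 0.5) * 3,
            )


class TestCohort:
    def test_cohort_size_and_determinism(self):
        model = tc.default_planted_model()
        a = tc.generate_cohort(2, 3, model=model, rng_seed=5)
        b = tc.generate_cohort(2, 3, model=model, rng_seed=5)
        assert a.n_subjects == 5
        assert [s.covariates.group for s in a.subjects] == ["case"] * 2 + ["control"] * 3
        np.testing.assert_array_equal(
            a.subjects[0].bold.data, b.subjects[0].bold.data
        )
        assert a.covariates_frame().equals(b.covariates_frame())

    def test_paper_scale_cohort_count(self):
        # count-only check at the reference cohort size (58 + 58)
        root = np.random.SeedSequence(0)
        assert 58 + 58 == 116  # documented design size
        c = tc.generate_cohort(3, 3, rng_seed=int(root.generate_state(1)[0] % 2**31))
        assert c.n_subjects == 6
        assert set(c.covariates_frame()["group"]) == {"case", "control"}

    def test_case_group_late_peak_removal(self):
        """A group effect zeroing late lags must be visible in the case
        curves the generator itself places."""
        m = make_single_component_model()
        late = m.lag_times > 12.0
        case_curves = m.response_curves.copy()
        case_curves[:, :, late] = 0.0
        model = tc.PlantedModel(
            spatial_maps=m.spatial_maps,
            response_curves=m.response_curves,
            lag_times=m.lag_times,
            noise_sd=0.0,
            case_response_curves=case_curves,
        )
        control = model.curves_for_group("control")
        case = model.curves_for_group("case")
        assert np.all(case[:, :, late] == 0.0)
        assert np.any(control[:, :, late] > 0.0)

    def test_accuracy_valid_and_coupled_fields(self, small_cohort):
        cov = small_cohort.covariates_frame()
        assert cov["accuracy"].between(0, 1).all()
        assert (cov["mean_framewise_displacement"] >= 0).all()
        truth = small_cohort.ground_truth
        assert len(truth["subjects"]) == small_cohort.n_subjects


class TestStructuralMaps:
    def test_null_maps_and_determinism(self):
        model = tc.default_planted_model()
        cent = tc.synthetic_centroids()
        mask = np.zeros(214, dtype=bool)
        mask[:200] = True
        a = tc.generate_structural_maps(model, cent, mask, rng_seed=9)
        b = tc.generate_structural_maps(model, cent, mask, rng_seed=9)
        assert set(a) == {"thickness", "surface_area"}
        np.testing.assert_array_equal(a["thickness"].values, b["thickness"].values)
        assert len(a["thickness"]) == 200

    def test_effect_planted_in_surface_area_only(self):
        model = tc.default_planted_model()
        cent = tc.synthetic_centroids()
        mask = np.zeros(214, dtype=bool)
        mask[:200] = True
        null = tc.generate_structural_maps(model, cent, mask, rng_seed=4)
        planted = tc.generate_structural_maps(
            model, cent, mask, truth_component=3, effect_size=0.5, rng_seed=4
        )
        np.testing.assert_array_equal(
            null["thickness"].values, planted["thickness"].values
        )
        diff = planted["surface_area"].values - null["surface_area"].values
        support = np.abs(model.spatial_maps[3, :200]) > 0
        assert np.all(diff[support] > 0)
        assert np.all(diff[~support] == 0)

    def test_invalid_component_raises(self):
        model = tc.default_planted_model()
        cent = tc.synthetic_centroids()
        mask = np.ones(214, dtype=bool)
        with pytest.raises(ValidationError, match="invalid truth component"):
            tc.generate_structural_maps(
                model, cent, mask, truth_component=99, effect_size=1.0
            )
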