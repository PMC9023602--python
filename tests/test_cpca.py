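"""Constrained PCA: projection identities, decomposition, retention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taskcpca as tc
from taskcpca.datatypes import ParcellatedBold, ValidationError
from taskcpca.cpca import (
    CPCAResults,
    choose_n_components,
    extract_task_variance,
    fit_group_cpca,
    identify_global_component,
)
from taskcpca.design import build_fir_design
from taskcpca.simulate import place_component_scores

from conftest import make_single_component_model, make_sparse_schedule


def _bold(data, tr=3.0, sid=""):
    return ParcellatedBold(data=data, repetition_time=tr, subject_id=sid)


class TestTaskVarianceExtraction:
    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        sched = make_sparse_schedule(n_trials=5)
        design = build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0)
        Z = rng.standard_normal((sched.n_volumes, 12))
        zhat, resid, _ = extract_task_variance(_bold(Z), design, standardize=False)
        np.testing.assert_allclose(design.matrix.T @ resid, 0, atol=1e-8)
        np.testing.assert_allclose(zhat + resid, Z, atol=1e-12)

    def test_signal_in_design_span_has_zero_residual(self):
        model = make_single_component_model()
        sched = make_sparse_schedule(n_trials=4)
        bold = tc.generate_subject_bold(sched, model, rng_seed=0, amplitudes=[1.0])
        design = build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0)
        _, resid, _ = extract_task_variance(bold, design, standardize=False)
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(bold.data)

    def test_signal_orthogonal_to_design_has_zero_prediction(self):
        sched = make_sparse_schedule(n_trials=3)
        design = build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0)
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((sched.n_volumes, 5))
        # project out the design space explicitly
        G = design.matrix
        Z -= G @ np.linalg.lstsq(G, Z, rcond=None)[0]
        zhat, _, _ = extract_task_variance(_bold(Z), design, standardize=False)
        assert np.linalg.norm(zhat) < 1e-8

    def test_volume_mismatch_raises(self):
        sched = make_sparse_schedule(n_trials=3)
        design = build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0)
        with pytest.raises(ValidationError, match="volume mismatch"):
            extract_task_variance(_bold(np.zeros((7, 3))), design)


def two_component_cohort(n_subjects=10, amplitude_ratio=2.0, n_regions=24):
    """Two planted components with temporally disjoint support: one
    responds only to threat trials, the other only to non-threat, with
    amplitude ratio ``amplitude_ratio`` and equal trial counts."""
    rng = np.random.default_rng(3)
    lag_times = (np.arange(6) + 0.5) * 3.0
    base = np.exp(-0.5 * ((lag_times - 7.5) / 2.5) ** 2)
    curves = np.zeros((2, 6, 6))
    for e, (s, r) in enumerate(tc.EVENT_TYPES):
        if r == "correct":
            target = 0 if s == "threat" else 1
            amp = amplitude_ratio if target == 0 else 1.0
            curves[target, e] = amp * base
    v = rng.standard_normal((2, n_regions))
    v[0, n_regions // 2 :] = 0.0
    v[1, : n_regions // 2] = 0.0
    v -= v.mean(axis=1, keepdims=True) * 0  # keep disjoint supports
    for k in range(2):
        v[k] /= np.linalg.norm(v[k])
    model = tc.PlantedModel(
        spatial_maps=v,
        response_curves=curves,
        lag_times=lag_times,
        noise_sd=0.0,
        noise_ar=0.0,
        subject_amplitude_sd=0.0,
    )
    bold_list, designs = [], []
    for i in range(n_subjects):
        sched = make_sparse_schedule(
            n_trials=8,
            stimulus_classes=["threat", "non-threat"] * 4,
            response_classes=["correct"] * 8,
        )
        bold = tc.generate_subject_bold(
            sched, model, rng_seed=i, amplitudes=[1.0, 1.0], subject_id=f"s{i}"
        )
        bold_list.append(bold)
        designs.append(build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0))
    return model, bold_list, designs


class TestGroupCpca:
    def test_rank_one_recovery(self):
        model = make_single_component_model()
        bold_list, designs = [], []
        for i in range(10):
            sched = make_sparse_schedule(n_trials=6)
            bold_list.append(
                tc.generate_subject_bold(sched, model, rng_seed=i, amplitudes=[1.0])
            )
            designs.append(
                build_fir_design(sched.to_event_table(), sched.n_volumes, 3.0)
            )
        res = tc.TaskCPCA(bold_list, designs, standardize=False).fit(n_components=1)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        cos = abs(res.loadings[:, 0] @ model.spatial_maps[0])
        assert cos > 0.999

    def test_variance_partition_two_components(self):
        model, bold_list, designs = two_component_cohort()
        res = tc.TaskCPCA(bold_list, designs, standardize=False).fit(n_components=2)
        assert res.variance_explained[0] == pytest.approx(0.8, abs=1e-6)
        assert res.variance_explained[1] == pytest.approx(0.2, abs=1e-6)
        for k in range(2):
            assert abs(res.loadings[:, k] @ model.spatial_maps[k]) > 0.999

    def test_subject_order_permutation_invariance(self):
        model, bold_list, designs = two_component_cohort(n_subjects=6)
        res_a = tc.TaskCPCA(bold_list, designs, standardize=False).fit(2)
        perm = [3, 1, 5, 0, 4, 2]
        res_b = tc.TaskCPCA(
            [bold_list[i] for i in perm], [designs[i] for i in perm],
            standardize=False,
        ).fit(2)
        # sign convention makes loadings identical, not just up to sign
        np.testing.assert_allclose(
            res_a.loadings[:, :2], res_b.loadings[:, :2], atol=1e-9
        )

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(5)
        zhat = [rng.standard_normal((15, 8)) for _ in range(3)]
        res = fit_group_cpca(zhat, n_components=8)
        stacked = np.vstack(zhat)
        recon = np.vstack(res.subject_scores) @ res.loadings.T
        np.testing.assert_allclose(recon, stacked, atol=1e-10)

    def test_too_many_components_raises(self):
        zhat = [np.zeros((10, 4))]
        with pytest.raises(ValidationError, match="exceeds"):
            fit_group_cpca(zhat, n_components=5)


def test_planted_map_recovery_small_cohort():
    """20-subject cohort at high task-variance fraction: all planted
    maps recovered with |cosine| > 0.95 after Hungarian matching and
    the planted amplitude order matches the variance order."""
    from scipy.optimize import linear_sum_assignment

    model = tc.default_planted_model(signal_scale=2.0)
    cohort = tc.generate_cohort(10, 10, model=model, rng_seed=21)
    res = tc.TaskCPCA.from_events(cohort.bold_list(), cohort.event_list()).fit(
        n_components=6
    )
    C = np.abs(model.spatial_maps @ res.loadings[:, :6])
    rows, cols = linear_sum_assignment(-C)
    assert C[rows, cols].min() > 0.95
    # matched in order: planted energies decrease with index, and so do
    # the singular values
    assert list(cols) == list(rows)


class TestGlobalComponent:
    def _results_with_loadings(self, V):
        K = V.shape[1]
        return CPCAResults(
            loadings=V,
            singular_values=np.linspace(2, 1, K),
            variance_explained=np.full(K, 1 / K),
            subject_scores=[np.zeros((2, K))],
            retained=K,
            region_labels=[f"r{i}" for i in range(V.shape[0])],
            subject_ids=["s0"],
        )

    def test_uniform_component_flagged(self):
        rng = np.random.default_rng(0)
        uniform = np.ones(50) / np.sqrt(50)
        bipolar = rng.standard_normal(50)
        bipolar -= bipolar.mean()
        bipolar /= np.linalg.norm(bipolar)
        res = self._results_with_loadings(np.column_stack([bipolar, uniform]))
        assert identify_global_component(res) == 1

    def test_bipolar_only_not_flagged(self):
        rng = np.random.default_rng(1)
        V = rng.standard_normal((60, 3))
        V -= V.mean(axis=0)
        res = self._results_with_loadings(V)
        assert identify_global_component(res) is None

    def test_reindexing_preserves_variance_order(self, small_fit):
        _, res = small_fit
        assert res.global_component == 0
        assert res.reindex_map[0] == "PC0"
        labels = [res.reindex_map[k] for k in res.reported_components]
        assert labels == ["PC1", "PC2", "PC3", "PC4", "PC5"]
        # bijection over retained components
        assert len(set(res.reindex_map.values())) == res.retained


def oracle_elbow(ve):
    """Independent maximum-distance-to-chord computation: normalized
    cumulative-variance points, point-to-line distance formula."""
    ve = np.asarray(ve, float)
    c = np.cumsum(ve)
    m = len(c)
    x = np.arange(m) / (m - 1)
    y = (c - c[0]) / (c[-1] - c[0])
    x1, y1, x2, y2 = x[0], y[0], x[-1], y[-1]
    denom = np.hypot(y2 - y1, x2 - x1)
    best, arg = -np.inf, 0
    for i in range(m):
        d = abs((y2 - y1) * x[i] - (x2 - x1) * y[i] + x2 * y1 - y2 * x1) / denom
        if d > best:
            best, arg = d, i
    return arg + 1


class TestChooseNComponents:
    def test_reference_scree_elbow_at_six(self):
        ve = [0.37, 0.08, 0.07, 0.05, 0.04, 0.03, 0.005, 0.004,
              0.003, 0.002, 0.0015, 0.001]
        retained, report = choose_n_components(np.array(ve))
        assert retained == 6
        assert retained == oracle_elbow(ve)
        assert report["cumulative"][5] == pytest.approx(0.64, abs=1e-9)

    def test_override_honored(self):
        ve = 0.5 ** np.arange(1, 11)
        retained, report = choose_n_components(ve, override=4)
        assert retained == 4
        assert report["override"] == 4
        # criterion itself is stable on geometric decay
        auto, _ = choose_n_components(ve)
        assert auto == choose_n_components(ve)[0]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=25))
    def test_matches_brute_force_oracle(self, raw):
        ve = np.sort(np.asarray(raw))[::-1]
        ve = ve / ve.sum()
        retained, report = choose_n_components(ve)
        # the retained point achieves the oracle's maximum distance
        # (indices may differ only under exact ties)
        oracle_idx = oracle_elbow(ve[:20])
        dist = np.asarray(report["distances"])
        assert dist[retained - 1] == pytest.approx(dist[oracle_idx - 1], abs=1e-12)

    def test_increasing_sequence_rejected(self):
        with pytest.raises(ValidationError):
            choose_n_components(np.array([0.1, 0.5, 0.4]))
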