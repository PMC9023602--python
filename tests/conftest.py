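import numpy as np
import pytest

import taskcpca as tc


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject cohort at elevated SNR shared across read-only tests."""
    model = tc.default_planted_model(signal_scale=2.0)
    return tc.generate_cohort(5, 5, model=model, rng_seed=42)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    model = tc.TaskCPCA.from_events(
        small_cohort.bold_list(), small_cohort.event_list()
    )
    return model, model.fit(n_components=6)


def make_single_component_model(
    n_regions: int = 30,
    curve: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
):
    """One bipolar component with a designed response curve; exact
    ground truth for deconvolution tests."""
    rng = np.random.default_rng(rng_seed)
    lag_times = (np.arange(6) + 0.5) * 3.0
    if curve is None:
        base = np.exp(-0.5 * ((lag_times - 7.5) / 2.5) ** 2)
        curve = np.stack([m * base for m in (1.0, 0.8, 0.3, 0.9, 0.7, 0.2)])
    v = rng.standard_normal(n_regions)
    v -= v.mean()
    v /= np.linalg.norm(v)
    return tc.PlantedModel(
        spatial_maps=v[None, :],
        response_curves=curve[None, :, :],
        lag_times=lag_times,
        noise_sd=noise_sd,
        noise_ar=0.0,
        subject_amplitude_sd=0.0,
        subject_event_amplitude_sd=0.0,
    )


def make_sparse_schedule(
    n_trials: int = 8,
    spacing: float = 24.0,
    repetition_time: float = 3.0,
    stimulus_classes=None,
    response_classes=None,
):
    """Volume-aligned schedule with non-overlapping 18-s windows."""
    onsets = np.arange(n_trials) * spacing
    if stimulus_classes is None:
        stimulus_classes = ["threat", "non-threat"] * (n_trials // 2 + 1)
    if response_classes is None:
        response_classes = ["correct", "incorrect", "correct", "non-response"] * (
            n_trials // 4 + 1
        )
    return tc.TaskSchedule(
        onsets=onsets,
        stimulus_class=np.array(stimulus_classes[:n_trials], dtype=object),
        response_class=np.array(response_classes[:n_trials], dtype=object),
        stimulus_duration=5.5,
        run_duration=onsets[-1] + 24.0,
        repetition_time=repetition_time,
        isi_bounds=(0.5, spacing),
        aligned_to_volumes=True,
    )
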