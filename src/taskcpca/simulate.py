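"""Synthetic cohorts with known ground truth.

The generator emulates a fast event-related emotion-identification
protocol: 60 face stimuli shown for 5.5 s with a jittered 0.5-18.5 s
inter-stimulus interval over a 10.5-minute run, parcellated into 214
regions (200 cortical + 14 subcortical).  A planted model defines
orthonormal spatial components, each with an HRF-like event-locked
response curve per event type, case-group modifications of the curve
shapes, AR(1) region noise, between-subject amplitude spread, and a
coupling from subject component amplitudes to task accuracy.  Every
planted quantity is recorded so downstream stages can be validated by
recovery rather than by eye.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .datatypes import (
    EVENT_TYPES,
    RESPONSE_CLASSES,
    ValidationError,
    EventTable,
    ParcellatedBold,
    event_label,
)
from .structure import StructuralMap

__all__ = [
    "TaskSchedule",
    "PlantedModel",
    "SubjectCovariates",
    "SubjectData",
    "Cohort",
    "generate_event_schedule",
    "generate_subject_bold",
    "generate_cohort",
    "generate_structural_maps",
    "default_planted_model",
    "synthetic_centroids",
]


# ---------------------------------------------------------------------------
# schedules


@dataclass
class TaskSchedule:
    """Trial timing and labels for one run."""

    onsets: np.ndarray
    stimulus_class: np.ndarray
    response_class: np.ndarray
    stimulus_duration: float
    run_duration: float
    repetition_time: float
    isi_bounds: tuple[float, float] = (0.5, 18.5)
    aligned_to_volumes: bool = False

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.stimulus_class = np.asarray(self.stimulus_class, dtype=object)
        self.response_class = np.asarray(self.response_class, dtype=object)
        self.validate()

    def validate(self) -> None:
        if len(self.onsets) == 0:
            raise ValidationError("schedule has no trials")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")
        if self.onsets[-1] + self.stimulus_duration > self.run_duration + 1e-6:
            raise ValidationError("last trial extends past run end")
        # gaps must cover the stimulus plus an ISI within bounds (a snapped
        # schedule may violate the bounds by up to half a TR on either side)
        slack = self.repetition_time if self.aligned_to_volumes else 1e-6
        lo = self.isi_bounds[0]
        gaps = np.diff(self.onsets)
        if np.any(gaps < self.stimulus_duration + lo - slack):
            raise ValidationError("inter-trial gap shorter than stimulus + minimum ISI")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_duration / self.repetition_time))

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.onsets) - self.stimulus_duration

    def to_event_table(self) -> EventTable:
        return EventTable(
            onset=self.onsets,
            stimulus_class=self.stimulus_class,
            response_class=self.response_class,
            duration=np.full(self.n_trials, self.stimulus_duration),
        )


def generate_event_schedule(
    n_trials: int = 60,
    stimulus_duration: float = 5.5,
    isi_bounds: tuple[float, float] = (0.5, 18.5),
    run_duration: float = 630.0,
    class_probabilities: dict | None = None,
    rng_seed=None,
    repetition_time: float = 3.0,
    response_probabilities: tuple[float, float, float] = (0.85, 0.10, 0.05),
    start_offset: float = 0.0,
    align_to_volumes: bool = False,
    stimulus_sequence=None,
    response_sequence=None,
) -> TaskSchedule:
    """Draw a jittered event schedule.

    ISIs are sampled uniformly within ``isi_bounds`` and affinely
    rescaled (anchored at the lower bound, order preserving) so the
    total run duration is matched; one ISI follows every trial,
    including the last.  At the default 60-trial / 630-s geometry the
    mean ISI is 5.0 s.

    ``align_to_volumes`` snaps onsets to the acquisition grid (used for
    exact-deconvolution experiments); ``stimulus_sequence`` /
    ``response_sequence`` override the random class draws.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = isi_bounds
    if not (0 <= lo <= hi):
        raise ValidationError("isi_bounds must be ordered and non-negative")
    budget = run_duration - start_offset - n_trials * stimulus_duration
    if budget < n_trials * lo - 1e-9:
        deficit = n_trials * lo - budget
        raise ValidationError(
            f"{n_trials} trials of {stimulus_duration} s with minimum ISI {lo} s "
            f"exceed the run by {deficit:.2f} s"
        )
    if budget > n_trials * hi + 1e-9:
        raise ValidationError(
            f"{n_trials} trials cannot fill {run_duration} s even at the "
            f"maximum ISI {hi} s"
        )
    isi = rng.uniform(lo, hi, n_trials)
    # affine rescale anchored at lo, then clip-and-redistribute until the
    # ISI budget is met while every ISI stays within bounds
    for _ in range(200):
        total = isi.sum()
        if abs(total - budget) < 1e-9:
            break
        spread = total - n_trials * lo
        if spread > 1e-12:
            b = (budget - n_trials * lo) / spread
            isi = lo + b * (isi - lo)
        else:
            isi = isi + (budget - total) / n_trials
        isi = np.clip(isi, lo, hi)
    if abs(isi.sum() - budget) > repetition_time:
        raise ValidationError("could not match run duration within one repetition time")

    onsets = start_offset + np.arange(n_trials) * stimulus_duration + np.concatenate(
        ([0.0], np.cumsum(isi[:-1]))
    )
    if align_to_volumes:
        onsets = np.round(onsets / repetition_time) * repetition_time

    if stimulus_sequence is not None:
        stim = np.asarray(stimulus_sequence, dtype=object)
    else:
        p_threat = 0.5 if class_probabilities is None else float(
            class_probabilities.get("threat", 0.5)
        )
        stim = np.where(rng.random(n_trials) < p_threat, "threat", "non-threat").astype(object)
    if response_sequence is not None:
        resp = np.asarray(response_sequence, dtype=object)
    else:
        p = np.asarray(response_probabilities, dtype=float)
        p = p / p.sum()
        resp = rng.choice(np.asarray(RESPONSE_CLASSES, dtype=object), size=n_trials, p=p)
    return TaskSchedule(
        onsets=onsets,
        stimulus_class=stim,
        response_class=resp,
        stimulus_duration=stimulus_duration,
        run_duration=run_duration,
        repetition_time=repetition_time,
        isi_bounds=isi_bounds,
        aligned_to_volumes=align_to_volumes,
    )


# ---------------------------------------------------------------------------
# planted model


@dataclass
class SubjectCovariates:
    subject_id: str
    group: str  # "case" | "control"
    age: float
    sex: int  # 0 female, 1 male
    total_brain_volume: float  # cm^3
    mean_framewise_displacement: float  # mm
    handedness: int  # 1 right, 0 non-right
    accuracy: float  # fraction correct

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValidationError("accuracy must lie in [0, 1]")
        if self.mean_framewise_displacement < 0:
            raise ValidationError("framewise displacement must be non-negative")
        if self.group not in ("case", "control"):
            raise ValidationError("group must be 'case' or 'control'")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "total_brain_volume": self.total_brain_volume,
            "mean_framewise_displacement": self.mean_framewise_displacement,
            "handedness": self.handedness,
            "accuracy": self.accuracy,
        }


@dataclass
class PlantedModel:
    """Ground-truth generative model for a synthetic cohort.

    ``spatial_maps`` has orthonormal rows (components x regions);
    ``response_curves`` is components x event types x lags, sampled at
    the acquisition-bin midpoints ``lag_times``; curves are placed on
    the continuous time axis by linear interpolation and the cohort's
    BOLD is sampled at acquisition midpoints.  ``case_response_curves``
    (defaulting to ``group_scale``-scaled control curves) defines the
    case group's curve shapes.  ``behavior_coupling[k, e]`` links the
    subject's amplitude on component ``k`` (hence its realized peak
    during event type ``e``) to task accuracy.
    """

    spatial_maps: np.ndarray
    response_curves: np.ndarray
    lag_times: np.ndarray
    noise_ar: float = 0.3
    noise_sd: float = 1.0
    subject_amplitude_sd: float = 0.3
    subject_event_amplitude_sd: float = 0.3
    group_scale: np.ndarray | None = None
    case_response_curves: np.ndarray | None = None
    behavior_coupling: np.ndarray | None = None
    global_component: int | None = None
    accuracy_base: dict = field(
        default_factory=lambda: {"case": 0.729, "control": 0.909}
    )
    accuracy_noise_sd: float = 0.05
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spatial_maps = np.asarray(self.spatial_maps, dtype=float)
        self.response_curves = np.asarray(self.response_curves, dtype=float)
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        K = self.n_components
        if self.group_scale is None:
            self.group_scale = np.ones(K)
        self.group_scale = np.asarray(self.group_scale, dtype=float)
        if self.case_response_curves is None:
            self.case_response_curves = (
                self.group_scale[:, None, None] * self.response_curves
            )
        self.case_response_curves = np.asarray(self.case_response_curves, dtype=float)
        if self.behavior_coupling is None:
            self.behavior_coupling = np.zeros((K, len(EVENT_TYPES)))
        self.behavior_coupling = np.asarray(self.behavior_coupling, dtype=float)
        if not self.component_names:
            self.component_names = [f"comp{k}" for k in range(K)]
        self.validate()

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_regions(self) -> int:
        return self.spatial_maps.shape[1]

    @property
    def n_lags(self) -> int:
        return self.response_curves.shape[2]

    def validate(self, tol: float = 1e-8) -> None:
        K = self.n_components
        gram = self.spatial_maps @ self.spatial_maps.T
        if not np.allclose(gram, np.eye(K), atol=1e-6):
            raise ValidationError("spatial_maps rows must be orthonormal")
        if not (-1.0 < self.noise_ar < 1.0):
            raise ValidationError("AR(1) coefficient must lie in (-1, 1)")
        expected = (K, len(EVENT_TYPES), len(self.lag_times))
        if self.response_curves.shape != expected:
            raise ValidationError(
                f"response_curves shape {self.response_curves.shape} != {expected}"
            )
        if self.case_response_curves.shape != expected:
            raise ValidationError("case_response_curves shape mismatch")
        if self.behavior_coupling.shape != (K, len(EVENT_TYPES)):
            raise ValidationError("behavior_coupling shape mismatch")

    def curves_for_group(self, group: str) -> np.ndarray:
        return self.case_response_curves if group == "case" else self.response_curves

    def to_jsonable(self) -> dict:
        return {
            "spatial_maps": self.spatial_maps.tolist(),
            "response_curves": self.response_curves.tolist(),
            "case_response_curves": self.case_response_curves.tolist(),
            "lag_times": self.lag_times.tolist(),
            "noise_ar": self.noise_ar,
            "noise_sd": self.noise_sd,
            "subject_amplitude_sd": self.subject_amplitude_sd,
            "subject_event_amplitude_sd": self.subject_event_amplitude_sd,
            "group_scale": self.group_scale.tolist(),
            "behavior_coupling": self.behavior_coupling.tolist(),
            "global_component": self.global_component,
            "accuracy_base": self.accuracy_base,
            "accuracy_noise_sd": self.accuracy_noise_sd,
            "component_names": self.component_names,
        }


def _gauss(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - peak) / width) ** 2)


def _expected_fir_gram(
    repetition_time: float, n_lags: int, n_rep: int = 8
) -> np.ndarray:
    """Monte-Carlo estimate of E[G'G] over default jittered schedules
    (60 trials, 5.5 s stimuli, 0.5-18.5 s ISI, 630 s run, pooled-group
    response mix); fixed internal seeds keep it deterministic."""
    from .design import build_fir_design

    M = np.zeros((len(EVENT_TYPES) * n_lags,) * 2)
    for i in range(n_rep):
        sched = generate_event_schedule(
            rng_seed=97_000 + i,
            repetition_time=repetition_time,
            response_probabilities=(0.82, 0.126, 0.054),
        )
        G = build_fir_design(
            sched.to_event_table(),
            sched.n_volumes,
            repetition_time,
            window=n_lags * repetition_time,
        ).matrix
        # the decomposition consumes per-region *centred* series projected
        # back onto the design, so the metric that must be diagonal is
        # B'B with B = P_G H G (H removes the temporal mean)
        HG = G - G.mean(axis=0, keepdims=True)
        coef = np.linalg.lstsq(G, HG, rcond=None)[0]
        B = G @ coef
        M += B.T @ B
    return M / n_rep


def default_planted_model(
    n_regions: int = 214,
    n_cortical: int = 200,
    repetition_time: float = 3.0,
    n_lags: int = 6,
    rng_seed: int = 12345,
    include_global: bool = True,
    signal_scale: float = 1.0,
) -> PlantedModel:
    """Planted model emulating the qualitative component structure of an
    emotion-identification task.

    Six components: a global (near-uniform, all-positive) mode plus
    five bipolar modes with distinct event-locked dynamics — an early
    7.5-s task-general response, a delayed 10.5-s error-dominant
    response (case-attenuated and coupled to accuracy), a
    correct/incorrect antiphase limbic response, an early
    error-dominant salience response, and a biphasic response whose
    late 13.5-s peak the case group lacks.  Component supports are
    disjoint so the planted maps are exactly orthogonal; amplitudes
    decrease with component index so the planted order matches the
    variance-explained order.
    """
    rng = np.random.default_rng(rng_seed)
    t = (np.arange(n_lags) + 0.5) * repetition_time
    E = len(EVENT_TYPES)

    def weights(resp_w: dict, threat_gain: float = 1.0) -> np.ndarray:
        return np.array(
            [resp_w[r] * (threat_gain if s == "threat" else 1.0)
             for s, r in EVENT_TYPES]
        )

    # each component is rank-1 over the event x lag grid: a signed
    # event-weight vector times a lag profile; the lag profiles are
    # orthonormalized (Gram-Schmidt, order preserving) so component score
    # time courses stay mutually identifiable under any event mix
    profiles = [
        _gauss(t, 7.5, 4.0),  # broad early (global)
        _gauss(t, 7.5, 1.8),  # early task-general
        _gauss(t, 10.5, 1.8),  # delayed error-dominant
        _gauss(t, 4.5, 1.8),  # early limbic
        _gauss(t, 13.5, 2.0),  # late salience/feedback
        -0.7 * _gauss(t, 4.5, 1.8) + _gauss(t, 13.5, 2.2),  # biphasic
    ]
    U = np.array(profiles, dtype=float)
    for k in range(len(U)):
        for j in range(k):
            U[k] -= (U[k] @ U[j]) * U[j]
        U[k] /= np.linalg.norm(U[k])

    event_weights = [
        weights({"correct": 1.0, "incorrect": 1.0, "non-response": 1.0}),
        weights({"correct": 1.0, "incorrect": 0.8, "non-response": 0.5}, 1.25),
        weights({"correct": 0.5, "incorrect": 1.4, "non-response": 0.4}),
        weights({"correct": 1.0, "incorrect": -0.8, "non-response": 0.3}, 1.3),
        weights({"correct": 1.0, "incorrect": 1.5, "non-response": 0.6}),
        weights({"correct": 1.1, "incorrect": 1.0, "non-response": 1.0}),
    ]
    start = 0 if include_global else 1
    targets = np.column_stack(
        [
            np.outer(w / np.linalg.norm(w), U[i]).ravel()
            for w, i in zip(event_weights[start:], range(start, len(U)))
        ]
    )  # (E*L) x K

    # Components should be the orthogonal modes of the task-variance space
    # that the decomposition assumes, i.e. their score time courses must be
    # uncorrelated under the task's trial overlap structure.  That structure
    # is the FIR Gram matrix E[G'G]; we estimate it once by Monte Carlo over
    # default schedules and replace the designed curve set by its closest
    # counterpart (polar factor) that is exactly orthonormal in that metric.
    M0 = _expected_fir_gram(repetition_time, n_lags)
    evals, evecs = np.linalg.eigh(M0)
    evals = np.maximum(evals, 1e-8 * evals.max())
    M_half = (evecs * np.sqrt(evals)) @ evecs.T
    M_ihalf = (evecs / np.sqrt(evals)) @ evecs.T
    P, _, Qt = np.linalg.svd(M_half @ targets, full_matrices=False)
    C = M_ihalf @ (P @ Qt)  # columns M0-orthonormal, closest to targets

    amp_full = np.array([56.0, 35.0, 26.0, 14.0, 9.1, 7.0])
    amps = signal_scale * amp_full[start:]
    curves = (C * amps).T.reshape(-1, E, len(t))
    n_bipolar = 5

    # disjoint supports -> exact orthogonality; zero mean -> orthogonal to
    # the uniform global map
    support_size = 32
    perm = rng.permutation(n_regions)
    maps = []
    if include_global:
        maps.append(np.ones(n_regions) / np.sqrt(n_regions))
    for k in range(n_bipolar):
        idx = perm[k * support_size : (k + 1) * support_size]
        v = np.zeros(n_regions)
        vals = rng.standard_normal(support_size)
        vals -= vals.mean()
        v[idx] = vals
        maps.append(v / np.linalg.norm(v))
    spatial = np.vstack(maps)

    K = spatial.shape[0]
    group_scale = np.ones(K)
    case_curves = curves.copy()
    coupling = np.zeros((K, E))
    offset = 1 if include_global else 0
    # case group: attenuated delayed error response
    group_scale[offset + 1] = 0.55
    case_curves[offset + 1] *= 0.55
    # case group: late biphasic peak replaced by a single early peak; the
    # replacement is M0-orthogonalized against the *other* planted curve
    # directions so the group difference does not bleed across components
    k5 = offset + 4
    w5 = event_weights[start + k5]
    early = np.outer(w5 / np.linalg.norm(w5), _gauss(t, 7.5, 2.0)).ravel()
    for j in range(C.shape[1]):
        if j != k5:
            early -= (C[:, j] @ (M0 @ early)) * C[:, j]
    early /= np.sqrt(early @ (M0 @ early))
    case_curves[k5] = 0.35 * curves[k5] + (0.85 * amps[k5] * early).reshape(
        E, len(t)
    )
    # accuracy coupled to the delayed error-dominant component during
    # incorrect trials
    for e, (s, r) in enumerate(EVENT_TYPES):
        if r == "incorrect":
            coupling[offset + 1, e] = 0.2

    names = [f"comp{k + 1}" for k in range(n_bipolar)]
    if include_global:
        names = ["global"] + names
    return PlantedModel(
        spatial_maps=spatial,
        response_curves=curves,
        lag_times=t,
        group_scale=group_scale,
        case_response_curves=case_curves,
        behavior_coupling=coupling,
        global_component=0 if include_global else None,
        component_names=names,
    )


# ---------------------------------------------------------------------------
# BOLD synthesis


def place_component_scores(
    schedule: TaskSchedule,
    curves: np.ndarray,
    lag_times: np.ndarray,
    n_volumes: int | None = None,
) -> np.ndarray:
    """Event-locked component score time series (volumes x components).

    Curves live on the continuous time axis (linear interpolation
    between lag midpoints, zero outside the window) and are sampled at
    acquisition midpoints; overlapping trials superpose linearly.
    """
    tr = schedule.repetition_time
    if n_volumes is None:
        n_volumes = schedule.n_volumes
    K, E, L = curves.shape
    window = lag_times[-1] + lag_times[0]  # symmetric midpoint grid
    xp = np.concatenate(([0.0], lag_times, [window]))
    t_acq = (np.arange(n_volumes) + 0.5) * tr
    scores = np.zeros((n_volumes, K))
    etype = schedule.to_event_table().event_type_index()
    for t0, e in zip(schedule.onsets, etype):
        dt = t_acq - t0
        mask = (dt >= 0) & (dt <= window)
        if not mask.any():
            continue
        for k in range(K):
            fp = np.concatenate(([0.0], curves[k, e], [0.0]))
            scores[mask, k] += np.interp(dt[mask], xp, fp)
    return scores


def draw_subject_amplitudes(
    model: PlantedModel, rng: np.random.Generator
) -> np.ndarray:
    """Per component x event type amplitude matrix: a shared component
    gain (spread ``subject_amplitude_sd``) plus event-type-specific
    variation (``subject_event_amplitude_sd``)."""
    K, E = model.n_components, len(EVENT_TYPES)
    base = 1.0 + model.subject_amplitude_sd * rng.standard_normal(K)
    amps = base[:, None] + model.subject_event_amplitude_sd * rng.standard_normal(
        (K, E)
    )
    return np.maximum(amps, 0.05)


def _ar1_noise(rng: np.random.Generator, n_volumes: int, n_regions: int,
               phi: float, sd: float) -> np.ndarray:
    eps = rng.standard_normal((n_volumes, n_regions)) * sd
    if phi == 0.0:
        return eps
    x0 = rng.standard_normal(n_regions) * sd / np.sqrt(1.0 - phi**2)
    zi = (phi * x0)[None, :]
    out, _ = sp_signal.lfilter([1.0], [1.0, -phi], eps, axis=0, zi=zi)
    return out


def generate_subject_bold(
    schedule: TaskSchedule,
    model: PlantedModel,
    covariates: SubjectCovariates | None = None,
    rng_seed=None,
    amplitudes: np.ndarray | None = None,
    subject_id: str = "",
) -> ParcellatedBold:
    """Synthesize one subject's parcellated BOLD run.

    signal = sum_k amplitude * (event-locked curve placed at each
    trial, case curves for the case group) * spatial map, plus AR(1)
    noise per region.  ``amplitudes`` may be per component (shape
    ``(K,)``) or per component x event type (``(K, E)``, the cohort
    generator's form); defaults are drawn as 1 + N(0, amplitude_sd)
    per component plus N(0, event_amplitude_sd) per event type.
    """
    rng = np.random.default_rng(rng_seed)
    group = covariates.group if covariates is not None else "control"
    curves = model.curves_for_group(group)
    if curves.shape[0] != model.spatial_maps.shape[0]:
        raise ValidationError("component count mismatch between curves and maps")
    if amplitudes is None:
        amplitudes = draw_subject_amplitudes(model, rng)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim == 1:
        amplitudes = np.repeat(amplitudes[:, None], curves.shape[1], axis=1)
    n_volumes = schedule.n_volumes
    scores = place_component_scores(
        schedule, curves * amplitudes[:, :, None], model.lag_times, n_volumes
    )
    data = scores @ model.spatial_maps
    if model.noise_sd > 0:
        data = data + _ar1_noise(
            rng, n_volumes, model.n_regions, model.noise_ar, model.noise_sd
        )
    labels = [f"region{i:03d}" for i in range(model.n_regions)]
    return ParcellatedBold(
        data=data,
        repetition_time=schedule.repetition_time,
        region_labels=labels,
        subject_id=subject_id or (covariates.subject_id if covariates else ""),
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SubjectData:
    bold: ParcellatedBold
    events: EventTable
    covariates: SubjectCovariates
    amplitudes: np.ndarray
    schedule: TaskSchedule


@dataclass
class Cohort:
    subjects: list[SubjectData]
    model: PlantedModel
    centroids: np.ndarray  # regions x 3, mm
    cortical_mask: np.ndarray  # bool per region
    region_labels: list[str]
    ground_truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.covariates.to_dict() for s in self.subjects])

    def bold_list(self) -> list[ParcellatedBold]:
        return [s.bold for s in self.subjects]

    def event_list(self) -> list[EventTable]:
        return [s.events for s in self.subjects]

    def to_dir(self, path) -> None:
        """Write the cohort as plain-text files (TSV/CSV/JSON)."""
        path = Path(path)
        (path / "timeseries").mkdir(parents=True, exist_ok=True)
        (path / "events").mkdir(exist_ok=True)
        for s in self.subjects:
            sid = s.covariates.subject_id
            s.bold.to_tsv(path / "timeseries" / f"{sid}_timeseries.tsv")
            s.events.to_tsv(path / "events" / f"{sid}_events.tsv")
        self.covariates_frame().to_csv(
            path / "covariates.csv", index=False, float_format="%.10g"
        )
        cent = pd.DataFrame(
            {
                "region": self.region_labels,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "cortical": self.cortical_mask.astype(int),
            }
        )
        cent.to_csv(path / "parcellation.csv", index=False, float_format="%.10g")
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)


def synthetic_centroids(
    n_cortical: int = 200, n_subcortical: int = 14, rng_seed: int = 2024
) -> np.ndarray:
    """Parcel centroids on two hemispheric ellipsoid shells (mm) with
    subcortical parcels in a central ball; purely geometric scaffolding
    for spatial-autocorrelation modelling."""
    rng = np.random.default_rng(rng_seed)
    half = n_cortical // 2
    pts = []
    for hemi, n_h in ((-1, half), (1, n_cortical - half)):
        u = rng.standard_normal((n_h, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        shell = u * np.array([55.0, 80.0, 60.0])
        shell[:, 0] = hemi * (np.abs(shell[:, 0]) + 8.0)
        pts.append(shell)
    sub = rng.standard_normal((n_subcortical, 3))
    sub = 20.0 * sub / np.maximum(np.linalg.norm(sub, axis=1, keepdims=True), 1.0)
    pts.append(sub)
    return np.vstack(pts)


def generate_cohort(
    n_cases: int,
    n_controls: int,
    model: PlantedModel | None = None,
    rng_seed=0,
    n_trials: int = 60,
    stimulus_duration: float = 5.5,
    isi_bounds: tuple[float, float] = (0.5, 18.5),
    run_duration: float = 630.0,
    repetition_time: float = 3.0,
    align_to_volumes: bool = True,
    class_probabilities: dict | None = None,
) -> Cohort:
    """Generate a full cohort bundle with ground truth.

    Each subject receives an independent jittered schedule; the
    response class of each trial is sampled from the subject's own
    accuracy, which is in turn computed from the planted
    behaviour-coupling applied to the subject's realized component
    amplitudes plus noise.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValidationError("need at least one case and one control")
    if model is None:
        model = default_planted_model(repetition_time=repetition_time)
    if isinstance(rng_seed, np.random.SeedSequence):
        root = rng_seed
    else:
        root = np.random.SeedSequence(rng_seed)
    n_total = n_cases + n_controls
    seeds = root.spawn(n_total + 1)
    subjects: list[SubjectData] = []
    truth_subjects = []
    groups = ["case"] * n_cases + ["control"] * n_controls
    for i, group in enumerate(groups):
        ss = seeds[i]
        rng = np.random.default_rng(ss)
        sid = f"sub-{i:03d}"
        amplitudes = draw_subject_amplitudes(model, rng)
        base = model.accuracy_base[group]
        acc = base + float(np.sum(model.behavior_coupling * (amplitudes - 1.0)))
        acc += model.accuracy_noise_sd * rng.standard_normal()
        acc = float(np.clip(acc, 0.02, 0.98))
        p_resp = (acc, 0.7 * (1 - acc), 0.3 * (1 - acc))
        schedule = generate_event_schedule(
            n_trials=n_trials,
            stimulus_duration=stimulus_duration,
            isi_bounds=isi_bounds,
            run_duration=run_duration,
            class_probabilities=class_probabilities,
            rng_seed=rng,
            repetition_time=repetition_time,
            response_probabilities=p_resp,
            align_to_volumes=align_to_volumes,
        )
        cov = SubjectCovariates(
            subject_id=sid,
            group=group,
            age=float(np.clip(20.0 + 4.5 * rng.standard_normal(), 10.0, 35.0)),
            sex=int(rng.random() < 0.5),
            total_brain_volume=float(
                (1110.0 if group == "case" else 1220.0) + 120.0 * rng.standard_normal()
            ),
            mean_framewise_displacement=float(
                max(
                    0.005,
                    (0.119 if group == "case" else 0.076)
                    + 0.06 * rng.standard_normal(),
                )
            ),
            handedness=int(rng.random() < 0.9),
            accuracy=acc,
        )
        bold = generate_subject_bold(
            schedule, model, cov, rng_seed=rng, amplitudes=amplitudes, subject_id=sid
        )
        subjects.append(
            SubjectData(
                bold=bold,
                events=schedule.to_event_table(),
                covariates=cov,
                amplitudes=amplitudes,
                schedule=schedule,
            )
        )
        truth_subjects.append(
            {"subject_id": sid, "group": group, "amplitudes": amplitudes.tolist(),
             "accuracy": acc}
        )
    # parcellation split: regions beyond the first 200 are subcortical
    n_cort = min(200, model.n_regions)
    centroids = synthetic_centroids(
        n_cortical=n_cort,
        n_subcortical=model.n_regions - n_cort,
        rng_seed=int(np.random.default_rng(seeds[-1]).integers(2**31)),
    )
    cortical_mask = np.zeros(model.n_regions, dtype=bool)
    cortical_mask[:n_cort] = True
    region_labels = [f"region{i:03d}" for i in range(model.n_regions)]
    ground_truth = {
        "model": model.to_jsonable(),
        "subjects": truth_subjects,
        "rng_seed": rng_seed if isinstance(rng_seed, int) else None,
        "n_cases": n_cases,
        "n_controls": n_controls,
    }
    return Cohort(
        subjects=subjects,
        model=model,
        centroids=centroids,
        cortical_mask=cortical_mask,
        region_labels=region_labels,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# structural maps


def smooth_spatial_noise(
    centroids: np.ndarray,
    spatial_autocorr_length: float,
    rng: np.random.Generator,
    sd: float = 1.0,
) -> np.ndarray:
    """Gaussian field with exponential covariance exp(-d / length)."""
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    cov = np.exp(-d / spatial_autocorr_length)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(cov)))
    return sd * (L @ rng.standard_normal(len(cov)))


def generate_structural_maps(
    model: PlantedModel,
    centroids: np.ndarray,
    cortical_mask: np.ndarray,
    truth_component: int | None = None,
    effect_size: float = 0.0,
    spatial_autocorr_length: float = 25.0,
    noise_sd: float = 0.05,
    rng_seed=0,
) -> dict[str, StructuralMap]:
    """Two cortical difference maps (thickness and surface area).

    The surface-area map receives ``effect_size * |loadings|`` of
    ``truth_component`` on top of spatially smooth noise; the thickness
    map is smooth noise only.  ``truth_component=None`` (or effect size
    0) gives a pure null pair for calibration.
    """
    if truth_component is not None and not (
        0 <= truth_component < model.n_components
    ):
        raise ValidationError(f"invalid truth component {truth_component}")
    rng = np.random.default_rng(rng_seed)
    cortical_idx = np.flatnonzero(cortical_mask)
    cent = centroids[cortical_idx]
    labels = [f"region{i:03d}" for i in cortical_idx]
    maps = {}
    for metric in ("thickness", "surface_area"):
        values = smooth_spatial_noise(cent, spatial_autocorr_length, rng, sd=noise_sd)
        if metric == "surface_area" and truth_component is not None and effect_size:
            values = values + effect_size * np.abs(
                model.spatial_maps[truth_component, cortical_idx]
            )
        maps[metric] = StructuralMap(
            values=values, centroids=cent, metric=metric, region_labels=labels
        )
    return maps
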