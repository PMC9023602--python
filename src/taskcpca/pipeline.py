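"""End-to-end orchestration: simulate -> design -> decompose -> curves
-> growth models -> brain-behaviour -> structural alignment.

A single YAML config drives the run; every stage writes plain-text
artifacts (TSV/CSV/JSON) into the run directory together with a
provenance manifest (resolved config, per-stage seeds, input hashes,
package versions).  Robustness toggles spawn parallel result sets: a
high-accuracy subject subset rerun and a phase-randomized surrogate
rerun of the decomposition and growth stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ValidationError, ParcellatedBold
from .design import build_fir_design, check_design_conditioning, read_events
from .cpca import TaskCPCA, CPCAResults
from .curves import ResponseCurveSet, aggregate_curves
from .inference import bootstrap_loadings, phase_randomize, threshold_map
from .behavior import extract_peak_scores, rank_accuracy_regression
from .growth import GrowthModel
from .structure import StructuralMap, mav_permutation_test, mav_results_frame
from .simulate import default_planted_model, generate_cohort, generate_structural_maps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid pipeline config:\n  " + "\n  ".join(errors))
        self.errors = errors


@dataclass
class PipelineConfig:
    out_dir: str = "taskcpca_run"
    seed: int = 0
    # data: either a prepared directory (timeseries/, events/,
    # covariates.csv, parcellation.csv) or simulation parameters below
    data_dir: str | None = None
    repetition_time: float = 3.0
    fir_window: float = 18.0
    # simulation
    n_cases: int = 58
    n_controls: int = 58
    n_trials: int = 60
    stimulus_duration: float = 5.5
    isi_bounds: tuple[float, float] = (0.5, 18.5)
    run_duration: float = 630.0
    # component retention: null -> scree elbow
    n_components: int | None = None
    global_sign_threshold: float = 0.90
    # inference
    n_boot: int = 500
    threshold_alpha: float = 1e-4
    # growth models
    selection_alpha: float = 0.05
    max_degree: int = 5
    # behaviour
    peak_convention: str = "max_abs"
    # structural alignment
    n_perm: int = 500
    structural_truth_component: int | None = None
    structural_effect_size: float = 0.0
    structural_autocorr_length: float = 25.0
    # robustness toggles
    accuracy_subset_threshold: float | None = None
    phase_randomized_rerun: bool = False

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["isi_bounds"] = list(self.isi_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


_DEFAULTS = PipelineConfig()


def validate_config(source) -> PipelineConfig:
    """Resolve a config mapping or YAML path; report every violation at
    once.  Unknown keys warn (forward compatibility) rather than error;
    missing keys take documented defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    elif isinstance(source, PipelineConfig):
        raw = asdict(source)
    else:
        raise ConfigError([f"unsupported config source {type(source)!r}"])

    known = set(asdict(_DEFAULTS))
    for key in sorted(set(raw) - known):
        logger.warning("unknown config key %r ignored", key)
    values = {k: raw[k] for k in known & set(raw)}
    if "isi_bounds" in values:
        values["isi_bounds"] = tuple(values["isi_bounds"])
    cfg = PipelineConfig(**values)

    errors = []
    for name in ("n_boot", "n_perm", "n_trials", "n_cases", "n_controls"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    for name in ("repetition_time", "fir_window", "run_duration",
                 "stimulus_duration"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    if cfg.accuracy_subset_threshold is not None and not (
        0.0 <= cfg.accuracy_subset_threshold <= 1.0
    ):
        errors.append("accuracy_subset_threshold must lie in [0, 1]")
    if not (0.0 < cfg.selection_alpha < 1.0):
        errors.append("selection_alpha must lie in (0, 1)")
    if not (0.0 < cfg.threshold_alpha <= 1.0):
        errors.append("threshold_alpha must lie in (0, 1]")
    if cfg.peak_convention not in ("max_abs", "signed_max"):
        errors.append("peak_convention must be 'max_abs' or 'signed_max'")
    if cfg.n_components is not None and cfg.n_components <= 0:
        errors.append("n_components must be positive or null")
    if errors:
        raise ConfigError(errors)
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _load_data_dir(data_dir: Path, repetition_time: float):
    cov = pd.read_csv(data_dir / "covariates.csv")
    bold_list, events_list = [], []
    for sid in cov["subject_id"]:
        bold_list.append(
            ParcellatedBold.from_tsv(
                data_dir / "timeseries" / f"{sid}_timeseries.tsv",
                repetition_time=repetition_time,
                subject_id=sid,
            )
        )
        events_list.append(read_events(data_dir / "events" / f"{sid}_events.tsv"))
    parc = pd.read_csv(data_dir / "parcellation.csv")
    centroids = parc[["x", "y", "z"]].to_numpy(dtype=float)
    cortical = parc["cortical"].to_numpy(dtype=bool)
    return bold_list, events_list, cov, centroids, cortical


def _growth_and_behavior(
    curveset: ResponseCurveSet,
    covariates: pd.DataFrame,
    results: CPCAResults,
    cfg: PipelineConfig,
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for k in results.reported_components:
        label = results.reindex_map[k]
        gm = GrowthModel(curveset, covariates, component=k)
        spec, fit, trace = gm.select(
            alpha_select=cfg.selection_alpha, max_degree=cfg.max_degree
        )
        trace.to_csv(out / f"{label}_selection_trace.tsv", sep="\t", index=False,
                     float_format="%.10g")
        fit.params.to_csv(out / f"{label}_terms.tsv", sep="\t", index=False,
                          float_format="%.10g")
        fit.fitted_trajectories().to_csv(
            out / f"{label}_trajectories.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        with open(out / f"{label}_model.json", "w") as fh:
            json.dump(
                {
                    "fixed_terms": spec.fixed_terms,
                    "random_slope": spec.random_slope,
                    "llf": fit.llf, "aic": fit.aic, "bic": fit.bic,
                    "random_effects": fit.random_effects,
                    "n_obs": fit.n_obs, "n_subjects": fit.n_subjects,
                },
                fh, indent=1,
            )
    peaks = extract_peak_scores(curveset, convention=cfg.peak_convention)
    # reported components only (PC0 excluded from the association family)
    reported = [results.reindex_map[k] for k in results.reported_components]
    peaks = peaks[peaks["component"].isin(reported)]
    cov = covariates.rename(columns={})
    try:
        assoc = rank_accuracy_regression(peaks, cov, group="case")
        assoc.to_csv(out / "associations_case.tsv", sep="\t", index=False,
                     float_format="%.10g")
        assoc_ctrl = rank_accuracy_regression(peaks, cov, group="control")
        assoc_ctrl.to_csv(out / "associations_control.tsv", sep="\t", index=False,
                          float_format="%.10g")
        assoc_int = rank_accuracy_regression(peaks, cov, group=None, interaction=True)
        assoc_int.to_csv(out / "associations_interaction.tsv", sep="\t",
                         index=False, float_format="%.10g")
    except ValidationError as err:
        logger.warning("behaviour stage skipped: %s", err)
    peaks.to_csv(out / "peak_scores.tsv", sep="\t", index=False,
                 float_format="%.10g")


def run_pipeline(config) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name attached to the
    exception.
    """
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {
        name: seq
        for name, seq in zip(
            ["simulate", "bootstrap", "structural", "surrogate", "phase"],
            master.spawn(5),
        )
    }
    from . import __version__ as pkg_version

    manifest: dict = {
        "package_version": pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "stages": [],
    }
    stage = "setup"
    try:
        # ---- data -------------------------------------------------------
        stage = "simulate"
        model = None
        centroids = cortical = None
        if cfg.data_dir is None:
            model = default_planted_model(repetition_time=cfg.repetition_time)
            cohort = generate_cohort(
                cfg.n_cases,
                cfg.n_controls,
                model=model,
                rng_seed=int(stage_seeds["simulate"].generate_state(1)[0] % 2**31),
                n_trials=cfg.n_trials,
                stimulus_duration=cfg.stimulus_duration,
                isi_bounds=cfg.isi_bounds,
                run_duration=cfg.run_duration,
                repetition_time=cfg.repetition_time,
            )
            data_dir = out / "data"
            cohort.to_dir(data_dir)
            bold_list = cohort.bold_list()
            events_list = cohort.event_list()
            covariates = cohort.covariates_frame()
            centroids, cortical = cohort.centroids, cohort.cortical_mask
        else:
            data_dir = Path(cfg.data_dir)
            bold_list, events_list, covariates, centroids, cortical = _load_data_dir(
                data_dir, cfg.repetition_time
            )
        manifest["stages"].append(stage)
        manifest["n_subjects"] = len(bold_list)
        manifest["input_hashes"] = {
            "covariates": _hash_file(data_dir / "covariates.csv")
        }

        # ---- design + decomposition ------------------------------------
        stage = "decompose"
        cpca_model = TaskCPCA.from_events(
            bold_list, events_list, window=cfg.fir_window
        )
        reports = [check_design_conditioning(d) for d in cpca_model.designs]
        with open(out / "design_conditioning.json", "w") as fh:
            json.dump(
                [
                    {
                        "subject": b.subject_id,
                        "rank": r.rank,
                        "condition_number": r.condition_number,
                        "zero_column_blocks": r.zero_column_blocks,
                        "warnings": r.warnings,
                    }
                    for b, r in zip(bold_list, reports)
                ],
                fh, indent=1,
            )
        results = cpca_model.fit(
            n_components=cfg.n_components,
            global_sign_threshold=cfg.global_sign_threshold,
        )
        results.to_dir(out / "cpca")
        with open(out / "cpca" / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
        manifest["stages"].append(stage)
        manifest["retained_components"] = results.retained
        manifest["global_component"] = results.global_component

        # ---- bootstrap thresholding ------------------------------------
        stage = "bootstrap"
        boot = bootstrap_loadings(
            cpca_model.task_variance(),
            results,
            n_boot=cfg.n_boot,
            rng_seed=stage_seeds["bootstrap"],
        )
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        masks: dict[str, np.ndarray] = {}
        for k in range(results.retained):
            label = results.reindex_map[k]
            tmap = threshold_map(
                results.loadings[:, k],
                boot["p"][:, k],
                alpha=cfg.threshold_alpha,
                se=boot["se"][:, k],
                region_labels=results.region_labels,
            )
            tmap.to_frame().to_csv(
                maps_dir / f"{label}_map.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            masks[label] = tmap.mask
        manifest["stages"].append(stage)

        # ---- response curves -------------------------------------------
        stage = "curves"
        curveset = ResponseCurveSet.from_solution(results, cpca_model.designs)
        curveset.to_tsv(out / "response_curves.tsv")
        aggregate_curves(curveset, covariates["group"].to_numpy()).to_csv(
            out / "group_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["stages"].append(stage)

        # ---- growth models + behaviour ---------------------------------
        stage = "growth"
        _growth_and_behavior(curveset, covariates, results, cfg, out / "growth")
        manifest["stages"].append(stage)

        # ---- structural alignment --------------------------------------
        stage = "structure"
        if model is not None and centroids is not None:
            smaps = generate_structural_maps(
                model,
                centroids,
                cortical,
                truth_component=cfg.structural_truth_component,
                effect_size=cfg.structural_effect_size,
                spatial_autocorr_length=cfg.structural_autocorr_length,
                rng_seed=stage_seeds["structural"],
            )
            cortical_masks = {
                label: mask[cortical] for label, mask in masks.items()
            }
            cortical_masks = {
                k: m for k, m in cortical_masks.items() if m.any()
            }
            if cortical_masks:
                mav = mav_permutation_test(
                    cortical_masks,
                    smaps,
                    n_perm=cfg.n_perm,
                    rng_seed=stage_seeds["surrogate"],
                )
                mav_results_frame(mav).to_csv(
                    out / "structural_alignment.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
                for metric, smap in smaps.items():
                    smap.to_csv(out / f"structural_{metric}.csv")
                manifest["stages"].append(stage)
            else:
                logger.warning("structure stage skipped: no suprathreshold "
                               "cortical regions in any map")
        else:
            logger.info("structure stage skipped: no structural inputs")

        # ---- robustness: accuracy subset -------------------------------
        if cfg.accuracy_subset_threshold is not None:
            stage = "accuracy_subset"
            keep = covariates["accuracy"] >= cfg.accuracy_subset_threshold
            manifest["accuracy_subset_n"] = int(keep.sum())
            if keep.sum() >= 4:
                sub_ids = set(covariates.loc[keep, "subject_id"])
                sel = [i for i, b in enumerate(bold_list)
                       if covariates["subject_id"].iloc[i] in sub_ids]
                sub_curves = ResponseCurveSet(
                    estimates=curveset.estimates[sel],
                    lag_times=curveset.lag_times,
                    subject_ids=[curveset.subject_ids[i] for i in sel],
                    component_labels=curveset.component_labels,
                )
                _growth_and_behavior(
                    sub_curves, covariates[keep], results, cfg,
                    out / "robustness_accuracy_subset",
                )
                manifest["stages"].append(stage)
            else:
                logger.warning("accuracy subset too small (%d); rerun skipped",
                               int(keep.sum()))

        # ---- robustness: phase-randomized surrogates -------------------
        if cfg.phase_randomized_rerun:
            stage = "phase_randomized"
            rng = np.random.default_rng(stage_seeds["phase"])
            surrogates = [
                phase_randomize(b, rng_seed=rng) for b in bold_list
            ]
            sur_model = TaskCPCA(surrogates, cpca_model.designs)
            sur_results = sur_model.fit(n_components=results.retained)
            sur_results.to_dir(out / "robustness_phase" / "cpca")
            sur_curves = ResponseCurveSet.from_solution(
                sur_results, sur_model.designs
            )
            sur_curves.to_tsv(out / "robustness_phase" / "response_curves.tsv")
            _growth_and_behavior(
                sur_curves, covariates, sur_results, cfg,
                out / "robustness_phase" / "growth",
            )
            manifest["stages"].append(stage)

    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
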