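"""Constrained PCA of task-related BOLD variance.

The constrained step regresses each subject's (per-region standardized)
time series onto the FIR design and keeps the predicted values — the
portion of the signal explainable by event timing.  Predicted matrices
are stacked across subjects and decomposed with one SVD, giving
group-level spatial loadings (right singular vectors) with
subject-level temporal scores (rows of ``U @ diag(d)``), so a single
spatial solution describes every subject while each subject keeps an
individual score time course.

A near-uniform-sign component is interpreted as a global signal
fluctuation, labelled "PC0" and excluded from interpretation; the
remaining components are re-indexed PC1..PC(K-1) in variance order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ParcellatedBold, ValidationError
from .design import FirDesign, build_fir_design

logger = logging.getLogger(__name__)

__all__ = [
    "TaskCPCA",
    "CPCAResults",
    "standardize_series",
    "extract_task_variance",
    "fit_group_cpca",
    "identify_global_component",
    "choose_n_components",
]


def standardize_series(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-region z-scoring; zero-variance regions are centred only."""
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=0)
    safe = np.where(sds > 0, sds, 1.0)
    return (data - means) / safe, means, sds


def extract_task_variance(
    bold: ParcellatedBold,
    design: FirDesign,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """FIR regression: split a subject's series into predicted + residual.

    Returns ``(zhat, residual, record)`` where ``zhat = G @ pinv(G) @ Z``
    and ``Z = zhat + residual`` exactly; the residual is orthogonal to
    the design's column space.  Rank-deficient designs (absent event
    types) are handled by the pseudoinverse and logged.
    """
    G = design.matrix
    if bold.n_volumes != G.shape[0]:
        raise ValidationError(
            f"volume mismatch: BOLD has {bold.n_volumes}, design has {G.shape[0]}"
        )
    if standardize:
        Z, means, sds = standardize_series(bold.data)
    else:
        Z = bold.data
        means = np.zeros(bold.n_regions)
        sds = np.ones(bold.n_regions)
    rank = np.linalg.matrix_rank(G)
    if rank < np.count_nonzero(G.any(axis=0)):
        logger.warning(
            "design for subject %s is rank deficient (rank %d of %d nonzero "
            "columns); using pseudoinverse",
            bold.subject_id, rank, np.count_nonzero(G.any(axis=0)),
        )
    beta = np.linalg.lstsq(G, Z, rcond=None)[0]
    zhat = G @ beta
    record = {
        "standardized": standardize,
        "means": means,
        "sds": sds,
        "design_rank": int(rank),
    }
    return zhat, Z - zhat, record


@dataclass
class CPCAResults:
    """Fitted group CPCA solution.

    ``loadings`` holds all computed components (regions x K, orthonormal
    columns, sign-fixed); ``subject_scores[i]`` is subject i's temporal
    score block (volumes_i x K, rows of U @ diag(d)).  ``retained`` is
    the number of components kept for interpretation;
    ``global_component`` indexes the flagged global-signal component
    among them (or None) and ``reindex_map`` maps original component
    indices to reported labels (PC0 for the global component, PC1.. for
    the rest).
    """

    loadings: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    subject_scores: list[np.ndarray]
    retained: int
    region_labels: list[str]
    subject_ids: list[str]
    standardization: list[dict] = field(default_factory=list)
    global_component: int | None = None
    reindex_map: dict[int, str] = field(default_factory=dict)
    scree_report: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_regions(self) -> int:
        return self.loadings.shape[0]

    @property
    def component_labels(self) -> list[str]:
        return [self.reindex_map.get(k, f"PC{k + 1}") for k in range(self.retained)]

    @property
    def reported_components(self) -> list[int]:
        """Retained component indices, excluding the global component."""
        return [
            k for k in range(self.retained) if k != self.global_component
        ]

    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_explained)

    def loadings_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.loadings[:, : self.retained],
            columns=self.component_labels,
        )
        frame.insert(0, "region", self.region_labels)
        return frame

    def summary(self) -> str:
        lines = [
            "Group CPCA solution",
            f"  subjects: {len(self.subject_scores)}   regions: {self.n_regions}",
            f"  retained components: {self.retained} of {self.n_components}",
            "",
            f"  {'component':<10}{'label':<8}{'var_explained':>14}{'cumulative':>12}",
        ]
        cum = self.cumulative_variance()
        for k in range(self.retained):
            tag = " (global)" if k == self.global_component else ""
            lines.append(
                f"  {k:<10}{self.reindex_map.get(k, f'PC{k+1}'):<8}"
                f"{self.variance_explained[k]:>14.4f}{cum[k]:>12.4f}{tag}"
            )
        return "\n".join(lines)

    # -- persistence (plain text) ------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.loadings_frame().to_csv(
            path / "loadings.tsv", sep="\t", index=False, float_format="%.10g"
        )
        (path / "scores").mkdir(exist_ok=True)
        for sid, block in zip(self.subject_ids, self.subject_scores):
            pd.DataFrame(
                block[:, : self.retained], columns=self.component_labels
            ).to_csv(
                path / "scores" / f"{sid}_scores.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
        meta = {
            "singular_values": self.singular_values.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "retained": self.retained,
            "global_component": self.global_component,
            "reindex_map": {str(k): v for k, v in self.reindex_map.items()},
            "subject_ids": self.subject_ids,
            "scree_report": self.scree_report,
        }
        with open(path / "solution.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_dir(cls, path) -> "CPCAResults":
        path = Path(path)
        with open(path / "solution.json") as fh:
            meta = json.load(fh)
        lf = pd.read_csv(path / "loadings.tsv", sep="\t")
        region_labels = lf["region"].tolist()
        loadings = lf.drop(columns="region").to_numpy(dtype=float)
        scores = []
        for sid in meta["subject_ids"]:
            scores.append(
                pd.read_csv(path / "scores" / f"{sid}_scores.tsv", sep="\t").to_numpy(
                    dtype=float
                )
            )
        return cls(
            loadings=loadings,
            singular_values=np.asarray(meta["singular_values"]),
            variance_explained=np.asarray(meta["variance_explained"]),
            subject_scores=scores,
            retained=int(meta["retained"]),
            region_labels=region_labels,
            subject_ids=list(meta["subject_ids"]),
            global_component=meta["global_component"],
            reindex_map={int(k): v for k, v in meta["reindex_map"].items()},
            scree_report=meta.get("scree_report", {}),
        )


def _fix_signs(V: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each loading column so its largest-|value| entry is positive."""
    V = V.copy()
    scores = scores.copy()
    for k in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, k])))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
            scores[:, k] = -scores[:, k]
    return V, scores


def fit_group_cpca(
    zhat_list: list[np.ndarray],
    n_components: int | None = None,
    region_labels: list[str] | None = None,
    subject_ids: list[str] | None = None,
    standardization: list[dict] | None = None,
    global_sign_threshold: float = 0.90,
    flag_global: bool = True,
) -> CPCAResults:
    """Group PCA of stacked predicted matrices.

    ``n_components=None`` retains the scree elbow (see
    :func:`choose_n_components`); an integer retains exactly that many.
    All components are computed regardless, so variance fractions sum
    to 1 over the full spectrum.
    """
    n_regions = zhat_list[0].shape[1]
    for i, z in enumerate(zhat_list):
        if z.shape[1] != n_regions:
            raise ValidationError(f"subject {i} region dimension mismatch")
    stacked = np.vstack(zhat_list)
    max_rank = min(stacked.shape)
    if n_components is not None and n_components > max_rank:
        raise ValidationError(
            f"n_components={n_components} exceeds the rank bound {max_rank}"
        )
    U, d, Vt = np.linalg.svd(stacked, full_matrices=False)
    scores_all = U * d
    V, scores_all = _fix_signs(Vt.T, scores_all)
    total = float(np.sum(d**2))
    variance_explained = d**2 / total if total > 0 else np.zeros_like(d)

    scree_report: dict = {}
    if n_components is None:
        retained, scree_report = choose_n_components(variance_explained)
    else:
        retained = int(n_components)

    bounds = np.cumsum([0] + [z.shape[0] for z in zhat_list])
    subject_scores = [
        scores_all[bounds[i] : bounds[i + 1]] for i in range(len(zhat_list))
    ]
    results = CPCAResults(
        loadings=V,
        singular_values=d,
        variance_explained=variance_explained,
        subject_scores=subject_scores,
        retained=retained,
        region_labels=region_labels or [f"region{i:03d}" for i in range(n_regions)],
        subject_ids=subject_ids or [f"sub-{i:03d}" for i in range(len(zhat_list))],
        standardization=standardization or [],
    )
    if flag_global:
        gidx = identify_global_component(results, threshold=global_sign_threshold)
        results.global_component = gidx
        results.reindex_map = _build_reindex_map(retained, gidx)
    else:
        results.reindex_map = _build_reindex_map(retained, None)
    return results


def _build_reindex_map(retained: int, global_idx: int | None) -> dict[int, str]:
    out: dict[int, str] = {}
    next_label = 1
    for k in range(retained):
        if k == global_idx:
            out[k] = "PC0"
        else:
            out[k] = f"PC{next_label}"
            next_label += 1
    return out


def identify_global_component(
    results: CPCAResults, threshold: float = 0.90
) -> int | None:
    """Flag the retained component with the highest same-sign loading
    fraction, if that fraction exceeds ``threshold``.

    A component whose loadings share one sign across (nearly) all
    regions behaves like a global signal fluctuation rather than a
    spatial contrast; it is labelled PC0 and excluded from reporting.
    """
    best_k, best_frac = None, 0.0
    for k in range(results.retained):
        v = results.loadings[:, k]
        nz = v[np.abs(v) > 1e-12]
        if nz.size == 0:
            continue
        frac = max(np.mean(nz > 0), np.mean(nz < 0))
        if frac > best_frac:
            best_k, best_frac = k, float(frac)
    if best_frac > threshold:
        return best_k
    return None


def choose_n_components(
    variance_explained: np.ndarray,
    override: int | None = None,
    max_scree: int = 20,
) -> tuple[int, dict]:
    """Scree elbow by maximum distance to the chord.

    The cumulative-variance curve over the leading ``max_scree``
    components (the scree as one would plot it) is normalized to the
    unit square and the retained count is the point with maximum
    perpendicular distance to the chord joining its endpoints — the
    bend of the scree.  An explicit ``override`` short-circuits the
    criterion but the report is still produced.
    """
    ve = np.asarray(variance_explained, dtype=float)
    if np.any(np.diff(ve) > 1e-12):
        raise ValidationError("variance_explained must be non-increasing")
    ve = ve[:max_scree]
    cum = np.cumsum(ve)
    m = len(ve)
    if m == 1:
        report = {"distances": [0.0], "cumulative": cum.tolist(), "elbow": 1}
        return (override or 1), report
    x = np.arange(m) / (m - 1)
    span = cum[-1] - cum[0]
    y = (cum - cum[0]) / span if span > 0 else np.zeros(m)
    # chord is y = x in normalized coordinates
    dist = (y - x) / np.sqrt(2.0)
    elbow = int(np.argmax(dist)) + 1
    report = {
        "distances": dist.tolist(),
        "cumulative": cum.tolist(),
        "elbow": elbow,
        "override": override,
    }
    return (override if override is not None else elbow), report


class TaskCPCA:
    """Constrained PCA model for a cohort of parcellated BOLD runs.

    Parameters
    ----------
    bold_list : list of ParcellatedBold
        One run per subject.
    designs : list of FirDesign
        Matching FIR design matrices (see :meth:`from_events` to build
        them from event tables).
    standardize : bool
        Per-region z-scoring before the FIR regression (default True;
        disable for noiseless constructions where scale is meaningful).

    Examples
    --------
    >>> model = TaskCPCA.from_events(bold_list, event_tables, window=18.0)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        bold_list: list[ParcellatedBold],
        designs: list[FirDesign],
        standardize: bool = True,
    ):
        if len(bold_list) != len(designs):
            raise ValidationError("need one design per subject")
        if not bold_list:
            raise ValidationError("empty cohort")
        self.bold_list = bold_list
        self.designs = designs
        self.standardize = standardize
        self._zhat: list[np.ndarray] | None = None
        self._records: list[dict] | None = None

    @classmethod
    def from_events(
        cls,
        bold_list: list[ParcellatedBold],
        event_tables,
        window: float = 18.0,
        standardize: bool = True,
    ) -> "TaskCPCA":
        designs = [
            build_fir_design(ev, b.n_volumes, b.repetition_time, window)
            for ev, b in zip(event_tables, bold_list)
        ]
        return cls(bold_list, designs, standardize=standardize)

    def task_variance(self) -> list[np.ndarray]:
        """Per-subject predicted matrices (cached)."""
        if self._zhat is None:
            zhat, records = [], []
            for bold, design in zip(self.bold_list, self.designs):
                z, _, rec = extract_task_variance(bold, design, self.standardize)
                zhat.append(z)
                records.append(rec)
            self._zhat = zhat
            self._records = records
        return self._zhat

    def fit(
        self,
        n_components: int | None = None,
        global_sign_threshold: float = 0.90,
        flag_global: bool = True,
    ) -> CPCAResults:
        zhat = self.task_variance()
        return fit_group_cpca(
            zhat,
            n_components=n_components,
            region_labels=self.bold_list[0].region_labels,
            subject_ids=[
                b.subject_id or f"sub-{i:03d}" for i, b in enumerate(self.bold_list)
            ],
            standardization=self._records,
            global_sign_threshold=global_sign_threshold,
            flag_global=flag_global,
        )
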