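"""Event-locked response curves of component scores.

Each subject's component score time series is regressed onto the same
FIR basis used for extraction, yielding the estimated mean score at
each post-event acquisition (six lags spanning 0-18 s at TR 3 s) for
each of the six event types.  Event types absent for a subject are
marked NaN ("absent"), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EVENT_LABELS, EVENT_TYPES, ValidationError
from .design import FirDesign

__all__ = ["ResponseCurveSet", "estimate_response_curves", "aggregate_curves"]


def estimate_response_curves(scores: np.ndarray, design: FirDesign) -> np.ndarray:
    """Back-regress one subject's scores on the FIR basis.

    Parameters
    ----------
    scores : array, volumes x components
    design : FirDesign

    Returns
    -------
    array, components x event_types x lags; NaN for event types with no
    trials (all-zero column blocks).
    """
    G = design.matrix
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] != G.shape[0]:
        raise ValidationError(
            f"score rows ({scores.shape[0]}) != design rows ({G.shape[0]})"
        )
    beta = np.linalg.lstsq(G, scores, rcond=None)[0]  # (E*L) x K
    K = scores.shape[1]
    curves = beta.T.reshape(K, design.n_event_types, design.n_lags)
    curves = curves.copy()
    for e in design.zero_column_blocks():
        curves[:, e, :] = np.nan
    return curves


@dataclass
class ResponseCurveSet:
    """Estimated response curves for a cohort.

    ``estimates`` is subjects x components x event_types x lags (NaN
    marks event types absent for a subject).
    """

    estimates: np.ndarray
    lag_times: np.ndarray
    subject_ids: list[str]
    component_labels: list[str]
    event_types: tuple = EVENT_TYPES
    #: trials per subject x event type (None when unknown); lets peak
    #: extraction treat sparsely sampled cells as missing
    event_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        S, K, E, L = self.estimates.shape
        if L != len(self.lag_times):
            raise ValidationError("lag count mismatch")
        if E != len(self.event_types):
            raise ValidationError("event type count mismatch")
        if K != len(self.component_labels):
            raise ValidationError("component label count mismatch")
        if S != len(self.subject_ids):
            raise ValidationError("subject id count mismatch")

    @classmethod
    def from_solution(cls, results, designs: list[FirDesign]) -> "ResponseCurveSet":
        """Back-regress every subject's retained scores."""
        est, counts = [], []
        for block, design in zip(results.subject_scores, designs):
            est.append(estimate_response_curves(block[:, : results.retained], design))
            L = design.n_lags
            counts.append(
                [
                    int(design.matrix[:, e * L : (e + 1) * L].sum(axis=0).max())
                    for e in range(design.n_event_types)
                ]
            )
        return cls(
            estimates=np.stack(est),
            lag_times=designs[0].lag_times,
            subject_ids=list(results.subject_ids),
            component_labels=list(results.component_labels),
            event_counts=np.asarray(counts),
        )

    @property
    def n_subjects(self) -> int:
        return self.estimates.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        S, K, E, L = self.estimates.shape
        rows = []
        for s in range(S):
            for k in range(K):
                for e in range(E):
                    for j in range(L):
                        rows.append(
                            (
                                self.subject_ids[s],
                                self.component_labels[k],
                                EVENT_LABELS[e],
                                self.lag_times[j],
                                self.estimates[s, k, e, j],
                            )
                        )
        return pd.DataFrame(
            rows,
            columns=["subject", "component", "event_type", "lag_time_s", "estimate"],
        )

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def aggregate_curves(
    curveset: ResponseCurveSet, group_labels: list[str] | np.ndarray
) -> pd.DataFrame:
    """Group mean +/- SE curves per component x event type.

    Subjects with an absent event type are excluded from that cell's
    denominator.  Requires at least two subjects per group.
    """
    groups = np.asarray(group_labels)
    if len(groups) != curveset.n_subjects:
        raise ValidationError("one group label per subject required")
    rows = []
    for g in pd.unique(groups):
        sel = curveset.estimates[groups == g]
        if sel.shape[0] < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
        n = np.sum(~np.isnan(sel), axis=0)  # K x E x L
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sel, axis=0)
            sd = np.nanstd(sel, axis=0, ddof=1)
        se = sd / np.sqrt(np.maximum(n, 1))
        K, E, L = mean.shape
        for k in range(K):
            for e in range(E):
                for j in range(L):
                    rows.append(
                        (
                            g,
                            curveset.component_labels[k],
                            EVENT_LABELS[e],
                            curveset.lag_times[j],
                            mean[k, e, j],
                            se[k, e, j],
                            int(n[k, e, j]),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["group", "component", "event_type", "lag_time_s", "mean", "se", "n"],
    )
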