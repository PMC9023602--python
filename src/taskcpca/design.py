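"""FIR design-matrix construction from event tables.

The finite impulse response (FIR) basis assigns each image acquisition
to a post-event time bin without assuming a haemodynamic response
shape: acquisition ``k`` (interval ``[k*TR, (k+1)*TR)``) falls in lag
bin ``j`` of a trial with onset ``t0`` iff ``k*TR - t0`` lies in
``[j*TR, (j+1)*TR)``.  With a window of 18 s at TR 3 s this yields six
lags per event type and 36 indicator columns; reported lag times are
the bin midpoints (1.5, 4.5, ..., 16.5 s), so response-curve peaks land
on half-TR offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    EVENT_LABELS,
    EVENT_TYPES,
    ValidationError,
    EventTable,
)

__all__ = [
    "FirDesign",
    "ConditionReport",
    "read_events",
    "build_fir_design",
    "check_design_conditioning",
]


@dataclass
class FirDesign:
    """Volumes x (event types x lags) indicator matrix.

    Columns are blocked event-type-major: block ``e`` holds lags
    ``0..n_lags-1`` of event type ``e`` in the fixed vocabulary order.
    Event types with no trials keep their (all-zero) columns so that
    column indices align across subjects.
    """

    matrix: np.ndarray
    repetition_time: float
    n_lags: int
    event_types: tuple[tuple[str, str], ...] = EVENT_TYPES
    lag_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.lag_times is None:
            self.lag_times = (np.arange(self.n_lags) + 0.5) * self.repetition_time
        self.lag_times = np.asarray(self.lag_times, dtype=float)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_event_types(self) -> int:
        return len(self.event_types)

    @property
    def column_labels(self) -> list[str]:
        return [
            f"{label}|lag{j}"
            for label in EVENT_LABELS
            for j in range(self.n_lags)
        ]

    def zero_column_blocks(self) -> list[int]:
        """Indices of event types whose whole column block is zero."""
        out = []
        for e in range(self.n_event_types):
            block = self.matrix[:, e * self.n_lags : (e + 1) * self.n_lags]
            if not block.any():
                out.append(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_events(path) -> EventTable:
    """Read a BIDS-style ``events.tsv`` into an :class:`EventTable`.

    Requires columns ``onset``, ``stimulus_class`` and
    ``response_class``; ``duration`` is optional.  Unknown class labels
    and malformed onsets are rejected with the offending row named.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in ("onset", "stimulus_class", "response_class"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if len(frame) == 0:
        raise ValidationError(f"{path}: no trials")
    onsets = pd.to_numeric(frame["onset"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(onsets)):
        row = int(np.flatnonzero(~np.isfinite(onsets))[0])
        raise ValidationError(f"{path}: unparseable onset at row {row}")
    duration = None
    if "duration" in frame.columns:
        duration = pd.to_numeric(frame["duration"], errors="coerce").to_numpy()
    return EventTable(
        onset=onsets,
        stimulus_class=frame["stimulus_class"].to_numpy(),
        response_class=frame["response_class"].to_numpy(),
        duration=duration,
    )


def build_fir_design(
    events: EventTable,
    n_volumes: int,
    repetition_time: float,
    window: float = 18.0,
) -> FirDesign:
    """Build the FIR indicator matrix for one subject.

    Parameters
    ----------
    events : EventTable
        Trial onsets and classes.
    n_volumes : int
        Number of acquisitions in the run; lag entries falling past the
        end of the run are dropped.
    repetition_time : float
        TR in seconds.
    window : float
        Post-event window in seconds; must be a positive multiple of
        the repetition time (default 18 s, i.e. six lags at TR 3 s).

    Overlapping trials superimpose: a volume inside two trial windows
    carries a 1 in a lag column of each trial's event type.
    """
    if n_volumes <= 0:
        raise ValidationError("n_volumes must be positive")
    if repetition_time <= 0:
        raise ValidationError("repetition_time must be positive")
    ratio = window / repetition_time
    n_lags = int(round(ratio))
    if n_lags <= 0 or abs(ratio - n_lags) > 1e-9:
        raise ValidationError(
            f"window ({window} s) must be a positive multiple of the "
            f"repetition time ({repetition_time} s)"
        )
    matrix = np.zeros((n_volumes, len(EVENT_TYPES) * n_lags))
    etype = events.event_type_index()
    for t0, e in zip(events.onset, etype):
        k0 = math.ceil(t0 / repetition_time - 1e-9)
        for j in range(n_lags):
            k = k0 + j
            if 0 <= k < n_volumes:
                matrix[k, e * n_lags + j] = 1.0
    return FirDesign(matrix=matrix, repetition_time=repetition_time, n_lags=n_lags)


@dataclass
class ConditionReport:
    """Diagnostics for an FIR design matrix.

    ``baseline_residual`` is the relative norm of the ones-vector after
    projecting out the design's column space; near zero it means the
    design spans the constant baseline (e.g. a schedule whose trial
    windows tile the run exactly), which inflates collinearity with the
    implicit baseline once the data are centred.
    """

    rank: int
    n_columns: int
    n_nonzero_columns: int
    condition_number: float
    zero_column_blocks: list[int]
    baseline_residual: float
    warnings: list[str]

    @property
    def full_rank(self) -> bool:
        return self.rank == self.n_nonzero_columns


def check_design_conditioning(
    design: FirDesign,
    cond_threshold: float = 1e8,
    baseline_threshold: float = 0.05,
) -> ConditionReport:
    """Report rank, conditioning and absent event types of a design.

    Reporting only: downstream fitting falls back to the pseudoinverse
    when the design is rank deficient.
    """
    G = design.matrix
    nonzero = np.flatnonzero(G.any(axis=0))
    warnings: list[str] = []
    zero_blocks = design.zero_column_blocks()
    if zero_blocks:
        labels = [EVENT_LABELS[e] for e in zero_blocks]
        warnings.append(f"event types absent (all-zero column blocks): {labels}")
    if nonzero.size == 0:
        return ConditionReport(0, G.shape[1], 0, np.inf, zero_blocks, 1.0, warnings)
    Gnz = G[:, nonzero]
    svals = np.linalg.svd(Gnz, compute_uv=False)
    tol = max(Gnz.shape) * np.finfo(float).eps * svals[0]
    rank = int(np.sum(svals > tol))
    smin = svals[svals > tol][-1] if rank else 0.0
    cond = (svals[0] / smin) ** 2 if smin else np.inf
    if rank < Gnz.shape[1]:
        warnings.append("design is rank deficient; fitting will use a pseudoinverse")
    if cond > cond_threshold:
        warnings.append(f"elevated collinearity: cond(G'G) = {cond:.3g}")
    ones = np.ones(G.shape[0])
    coef, *_ = np.linalg.lstsq(Gnz, ones, rcond=None)
    resid = ones - Gnz @ coef
    baseline_residual = float(np.linalg.norm(resid) / np.linalg.norm(ones))
    if baseline_residual < baseline_threshold:
        warnings.append(
            "elevated collinearity: design spans the constant baseline "
            f"(relative residual {baseline_residual:.3g}); periodic schedules "
            "whose windows tile the run exactly behave this way"
        )
    return ConditionReport(
        rank=rank,
        n_columns=G.shape[1],
        n_nonzero_columns=Gnz.shape[1],
        condition_number=float(cond),
        zero_column_blocks=zero_blocks,
        baseline_residual=baseline_residual,
        warnings=warnings,
    )
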