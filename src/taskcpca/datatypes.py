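"""Shared containers and the fixed event-type vocabulary.

The task crosses two stimulus classes (threat / non-threat) with three
response classes (correct / incorrect / non-response), giving six event
types.  Column blocks of the FIR design, response-curve arrays and the
growth-model data all use the ordering defined by :data:`EVENT_TYPES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULUS_CLASSES: tuple[str, ...] = ("threat", "non-threat")
RESPONSE_CLASSES: tuple[str, ...] = ("correct", "incorrect", "non-response")

#: The six event types, ordered stimulus-major then response.
EVENT_TYPES: tuple[tuple[str, str], ...] = tuple(
    (s, r) for s in STIMULUS_CLASSES for r in RESPONSE_CLASSES
)

#: The four event types entered into growth models (non-responses excluded).
MODELED_EVENT_TYPES: tuple[tuple[str, str], ...] = tuple(
    (s, r) for s, r in EVENT_TYPES if r != "non-response"
)


def event_label(stimulus_class: str, response_class: str) -> str:
    """Canonical string label for an event type, e.g. ``"threat:correct"``."""
    return f"{stimulus_class}:{response_class}"


EVENT_LABELS: tuple[str, ...] = tuple(event_label(s, r) for s, r in EVENT_TYPES)


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class EventTable:
    """Trial-level event listing for one subject.

    Parameters
    ----------
    onset : array of float
        Stimulus onsets in seconds from run start; non-negative and
        strictly increasing.
    stimulus_class, response_class : arrays of str
        Labels drawn from the fixed vocabularies.
    duration : array of float, optional
        Stimulus duration in seconds (constant 5.5 s in the emulated
        protocol); kept for BIDS-events round trips.
    """

    onset: np.ndarray
    stimulus_class: np.ndarray
    response_class: np.ndarray
    duration: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.stimulus_class = np.asarray(self.stimulus_class, dtype=object)
        self.response_class = np.asarray(self.response_class, dtype=object)
        if self.duration is not None:
            self.duration = np.asarray(self.duration, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.onset)
        if n == 0:
            raise ValidationError("event table contains no trials")
        if len(self.stimulus_class) != n or len(self.response_class) != n:
            raise ValidationError("event table columns have unequal lengths")
        if np.any(self.onset < 0):
            row = int(np.flatnonzero(self.onset < 0)[0])
            raise ValidationError(f"negative onset at row {row}")
        if np.any(np.diff(self.onset) <= 0):
            row = int(np.flatnonzero(np.diff(self.onset) <= 0)[0]) + 1
            raise ValidationError(f"onsets not strictly increasing at row {row}")
        for row, value in enumerate(self.stimulus_class):
            if value not in STIMULUS_CLASSES:
                raise ValidationError(
                    f"unknown stimulus_class {value!r} at row {row}; "
                    f"expected one of {STIMULUS_CLASSES}"
                )
        for row, value in enumerate(self.response_class):
            if value not in RESPONSE_CLASSES:
                raise ValidationError(
                    f"unknown response_class {value!r} at row {row}; "
                    f"expected one of {RESPONSE_CLASSES}"
                )

    def __len__(self) -> int:
        return len(self.onset)

    def event_type_index(self) -> np.ndarray:
        """Index of each trial into :data:`EVENT_TYPES`."""
        lut = {et: i for i, et in enumerate(EVENT_TYPES)}
        return np.array(
            [lut[(s, r)] for s, r in zip(self.stimulus_class, self.response_class)],
            dtype=int,
        )

    def to_frame(self) -> pd.DataFrame:
        dur = self.duration
        if dur is None:
            dur = np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "onset": self.onset,
                "duration": dur,
                "stimulus_class": self.stimulus_class,
                "response_class": self.response_class,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class ParcellatedBold:
    """One subject's parcellated BOLD run.

    ``data`` is volumes x regions (time runs down the rows); the TSV
    round trip writes one column per region with the region labels as
    header.
    """

    data: np.ndarray
    repetition_time: float
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("BOLD data must be 2-D (volumes x regions)")
        if not self.region_labels:
            self.region_labels = [f"region{i:03d}" for i in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValidationError("region label count does not match data columns")
        if self.repetition_time <= 0:
            raise ValidationError("repetition_time must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.region_labels).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path, repetition_time: float, subject_id: str = "") -> "ParcellatedBold":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            data=frame.to_numpy(dtype=float),
            repetition_time=repetition_time,
            region_labels=list(frame.columns),
            subject_id=subject_id,
        )
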