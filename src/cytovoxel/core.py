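"""Core containers and exceptions shared across the pipeline.

The central in-memory object is :class:`EventMatrix`: one cytometry sample,
cells x markers, together with the identities (sample, batch, optional class
label) needed to organise multi-batch experiments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class CytoVoxelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytoVoxelError):
    """A parameter or config value is inconsistent or unsupported."""


class IdentityNotFoundError(CytoVoxelError):
    """A referenced sample/batch/biological identity does not exist."""


class EmptySampleError(CytoVoxelError):
    """An operation received a sample with no events."""


class FCSParseError(CytoVoxelError):
    """An FCS file could not be parsed; the message carries the byte offset."""


class TransformState(str, enum.Enum):
    """Pre-processing state of an event matrix; transitions only forward."""

    RAW = "raw"
    COMPENSATED = "compensated"
    TRANSFORMED = "transformed"


_STATE_ORDER = {TransformState.RAW: 0, TransformState.COMPENSATED: 1, TransformState.TRANSFORMED: 2}


@dataclass
class EventMatrix:
    """One sample's events.

    Parameters
    ----------
    values
        ``(n_cells, n_markers)`` float array. Raw fluorescence units before
        transformation, normalized display units (nominally ``[0, 1]``) after.
    marker_names
        Channel labels, one per column.
    sample_id, batch_id
        Identities used for grouping; ``label`` is an optional class label.
    """

    values: np.ndarray
    marker_names: list[str]
    sample_id: str
    batch_id: str
    label: str | None = None
    biological_id: str | None = None
    transform_state: TransformState = TransformState.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigurationError("EventMatrix values must be 2-D (cells x markers)")
        if self.values.shape[1] != len(self.marker_names):
            raise ConfigurationError(
                f"{self.values.shape[1]} columns but {len(self.marker_names)} marker names"
            )
        if not np.isfinite(self.values).all():
            raise ConfigurationError("EventMatrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, state: TransformState | None = None) -> "EventMatrix":
        """Copy with new values; transform state may only move forward."""
        new_state = state if state is not None else self.transform_state
        if _STATE_ORDER[new_state] < _STATE_ORDER[self.transform_state]:
            raise ConfigurationError(
                f"transform state cannot move backwards ({self.transform_state.value} -> {new_state.value})"
            )
        return replace(self, values=np.asarray(values, dtype=np.float64), transform_state=new_state)

    def column(self, marker: str) -> np.ndarray:
        try:
            return self.values[:, self.marker_names.index(marker)]
        except ValueError:
            raise ConfigurationError(f"unknown marker {marker!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.marker_names)


@dataclass
class SampleSet:
    """An ordered collection of samples plus a tidy metadata table."""

    samples: list[EventMatrix]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.metadata.empty and self.samples:
            self.metadata = pd.DataFrame(
                {
                    "sample_id": [s.sample_id for s in self.samples],
                    "batch_id": [s.batch_id for s in self.samples],
                    "biological_id": [s.biological_id for s in self.samples],
                    "label": [s.label for s in self.samples],
                }
            )

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, key: int | str) -> EventMatrix:
        if isinstance(key, int):
            return self.samples[key]
        for s in self.samples:
            if s.sample_id == key:
                return s
        raise IdentityNotFoundError(f"no sample with id {key!r}")

    @property
    def marker_names(self) -> list[str]:
        return list(self.samples[0].marker_names)

    def batch(self, batch_id: str) -> list[EventMatrix]:
        out = [s for s in self.samples if s.batch_id == batch_id]
        if not out:
            raise IdentityNotFoundError(f"no samples in batch {batch_id!r}")
        return out

    @property
    def batch_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.batch_id, None)
        return list(seen)


def check_shared_panel(samples: list[EventMatrix]) -> list[str]:
    """Return the common marker panel, or raise if samples disagree."""
    if not samples:
        raise EmptySampleError("no samples supplied")
    panel = samples[0].marker_names
    for s in samples[1:]:
        if s.marker_names != panel:
            raise ConfigurationError(
                f"marker panel mismatch: {s.sample_id} has {s.marker_names}, expected {panel}"
            )
    return list(panel)
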