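"""Core data model for multiwell cytometry screens.

A screen is a collection of wells; each well carries a table of single-cell
events (rows) over named fluorescence/mass channels (columns) plus plate
metadata (position, acquisition read order, control/treatment role, drug and
concentration).  These containers are deliberately thin: events live in a
plain float64 ndarray and all statistics are computed by the analysis
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


class GridscreenError(Exception):
    """Base class for all package errors."""


class FileFormatError(GridscreenError):
    """Unreadable or malformed input file."""


class ZeroEventsError(GridscreenError):
    """An event file contains no events."""


class ChannelError(GridscreenError):
    """A requested channel is absent or channel sets are inconsistent."""


class ValidationError(GridscreenError):
    """A record violates a data-model invariant."""


class TransformError(GridscreenError):
    """Invalid or repeated intensity transform."""


@dataclass(frozen=True)
class EventTable:
    """Events-by-channels matrix for one well/sample.

    Parameters
    ----------
    events : ndarray of shape (n_events, n_channels)
        Raw (or transformed) intensities; no missing values allowed.
    channel_names : tuple of str
        Unique, ordered channel names, one per column.
    transform_state : str
        ``"none"`` for raw intensities or ``"arcsinh(c)"`` after an
        arcsinh transform with cofactor ``c``.
    """

    events: np.ndarray
    channel_names: tuple[str, ...]
    transform_state: str = "none"

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=np.float64)
        if ev.ndim != 2:
            raise ValidationError("events must be a 2-D matrix")
        if ev.shape[0] < 1 or ev.shape[1] < 1:
            raise ZeroEventsError("EventTable needs at least 1 event and 1 channel")
        if not np.all(np.isfinite(ev)):
            raise ValidationError("events contain missing/non-finite values")
        names = tuple(str(c).strip() for c in self.channel_names)
        if len(names) != ev.shape[1]:
            raise ValidationError(
                f"{len(names)} channel names for {ev.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name.strip())
        except ValueError:
            raise ChannelError(f"channel {name!r} not present") from None

    def select_channels(self, names: Sequence[str]) -> "EventTable":
        """Project onto the given channels, in the given order."""
        idx = [self.channel_index(n) for n in names]
        return EventTable(self.events[:, idx],
                          tuple(self.channel_names[i] for i in idx),
                          self.transform_state)

    def channel(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]


VALID_ROLES = ("negative_control", "treatment")


@dataclass
class WellRecord:
    """One well of a plate: metadata plus its event table."""

    well_id: str
    plate_id: str
    row: int
    col: int
    read_order: int
    role: str
    drug: str = ""
    concentration: float = 0.0
    concentration_unit: str = ""
    events: EventTable | None = None
    live_count: float | None = None  # viability metadata; defaults to n_events

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.role == "negative_control" and self.drug:
            raise ValidationError(
                f"well {self.well_id}: negative control must have empty drug"
            )
        if self.row < 1 or self.col < 1:
            raise ValidationError("row/col must be >= 1")
        if self.read_order < 1:
            raise ValidationError("read_order must be >= 1")
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")

    @property
    def sample_id(self) -> str:
        return f"{self.plate_id}/{self.well_id}"

    @property
    def is_control(self) -> bool:
        return self.role == "negative_control"

    def get_live_count(self) -> float:
        if self.live_count is not None:
            return self.live_count
        if self.events is not None:
            return float(self.events.n_events)
        raise ValidationError(f"well {self.well_id} has no events or live_count")


@dataclass
class Screen:
    """A collection of wells across one or more plates.

    ``tube`` grouping is implicit: wells that carry different channel panels
    are compared on shared channels only (see ``similarity.similarity_pair``).
    """

    wells: list[WellRecord]
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        order_seen: set[tuple[str, int]] = set()
        for w in self.wells:
            key = (w.plate_id, w.well_id)
            if key in seen:
                raise ValidationError(f"duplicate well {key}")
            seen.add(key)
            okey = (w.plate_id, w.read_order)
            if okey in order_seen:
                raise ValidationError(
                    f"duplicate read_order {w.read_order} on plate {w.plate_id}"
                )
            order_seen.add(okey)

    @property
    def plates(self) -> list[str]:
        out: list[str] = []
        for w in self.wells:
            if w.plate_id not in out:
                out.append(w.plate_id)
        return out

    def plate_wells(self, plate_id: str) -> list[WellRecord]:
        ws = [w for w in self.wells if w.plate_id == plate_id]
        if not ws:
            raise ValidationError(f"unknown plate {plate_id!r}")
        return ws

    def well(self, sample_id: str) -> WellRecord:
        for w in self.wells:
            if w.sample_id == sample_id:
                return w
        raise ValidationError(f"unknown sample {sample_id!r}")

    @property
    def control_ids(self) -> list[str]:
        return [w.sample_id for w in self.wells if w.is_control]

    def shared_channels(self) -> tuple[str, ...]:
        """Channels present in every well with events, in first-well order."""
        tables = [w.events for w in self.wells if w.events is not None]
        if not tables:
            raise ValidationError("screen has no event data")
        common = set(tables[0].channel_names)
        for t in tables[1:]:
            common &= set(t.channel_names)
        if not common:
            raise ChannelError("no channel shared by all wells")
        return tuple(c for c in tables[0].channel_names if c in common)

    def with_wells(self, wells: Iterable[WellRecord]) -> "Screen":
        return Screen(list(wells), ground_truth=self.ground_truth)


def replace_events(well: WellRecord, events: EventTable) -> WellRecord:
    return replace(well, events=events)
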