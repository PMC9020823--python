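"""Two-step plate bias correction.

Intra-plate signal drift: for each plate and channel, the per-well channel
medians are regressed on acquisition read order (OLS).  Every event in a
well read at order t is then translated by ``b * (t_bar - t)`` — the fitted
line is rotated to slope zero about the mean read order, so each well moves
rigidly (the population shape is untouched) and the plate's average level is
preserved.  Viability drift is corrected analogously but multiplicatively on
per-well live counts (counts cannot go negative): each count is scaled by
``f(t_bar) / f(t)`` with f the fitted line.  Inter-plate batch shift is then
removed by translating every plate's events so the plate medians (computed
over negative-control wells when every plate carries at least 3, otherwise
over all wells) meet at a common baseline, the median of the plate medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import EventTable, Screen, ValidationError, WellRecord

__all__ = [
    "IntraplateFit",
    "CorrectionModel",
    "fit_intraplate",
    "apply_intraplate",
    "correct_viability",
    "align_plates",
    "DriftCorrector",
]


@dataclass(frozen=True)
class IntraplateFit:
    """OLS fit of per-well medians (or counts) on read order for one plate."""

    plate_id: str
    channel: str  # channel name, or "__count__" for viability
    intercept: float
    slope: float
    mean_read_order: float


@dataclass
class CorrectionModel:
    """All fitted correction parameters of a screen.

    With every slope and shift at zero, applying the model is the identity.
    """

    intraplate: dict[tuple[str, str], IntraplateFit] = field(default_factory=dict)
    viability: dict[str, IntraplateFit] = field(default_factory=dict)
    plate_shifts: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "intraplate": [vars(f) for f in self.intraplate.values()],
            "viability": [vars(f) for f in self.viability.values()],
            "plate_shifts": [{"plate_id": p, "channel": c, "shift": s}
                             for (p, c), s in self.plate_shifts.items()],
        }


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least squares of y on x: (intercept, slope, x_bar)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0:
        raise ValidationError("degenerate read orders (no variation)")
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    return intercept, slope, float(xbar)


def _well_medians(screen: Screen, plate_id: str, channel: str
                  ) -> tuple[list[WellRecord], np.ndarray, np.ndarray]:
    wells = screen.plate_wells(plate_id)
    orders = np.array([w.read_order for w in wells], dtype=float)
    meds = np.array([float(np.median(w.events.channel(channel)))
                     for w in wells])
    return wells, orders, meds


def fit_intraplate(screen: Screen, plate_id: str, channel: str) -> IntraplateFit:
    """Fit the signal-drift line: per-well channel medians vs read order."""
    wells, orders, meds = _well_medians(screen, plate_id, channel)
    if len(wells) < 3:
        raise ValidationError("need >= 3 wells to fit a drift line")
    a, b, tbar = _ols(orders, meds)
    return IntraplateFit(plate_id, channel, intercept=a, slope=b,
                         mean_read_order=tbar)


def apply_intraplate(screen: Screen, fit: IntraplateFit) -> Screen:
    """Detrend one plate/channel: translate each well's events by b*(t_bar - t).

    The fitted drift line is rotated to slope zero about the mean read
    order; the mean of the well medians is preserved and within-well event
    order and count are untouched.
    """
    wells = []
    for w in screen.wells:
        if w.plate_id != fit.plate_id or w.events is None:
            wells.append(w)
            continue
        table = w.events
        j = table.channel_index(fit.channel)
        shift = fit.slope * (fit.mean_read_order - w.read_order)
        ev = table.events.copy()
        ev[:, j] += shift
        wells.append(replace(w, events=EventTable(ev, table.channel_names,
                                                  table.transform_state)))
    return screen.with_wells(wells)


def correct_viability(screen: Screen, plate_id: str) -> Screen:
    """Detrend per-well live counts multiplicatively along read order.

    Each count is rescaled by f(t_bar)/f(t) where f is the OLS fit of
    counts on read order; the event tables themselves are untouched (counts
    are metadata).  Fails if the fitted line is non-positive at any well,
    where a multiplicative detrend is meaningless.
    """
    wells = screen.plate_wells(plate_id)
    if len(wells) < 3:
        raise ValidationError("need >= 3 wells to fit a viability trend")
    orders = np.array([w.read_order for w in wells], dtype=float)
    counts = np.array([w.get_live_count() for w in wells], dtype=float)
    a, b, tbar = _ols(orders, counts)
    fitted = a + b * orders
    if np.any(fitted <= 0):
        raise ValidationError(
            "viability trend crosses zero; too steep for multiplicative correction")
    target = a + b * tbar
    corrected = counts * target / fitted
    by_id = {w.well_id: c for w, c in zip(wells, corrected)}
    out = []
    for w in screen.wells:
        if w.plate_id == plate_id:
            out.append(replace(w, live_count=float(by_id[w.well_id])))
        else:
            out.append(w)
    return screen.with_wells(out)


def _plate_median(screen: Screen, plate_id: str, channel: str,
                  controls_only: bool) -> float:
    wells = screen.plate_wells(plate_id)
    if controls_only:
        wells = [w for w in wells if w.is_control]
    vals = np.concatenate([w.events.channel(channel) for w in wells])
    return float(np.median(vals))


def align_plates(screen: Screen, channel: str) -> tuple[Screen, dict[str, float]]:
    """Translate plates so their medians meet at a common baseline.

    The baseline is the median across plates of the plate medians; each
    plate's events on ``channel`` are shifted by baseline - plate_median.
    Plate medians are computed over negative-control wells when every plate
    carries at least 3 controls, otherwise over all wells.

    Returns the corrected screen and the per-plate shifts.
    """
    plates = screen.plates
    if len(plates) < 2:
        raise ValidationError("need >= 2 plates to align")
    controls_only = all(
        sum(w.is_control for w in screen.plate_wells(p)) >= 3 for p in plates)
    medians = {p: _plate_median(screen, p, channel, controls_only)
               for p in plates}
    baseline = float(np.median(list(medians.values())))
    shifts = {p: baseline - m for p, m in medians.items()}
    wells = []
    for w in screen.wells:
        if w.events is None:
            wells.append(w)
            continue
        j = w.events.channel_index(channel)
        ev = w.events.events.copy()
        ev[:, j] += shifts[w.plate_id]
        wells.append(replace(w, events=EventTable(ev, w.events.channel_names,
                                                  w.events.transform_state)))
    return screen.with_wells(wells), shifts


class DriftCorrector(BaseEstimator, TransformerMixin):
    """Fit-and-apply two-step bias correction over a whole screen.

    ``fit`` learns, per plate and channel, the intra-plate drift line, the
    per-plate viability trend, and (for multi-plate screens) the
    inter-plate median shifts; ``transform`` applies them in that order.

    Parameters
    ----------
    channels : channels to correct; None means all shared channels.
    correct_signal, correct_counts, align : stage toggles.

    Attributes
    ----------
    model_ : the fitted :class:`CorrectionModel`.
    """

    def __init__(self, channels: list[str] | None = None,
                 correct_signal: bool = True,
                 correct_counts: bool = True,
                 align: bool = True):
        self.channels = channels
        self.correct_signal = correct_signal
        self.correct_counts = correct_counts
        self.align = align

    def _channels(self, screen: Screen) -> list[str]:
        return list(self.channels) if self.channels is not None \
            else list(screen.shared_channels())

    def fit(self, X: Screen, y=None):
        screen = X
        model = CorrectionModel()
        chans = self._channels(screen)
        working = screen
        if self.correct_signal:
            for plate in screen.plates:
                for ch in chans:
                    f = fit_intraplate(working, plate, ch)
                    model.intraplate[(plate, ch)] = f
                    working = apply_intraplate(working, f)
        if self.correct_counts:
            for plate in screen.plates:
                wells = working.plate_wells(plate)
                orders = np.array([w.read_order for w in wells], dtype=float)
                counts = np.array([w.get_live_count() for w in wells])
                a, b, tbar = _ols(orders, counts)
                model.viability[plate] = IntraplateFit(
                    plate, "__count__", intercept=a, slope=b,
                    mean_read_order=tbar)
        if self.align and len(screen.plates) >= 2:
            for ch in chans:
                working, shifts = align_plates(working, ch)
                for p, s in shifts.items():
                    model.plate_shifts[(p, ch)] = s
        self.model_ = model
        return self

    def transform(self, X: Screen) -> Screen:
        if not hasattr(self, "model_"):
            raise ValidationError("DriftCorrector is not fitted")
        screen = X
        for f in self.model_.intraplate.values():
            screen = apply_intraplate(screen, f)
        for plate in screen.plates:
            if plate in self.model_.viability:
                screen = correct_viability(screen, plate)
        if self.model_.plate_shifts:
            wells = []
            for w in screen.wells:
                if w.events is None:
                    wells.append(w)
                    continue
                ev = w.events.events.copy()
                for (p, ch), s in self.model_.plate_shifts.items():
                    if p == w.plate_id and ch in w.events.channel_names:
                        ev[:, w.events.channel_index(ch)] += s
                wells.append(replace(w, events=EventTable(
                    ev, w.events.channel_names, w.events.transform_state)))
            screen = screen.with_wells(wells)
        return screen

    def fit_transform(self, X: Screen, y=None, **kwargs) -> Screen:
        return self.fit(X).transform(X)
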