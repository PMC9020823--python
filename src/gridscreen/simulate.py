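"""Synthetic multiwell cytometry screens with known ground truth.

Each well draws cells from a Gaussian mixture over the marker channels.
Treatment wells modify the mixture through a log-dose logistic (Hill)
dose-response acting on one target population: shifting its abundance,
translating its mean, or killing cells (viability loss).  Plate artifacts —
linear signal drift along acquisition read order, per-plate batch offsets,
border-well edge effects and viability drift — are injected on top, so the
QC and correction modules can be exercised against a known truth.

Event counts are drawn Poisson around the nominal per-well count (scaled by
viability effects) so that wells genuinely differ in size; the similarity
engine must be insensitive to that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import EventTable, Screen, ValidationError, WellRecord

__all__ = [
    "PopulationSpec",
    "ArtifactSpec",
    "DrugEffectSpec",
    "simulate_screen",
    "sample_mixture",
    "perturb_with_noise",
    "noise_sd_from_iqr",
    "remove_cluster_fraction",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian cell subpopulation: mean vector, covariance, mixture weight."""

    mean: tuple[float, ...]
    covariance: tuple[tuple[float, ...], ...] | tuple[float, ...]
    weight: float

    def cov_matrix(self) -> np.ndarray:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        d = len(self.mean)
        if cov.shape != (d, d):
            raise ValidationError("covariance shape does not match mean length")
        # symmetric positive definite check via Cholesky
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("covariance not positive definite") from exc
        return cov


@dataclass(frozen=True)
class ArtifactSpec:
    """Injected plate biases.

    drift_slope : per-channel intensity added per unit read order.
    plate_offset : per-channel batch offset added to plate k as k*offset
        (k = 0, 1, ... in plate order), or a mapping plate_id -> offset.
    viability_slope : expected live-count change per unit read order.
    edge_effect : additive intensity on wells at the plate border.
    noise_sd : per-channel Gaussian sd used by batch-effect perturbation.
    """

    drift_slope: float | tuple[float, ...] = 0.0
    plate_offset: float | dict = 0.0
    viability_slope: float = 0.0
    edge_effect: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


NULL_ARTIFACTS = ArtifactSpec()


@dataclass(frozen=True)
class DrugEffectSpec:
    """A dose-dependent effect on one target population.

    ``effect_kind`` is one of ``abundance_shift`` (additive change of
    population weights, renormalized), ``mean_shift`` (translation of the
    target mean) or ``viability_loss`` (fractional reduction of expected
    live count).  The magnitude at dose c is ``magnitude_at_max * h(c)``
    with the Hill response h(c) = c^s / (c^s + m^s) in dose (logistic in
    log10 dose), midpoint ``hill_midpoint`` and slope ``hill_slope``.

    For ``abundance_shift`` the magnitude may be a vector over all
    populations (subtype-specific kill or expansion, as strong cytotoxic or
    differentiating agents produce); a scalar applies to the target
    population alone.
    """

    name: str
    target_population: int = 0
    effect_kind: str = "mean_shift"
    magnitude_at_max: float | tuple[float, ...] = 0.0
    hill_midpoint: float = 1.0
    hill_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_kind not in ("abundance_shift", "mean_shift",
                                    "viability_loss"):
            raise ValidationError(f"unknown effect_kind {self.effect_kind!r}")
        if self.effect_kind == "viability_loss":
            m = float(np.asarray(self.magnitude_at_max))
            if not 0 <= m <= 1:
                raise ValidationError("viability_loss magnitude must be in [0,1]")

    def response(self, dose: float) -> float:
        """Fraction of the maximal effect reached at the given dose."""
        if dose <= 0:
            return 0.0
        s = self.hill_slope
        return dose ** s / (dose ** s + self.hill_midpoint ** s)


def _normalized_weights(populations: list[PopulationSpec]) -> np.ndarray:
    w = np.array([p.weight for p in populations], dtype=float)
    if np.any(w <= 0) or np.any(w > 1):
        raise ValidationError("population weights must be in (0, 1]")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("population weights must sum to 1")
    return w


def sample_mixture(populations: list[PopulationSpec],
                   weights: np.ndarray,
                   means: np.ndarray,
                   n_events: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw events from a Gaussian mixture; returns (events, component labels)."""
    d = means.shape[1]
    labels = rng.choice(len(populations), size=n_events, p=weights / weights.sum())
    out = np.empty((n_events, d))
    for i, pop in enumerate(populations):
        mask = labels == i
        k = int(mask.sum())
        if k:
            out[mask] = rng.multivariate_normal(means[i], pop.cov_matrix(),
                                                size=k, method="cholesky")
    return out, labels


def _is_edge(row: int, col: int, n_rows: int, n_cols: int) -> bool:
    return row == 1 or col == 1 or row == n_rows or col == n_cols


def _well_id(row: int, col: int) -> str:
    letters = ""
    r = row
    while r > 0:
        r, rem = divmod(r - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{col:02d}"


def simulate_screen(populations: list[PopulationSpec],
                    drugs: list[DrugEffectSpec],
                    doses: list[float],
                    artifacts: ArtifactSpec = NULL_ARTIFACTS,
                    wells_per_condition: int = 1,
                    events_per_well: int = 2000,
                    seed: int = 0,
                    n_controls: int = 20,
                    channels: list[str] | None = None,
                    plate_shape: tuple[int, int] = (16, 24),
                    well_jitter_sd: float = 0.0) -> Screen:
    """Simulate a multiwell screen and return it with ground truth attached.

    Wells are laid out row-major on 384-well (16x24 by default) plates in
    the order: negative controls first, then every drug at every dose,
    ``wells_per_condition`` replicates each; read order follows layout
    order.  With all artifact magnitudes zero and no drugs, every well is an
    i.i.d. draw from the base mixture.

    ``well_jitter_sd`` adds biological well-to-well variability: each
    well's population means get an independent offset per channel, drawn
    uniformly with this standard deviation (bounded support — plate-level
    biology varies within limits, it does not produce arbitrarily extreme
    wells).  For treatment wells with a genuine effect the jitter is scaled
    by (1 - response fraction): a saturating dose canalizes the phenotype,
    driving all wells with the same strong response toward the same state,
    while untreated and inert wells retain full variability.
    """
    if not populations:
        raise ValidationError("need at least one population")
    base_weights = _normalized_weights(populations)
    d = len(populations[0].mean)
    for p in populations:
        if len(p.mean) != d:
            raise ValidationError("populations must share dimensionality")
    if channels is None:
        channels = [f"M{i + 1}" for i in range(d)]
    if len(channels) != d:
        raise ValidationError("channel count must match dimensionality")
    base_means = np.array([p.mean for p in populations], dtype=float)

    drift = np.broadcast_to(np.asarray(artifacts.drift_slope, dtype=float),
                            (d,)).copy()

    # condition list: (role, drug spec or None, dose)
    conditions: list[tuple[str, DrugEffectSpec | None, float]] = []
    conditions += [("negative_control", None, 0.0)] * n_controls
    for drug in drugs:
        for dose in doses:
            conditions += [("treatment", drug, float(dose))] * wells_per_condition

    n_rows, n_cols = plate_shape
    per_plate = n_rows * n_cols
    rng = np.random.default_rng(seed)

    wells: list[WellRecord] = []
    truth_wells: dict[str, dict] = {}
    for idx, (role, drug, dose) in enumerate(conditions):
        plate_idx, pos = divmod(idx, per_plate)
        plate_id = f"P{plate_idx + 1}"
        row, col = pos // n_cols + 1, pos % n_cols + 1
        read_order = pos + 1

        weights = base_weights.copy()
        means = base_means.copy()
        expected = float(events_per_well)
        effect_size = 0.0
        canalization = 0.0
        if drug is not None:
            f = drug.response(dose)
            effect_size = f
            mag = np.asarray(drug.magnitude_at_max, dtype=float)
            if np.any(mag != 0):
                canalization = f
            t = drug.target_population
            if drug.effect_kind == "abundance_shift":
                if mag.ndim == 0:
                    weights[t] = np.clip(weights[t] + float(mag) * f, 0.0, 1.0)
                else:
                    if mag.shape != weights.shape:
                        raise ValidationError(
                            "abundance_shift vector must have one entry "
                            "per population")
                    weights = np.clip(weights + mag * f, 0.0, 1.0)
                total = weights.sum()
                if total <= 0:
                    raise ValidationError("abundance shift removed all mass")
                weights = weights / total
            elif drug.effect_kind == "mean_shift":
                means[t] = means[t] + np.broadcast_to(mag, (d,)) * f
            else:  # viability_loss
                expected = expected * (1.0 - float(mag) * f)

        if well_jitter_sd > 0:
            half = np.sqrt(3.0) * well_jitter_sd * (1.0 - canalization)
            means = means + rng.uniform(-half, half, size=means.shape)

        expected = expected + artifacts.viability_slope * (read_order - 1)
        if expected <= 0:
            raise ValidationError("expected event count driven below zero")
        n_events = max(1, int(rng.poisson(expected)))

        active = weights > 0
        events, labels = sample_mixture(
            [p for p, a in zip(populations, active) if a],
            weights[active], means[active], n_events, rng)
        # re-map labels to original population indices
        labels = np.flatnonzero(active)[labels]

        # artifacts: signal drift, batch offset, edge effect
        events = events + drift * (read_order - 1)
        if isinstance(artifacts.plate_offset, dict):
            events = events + float(artifacts.plate_offset.get(plate_id, 0.0))
        else:
            events = events + float(artifacts.plate_offset) * plate_idx
        if artifacts.edge_effect and _is_edge(row, col, n_rows, n_cols):
            events = events + artifacts.edge_effect

        well = WellRecord(
            well_id=_well_id(row, col), plate_id=plate_id, row=row, col=col,
            read_order=read_order, role=role,
            drug=(drug.name if drug is not None else ""),
            concentration=dose,
            events=EventTable(events, tuple(channels)),
        )
        wells.append(well)
        truth_wells[well.sample_id] = {
            "role": role,
            "drug": drug.name if drug is not None else "",
            "dose": dose,
            "effect_kind": drug.effect_kind if drug is not None else "",
            "effect_fraction": effect_size,
            "population_labels_counts": np.bincount(
                labels, minlength=len(populations)).tolist(),
        }

    truth = {
        "seed": seed,
        "channels": list(channels),
        "populations": [{"mean": list(p.mean), "weight": p.weight}
                        for p in populations],
        "artifacts": {
            "drift_slope": drift.tolist(),
            "plate_offset": artifacts.plate_offset
            if not isinstance(artifacts.plate_offset, dict)
            else dict(artifacts.plate_offset),
            "viability_slope": artifacts.viability_slope,
            "edge_effect": artifacts.edge_effect,
            "noise_sd": artifacts.noise_sd,
        },
        "wells": truth_wells,
    }
    return Screen(wells, ground_truth=truth)


# ---------------------------------------------------------------------------
# Perturbations used in robustness experiments
# ---------------------------------------------------------------------------

def noise_sd_from_iqr(table: EventTable, scale: float = 0.5) -> np.ndarray:
    """Per-channel noise sd as a fraction of that channel's interquartile range."""
    q75, q25 = np.percentile(table.events, [75, 25], axis=0)
    return scale * (q75 - q25)


def perturb_with_noise(table: EventTable,
                       sd: float | np.ndarray,
                       seed: int) -> EventTable:
    """Add i.i.d. Gaussian noise per value to every channel (batch-effect model)."""
    sd_arr = np.broadcast_to(np.asarray(sd, dtype=float), (table.n_channels,))
    if np.any(sd_arr < 0):
        raise ValidationError("noise sd must be >= 0")
    if np.all(sd_arr == 0):
        return table
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=table.events.shape) * sd_arr
    return EventTable(table.events + noise, table.channel_names,
                      table.transform_state)


def remove_cluster_fraction(table: EventTable,
                            member_mask: np.ndarray,
                            fraction: float,
                            seed: int) -> EventTable:
    """Remove a random fraction of the events in a designated cluster.

    Exactly ``floor(fraction * n_members)`` masked events are removed,
    chosen uniformly at random; removals are nested across fractions for a
    fixed seed (a seeded permutation is drawn once and the first k entries
    removed), so similarity traced over increasing fractions reflects the
    gradual disappearance of the population rather than resampling noise.
    """
    mask = np.asarray(member_mask, dtype=bool)
    if mask.shape != (table.n_events,):
        raise ValidationError("member_mask length must equal event count")
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must be in [0, 1]")
    members = np.flatnonzero(mask)
    k = math.floor(fraction * members.size)
    if k == 0:
        return table
    rng = np.random.default_rng(seed)
    perm = rng.permutation(members.size)
    drop = members[perm[:k]]
    keep = np.ones(table.n_events, dtype=bool)
    keep[drop] = False
    if not keep.any():
        raise ValidationError("removal would leave an empty table")
    return EventTable(table.events[keep], table.channel_names,
                      table.transform_state)
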