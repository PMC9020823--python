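"""Pairwise sample similarity by dynamic mass-aware gridding.

Each sample is gridded independently: every marker axis is split into ``n``
equal-width intervals between that sample's own post-denoising minimum and
maximum, so a d-marker sample occupies at most ``n**d`` hypercubes, of which
only the occupied ones are stored (sparse).  A hypercube is identified by
its integer index vector — its *relative* spatial position — which makes the
occupancy map exactly invariant under any per-channel strictly increasing
affine transform of the raw intensities.  Signal shift between batches or
plates therefore cancels without any explicit correction.

Two samples are compared through the fractions of their events (mass) that
fall in corresponding hypercubes: per occupied cube the score is
``min(p, q) / max(p, q)`` (1 when the masses agree, 0 when a cube is
exclusive to one sample), and the similarity is 100 times the average of
this score over the union of occupied cubes.  Using mass fractions makes
the score independent of absolute event counts.

Noise events are removed beforehand with the local outlier factor (LOF).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors

from .core import ChannelError, EventTable, Screen, ValidationError

__all__ = [
    "LofParams",
    "OccupancyMap",
    "SimilarityMatrix",
    "remove_noise_lof",
    "grid_sample",
    "compare",
    "similarity_pair",
    "similarity_multitube",
    "similarity_matrix",
    "GridSimilarity",
]

MAX_NOISE_FRACTION = 0.10  # hard cap on events removable as noise
LOF_SUBSAMPLE = 50_000     # LOF fitted on at most this many events


@dataclass(frozen=True)
class LofParams:
    """Local-outlier-factor denoising parameters.

    k : number of neighbours for the density ratio.
    threshold : events with LOF score above this are noise candidates.
    max_events : LOF is fitted on a seeded uniform subsample of at most this
        many events; excluded events get the score of their nearest fitted
        neighbour.
    seed : seed for the subsample draw.
    """

    k: int = 30
    threshold: float = 1.5
    max_events: int = LOF_SUBSAMPLE
    seed: int = 0


@dataclass(frozen=True)
class OccupancyMap:
    """Sparse hypercube occupancy of one gridded sample.

    ``masses`` maps index vectors in {0..n-1}^d to mass fractions in (0, 1]
    summing to 1; only occupied hypercubes are stored.
    """

    masses: dict[tuple[int, ...], float]
    n: int
    channel_names: tuple[str, ...]
    total_events: int

    @property
    def d(self) -> int:
        return len(self.channel_names)

    def __post_init__(self) -> None:
        total = sum(self.masses.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"masses sum to {total}, expected 1")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity on a 0-100 scale, diagonal 100."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = len(self.sample_ids)
        if v.shape != (m, m):
            raise ValidationError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=0, rtol=0, equal_nan=False):
            raise ValidationError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 100:
            raise ValidationError("similarities must lie in [0, 100]")
        if not np.all(np.diag(v) == 100.0):
            raise ValidationError("diagonal must be exactly 100")
        object.__setattr__(self, "values", v)

    def index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample {sample_id!r}") from None

    def between(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, ids: list[str]) -> "SimilarityMatrix":
        idx = [self.index(i) for i in ids]
        return SimilarityMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.sample_ids))


# ---------------------------------------------------------------------------
# LOF denoising
# ---------------------------------------------------------------------------

def remove_noise_lof(table: EventTable,
                     k: int = 30,
                     threshold: float = 1.5,
                     max_events: int = LOF_SUBSAMPLE,
                     seed: int = 0) -> EventTable:
    """Drop locally sparse events (noise) by their local outlier factor.

    Events whose LOF score (k Euclidean neighbours) exceeds ``threshold``
    are removed, capped at 10% of events — when more exceed the threshold
    only the highest-scoring 10% go, the rest are retained.  On tables
    larger than ``max_events`` the LOF model is fitted on a seeded uniform
    subsample and out-of-sample events inherit the score of their nearest
    fitted neighbour.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = table.n_events
    if k >= n:
        raise ValidationError(f"k={k} must be below the event count {n}")
    X = table.events
    if n > max_events:
        rng = np.random.default_rng(seed)
        fit_idx = rng.choice(n, size=max_events, replace=False)
        fit_idx.sort()
        Xfit = X[fit_idx]
        lof = LocalOutlierFactor(n_neighbors=k)
        lof.fit(Xfit)
        scores = np.empty(n)
        scores[fit_idx] = -lof.negative_outlier_factor_
        rest = np.setdiff1d(np.arange(n), fit_idx, assume_unique=False)
        if rest.size:
            nn = NearestNeighbors(n_neighbors=1).fit(Xfit)
            _, nearest = nn.kneighbors(X[rest])
            scores[rest] = scores[fit_idx][nearest[:, 0]]
    else:
        lof = LocalOutlierFactor(n_neighbors=k)
        lof.fit(X)
        scores = -lof.negative_outlier_factor_

    flagged = np.flatnonzero(scores > threshold)
    cap = int(MAX_NOISE_FRACTION * n)
    if flagged.size > cap:
        order = np.argsort(scores[flagged])[::-1]  # keep worst offenders
        flagged = flagged[order[:cap]]
    if flagged.size == 0:
        return table
    keep = np.ones(n, dtype=bool)
    keep[flagged] = False
    return EventTable(X[keep], table.channel_names, table.transform_state)


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------

def grid_sample(table: EventTable, n: int = 5) -> OccupancyMap:
    """Grid a sample into its sparse hypercube occupancy map.

    Each retained channel is divided into ``n`` equal-width intervals
    between that channel's own min and max; the top interval is closed on
    the right so maxima land in bin ``n - 1``.  Channels with zero range
    carry no positional information and are dropped with a warning; a table
    whose channels are all constant cannot be gridded.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    X = table.events
    if X.shape[0] == 1:  # a lone event occupies a single hypercube
        return OccupancyMap({(0,) * X.shape[1]: 1.0}, n=n,
                            channel_names=table.channel_names, total_events=1)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    keep = hi > lo
    if not keep.any():
        raise ValidationError("all channels constant; nothing to grid")
    if not keep.all():
        dropped = [c for c, k in zip(table.channel_names, keep) if not k]
        warnings.warn(f"dropping constant channels {dropped}", stacklevel=2)
        X, lo, hi = X[:, keep], lo[keep], hi[keep]
    names = tuple(c for c, k in zip(table.channel_names, keep) if k)

    idx = np.floor((X - lo) / (hi - lo) * n).astype(np.int64)
    np.clip(idx, 0, n - 1, out=idx)  # right-close the top bin
    cubes, counts = np.unique(idx, axis=0, return_counts=True)
    total = X.shape[0]
    masses = {tuple(int(v) for v in cube): cnt / total
              for cube, cnt in zip(cubes, counts)}
    return OccupancyMap(masses, n=n, channel_names=names, total_events=total)


def compare(a: OccupancyMap, b: OccupancyMap) -> float:
    """Similarity of two occupancy maps on the 0-100 scale.

    S = 100 * mean over the union of occupied hypercubes of
    min(p, q) / max(p, q), where an absent cube has mass 0 — hypercubes
    exclusive to one sample contribute exactly 0.
    """
    if a.n != b.n or a.d != b.d:
        raise ValidationError(
            f"grid mismatch: n={a.n}/{b.n}, d={a.d}/{b.d}")
    union = a.masses.keys() | b.masses.keys()
    acc = 0.0
    for cube in a.masses.keys() & b.masses.keys():
        p, q = a.masses[cube], b.masses[cube]
        acc += min(p, q) / max(p, q)
    return 100.0 * acc / len(union)


def compare_dense(a: OccupancyMap, b: OccupancyMap) -> float:
    """Reference implementation enumerating all n**d hypercubes densely.

    Exists as an independent cross-check of :func:`compare`; O(n^d) and
    only sensible for small d.
    """
    if a.n != b.n or a.d != b.d:
        raise ValidationError("grid mismatch")
    acc = 0.0
    occupied = 0
    for cube in itertools.product(range(a.n), repeat=a.d):
        p = a.masses.get(cube, 0.0)
        q = b.masses.get(cube, 0.0)
        if p == 0.0 and q == 0.0:
            continue
        occupied += 1
        acc += min(p, q) / max(p, q)
    return 100.0 * acc / occupied


# ---------------------------------------------------------------------------
# Pairwise similarity over samples and screens
# ---------------------------------------------------------------------------

def _shared_channels(a: EventTable, b: EventTable) -> tuple[str, ...]:
    common = [c for c in a.channel_names if c in b.channel_names]
    if not common:
        raise ChannelError("samples share no channels")
    return tuple(common)


def _prepare(table: EventTable, n: int, lof: LofParams | None) -> OccupancyMap:
    if lof is not None and table.n_events > lof.k:
        table = remove_noise_lof(table, k=lof.k, threshold=lof.threshold,
                                 max_events=lof.max_events, seed=lof.seed)
    return grid_sample(table, n)


def similarity_pair(a: EventTable, b: EventTable,
                    n: int = 5,
                    lof_params: LofParams | None = LofParams()) -> float:
    """Similarity of two event tables on shared channels (0-100)."""
    shared = _shared_channels(a, b)
    return compare(_prepare(a.select_channels(shared), n, lof_params),
                   _prepare(b.select_channels(shared), n, lof_params))


def similarity_multitube(tubes_a: dict[str, EventTable],
                         tubes_b: dict[str, EventTable],
                         n: int = 5,
                         lof_params: LofParams | None = LofParams()) -> float:
    """Similarity of two samples measured in several staining tubes.

    Tubes present in both samples are compared on their shared channels and
    the per-tube similarities averaged (unweighted), so samples remain
    comparable in marker subspaces even when the full panels differ.
    """
    comparable = [t for t in tubes_a if t in tubes_b]
    if not comparable:
        raise ValidationError("samples have no tube in common")
    vals = [similarity_pair(tubes_a[t], tubes_b[t], n=n, lof_params=lof_params)
            for t in comparable]
    return float(np.mean(vals))


class GridSimilarity(BaseEstimator):
    """Pairwise affinity of cytometry samples by dynamic mass-aware gridding.

    A scikit-learn-style estimator: ``fit`` takes a list of
    :class:`EventTable` (or a :class:`Screen`) and computes the full
    pairwise similarity matrix; each sample is denoised and gridded exactly
    once, so an m-sample screen costs m LOF/grid passes plus m(m-1)/2
    sparse-map comparisons.

    Parameters
    ----------
    n : grid resolution, intervals per marker axis (assay-specific; typical
        published choices are 3-5).
    lof_k, lof_threshold : LOF denoising parameters (``lof_k=0`` disables
        denoising).
    workers : parallel jobs for the comparison stage; the result is
        identical for any worker count.
    seed : seed for the LOF subsample draw on very large wells.

    Attributes
    ----------
    sample_ids_ : tuple of sample identifiers.
    similarity_ : the fitted :class:`SimilarityMatrix`.
    n_comparisons_ : number of unordered pairs actually compared.
    """

    def __init__(self, n: int = 5, lof_k: int = 30, lof_threshold: float = 1.5,
                 workers: int = 1, seed: int = 0):
        self.n = n
        self.lof_k = lof_k
        self.lof_threshold = lof_threshold
        self.workers = workers
        self.seed = seed

    def _lof_params(self) -> LofParams | None:
        if self.lof_k <= 0:
            return None
        return LofParams(k=self.lof_k, threshold=self.lof_threshold,
                         seed=self.seed)

    def fit(self, X, y=None, sample_ids: list[str] | None = None):
        """Compute the pairwise similarity matrix.

        ``X`` may be a Screen, a list of EventTables, or a dict mapping
        sample id to EventTable.
        """
        if isinstance(X, Screen):
            tables = {w.sample_id: w.events for w in X.wells
                      if w.events is not None}
        elif isinstance(X, dict):
            tables = dict(X)
        else:
            ids = sample_ids or [f"S{i + 1}" for i in range(len(X))]
            tables = dict(zip(ids, X))
        if len(tables) < 2:
            raise ValidationError("need at least 2 samples")
        ids = tuple(tables)
        shared = None
        for t in tables.values():
            cols = set(t.channel_names)
            shared = cols if shared is None else shared & cols
        if not shared:
            raise ChannelError("no channel shared by all samples")
        first = next(iter(tables.values()))
        order = tuple(c for c in first.channel_names if c in shared)

        lof = self._lof_params()
        jobs = Parallel(n_jobs=max(1, self.workers))
        maps = jobs(delayed(_prepare)(tables[i].select_channels(order),
                                      self.n, lof) for i in ids)
        maps = dict(zip(ids, maps))

        m = len(ids)
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
        vals = jobs(delayed(compare)(maps[ids[i]], maps[ids[j]])
                    for i, j in pairs)
        S = np.full((m, m), 100.0)
        for (i, j), v in zip(pairs, vals):
            S[i, j] = S[j, i] = v
        self.sample_ids_ = ids
        self.similarity_ = SimilarityMatrix(ids, S)
        self.n_comparisons_ = len(pairs)
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted similarity matrix values."""
        if not hasattr(self, "similarity_"):
            raise ValidationError("GridSimilarity is not fitted")
        return self.similarity_.values


def similarity_matrix(screen: Screen, n: int = 5,
                      lof_params: LofParams | None = LofParams(),
                      workers: int = 1) -> SimilarityMatrix:
    """Full pairwise similarity matrix of a screen (thin estimator wrapper)."""
    lof = lof_params or LofParams(k=0)
    est = GridSimilarity(n=n,
                         lof_k=(lof_params.k if lof_params else 0),
                         lof_threshold=(lof_params.threshold if lof_params else 0),
                         workers=workers,
                         seed=(lof_params.seed if lof_params else 0))
    return est.fit(screen).similarity_
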