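"""Plate-level quality control.

Before any correction, per-well summary statistics (channel medians or live
event counts) are laid out on the plate and screened for acquisition
artifacts: a linear trend along read order (signal or viability drift) and
systematic differences between border and interior wells (edge effect).
Heatmap colors are rank-normalized so small but consistent differences are
not washed out by a few extreme wells.  After similarity computation,
negative controls that disagree with the other controls are dropped before
the clustering cutoff is inferred from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChannelError, Screen, ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "PlateSummary",
    "plate_summary",
    "rank_normalized_palette",
    "detect_drift",
    "detect_edge_effect",
    "remove_control_outliers",
    "DriftResult",
    "EdgeEffectResult",
]


@dataclass(frozen=True)
class PlateSummary:
    """One statistic per well of one plate."""

    plate_id: str
    statistic_name: str
    table: pd.DataFrame  # columns: well_id, read_order, row, col, value

    def __post_init__(self) -> None:
        required = {"well_id", "read_order", "row", "col", "value"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"summary table needs columns {sorted(required)}")


@dataclass(frozen=True)
class DriftResult:
    slope: float
    intercept: float
    p_value: float
    flagged: bool


@dataclass(frozen=True)
class EdgeEffectResult:
    statistic: float
    p_value: float
    flagged: bool


def plate_summary(screen: Screen, plate_id: str,
                  statistic: str = "event_count") -> PlateSummary:
    """Per-well statistic table for one plate.

    ``statistic`` is ``"event_count"`` (live events per well) or
    ``"median:<channel>"`` (that channel's median over all retained events).
    """
    wells = screen.plate_wells(plate_id)
    rows = []
    for w in wells:
        if statistic == "event_count":
            value = w.get_live_count()
        elif statistic.startswith("median:"):
            channel = statistic.split(":", 1)[1]
            if w.events is None:
                raise ValidationError(f"well {w.sample_id} has no events")
            value = float(np.median(w.events.channel(channel)))
        else:
            raise ChannelError(f"unknown statistic {statistic!r}")
        rows.append({"well_id": w.well_id, "read_order": w.read_order,
                     "row": w.row, "col": w.col, "value": value})
    table = pd.DataFrame(rows).sort_values("read_order", ignore_index=True)
    return PlateSummary(plate_id, statistic, table)


def rank_normalized_palette(summary: PlateSummary) -> pd.DataFrame:
    """Color positions in [0, 1] from the empirical CDF of the statistic.

    Position = rank / n_wells with mid-ranks for ties, so the palette is
    stretched by the *distribution* of the well statistics and is invariant
    under any strictly increasing transform of them.
    """
    t = summary.table
    if len(t) < 2:
        raise ValidationError("need at least 2 wells")
    ranks = stats.rankdata(t["value"].to_numpy(), method="average")
    return pd.DataFrame({"well_id": t["well_id"],
                         "color_position": ranks / len(t)})


def detect_drift(summary: PlateSummary, alpha: float = 0.01) -> DriftResult:
    """OLS of the well statistic on read order; flags a linear drift.

    Flagged when the two-sided p-value of the slope falls below ``alpha``
    (default 0.01).
    """
    t = summary.table
    x = t["read_order"].to_numpy(dtype=float)
    y = t["value"].to_numpy(dtype=float)
    if len(t) < 3 or np.unique(x).size < 2:
        raise ValidationError("need >= 3 wells with distinct read orders")
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if np.isnan(p):  # exact line: zero residual variance
        p = 0.0 if res.slope != 0 else 1.0
    return DriftResult(slope=float(res.slope), intercept=float(res.intercept),
                       p_value=p, flagged=bool(p < alpha))


def detect_edge_effect(summary: PlateSummary,
                       plate_shape: tuple[int, int] | None = None,
                       alpha: float = 0.01) -> EdgeEffectResult:
    """Two-sided Wilcoxon rank-sum of edge-well vs interior-well statistics.

    Edge wells sit on the border of the plate grid (inferred from the
    max row/col present unless ``plate_shape`` is given).
    """
    t = summary.table
    if plate_shape is None:
        n_rows, n_cols = int(t["row"].max()), int(t["col"].max())
    else:
        n_rows, n_cols = plate_shape
    edge_mask = ((t["row"] == 1) | (t["col"] == 1) |
                 (t["row"] == n_rows) | (t["col"] == n_cols)).to_numpy()
    edge = t.loc[edge_mask, "value"].to_numpy(dtype=float)
    interior = t.loc[~edge_mask, "value"].to_numpy(dtype=float)
    if len(edge) < 3 or len(interior) < 3:
        raise ValidationError("need >= 3 wells in both edge and interior groups")
    res = stats.mannwhitneyu(edge, interior, alternative="two-sided")
    return EdgeEffectResult(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            flagged=bool(res.pvalue < alpha))


def remove_control_outliers(sim: SimilarityMatrix,
                            controls: list[str]) -> list[str]:
    """Drop negative controls that disagree with the other controls.

    Each control is scored by its median similarity to the other controls;
    a control is an outlier when its score falls below the lower Tukey
    fence Q1 - 1.5*IQR of those scores.  The rule is applied once (no
    iteration) and never removes more than half of the controls (worst
    offenders go first), so enough controls remain to infer the clustering
    cutoff.
    """
    if len(controls) < 3:
        raise ValidationError("need at least 3 controls")
    sub = sim.submatrix(list(controls)).values
    m = len(controls)
    med = np.array([np.median(np.delete(sub[i], i)) for i in range(m)])
    q1, q3 = np.percentile(med, [25, 75])
    cut = q1 - 1.5 * (q3 - q1)
    outliers = np.flatnonzero(med < cut)
    max_removals = m // 2
    if outliers.size > max_removals:
        order = np.argsort(med[outliers])  # lowest medians removed first
        outliers = outliers[order[:max_removals]]
    drop = set(outliers.tolist())
    return [c for i, c in enumerate(controls) if i not in drop]
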