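"""One-command pipeline: QC -> correction -> similarity -> clustering -> viz.

``run_pipeline`` chains the stages over a screen directory, driven by a
single serializable :class:`RunConfig`; all randomness (LOF subsampling,
embedding, community tie-breaks) flows from its one root seed.  Every stage
failure is re-raised with the stage name so a run log always names the
culprit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .core import GridscreenError, Screen
from .correct import DriftCorrector
from .cluster import CliqueClusterer, clique_centroids
from .io import read_screen
from .qc import detect_drift, plate_summary, remove_control_outliers
from .similarity import GridSimilarity
from .viz import band_transform, dispersion_graph, dispersion_map

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(GridscreenError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    screen_dir: str
    out_dir: str
    n: int = 5
    channels: list[str] | None = None
    lof_k: int = 30
    lof_threshold: float = 1.5
    drift_alpha: float = 0.01
    cutoff_override: float | None = None
    skip_qc: bool = False
    skip_correction: bool = False
    seed: int = 0
    workers: int = 1
    band_k: float = 5.0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Outputs: ``qc_report.csv``, ``correction_model.json``,
    ``similarity.csv``, ``cliques.csv``, ``communities.csv``,
    ``sample_graph.graphml``, ``band_matrix.csv``,
    ``dispersion_tree.graphml``, ``dispersion_map.csv`` (when >= 2
    cliques), and ``run_log.json`` recording versions, seeds, the inferred
    cutoff and stage timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": __version__, "seed": config.seed,
                 "config": asdict(config), "timings_s": {}}
    t0 = time.perf_counter()

    screen_dir = Path(config.screen_dir)
    if not (screen_dir / "plate_map.csv").exists():
        raise StageError(f"stage 'io' failed: no plate map in {screen_dir}")
    with _stage("io"):
        screen = read_screen(screen_dir, channel_filter=config.channels)
        channels = list(config.channels or screen.shared_channels())
    log["timings_s"]["io"] = round(time.perf_counter() - t0, 3)

    # ---- QC: per-plate drift report ---------------------------------------
    t0 = time.perf_counter()
    if not config.skip_qc:
        with _stage("qc"):
            rows = []
            for plate in screen.plates:
                stats = [f"median:{c}" for c in channels] + ["event_count"]
                for stat in stats:
                    summ = plate_summary(screen, plate, stat)
                    if len(summ.table) >= 3:
                        dr = detect_drift(summ, alpha=config.drift_alpha)
                        rows.append({"plate_id": plate, "statistic": stat,
                                     "slope": dr.slope, "p_value": dr.p_value,
                                     "flagged": dr.flagged})
            pd.DataFrame(rows).to_csv(out / "qc_report.csv", index=False)
    log["timings_s"]["qc"] = round(time.perf_counter() - t0, 3)

    # ---- correction -------------------------------------------------------
    t0 = time.perf_counter()
    if not config.skip_correction:
        with _stage("correct"):
            corrector = DriftCorrector(channels=channels)
            screen = corrector.fit_transform(screen)
            with open(out / "correction_model.json", "w") as fh:
                json.dump(corrector.model_.to_dict(), fh, indent=2)
    log["timings_s"]["correct"] = round(time.perf_counter() - t0, 3)

    # ---- similarity -------------------------------------------------------
    t0 = time.perf_counter()
    with _stage("similarity"):
        est = GridSimilarity(n=config.n, lof_k=config.lof_k,
                             lof_threshold=config.lof_threshold,
                             workers=config.workers, seed=config.seed)
        est.fit(screen)
        sim = est.similarity_
        sim.to_dataframe().to_csv(out / "similarity.csv")
    log["timings_s"]["similarity"] = round(time.perf_counter() - t0, 3)
    log["n_comparisons"] = est.n_comparisons_

    # ---- clustering -------------------------------------------------------
    t0 = time.perf_counter()
    with _stage("cluster"):
        controls = [c for c in screen.control_ids if c in sim.sample_ids]
        if not config.skip_qc and len(controls) >= 3:
            controls = remove_control_outliers(sim, controls)
        log["retained_controls"] = controls
        clusterer = CliqueClusterer(cutoff=config.cutoff_override,
                                    seed=config.seed)
        clusterer.fit(sim, controls=controls)
        log["cutoff"] = clusterer.cutoff_

        well_by_id = {w.sample_id: w for w in screen.wells}
        clique_rows = []
        for i, clique in enumerate(clusterer.cliques_, start=1):
            for s in clique:
                w = well_by_id[s]
                clique_rows.append({"clique_id": f"C{i}", "sample_id": s,
                                    "drug": w.drug,
                                    "concentration": w.concentration})
        pd.DataFrame(clique_rows,
                     columns=["clique_id", "sample_id", "drug",
                              "concentration"]).to_csv(
            out / "cliques.csv", index=False)
        pd.DataFrame(
            [{"sample_id": s, "community": c, "label": clusterer.labels_[s]}
             for s, c in clusterer.communities_.items()]).to_csv(
            out / "communities.csv", index=False)
        nx.write_graphml(clusterer.graph_.graph, out / "sample_graph.graphml")
    log["timings_s"]["cluster"] = round(time.perf_counter() - t0, 3)

    # ---- visualization products -------------------------------------------
    t0 = time.perf_counter()
    with _stage("viz"):
        band_transform(sim, k=config.band_k).to_csv(out / "band_matrix.csv")
        nx.write_graphml(dispersion_graph(sim), out / "dispersion_tree.graphml")
        if len(clusterer.cliques_) >= 2:
            cents = clique_centroids(clusterer.cliques_, screen, channels)
            dispersion_map(cents, seed=config.seed).to_csv(
                out / "dispersion_map.csv")
    log["timings_s"]["viz"] = round(time.perf_counter() - t0, 3)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out
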