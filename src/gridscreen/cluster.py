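"""Graph-based clustering of samples into response groups.

The similarity matrix defines a complete weighted graph over samples.  A
pruning cutoff is inferred from the negative controls alone: it is the
minimum edge weight of the maximum spanning tree over the control nodes —
the weakest link that still keeps all controls mutually connected.  Edges
below the cutoff are removed (edges exactly at the cutoff are retained, so
the controls stay connected).  Samples still connected by some path to a
control are *inactive*; disconnected samples are *active* agents, and
clustering them is maximal-clique enumeration on the pruned graph.  Looser
groups are reported as random-walk (walktrap) communities; a clique's
members always sit inside one community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .core import Screen, ValidationError
from .similarity import SimilarityMatrix

__all__ = [
    "SampleGraph",
    "CliqueSet",
    "infer_cutoff",
    "build_graph",
    "prune",
    "split_active",
    "find_cliques",
    "find_communities",
    "clique_centroids",
    "CliqueClusterer",
]

MAX_ACTIVE_NODES = 5000  # clique enumeration refuses beyond this


@dataclass
class SampleGraph:
    """Weighted graph over samples with role labels and a pruning state."""

    graph: nx.Graph
    roles: dict[str, str]            # sample id -> role
    cutoff: float | None = None
    pruned: bool = False

    @property
    def controls(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == "negative_control"]


@dataclass
class CliqueSet:
    """Maximal cliques, communities and activity labels of a pruned graph."""

    cliques: list[tuple[str, ...]]
    communities: dict[str, int]
    labels: dict[str, str]           # sample id -> "active" | "inactive"
    centroids: "object | None" = None  # pandas DataFrame when computed


def build_graph(sim: SimilarityMatrix,
                roles: dict[str, str] | None = None) -> SampleGraph:
    """Complete weighted graph whose edge weights are pairwise similarities."""
    g = nx.Graph()
    ids = sim.sample_ids
    g.add_nodes_from(ids)
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            g.add_edge(ids[i], ids[j], weight=float(sim.values[i, j]))
    roles = roles or {s: "treatment" for s in ids}
    return SampleGraph(graph=g, roles=dict(roles))


def infer_cutoff(sim: SimilarityMatrix, controls: list[str]) -> float:
    """Pruning cutoff: minimum edge weight of the controls' maximum spanning tree.

    The maximum spanning tree over the (retained) negative controls is the
    strongest set of links keeping them all connected; its weakest edge is
    the lowest similarity still consistent with "same as untreated", hence
    the threshold below which edges are treated as false positives.
    """
    if len(controls) < 2:
        raise ValidationError("need >= 2 controls to infer a cutoff")
    g = nx.Graph()
    for i, a in enumerate(controls):
        for b in controls[i + 1:]:
            g.add_edge(a, b, weight=sim.between(a, b))
    mst = nx.maximum_spanning_tree(g, weight="weight")
    return float(min(d["weight"] for _, _, d in mst.edges(data=True)))


def prune(sg: SampleGraph, cutoff: float) -> SampleGraph:
    """Remove edges below the cutoff; edges exactly at the cutoff survive."""
    g = sg.graph.copy()
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["weight"] < cutoff]
    g.remove_edges_from(drop)
    return SampleGraph(graph=g, roles=dict(sg.roles), cutoff=cutoff,
                       pruned=True)


def split_active(sg: SampleGraph) -> dict[str, str]:
    """Label samples: inactive iff a path connects them to any negative control."""
    if not sg.pruned:
        raise ValidationError("split_active expects a pruned graph")
    controls = sg.controls
    if not controls:
        raise ValidationError("no negative controls in graph")
    reachable: set[str] = set()
    for c in controls:
        if c in sg.graph:
            reachable |= nx.node_connected_component(sg.graph, c)
    return {s: ("inactive" if s in reachable else "active")
            for s in sg.graph.nodes}


def find_cliques(sg: SampleGraph,
                 labels: dict[str, str] | None = None) -> list[tuple[str, ...]]:
    """All maximal cliques among active nodes (singletons included).

    Uses pivoting Bron-Kerbosch; output is sorted lexicographically by
    sorted member ids for determinism.  Clique counts can explode, so more
    than 5000 active nodes is an error.
    """
    if not sg.pruned:
        raise ValidationError("find_cliques expects a pruned graph")
    labels = labels if labels is not None else split_active(sg)
    active = [s for s in sg.graph.nodes if labels.get(s) == "active"]
    if len(active) > MAX_ACTIVE_NODES:
        raise ValidationError(f"more than {MAX_ACTIVE_NODES} active nodes")
    sub = sg.graph.subgraph(active)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(sub)] if active else []
    return sorted(cliques)


def find_communities(sg: SampleGraph, walk_length: int = 4,
                     seed: int = 0) -> dict[str, int]:
    """Random-walk (walktrap) communities of the weighted pruned graph.

    Walktrap agglomerates nodes by short random-walk (length 4) proximity;
    isolated nodes get their own community.  Community ids are renumbered
    in first-member order for determinism.
    """
    if not sg.pruned:
        raise ValidationError("find_communities expects a pruned graph")
    nodes = list(sg.graph.nodes)
    if not nodes:
        return {}
    index = {s: i for i, s in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in sg.graph.edges]
    weights = [float(sg.graph[u][v]["weight"]) for u, v in sg.graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    if edges:
        dendro = g.community_walktrap(weights=weights, steps=walk_length)
        membership = dendro.as_clustering().membership
    else:
        membership = list(range(len(nodes)))
    # renumber by order of first appearance
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for s in nodes:
        c = membership[index[s]]
        if c not in remap:
            remap[c] = len(remap)
        out[s] = remap[c]
    return out


def cliques_within_communities(cliques: list[tuple[str, ...]],
                               communities: dict[str, int]) -> bool:
    """True iff every clique's members share one community."""
    return all(len({communities[m] for m in c}) == 1 for c in cliques)


def clique_centroids(cliques: list[tuple[str, ...]], screen: Screen,
                     channels: list[str] | None = None):
    """Per-clique centroid: the median over member wells of each statistic.

    Statistics are each channel's per-well median plus the live count.
    Returns a DataFrame indexed by clique id ``C1..Ck``.
    """
    import pandas as pd

    channels = list(channels) if channels is not None \
        else list(screen.shared_channels())
    rows = []
    for i, clique in enumerate(cliques, start=1):
        members = [screen.well(s) for s in clique]
        rec: dict[str, object] = {"clique_id": f"C{i}",
                                  "size": len(members),
                                  "members": ";".join(clique)}
        for ch in channels:
            med = [float(np.median(w.events.channel(ch))) for w in members]
            rec[f"median_{ch}"] = float(np.median(med))
        rec["live_count"] = float(np.median([w.get_live_count()
                                             for w in members]))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("clique_id")


class CliqueClusterer(BaseEstimator):
    """Response-group clustering of a similarity matrix.

    scikit-learn-style estimator: ``fit`` takes a :class:`SimilarityMatrix`
    plus the control sample ids, infers the pruning cutoff from the
    controls' maximum spanning tree (unless ``cutoff`` overrides it),
    prunes, splits active from inactive samples, and enumerates maximal
    cliques and walktrap communities.

    Attributes
    ----------
    cutoff_ : inferred (or overridden) pruning cutoff.
    graph_ : the pruned :class:`SampleGraph`.
    labels_ : dict sample id -> "active" / "inactive".
    cliques_ : sorted maximal cliques over active samples.
    communities_ : dict sample id -> community index.
    """

    def __init__(self, cutoff: float | None = None, walk_length: int = 4,
                 seed: int = 0):
        self.cutoff = cutoff
        self.walk_length = walk_length
        self.seed = seed

    def fit(self, X: SimilarityMatrix, y=None,
            controls: list[str] | None = None):
        controls = list(controls or [])
        roles = {s: ("negative_control" if s in controls else "treatment")
                 for s in X.sample_ids}
        if self.cutoff is not None:
            cutoff = float(self.cutoff)
        else:
            cutoff = infer_cutoff(X, controls)
        sg = prune(build_graph(X, roles), cutoff)
        self.cutoff_ = cutoff
        self.graph_ = sg
        self.labels_ = split_active(sg) if controls else \
            {s: "active" for s in sg.graph.nodes}
        self.cliques_ = find_cliques(sg, self.labels_)
        self.communities_ = find_communities(sg, walk_length=self.walk_length,
                                             seed=self.seed)
        return self

    def predict(self, sample_ids: list[str] | None = None) -> list[str]:
        """Activity labels ("active"/"inactive") for the fitted samples."""
        if not hasattr(self, "labels_"):
            raise ValidationError("CliqueClusterer is not fitted")
        ids = sample_ids or list(self.labels_)
        return [self.labels_[s] for s in ids]

    def result(self, screen: Screen | None = None,
               channels: list[str] | None = None) -> CliqueSet:
        cents = None
        if screen is not None and self.cliques_:
            cents = clique_centroids(self.cliques_, screen, channels)
        return CliqueSet(cliques=self.cliques_, communities=self.communities_,
                         labels=self.labels_, centroids=cents)
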