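"""Visualization data products.

Three read-outs of a screen analysis are produced as plain tables/graphs so
any plotting front end can render them: (i) the *similarity band matrix* —
each sample's row of similarities rescaled to [0, 1] and passed through an
exponential transform that stretches the extremes, (ii) the *dispersion
graph* — the maximum spanning tree of the full similarity graph, and (iii)
the *dispersion map* — a seeded 2-D UMAP embedding of clique centroids,
with the raw centroid statistics attached for coloring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .core import ValidationError
from .similarity import SimilarityMatrix

__all__ = ["band_transform", "dispersion_graph", "dispersion_map"]


def band_transform(sim: SimilarityMatrix, k: float = 5.0) -> pd.DataFrame:
    """Row-wise exponential band transform of a similarity matrix.

    Each row (band) is independently rescaled to [0, 1] by its own
    off-diagonal min/max, then mapped through f(x) = (e^(kx) - 1)/(e^k - 1)
    — strictly increasing, so within-row ranking is preserved exactly while
    the highest and lowest similarities are emphasized.  A constant row maps
    to 0.5 everywhere by convention.  As k -> 0, f approaches the identity.
    """
    if k <= 0:
        raise ValidationError("k must be > 0")
    m = len(sim.sample_ids)
    out = np.full((m, m), np.nan)
    denom = np.expm1(k)
    for i in range(m):
        row = np.delete(sim.values[i], i)
        lo, hi = row.min(), row.max()
        for j in range(m):
            if j == i:
                continue
            x = 0.5 if hi == lo else (sim.values[i, j] - lo) / (hi - lo)
            out[i, j] = np.expm1(k * x) / denom if hi != lo else 0.5
    return pd.DataFrame(out, index=list(sim.sample_ids),
                        columns=list(sim.sample_ids))


def dispersion_graph(sim: SimilarityMatrix) -> nx.Graph:
    """Maximum spanning tree of the complete similarity graph.

    The tree keeps, for every sample, its strongest links, giving a compact
    picture of how samples disperse.  Ties are broken deterministically by
    lexicographic edge ids.
    """
    ids = sim.sample_ids
    if len(ids) < 2:
        raise ValidationError("need >= 2 samples")
    g = nx.Graph()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            g.add_edge(a, b, weight=float(sim.between(a, b)))
    # negate weights and use Kruskal with a deterministic secondary sort
    edges = sorted(g.edges(data=True),
                   key=lambda e: (-e[2]["weight"], e[0], e[1]))
    tree = nx.Graph()
    tree.add_nodes_from(ids)
    uf = {s: s for s in ids}

    def find(s):
        while uf[s] != s:
            uf[s] = uf[uf[s]]
            s = uf[s]
        return s

    for u, v, d in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            uf[ru] = rv
            tree.add_edge(u, v, weight=d["weight"])
    return tree


def dispersion_map(centroids: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of clique centroids.

    Numeric centroid statistics are z-scored per column (constant columns
    dropped) before embedding; the raw statistics are attached to the
    output for coloring.  Neighborhood size is scaled down for small clique
    counts.
    """
    numeric = centroids.select_dtypes(include=[np.number]).drop(
        columns=["size"], errors="ignore")
    if len(numeric) < 2:
        raise ValidationError("need >= 2 cliques to embed")
    X = numeric.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if Xz.shape[1] == 0:
        Xz = np.zeros((len(numeric), 1))

    if len(numeric) < 4:
        # neighborhood embeddings degenerate below ~4 points; principal
        # components give deterministic coordinates with the same intent
        from sklearn.decomposition import PCA

        k = min(2, Xz.shape[1])
        coords = np.zeros((len(numeric), 2))
        coords[:, :k] = PCA(n_components=k, random_state=seed).fit_transform(Xz)
    else:
        import umap  # deferred: numba compilation is slow at import

        n_neighbors = min(15, len(numeric) - 1)
        reducer = umap.UMAP(n_components=2, n_neighbors=max(2, n_neighbors),
                            random_state=seed)
        coords = reducer.fit_transform(Xz)
    out = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]},
                       index=centroids.index)
    return out.join(numeric)
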