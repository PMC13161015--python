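"""Species co-occurrence networks and species-level centrality metrics.

Each locality's flock × species matrix is projected to a unipartite weighted
graph whose nodes are species and whose edge weight w(i, j) counts the flocks
containing both i and j.  Three species-level metrics quantify a species'
"nuclearity" (its structural importance in the flock system):

* **connectivity** — normalized degree: the fraction of the other species in
  the locality network the focal species co-occurs with at least once,
  degree/(S−1).
* **strength** — the sum of the focal species' edge weights, i.e. the total
  frequency of its interspecific associations.
* **weighted closeness** — closeness centrality on shortest paths computed
  with edge lengths 1/w, so stronger associations are shorter distances.
  On disconnected graphs the Wasserman–Faust component scaling is used:
  ``(R/(S−1)) · (R/Σ d)`` where R is the number of reachable nodes, which
  gives peripheral components low but finite values and keeps the metric
  comparable across localities.

Metrics are computed per locality and then averaged (unweighted arithmetic
mean) across the localities where each species occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .flock_data import FlockMatrix

__all__ = [
    "CooccurrenceNetwork",
    "project_unipartite",
    "connectivity",
    "strength",
    "weighted_closeness",
    "metrics_from_weights",
    "locality_metrics",
    "average_metrics",
    "pooled_network",
]

METRICS = ("connectivity", "strength", "closeness")


@dataclass
class CooccurrenceNetwork:
    """Symmetric weighted species × species co-occurrence graph for one locality."""

    locality_id: str
    species_ids: list[str] = field(repr=False)
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        S = len(self.species_ids)
        if self.W.shape != (S, S):
            raise ValueError("weight matrix shape does not match species list")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.diagonal(self.W).any():
            raise ValueError("weight matrix must have zero diagonal")
        if (self.W < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle edges as (species_a, species_b, weight) rows."""
        i, j = np.nonzero(np.triu(self.W, k=1))
        return pd.DataFrame(
            {
                "species_a": [self.species_ids[a] for a in i],
                "species_b": [self.species_ids[b] for b in j],
                "weight": self.W[i, j],
            }
        )


def project_unipartite(m: FlockMatrix) -> CooccurrenceNetwork:
    """Project a flock × species matrix to its species co-occurrence graph.

    ``W[i, j]`` is the number of flocks in which species i and j were
    recorded together; the diagonal is zeroed.
    """
    if m.n_species < 2:
        raise ValueError(
            f"locality {m.locality_id!r}: cannot project a single-species matrix"
        )
    occ = m.occ.astype(np.int64)
    W = occ.T @ occ
    np.fill_diagonal(W, 0)
    return CooccurrenceNetwork(m.locality_id, list(m.species_ids), W)


def _closeness_from_weights(W: np.ndarray) -> np.ndarray:
    """Wasserman–Faust weighted closeness for every node, from a weight matrix."""
    S = W.shape[0]
    lengths = np.zeros_like(W, dtype=float)
    nz = W > 0
    lengths[nz] = 1.0 / W[nz]
    D = shortest_path(csr_matrix(lengths), method="D", directed=False)
    finite = np.isfinite(D)
    np.fill_diagonal(finite, False)
    R = finite.sum(axis=1)  # reachable nodes, self excluded
    tot = np.where(finite, D, 0.0).sum(axis=1)
    out = np.zeros(S)
    ok = (R > 0) & (tot > 0)
    out[ok] = (R[ok] / (S - 1)) * (R[ok] / tot[ok])
    return out


def metrics_from_weights(W: np.ndarray) -> dict[str, np.ndarray]:
    """All three species-level metrics from a weight matrix (vectorized).

    Used both by the public per-locality API and by the null-model loop,
    where it is called tens of thousands of times.
    """
    S = W.shape[0]
    if S < 2:
        raise ValueError("metrics undefined for a single-species network")
    deg = (W > 0).sum(axis=1)
    return {
        "connectivity": deg / (S - 1),
        "strength": W.sum(axis=1).astype(float),
        "closeness": _closeness_from_weights(W),
    }


def connectivity(net: CooccurrenceNetwork, sp: str | None = None):
    """Normalized degree: fraction of possible partners with w > 0."""
    vals = pd.Series(
        metrics_from_weights(net.W)["connectivity"], index=net.species_ids
    )
    return vals if sp is None else float(vals[sp])


def strength(net: CooccurrenceNetwork, sp: str | None = None):
    """Sum of a species' co-occurrence edge weights."""
    vals = pd.Series(net.W.sum(axis=1).astype(float), index=net.species_ids)
    return vals if sp is None else float(vals[sp])


def weighted_closeness(net: CooccurrenceNetwork, sp: str | None = None):
    """Closeness centrality on 1/w edge lengths with Wasserman–Faust scaling."""
    vals = pd.Series(_closeness_from_weights(net.W), index=net.species_ids)
    return vals if sp is None else float(vals[sp])


def locality_metrics(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Tidy per-species metric table for one locality network."""
    mets = metrics_from_weights(net.W)
    return pd.DataFrame(
        {
            "species_id": net.species_ids,
            "locality_id": net.locality_id,
            "connectivity": mets["connectivity"],
            "strength": mets["strength"],
            "closeness": mets["closeness"],
        }
    )


def average_metrics(tables: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Average per-locality metrics over the localities where each species occurs.

    Returns one row per species with ``locality_id == "MEAN"`` and the number
    of contributing localities in ``n_localities``.  The mean is unweighted.
    """
    df = pd.concat(tables, ignore_index=True) if isinstance(tables, list) else tables
    grouped = df.groupby("species_id")[list(METRICS)].mean()
    grouped["n_localities"] = df.groupby("species_id")["locality_id"].nunique()
    grouped = grouped.reset_index()
    grouped.insert(1, "locality_id", "MEAN")
    return grouped


def pooled_network(ms: list[FlockMatrix]) -> CooccurrenceNetwork:
    """Single metanetwork pooling all localities' flocks (optional variant).

    Species sets are unioned; weights count co-occurrences over every flock
    in the dataset.
    """
    species = sorted({sp for m in ms for sp in m.species_ids})
    idx = {sp: k for k, sp in enumerate(species)}
    W = np.zeros((len(species), len(species)), dtype=np.int64)
    for m in ms:
        cols = [idx[sp] for sp in m.species_ids]
        occ = m.occ.astype(np.int64)
        sub = occ.T @ occ
        W[np.ix_(cols, cols)] += sub
    np.fill_diagonal(W, 0)
    return CooccurrenceNetwork("POOLED", species, W)
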