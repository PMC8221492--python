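"""Weighted social networks, Louvain communities, and structural stability.

Networks carry one node per qualifying individual and one weighted edge per
non-zero association (SRI) or positive affiliation (GAI; negatives zeroed).
Community structure is found by Louvain modularity maximization with a fixed
resolution and seed-controlled restarts; its significance is judged against
data-stream permutations (swap-randomized group compositions, rebuilt
networks, re-detected communities). A running multi-year window tracks
whether modularity, community count, and the concentration of the population
in the largest communities drift outside their null envelopes over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._core import PermutationResult, as_rng, empirical_p
from .associations import DatastreamPermuter, DyadStats, sri_matrix
from .sightings import restrict_history

__all__ = [
    "CommunityPartition",
    "build_network",
    "detect_communities",
    "structure_null",
    "running_window",
]


@dataclass
class CommunityPartition:
    """Node -> community labels with the partition's weighted modularity."""

    labels: dict
    modularity: float

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="community")

    def sizes(self) -> np.ndarray:
        _, counts = np.unique(list(self.labels.values()), return_counts=True)
        return np.sort(counts)[::-1]


def build_network(dyads_or_ids, weights: np.ndarray | None = None,
                  zero_negative: bool = True) -> nx.Graph:
    """Weighted association network.

    Accepts a DyadStats (edges = non-zero SRI) or an id list plus a symmetric
    weight matrix (e.g. a GAI matrix; negative weights are zeroed when
    ``zero_negative``). All individuals appear as nodes, including isolates.
    """
    if isinstance(dyads_or_ids, DyadStats):
        ids = dyads_or_ids.ids
        w = np.nan_to_num(dyads_or_ids.sri, nan=0.0)
    else:
        ids = list(dyads_or_ids)
        w = np.nan_to_num(np.asarray(weights, dtype=float), nan=0.0)
    if zero_negative:
        w = np.where(w > 0, w, 0.0)
    g = nx.Graph()
    g.add_nodes_from(ids)
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        (ids[a], ids[b], float(w[a, b])) for a, b in zip(ii, jj)
    )
    return g


def detect_communities(
    g: nx.Graph,
    seed=None,
    n_restarts: int = 10,
    resolution: float = 1.0,
) -> CommunityPartition:
    """Louvain community detection, best of ``n_restarts`` by modularity.

    Deterministic given the seed; ties in modularity break toward the lower
    community count. Isolated nodes become singleton communities.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    rng = as_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        s = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=s
        )
        q = (
            nx.community.modularity(g, comms, weight="weight", resolution=resolution)
            if g.number_of_edges()
            else 0.0
        )
        key = (round(q, 12), -len(comms))
        if best is None or key > best[0]:
            best = (key, comms, q)
    labels = {}
    for ci, comm in enumerate(sorted(best[1], key=lambda c: (-len(c), sorted(map(str, c))))):
        for node in comm:
            labels[node] = ci
    return CommunityPartition(labels=labels, modularity=float(best[2]))


def structure_null(
    history,
    n_iter: int = 1000,
    min_sightings: int = 5,
    n_restarts: int = 10,
    rng=None,
) -> PermutationResult:
    """Data-stream null for modularity Q and community count K.

    Each iteration permutes group compositions within days, rebuilds the SRI
    network, and re-runs community detection. Q is tested one-tailed high
    (more structure than random association dynamics); K two-tailed.
    """
    rng = as_rng(rng)
    dyads = sri_matrix(history, min_sightings=min_sightings)
    obs_part = detect_communities(build_network(dyads), seed=rng, n_restarts=n_restarts)
    perm = DatastreamPermuter(history, min_sightings=min_sightings, rng=rng)
    d = np.maximum(dyads.d, 1)
    null_q = np.empty(n_iter)
    null_k = np.empty(n_iter)
    for it, x_perm in enumerate(perm.stream(n_iter)):
        w = np.where(dyads.d > 0, x_perm / d, 0.0)
        g = build_network(dyads.ids, w)
        part = detect_communities(g, seed=rng, n_restarts=n_restarts)
        null_q[it] = part.modularity
        null_k[it] = part.k
    return PermutationResult(
        statistic=obs_part.modularity,
        null=null_q,
        p_value=empirical_p(obs_part.modularity, null_q, "greater"),
        n_iter=n_iter,
        extras={
            "partition": obs_part,
            "k_observed": obs_part.k,
            "null_k": null_k,
            "p_k": empirical_p(obs_part.k, null_k, "two-sided"),
            "null_q_mean": float(null_q.mean()),
            "null_k_mean": float(null_k.mean()),
        },
    )


def running_window(
    history,
    window_years: int = 4,
    min_sightings: int = 5,
    n_iter: int = 100,
    n_top: int = 5,
    n_restarts: int = 10,
    rng=None,
) -> pd.DataFrame:
    """Community structure over a running multi-year window with null envelopes.

    For each window of ``window_years`` consecutive study years, the network
    is rebuilt from that window's records (individuals re-qualified on
    within-window sightings) and Q, K, and the fraction of the population in
    the ``n_top`` largest communities are computed, each with an independent
    within-window data-stream envelope (2.5/97.5 percentiles). Windows with
    no qualifying individuals yield a missing row.
    """
    rng = as_rng(rng)
    all_years = sorted(set(int(y) for y in history.years))
    if len(all_years) < window_years:
        raise ValueError("fewer study years than the window length")
    rows = []
    for start in range(len(all_years) - window_years + 1):
        yrs = all_years[start : start + window_years]
        row = {"start_year": yrs[0], "end_year": yrs[-1]}
        try:
            sub = restrict_history(history, years=yrs, min_sightings=min_sightings)
        except ValueError:
            sub = None
        if sub is None or sub.n_individuals < 2:
            warnings.warn(f"window {yrs[0]}-{yrs[-1]} has no qualifying individuals")
            rows.append(row)
            continue
        dyads = sri_matrix(sub, min_sightings=1)  # already qualified in restrict
        part = detect_communities(build_network(dyads), seed=rng, n_restarts=n_restarts)
        sizes = part.sizes()
        top = sizes[:n_top].sum() / sizes.sum()
        perm = DatastreamPermuter(sub, min_sightings=1, rng=rng)
        d = np.maximum(dyads.d, 1)
        nq, nk, ntop = (np.empty(n_iter) for _ in range(3))
        for it, x_perm in enumerate(perm.stream(n_iter)):
            w = np.where(dyads.d > 0, x_perm / d, 0.0)
            p = detect_communities(build_network(dyads.ids, w), seed=rng,
                                   n_restarts=n_restarts)
            nq[it] = p.modularity
            nk[it] = p.k
            s = p.sizes()
            ntop[it] = s[:n_top].sum() / s.sum()
        row.update(
            n_individuals=sub.n_individuals,
            q=part.modularity,
            k=part.k,
            top_fraction=float(top),
            q_lo=float(np.percentile(nq, 2.5)),
            q_hi=float(np.percentile(nq, 97.5)),
            k_lo=float(np.percentile(nk, 2.5)),
            k_hi=float(np.percentile(nk, 97.5)),
            top_lo=float(np.percentile(ntop, 2.5)),
            top_hi=float(np.percentile(ntop, 97.5)),
        )
        rows.append(row)
    return pd.DataFrame(rows)
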