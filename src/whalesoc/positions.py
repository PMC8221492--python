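"""Trait assortativity and network-position ~ trait tests on affiliation networks.

Assortativity coefficients (AC) measure whether connected individuals have
similar traits: the weighted Newman formulation — an edge-weighted
covariance of trait values at edge endpoints over the endpoint variance —
for continuous traits, and the weighted mixing-matrix formulation for
categorical ones. Run separately on the positive-GAI (affiliation) and
|negative-GAI| (avoidance) networks, with node-shuffle nulls. Position
metrics follow the generalized weighted scheme with tuning parameter alpha:
each edge contributes a path cost (1/w)^alpha, so alpha = 0 recovers binary
shortest paths and alpha = 1 the pure inverse-weight cost; betweenness at
alpha = 0.5 favors short paths of weak ties over long paths of strong ties.
Closeness is harmonic (unreachable pairs contribute zero), which handles the
disconnected components these networks typically have.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from ._core import PermutationResult, as_rng, empirical_p

__all__ = [
    "assortativity",
    "assortativity_null",
    "position_metrics",
    "position_trait_test",
]


def _edge_arrays(g: nx.Graph, trait: pd.Series):
    ii, jj, ww = [], [], []
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            continue
        ii.append(trait.loc[u])
        jj.append(trait.loc[v])
        ww.append(w)
    return np.array(ii), np.array(jj), np.array(ww)


def assortativity(g: nx.Graph, trait: pd.Series, kind: str = "continuous") -> float:
    """Weighted assortativity coefficient of a node trait.

    continuous: AC = (sum_e w x_i x_j / W - mu^2) / (sum_e w (x_i^2+x_j^2)/2W - mu^2)
    with mu the edge-weighted endpoint mean and W the total (ordered) edge
    weight; categorical: AC = (tr e - sum_g a_g b_g) / (1 - sum_g a_g b_g)
    on the weighted mixing matrix e. Positive when similar individuals
    connect. Constant traits are an error (the coefficient is undefined).
    """
    trait = pd.Series(trait)
    xi, xj, w = _edge_arrays(g, trait)
    if w.size < 2:
        raise ValueError("need at least 2 positively weighted edges")
    if kind == "continuous":
        x = np.concatenate([xi, xj]).astype(float)
        y = np.concatenate([xj, xi]).astype(float)
        ww = np.concatenate([w, w])
        W = ww.sum()
        mu = np.sum(ww * x) / W
        var = np.sum(ww * x**2) / W - mu**2
        if var <= 0:
            raise ValueError("trait is constant on the network; AC undefined")
        cov = np.sum(ww * x * y) / W - mu**2
        return float(cov / var)
    if kind == "categorical":
        cats, xi_c = np.unique(np.concatenate([xi, xj]), return_inverse=True)
        if cats.size < 2:
            raise ValueError("trait is constant on the network; AC undefined")
        k = cats.size
        half = xi.size
        e = np.zeros((k, k))
        for a, b, wt in zip(xi_c[:half], xi_c[half:], w):
            e[a, b] += wt
            e[b, a] += wt
        e /= e.sum()
        a_marg = e.sum(axis=1)
        b_marg = e.sum(axis=0)
        chance = float(np.sum(a_marg * b_marg))
        return float((np.trace(e) - chance) / (1.0 - chance))
    raise ValueError(f"unknown kind {kind!r}")


def assortativity_null(
    g: nx.Graph,
    trait: pd.Series,
    n_iter: int = 1000,
    kind: str = "continuous",
    rng=None,
) -> PermutationResult:
    """Node-shuffle null for an assortativity coefficient.

    Trait values are permuted over nodes (topology fixed, trait multiset
    preserved). Reported tails: ``p_high``/``p_low`` (one-sided), plus the
    avoidance-network readings ``p_more_extreme`` (|AC| beyond the null) and
    ``p_less_extreme`` (|AC| closer to zero than the null). The headline
    p-value is two-tailed.
    """
    rng = as_rng(rng)
    trait = pd.Series(trait)
    obs = assortativity(g, trait, kind)
    nodes = list(trait.index)
    vals = trait.to_numpy()
    pos = {n: i for i, n in enumerate(nodes)}
    e_i, e_j, e_w = [], [], []
    for u, v_, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w > 0:
            e_i.append(pos[u])
            e_j.append(pos[v_])
            e_w.append(w)
    e_i, e_j = np.array(e_i), np.array(e_j)
    ww = np.concatenate([e_w, e_w])
    W = ww.sum()
    null = np.empty(n_iter)
    for it in range(n_iter):
        sv = vals[rng.permutation(vals.size)]
        if kind == "continuous":
            x = np.concatenate([sv[e_i], sv[e_j]])
            y = np.concatenate([sv[e_j], sv[e_i]])
            mu = np.sum(ww * x) / W
            var = np.sum(ww * x**2) / W - mu**2
            null[it] = (np.sum(ww * x * y) / W - mu**2) / var
        else:
            shuffled = pd.Series(sv, index=nodes)
            null[it] = assortativity(g, shuffled, kind)
    return PermutationResult(
        statistic=float(obs),
        null=null,
        p_value=empirical_p(obs, null, "two-sided"),
        n_iter=n_iter,
        alternative="two-sided",
        extras={
            "p_high": empirical_p(obs, null, "greater"),
            "p_low": empirical_p(obs, null, "less"),
            "p_more_extreme": empirical_p(abs(obs), np.abs(null), "greater"),
            "p_less_extreme": empirical_p(abs(obs), np.abs(null), "less"),
        },
    )


def position_metrics(g: nx.Graph, alpha: float = 0.5) -> pd.DataFrame:
    """Individual network-position metrics on a non-negatively weighted network.

    weighted_degree: summed weight of all connections; contacts: edge count;
    betweenness: generalized weighted betweenness with edge cost (1/w)^alpha;
    closeness: harmonic closeness on the same generalized cost; clustering:
    local weighted clustering coefficient. Isolated nodes score zero
    throughout (clustering of degree-<2 nodes is defined as zero).
    """
    h = nx.Graph()
    h.add_nodes_from(g.nodes())
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w > 0:
            h.add_edge(u, v, weight=w, cost=(1.0 / w) ** alpha)
    degree = dict(h.degree(weight="weight"))
    contacts = dict(h.degree())
    betweenness = nx.betweenness_centrality(h, weight="cost", normalized=False)
    closeness = {}
    for node in h.nodes():
        dist = nx.single_source_dijkstra_path_length(h, node, weight="cost")
        closeness[node] = sum(1.0 / d for n2, d in dist.items() if n2 != node and d > 0)
    clustering = nx.clustering(h, weight="weight")
    return pd.DataFrame(
        {
            "weighted_degree": pd.Series(degree, dtype=float),
            "contacts": pd.Series(contacts, dtype=float),
            "betweenness": pd.Series(betweenness, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
            "clustering": pd.Series(clustering, dtype=float),
        }
    )


def position_trait_test(
    metrics: pd.DataFrame,
    trait: pd.Series,
    n_iter: int = 1000,
    rng=None,
) -> pd.DataFrame:
    """Node-permutation regression of each position metric on a trait.

    The statistic is the least-squares slope of metric ~ trait; the null
    shuffles the trait over individuals (the same permutations for every
    metric). ``p_greater`` is the add-one fraction of null slopes at least
    as large as observed: values below 0.025 mean the metric rises with the
    trait more strongly than chance, values above 0.975 mean more weakly
    (two-tailed at alpha = 0.05).
    """
    rng = as_rng(rng)
    trait = pd.Series(trait)
    common = metrics.index.intersection(trait.index)
    if len(common) < 10:
        raise ValueError("need at least 10 individuals")
    m = metrics.loc[common].to_numpy(dtype=float)
    t = trait.loc[common].to_numpy(dtype=float)
    if np.var(t) == 0:
        raise ValueError("trait has zero variance")

    def slopes(tv):
        tc = tv - tv.mean()
        return (tc @ (m - m.mean(axis=0))) / np.sum(tc**2)

    obs = slopes(t)
    null = np.empty((n_iter, m.shape[1]))
    for it in range(n_iter):
        null[it] = slopes(t[rng.permutation(t.size)])
    p_greater = (np.sum(null >= obs[None, :], axis=0) + 1) / (n_iter + 1)
    p_two = np.array(
        [empirical_p(obs[k], null[:, k], "two-sided") for k in range(m.shape[1])]
    )
    return pd.DataFrame(
        {"slope": obs, "p_greater": p_greater, "p_two_sided": p_two},
        index=metrics.columns,
    )
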