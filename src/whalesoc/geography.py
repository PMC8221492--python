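"""Fjord position on a navigable-water graph and binned behavior-rate tests.

Fjord position is the shortest swimming distance, in km, from a location to a
fixed inland reference point, measured along a graph of navigable waterways so
that routes go around islands rather than across them. The behavior-rate test
pools encounters into 10-km bins of fjord position and compares each bin's
behavior rate (or the bin mean of a numeric variable) to a null that permutes
the variable across encounters while holding bin occupancy fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._core import as_rng

__all__ = ["WaterwayGraph", "BinnedRates", "fjord_position", "behavior_rate_test"]

_EARTH_RADIUS_KM = 6371.0088


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class WaterwayGraph:
    """Connected graph of navigable waypoints with km edge lengths."""

    graph: nx.Graph
    coords: dict           # node -> (lat, lon)
    reference_node: object  # the inland-most point (fjord position zero)

    def __post_init__(self):
        if self.reference_node not in self.graph:
            raise ValueError("reference node missing from graph")
        if not nx.is_connected(self.graph):
            raise ValueError("waterway graph must be connected")
        for _, _, data in self.graph.edges(data=True):
            if data.get("length_km", 0) <= 0:
                raise ValueError("edge lengths must be positive")

    @classmethod
    def from_csv(cls, edges_path, nodes_path, reference_node) -> "WaterwayGraph":
        """Build from an edge list (node_a, node_b, length_km) and a node
        coordinate table (node, lat, lon)."""
        edges = pd.read_csv(edges_path)
        nodes = pd.read_csv(nodes_path)
        g = nx.Graph()
        for row in nodes.itertuples(index=False):
            g.add_node(row.node)
        for row in edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, length_km=float(row.length_km))
        coords = {row.node: (float(row.lat), float(row.lon)) for row in nodes.itertuples(index=False)}
        return cls(g, coords, reference_node)


def fjord_position(point, graph: WaterwayGraph, snap_tolerance_km: float = 5.0) -> float:
    """Shortest around-island distance (km) from a (lat, lon) point to the
    inland reference, after snapping the point to its nearest waypoint.

    Raises if the nearest waypoint is farther than ``snap_tolerance_km``,
    naming the offending distance.
    """
    lat, lon = point
    nodes = list(graph.coords)
    lats = np.array([graph.coords[n][0] for n in nodes])
    lons = np.array([graph.coords[n][1] for n in nodes])
    dists = _haversine_km(lat, lon, lats, lons)
    k = int(np.argmin(dists))
    if dists[k] > snap_tolerance_km:
        raise ValueError(
            f"point {point} is {dists[k]:.2f} km from the nearest waypoint "
            f"(tolerance {snap_tolerance_km} km)"
        )
    return float(
        nx.shortest_path_length(
            graph.graph, nodes[k], graph.reference_node, weight="length_km"
        )
    )


@dataclass
class BinnedRates:
    """Behavior rates (or variable means) by 10-km fjord-position bin."""

    bin_edges: np.ndarray
    n_encounters: np.ndarray
    observed: np.ndarray       # NaN in empty bins
    null_lo: np.ndarray
    null_med: np.ndarray
    null_hi: np.ndarray
    p_value: np.ndarray        # two-tailed per bin
    n_excluded: int            # encounters beyond the binned range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "n_encounters": self.n_encounters,
                "observed": self.observed,
                "null_lo": self.null_lo,
                "null_med": self.null_med,
                "null_hi": self.null_hi,
                "p_value": self.p_value,
            }
        )


def behavior_rate_test(
    encounters,
    variable,
    n_iter: int = 1000,
    bin_width: float = 10.0,
    max_km: float = 100.0,
    rng=None,
) -> BinnedRates:
    """Permutation test of a variable's geographic pattern along the fjord axis.

    ``variable`` is either a behavior code (bin statistic = proportion of
    encounters exhibiting it) or a callable mapping an encounter to a numeric
    value (bin statistic = mean). Bins are half-open [lo, hi) with the last
    bin closed at ``max_km``; encounters without a position or beyond the
    range are excluded and counted. The null permutes the variable across
    encounters, preserving bin occupancy; the envelope is the 2.5/50/97.5
    percentile band and p-values are per-bin two-tailed exceedances.
    """
    rng = as_rng(rng)
    if callable(variable):
        values_all = np.array([float(variable(e)) for e in encounters])
    else:
        values_all = np.array([float(variable in e.behaviors) for e in encounters])
    pos = np.array(
        [e.position_km if e.position_km is not None else np.nan for e in encounters]
    )
    ok = ~np.isnan(pos) & (pos >= 0) & (pos <= max_km)
    n_excluded = int((~ok).sum())
    pos, values = pos[ok], values_all[ok]
    edges = np.arange(0.0, max_km + bin_width, bin_width)
    nbins = edges.size - 1
    bin_of = np.minimum((pos // bin_width).astype(int), nbins - 1)
    n_enc = np.bincount(bin_of, minlength=nbins)

    def bin_stat(v):
        s = np.bincount(bin_of, weights=v, minlength=nbins)
        with np.errstate(invalid="ignore"):
            return np.where(n_enc > 0, s / np.maximum(n_enc, 1), np.nan)

    obs = bin_stat(values)
    null = np.empty((n_iter, nbins))
    for it in range(n_iter):
        null[it] = bin_stat(values[rng.permutation(values.size)])
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        lo, med, hi = np.nanpercentile(null, [2.5, 50.0, 97.5], axis=0)
    with np.errstate(invalid="ignore"):
        ge = (np.sum(null >= obs[None, :], axis=0) + 1) / (n_iter + 1)
        le = (np.sum(null <= obs[None, :], axis=0) + 1) / (n_iter + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(ge, le))
    p[n_enc == 0] = np.nan
    return BinnedRates(edges, n_enc, obs, lo, med, hi, p, n_excluded)
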