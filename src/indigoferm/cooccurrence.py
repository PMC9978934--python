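"""Taxon co-occurrence networks from abundance trends.

Each pair of taxa is scored by Spearman's rank correlation rs over the
relative-abundance trajectory of a fermentation period; an undirected edge is
kept iff |rs| > 0.6 and p < 0.05.  Edge sign records whether the pair co-rises
(positive) or trades places (negative); node weight accumulates the taxon's
total proportion over the period, mirroring the circle sizes of the study's
network figures.

The two-sided p-value is exact for short series (full enumeration of rank
permutations for n <= 8) and a t-approximation with n-2 degrees of freedom
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_metrics import AnalysisThresholds

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 8

__all__ = ["Edge", "Network", "spearman_rs", "spearman_p", "build_network",
           "export_network", "read_network"]


@dataclass(frozen=True)
class Edge:
    taxon_a: str
    taxon_b: str
    rs: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.rs > 0 else "negative"


@dataclass
class Network:
    """Thresholded co-occurrence network for one fermentation period."""

    nodes: dict[str, float]          # taxon id -> accumulated abundance
    edges: list[Edge] = field(default_factory=list)
    period: str = ""

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(period=self.period)
        for taxon, weight in self.nodes.items():
            g.add_node(taxon, accumulated_abundance=float(weight))
        for e in self.edges:
            g.add_edge(e.taxon_a, e.taxon_b, rs=float(e.rs),
                       p_value=float(e.p_value), sign=e.sign)
        return g


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rs(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of average ranks.

    Raises on constant input (zero rank variance leaves rs undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _ranks(x), _ranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant series: Spearman rs undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _pearson_safe(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom) if denom > 0 else 0.0


# Exact null |r| distributions, keyed by the (sorted) rank multisets — the
# permutation distribution depends only on those, so tables are reused across
# all taxon pairs of the same length and tie pattern.
_null_cache: dict = {}


def _exact_null_abs_r(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
    cached = _null_cache.get(key)
    if cached is not None:
        return cached
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perms = ry[perms]                       # n! x n
    rxc = rx - rx.mean()
    ryc = ry_perms - ry_perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ryc @ rxc) / denom, 0.0)
    table = np.sort(np.abs(r))
    _null_cache[key] = table
    return table


def spearman_p(rs: float, n: int, ranks_x=None, ranks_y=None) -> float:
    """Two-sided p-value for Spearman's rs.

    For n <= 8 the null distribution is enumerated exactly by permuting one
    rank vector (ties in the observed ranks are respected, because the
    observed average-rank vectors are permuted).  For larger n the usual
    t = rs * sqrt((n-2)/(1-rs^2)) approximation with n-2 df is used; |rs| = 1
    under the approximation is clamped to the smallest positive double with
    a warning.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if n <= EXACT_P_MAX_N:
        rx = (np.arange(1.0, n + 1) if ranks_x is None
              else np.asarray(ranks_x, dtype=float))
        ry = (np.arange(1.0, n + 1) if ranks_y is None
              else np.asarray(ranks_y, dtype=float))
        table = _exact_null_abs_r(rx, ry)
        # count |r_perm| >= |rs| (within fp tolerance)
        idx = np.searchsorted(table, abs(rs) - 1e-12, side="left")
        return float(len(table) - idx) / len(table)
    if abs(rs) >= 1.0:
        logger.warning("|rs| = 1 at n = %d: p clamped to smallest positive value", n)
        return float(np.nextafter(0, 1))
    t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_test(x, y) -> tuple[float, float]:
    """rs and its two-sided p for a pair of series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rs = spearman_rs(x, y)
    return rs, spearman_p(rs, len(x), _ranks(x), _ranks(y))


def build_network(
    rel: pd.DataFrame,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    period: str = "",
    mode: str = "level",
) -> Network:
    """Threshold all taxon pairs of a period's proportion table into a network.

    ``rel`` is taxa x samples for one period, samples in temporal order.
    ``mode='level'`` correlates the abundance trajectories themselves
    (default); ``'diff'`` correlates consecutive-sample first differences.
    An edge is kept iff |rs| > rs_min and p < alpha (both strict).
    """
    if rel.shape[1] < 3:
        raise ValueError(f"period needs >= 3 samples, got {rel.shape[1]}")
    if mode == "diff":
        data = rel.diff(axis=1).iloc[:, 1:]
        if data.shape[1] < 3:
            raise ValueError("period too short for difference mode")
    elif mode == "level":
        data = rel
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nodes = {taxon: float(rel.loc[taxon].sum()) for taxon in rel.index}
    edges: list[Edge] = []
    for a, b in combinations(rel.index, 2):
        xa = data.loc[a].to_numpy()
        xb = data.loc[b].to_numpy()
        try:
            rs, p = spearman_test(xa, xb)
        except ValueError:
            logger.warning("skipping constant-series pair (%s, %s)", a, b)
            continue
        if abs(rs) > thresholds.rs_min and p < thresholds.alpha:
            a_c, b_c = sorted((a, b))
            edges.append(Edge(a_c, b_c, rs=rs, p_value=p))
    return Network(nodes=nodes, edges=edges, period=period)


def export_network(net: Network, path, fmt: str = "edge_tsv") -> None:
    """Write a network as an edge TSV (with a node sidecar) or GraphML."""
    path = str(path)
    if fmt == "edge_tsv":
        rows = [
            {"taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "rs": e.rs,
             "p": e.p_value, "sign": e.sign}
            for e in net.edges
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rs", "p", "sign"]).to_csv(
            path, sep="\t", index=False)
        nodes = pd.DataFrame(
            [{"taxon_id": t, "accumulated_abundance": w} for t, w in net.nodes.items()]
        )
        nodes.to_csv(path + ".nodes.tsv", sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path, fmt: str = "edge_tsv") -> Network:
    """Read back a network written by :func:`export_network`."""
    path = str(path)
    if fmt == "edge_tsv":
        edges_df = pd.read_csv(path, sep="\t", dtype={"taxon_a": str, "taxon_b": str})
        nodes_df = pd.read_csv(path + ".nodes.tsv", sep="\t", dtype={"taxon_id": str})
        nodes = dict(zip(nodes_df["taxon_id"], nodes_df["accumulated_abundance"]))
        edges = [Edge(r.taxon_a, r.taxon_b, float(r.rs), float(r.p))
                 for r in edges_df.itertuples()]
        return Network(nodes=nodes, edges=edges)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = {str(t): float(d.get("accumulated_abundance", 0.0))
                 for t, d in g.nodes(data=True)}
        edges = [Edge(*sorted((str(a), str(b))), rs=float(d["rs"]),
                      p_value=float(d["p_value"])) for a, b, d in g.edges(data=True)]
        return Network(nodes=nodes, edges=edges, period=g.graph.get("period", ""))
    raise ValueError(f"unknown format {fmt!r}")
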