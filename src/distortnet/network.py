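"""Co-occurrence network construction, topology and centrality metrics.

The network is a simple undirected graph: one node per distortion label
(isolates optionally dropped), one edge per pair that survived the
association filter, weighted by lift. Reported metrics follow network-
psychometrics convention:

* density |E| / C(|V|, 2);
* clustering: average local clustering coefficient (unweighted) as the
  headline value, global transitivity also reported;
* degree and weighted degree (sum of incident lift weights);
* betweenness centrality, normalised, over shortest paths with edge
  distance 1/lift so stronger associations are shorter;
* degree assortativity (undefined on degree-regular graphs — reported as
  ``None``, never NaN);
* hubs: nodes ranked by degree, ties broken by weighted degree then label.

``adjacency_metrics`` provides a vectorised density/clustering computation
on boolean adjacency matrices for resampling hot loops; it is tested for
equality against the networkx path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pairs import AssociationConfig
from .taxonomy import DistortionTaxonomy


@dataclass
class DistortionNetwork:
    """A filtered co-occurrence graph with its filter provenance."""

    graph: nx.Graph
    filter_provenance: AssociationConfig | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def adjacency(
        self, taxonomy: DistortionTaxonomy, weight: str | None = "lift"
    ) -> np.ndarray:
        """Dense adjacency on the full taxonomy node set (absent edges 0).

        ``weight=None`` gives a binary adjacency.
        """
        D = taxonomy.size
        a = np.zeros((D, D))
        for u, v, data in self.graph.edges(data=True):
            i, j = taxonomy.index(u), taxonomy.index(v)
            w = 1.0 if weight is None else float(data[weight])
            a[i, j] = a[j, i] = w
        return a


def build_network(
    pairs: pd.DataFrame,
    cfg: AssociationConfig | None = None,
    isolate_policy: str = "drop",
    taxonomy: DistortionTaxonomy | None = None,
) -> DistortionNetwork:
    """Build the graph from an already-filtered pair table.

    One edge per row of *pairs*, weighted by lift and carrying the observed
    count and p-value as attributes. With ``isolate_policy="keep"`` every
    taxonomy label becomes a node regardless of incident edges (requires
    *taxonomy*); with ``"drop"`` only labels incident to an edge appear.
    """
    if isolate_policy not in ("drop", "keep"):
        raise ValueError("isolate_policy must be 'drop' or 'keep'")
    g = nx.Graph()
    if isolate_policy == "keep":
        if taxonomy is None:
            raise ValueError("isolate_policy='keep' requires a taxonomy")
        g.add_nodes_from(taxonomy.labels)
    for row in pairs.itertuples(index=False):
        u, v = row.label_i, row.label_j
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if g.has_edge(u, v):
            raise ValueError(f"duplicate pair ({u!r}, {v!r})")
        g.add_edge(
            u, v,
            lift=float(row.lift),
            observed=int(row.observed),
            p_value=float(getattr(row, "p_value", np.nan)),
        )
    return DistortionNetwork(graph=g, filter_provenance=cfg)


@dataclass
class CentralityReport:
    """Global topology and per-node centrality metrics."""

    density: float
    avg_clustering: float
    transitivity: float
    assortativity: float | None
    degree: dict[str, int] = field(default_factory=dict)
    weighted_degree: dict[str, float] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)
    local_clustering: dict[str, float] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "transitivity": self.transitivity,
            "assortativity": self.assortativity,
            "degree": self.degree,
            "weighted_degree": self.weighted_degree,
            "betweenness": self.betweenness,
            "local_clustering": self.local_clustering,
            "hubs": self.hubs,
        }


def topology(net: DistortionNetwork) -> CentralityReport:
    """Global metrics only (density, clustering, assortativity)."""
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValueError("topology requires at least 2 nodes")
    density = nx.density(g)
    avg_clust = nx.average_clustering(g)
    trans = nx.transitivity(g)
    assort = _safe_assortativity(g)
    return CentralityReport(
        density=density,
        avg_clustering=avg_clust,
        transitivity=trans,
        assortativity=assort,
    )


def _safe_assortativity(g: nx.Graph) -> float | None:
    degrees = {d for _, d in g.degree}
    if g.number_of_edges() == 0 or len(degrees) < 2:
        return None  # degree-regular: correlation undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = nx.degree_assortativity_coefficient(g)
    return None if np.isnan(r) else float(r)


def centralities(net: DistortionNetwork, top_k: int = 5) -> CentralityReport:
    """Global and per-node metrics plus the ranked hub list."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    report = topology(net) if g.number_of_nodes() >= 2 else CentralityReport(
        density=0.0, avg_clustering=0.0, transitivity=0.0, assortativity=None
    )
    report.degree = dict(g.degree)
    report.weighted_degree = {
        n: float(sum(d["lift"] for _, _, d in g.edges(n, data=True)))
        for n in g.nodes
    }
    for u, v, d in g.edges(data=True):
        d["distance"] = 1.0 / d["lift"] if d.get("lift", 0) > 0 else np.inf
    report.betweenness = {
        n: float(b)
        for n, b in nx.betweenness_centrality(
            g, weight="distance", normalized=True
        ).items()
    }
    report.local_clustering = {n: float(c) for n, c in nx.clustering(g).items()}
    report.hubs = top_hubs(report, k=top_k)
    return report


def top_hubs(report: CentralityReport, k: int = 5) -> list[str]:
    """Top-k nodes by degree; ties by weighted degree desc, then label."""
    nodes = sorted(
        report.degree,
        key=lambda n: (-report.degree[n], -report.weighted_degree.get(n, 0.0), n),
    )
    return nodes[:k]


def hubs_from_graph(net: DistortionNetwork, k: int = 5) -> list[str]:
    """Convenience: ranked hubs straight from a network."""
    g = net.graph
    wdeg = {
        n: float(sum(d["lift"] for _, _, d in g.edges(n, data=True)))
        for n in g.nodes
    }
    nodes = sorted(g.nodes, key=lambda n: (-g.degree[n], -wdeg[n], n))
    return nodes[:k]


# ---------------------------------------------------------------------------
# Vectorised metrics on boolean adjacency (resampling hot loops)
# ---------------------------------------------------------------------------

def adjacency_metrics(adj: np.ndarray, drop_isolates: bool = True) -> tuple[float, float]:
    """(density, average local clustering) from a boolean adjacency matrix.

    Matches the networkx definitions on simple undirected graphs; with
    ``drop_isolates`` the node set is restricted to nodes with at least one
    edge (the isolate-drop construction policy).
    """
    A = np.asarray(adj, dtype=bool)
    deg = A.sum(axis=1)
    if drop_isolates:
        keep = deg > 0
        A = A[np.ix_(keep, keep)]
        deg = deg[keep]
    n = A.shape[0]
    if n < 2:
        return 0.0, 0.0
    e = A.sum() / 2
    density = e / (n * (n - 1) / 2)
    Af = A.astype(np.float64)
    tri = np.diag(Af @ Af @ Af) / 2.0
    denom = deg * (deg - 1) / 2.0
    local = np.where(denom > 0, tri / np.maximum(denom, 1e-300), 0.0)
    return float(density), float(local.mean())


def degrees_from_adjacency(adj: np.ndarray) -> np.ndarray:
    return np.asarray(adj, dtype=bool).sum(axis=1)


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def write_network(
    net: DistortionNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write a network as GraphML, CSV edge list or JSON report.

    GraphML and edge CSV round-trip exactly through :func:`read_network`.
    """
    path = Path(path)
    fmt = format or {
        ".graphml": "graphml",
        ".csv": "edge_csv",
        ".json": "json_report",
    }.get(path.suffix.lower())
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "edge_csv":
        rows = [
            {
                "source": u,
                "target": v,
                "lift": d.get("lift"),
                "count": d.get("observed"),
                "p_value": d.get("p_value"),
            }
            for u, v, d in net.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "lift", "count", "p_value"])
        df.to_csv(path, index=False)
        # isolates are representable only in graphml/json
    elif fmt == "json_report":
        payload = {
            "nodes": list(net.graph.nodes),
            "edges": [
                {
                    "source": u,
                    "target": v,
                    "lift": d.get("lift"),
                    "count": d.get("observed"),
                    "p_value": d.get("p_value"),
                }
                for u, v, d in net.graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, format: str | None = None) -> DistortionNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = format or {
        ".graphml": "graphml",
        ".csv": "edge_csv",
        ".json": "json_report",
    }.get(path.suffix.lower())
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        for _, _, d in g.edges(data=True):
            d["lift"] = float(d["lift"])
            d["observed"] = int(d["observed"])
            if "p_value" in d:
                d["p_value"] = float(d["p_value"])
        return DistortionNetwork(graph=nx.Graph(g))
    if fmt == "edge_csv":
        df = pd.read_csv(path)
        g = nx.Graph()
        for rec in df.to_dict("records"):
            g.add_edge(
                str(rec["source"]), str(rec["target"]),
                lift=float(rec["lift"]),
                observed=int(rec["count"]),
                p_value=float(rec["p_value"]),
            )
        return DistortionNetwork(graph=g)
    if fmt == "json_report":
        with open(path) as fh:
            payload = json.load(fh)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in payload["nodes"])
        for e in payload["edges"]:
            g.add_edge(
                str(e["source"]), str(e["target"]),
                lift=float(e["lift"]),
                observed=int(e["count"]),
                p_value=float(e["p_value"]) if e.get("p_value") is not None else np.nan,
            )
        return DistortionNetwork(graph=g)
    raise ValueError(f"unknown network format {fmt!r}")
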