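"""Per-threshold network topology and automatic threshold selection.

For each candidate correlation threshold tau, the graph of edges with
rho >= tau is profiled over ALL input regions — isolated nodes stay in the
node set, so density and the relative largest connected component (rLCC)
are computed against the full region count. The selected threshold is the
one maximizing rLCC, favouring well-connected networks; ties go to the more
stringent (larger) tau, which removes weak edges without changing topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import pandas as pd

from .corrnet import EdgeStore

__all__ = ["NetworkMetrics", "NetworkSeries", "compute_metrics", "build_series", "select_threshold"]


@dataclass(frozen=True)
class NetworkMetrics:
    tau: float
    n_edges: int
    n_connected_nodes: int
    n_total_nodes: int
    density: float
    transitivity: float
    lcc: int
    rlcc: float


@dataclass
class NetworkSeries:
    metrics: list[NetworkMetrics]
    selected_tau: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.__dict__ for m in self.metrics])


def _graph_at(store: EdgeStore, tau: float) -> ig.Graph:
    df = store.edges_frame(tau)
    g = ig.Graph()
    g.add_vertices(store.node_ids)
    if len(df):
        g.add_edges(list(zip(df["source_id"], df["target_id"])), attributes={"rho": list(df["rho"])})
    return g


def compute_metrics(store: EdgeStore, tau: float) -> NetworkMetrics:
    """Topology metrics of the graph at threshold tau over all input regions.

    density = E / (N*(N-1)/2) with N the total region count;
    transitivity = 3*triangles / connected triples (0 when there are none);
    rlcc = largest component size / N.
    """
    g = _graph_at(store, tau)
    n_total = store.n
    n_edges = g.ecount()
    degrees = g.degree()
    n_connected = sum(1 for d in degrees if d > 0)
    density = n_edges / (n_total * (n_total - 1) / 2) if n_total > 1 else 0.0
    trans = g.transitivity_undirected(mode="zero")
    comps = g.connected_components()
    lcc = max(comps.sizes()) if n_total else 0
    return NetworkMetrics(
        tau=float(tau),
        n_edges=int(n_edges),
        n_connected_nodes=int(n_connected),
        n_total_nodes=int(n_total),
        density=float(density),
        transitivity=float(trans),
        lcc=int(lcc),
        rlcc=float(lcc / n_total),
    )


def build_series(store: EdgeStore, taus: list[float] | None = None) -> NetworkSeries:
    """One NetworkMetrics per tau (default: the store's bin lower bounds)."""
    if taus is None:
        taus = [lo for lo, _ in store.bins]
    else:
        floor_ = store.bins[0][0] if store.bins else 0.0
        taus = [t for t in taus if t >= floor_]
    if not taus:
        raise ValueError("no valid thresholds to profile")
    taus = sorted(set(float(t) for t in taus))
    return NetworkSeries(metrics=[compute_metrics(store, t) for t in taus])


def select_threshold(series: NetworkSeries) -> float:
    """The tau with maximal rLCC; among equal rLCC values, the largest tau."""
    if not series.metrics:
        raise ValueError("empty network series")
    best = max(series.metrics, key=lambda nm: (nm.rlcc, nm.tau))
    series.selected_tau = best.tau
    return best.tau
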