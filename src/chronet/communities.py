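"""Community detection on the thresholded co-accessibility network.

The thresholded graph keeps every input region as a node; communities are
found with the Leiden algorithm under the RB-configuration quality function
over a resolution grid (default 0.5–1.5, step 0.1). Because the quality at
different resolutions is not directly comparable, each partition is scored
with standard Newman–Girvan modularity (gamma = 1) and the resolution
maximizing that score is selected automatically; ties break toward the
smaller (coarser) resolution to avoid over-fragmentation.

Isolated regions carry no edge information: they are left unlabeled by
default, or gathered into one extra "disconnected" community on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .corrnet import EdgeStore

__all__ = [
    "ChromatinNetwork",
    "CommunityConfig",
    "Partition",
    "materialize",
    "modularity",
    "detect",
    "select_resolution",
    "stability",
]

DISCONNECTED = "disconnected"


@dataclass
class ChromatinNetwork:
    """Weighted graph over ALL input regions; weights are Spearman rho."""

    node_ids: list[str]
    edges: list[tuple[str, str, float]]
    tau: float

    def __post_init__(self):
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node ids")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_igraph(self, weighted: bool = True) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.node_ids)
        if self.edges:
            g.add_edges([(s, t) for s, t, _ in self.edges])
            g.es["weight"] = [w if weighted else 1.0 for _, _, w in self.edges]
        return g

    def isolated_nodes(self) -> list[str]:
        touched = set()
        for s, t, _ in self.edges:
            touched.add(s)
            touched.add(t)
        return [nid for nid in self.node_ids if nid not in touched]


@dataclass(frozen=True)
class CommunityConfig:
    resolutions: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.51, 0.1), 2))
    seed: int = 42
    n_iterations: int = -1  # run Leiden to convergence
    weighted: bool = True
    include_disconnected_as_community: bool = False

    def __post_init__(self):
        if not self.resolutions:
            raise ValueError("resolution grid must be non-empty")
        if any(g <= 0 for g in self.resolutions):
            raise ValueError("all resolutions must be > 0")


@dataclass
class Partition:
    gamma: float
    labels: dict[str, int]
    modularity: float  # Newman-Girvan Q at gamma = 1
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sizes:
            counts: dict[int, int] = {}
            for c in self.labels.values():
                counts[c] = counts.get(c, 0) + 1
            self.sizes = dict(sorted(counts.items()))

    @property
    def n_communities(self) -> int:
        return len(self.sizes)


def materialize(store: EdgeStore, tau: float) -> ChromatinNetwork:
    """Graph with all regions as nodes and edges rho >= tau, weighted by rho."""
    df = store.edges_frame(tau)
    edges = list(zip(df["source_id"], df["target_id"], (float(r) for r in df["rho"])))
    return ChromatinNetwork(node_ids=list(store.node_ids), edges=edges, tau=float(tau))


def modularity(net: ChromatinNetwork, labels: dict[str, int], gamma: float = 1.0) -> float:
    """Weighted Newman–Girvan modularity with resolution gamma.

    Q = (1/2W) * sum_ij [w_ij - gamma * s_i s_j / (2W)] * delta(c_i, c_j),
    W total edge weight, s_i weighted degree. Isolated nodes contribute
    nothing; an edgeless graph has no defined Q.
    """
    if not net.edges:
        raise ValueError("modularity is undefined on an edgeless graph")
    strength: dict[str, float] = {}
    W = 0.0
    within: dict[int, float] = {}
    for s, t, w in net.edges:
        W += w
        strength[s] = strength.get(s, 0.0) + w
        strength[t] = strength.get(t, 0.0) + w
        cs, ct = labels.get(s), labels.get(t)
        if cs is None or ct is None:
            raise ValueError(f"labels must cover all non-isolated nodes (missing {s if cs is None else t})")
        if cs == ct:
            within[cs] = within.get(cs, 0.0) + w
    comm_strength: dict[int, float] = {}
    for nid, st in strength.items():
        c = labels[nid]
        comm_strength[c] = comm_strength.get(c, 0.0) + st
    q = 0.0
    for c, s_c in comm_strength.items():
        q += within.get(c, 0.0) / W - gamma * (s_c / (2.0 * W)) ** 2
    return float(q)


def _relabel_by_size(membership: list[int]) -> list[int]:
    """Dense community ids 1..K by decreasing size (ties by first appearance)."""
    counts: dict[int, int] = {}
    first: dict[int, int] = {}
    for pos, c in enumerate(membership):
        counts[c] = counts.get(c, 0) + 1
        first.setdefault(c, pos)
    order = sorted(counts, key=lambda c: (-counts[c], first[c]))
    remap = {c: k + 1 for k, c in enumerate(order)}
    return [remap[c] for c in membership]


def detect(net: ChromatinNetwork, cfg: CommunityConfig = CommunityConfig()) -> list[Partition]:
    """Leiden partitions of the connected part of the graph, one per gamma.

    Community ids are dense from 1, assigned by decreasing size. With
    ``include_disconnected_as_community`` all isolated nodes share one extra
    community labeled after the last detected one.
    """
    if not net.edges:
        raise ValueError("cannot detect communities on an edgeless graph")
    g = net.to_igraph(weighted=cfg.weighted)
    connected = [v.index for v in g.vs if g.degree(v.index) > 0]
    sub = g.induced_subgraph(connected)
    sub_ids = sub.vs["name"]
    isolated = net.isolated_nodes()

    partitions = []
    for gamma in cfg.resolutions:
        part = la.find_partition(
            sub,
            la.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=float(gamma),
            n_iterations=cfg.n_iterations,
            seed=cfg.seed,
        )
        membership = _relabel_by_size(part.membership)
        labels = dict(zip(sub_ids, membership))
        q = modularity(net, labels, gamma=1.0)
        if cfg.include_disconnected_as_community and isolated:
            extra = max(labels.values()) + 1
            for nid in isolated:
                labels[nid] = extra
        partitions.append(Partition(gamma=float(gamma), labels=labels, modularity=q))
    return partitions


def select_resolution(partitions: list[Partition]) -> float:
    """The gamma whose partition maximizes Q (at gamma = 1); ties -> smaller gamma."""
    if not partitions:
        raise ValueError("no partitions to select from")
    best = min(partitions, key=lambda p: (-p.modularity, p.gamma))
    return best.gamma


def stability(partitions: list[Partition]) -> np.ndarray:
    """Pairwise Adjusted Rand Index matrix between partitions (common nodes)."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    k = len(partitions)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            common = sorted(set(partitions[i].labels) & set(partitions[j].labels))
            a = [partitions[i].labels[n] for n in common]
            b = [partitions[j].labels[n] for n in common]
            out[i, j] = out[j, i] = adjusted_rand_score(a, b)
    return out
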