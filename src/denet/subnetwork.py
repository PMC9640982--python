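"""DE-induced subgraphs, the giant subnetwork, and its permutation tests.

The induced subgraph keeps only DE nodes and the edges joining two DE
nodes; its connected components of size >= 2 are the "subnetworks" (an
isolated DE node is merely scattered).  The largest component — the giant
subnetwork — is tested for size against uniformly re-drawn node sets, and
for hub capture against uniform subsets of the DE set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .de_sets import DESetCollection
from .expression import condition_name
from .pathways import BioNetwork
from .permutation import PermutationResult
from .topology import DEFAULT_HUB_DEGREE, degrees, hubs

__all__ = [
    "SubnetworkReport",
    "de_induced_subgraph",
    "connected_components",
    "subnetwork_size_test",
    "hub_capture_test",
    "per_condition_subnetworks",
    "recurrent_nodes",
]


@dataclass(frozen=True)
class SubnetworkReport:
    """Connected components of a DE-induced subgraph, deterministically ordered.

    Components (size >= 2) are sorted by decreasing size, ties broken by
    their lexicographically smallest member; singletons are reported as
    ``scattered``.  ``hubs_in_giant`` uses full-network degrees when the
    report was built with one.
    """

    components: tuple[frozenset[str], ...]
    scattered: frozenset[str]
    edge_counts: tuple[int, ...]
    hubs_in_giant: frozenset[str]

    @property
    def giant(self) -> frozenset[str]:
        return self.components[0] if self.components else frozenset()

    @property
    def n_components(self) -> int:
        return len(self.components)

    def membership(self) -> dict[str, int]:
        """node -> component index (0 = giant)."""
        return {n: i for i, comp in enumerate(self.components) for n in comp}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, comp in enumerate(self.components):
            for n in sorted(comp):
                rows.append({"node": n, "component_id": i, "component_size": len(comp),
                             "is_hub": n in self.hubs_in_giant and i == 0})
        for n in sorted(self.scattered):
            rows.append({"node": n, "component_id": -1, "component_size": 1, "is_hub": False})
        return pd.DataFrame(rows, columns=["node", "component_id", "component_size", "is_hub"])


def de_induced_subgraph(net: BioNetwork, de_set: Iterable[str]) -> nx.Graph:
    """Subgraph on the DE nodes: edges whose endpoints are both DE."""
    members = set(de_set) & set(net.graph.nodes)
    return net.graph.subgraph(members).copy()


def connected_components(
    g: nx.Graph,
    degree_table: pd.Series | None = None,
    k_min: int = DEFAULT_HUB_DEGREE,
) -> SubnetworkReport:
    """Components of size >= 2, ordered (size desc, then smallest member).

    ``degree_table`` supplies full-network degrees for hub labeling; by
    default hubs are judged on the subgraph's own degrees, which
    understates connectivity of nodes with non-DE neighbors.
    """
    comps = [frozenset(c) for c in nx.connected_components(g)]
    scattered = frozenset(n for c in comps if len(c) == 1 for n in c)
    comps = [c for c in comps if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    edge_counts = tuple(g.subgraph(c).number_of_edges() for c in comps)
    if comps:
        dt = degree_table if degree_table is not None else pd.Series(dict(g.degree()))
        hub_set = hubs(dt, k_min)
        hubs_in_giant = frozenset(comps[0] & hub_set)
    else:
        hubs_in_giant = frozenset()
    return SubnetworkReport(tuple(comps), scattered, edge_counts, hubs_in_giant)


# -- fast giant-component size for permutation nulls ------------------------

def _index_graph(net: BioNetwork) -> tuple[list[str], list[np.ndarray]]:
    """Node order plus adjacency as integer index arrays."""
    nodes = sorted(net.graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    adj = [np.array([pos[m] for m in net.graph.neighbors(n)], dtype=np.int64) for n in nodes]
    return nodes, adj


def _giant_size(adj: list[np.ndarray], member: np.ndarray) -> int:
    """Largest connected-component size of the induced subgraph (>=2, else 0)."""
    seen = np.zeros(member.size, dtype=bool)
    best = 0
    for start in np.flatnonzero(member):
        if seen[start]:
            continue
        seen[start] = True
        stack = [start]
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for w in adj[v]:
                if member[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if size > best:
            best = size
    return best if best >= 2 else 0


def subnetwork_size_test(
    net: BioNetwork,
    de_set: Iterable[str],
    n_iter: int = 1000,
    seed: int | None = None,
    side: str = "less",
) -> PermutationResult:
    """Giant-subnetwork size vs uniformly re-drawn node sets of equal size.

    Default side is "less": a DE set biased toward sparsely connected
    nodes produces a *smaller* connected core than chance.
    """
    nodes, adj = _index_graph(net)
    pos = {n: i for i, n in enumerate(nodes)}
    de = set(de_set)
    extra = de - set(nodes)
    if extra:
        raise ValueError(f"DE set contains node(s) absent from the network: {sorted(extra)[:5]}")
    if not de:
        raise ValueError("DE set is empty")
    n, n_de = len(nodes), len(de)
    member = np.zeros(n, dtype=bool)
    member[[pos[g] for g in de]] = True
    observed = float(_giant_size(adj, member))

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=float)
    scratch = np.zeros(n, dtype=bool)
    for it in range(n_iter):
        idx = rng.choice(n, size=n_de, replace=False)
        scratch[:] = False
        scratch[idx] = True
        null[it] = _giant_size(adj, scratch)
    return PermutationResult("giant_subnetwork_size", observed, null, side, seed,
                             tie_u=float(rng.uniform()))


def hub_capture_test(
    net: BioNetwork,
    de_set: Iterable[str],
    k_min: int = DEFAULT_HUB_DEGREE,
    n_iter: int = 1000,
    seed: int | None = None,
    side: str = "greater",
    null: str = "within_de",
) -> PermutationResult:
    """Number of DE hubs inside the giant subnetwork vs a permutation null.

    ``within_de`` (default) conditions on the observed DE set and giant
    size, sampling giant membership uniformly from the DE set — it isolates
    "do hubs concentrate in the connected core" from the degree bias of
    the DE set itself.  ``uniform_nodes`` re-draws whole node sets of size
    |DE| and re-derives their giant component.
    """
    de = sorted(set(de_set) & set(net.graph.nodes))
    dt = degrees(net)
    hub_set = hubs(dt, k_min)
    de_hubs = [g for g in de if g in hub_set]
    if not de_hubs:
        raise ValueError(f"DE set contains no hub (degree >= {k_min}); the statistic is undefined")

    sub = de_induced_subgraph(net, de)
    report = connected_components(sub, degree_table=dt, k_min=k_min)
    giant = report.giant
    observed = float(len(giant & set(de_hubs)))
    rng = np.random.default_rng(seed)

    if null == "within_de":
        k = len(giant)
        is_hub = np.array([g in hub_set for g in de], dtype=float)
        if k == 0:
            null_vals = np.zeros(n_iter)
        elif k == len(de):
            null_vals = np.full(n_iter, is_hub.sum())
        else:
            keys = rng.random((n_iter, len(de)))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            null_vals = is_hub[idx].sum(axis=1)
    elif null == "uniform_nodes":
        nodes, adj = _index_graph(net)
        pos = {n: i for i, n in enumerate(nodes)}
        hub_mask = np.array([n in hub_set for n in nodes], dtype=bool)
        n = len(nodes)
        null_vals = np.empty(n_iter, dtype=float)
        scratch = np.zeros(n, dtype=bool)
        for it in range(n_iter):
            idx = rng.choice(n, size=len(de), replace=False)
            scratch[:] = False
            scratch[idx] = True
            null_vals[it] = _hubs_in_giant(adj, scratch, hub_mask)
    else:
        raise ValueError(f"unknown null model {null!r}")
    return PermutationResult(f"de_hubs_in_giant_k{k_min}", observed, null_vals, side, seed,
                             tie_u=float(rng.uniform()))


def _hubs_in_giant(adj: list[np.ndarray], member: np.ndarray, hub_mask: np.ndarray) -> int:
    seen = np.zeros(member.size, dtype=bool)
    best_size, best_hubs = 0, 0
    for start in np.flatnonzero(member):
        if seen[start]:
            continue
        seen[start] = True
        stack = [start]
        size = hubs_n = 0
        while stack:
            v = stack.pop()
            size += 1
            hubs_n += int(hub_mask[v])
            for w in adj[v]:
                if member[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if size > best_size:
            best_size, best_hubs = size, hubs_n
    return best_hubs if best_size >= 2 else 0


def per_condition_subnetworks(
    net: BioNetwork, coll: DESetCollection, k_min: int = DEFAULT_HUB_DEGREE
) -> dict[str, SubnetworkReport]:
    """One subnetwork report per condition, using that condition's DE set."""
    dt = degrees(net)
    out = {}
    for cond in coll.conditions:
        label = condition_name(*cond)
        members = {g.upper() for g in coll.genes(cond)}
        sub = de_induced_subgraph(net, members)
        out[label] = connected_components(sub, degree_table=dt, k_min=k_min)
    return out


def recurrent_nodes(
    reports: Mapping[str, SubnetworkReport], min_conditions: int = 1
) -> pd.Series:
    """Nodes present in components of >= min_conditions condition subnetworks."""
    if not reports:
        raise ValueError("need at least one subnetwork report")
    counts: dict[str, int] = {}
    for report in reports.values():
        for comp in report.components:
            for n in comp:
                counts[n] = counts.get(n, 0) + 1
    s = pd.Series(counts, name="n_conditions", dtype=int).sort_index()
    return s[s >= min_conditions].sort_values(ascending=False, kind="stable")
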