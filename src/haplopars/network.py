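"""Unit-step haplotype networks under a parsimony connection limit.

Haplotype pairs are joined in order of increasing mutational step distance,
up to the connection limit ``j_max``.  The resulting component structure is
exactly single-linkage clustering at threshold ``j_max`` on the step-distance
matrix; within a component, every multi-step join is realized as a chain of
inferred intermediate nodes ("missing intermediates") so that every edge in
the graph represents exactly one substitution.  Equal-length alternative
joins between the same pair of components are kept and flagged as ambiguous
loops rather than pruned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .distances import distance_matrix
from .parsimony import ConnectionLimit
from .records import HaplotypeTable

log = logging.getLogger(__name__)


@dataclass
class HaplotypeNetwork:
    """One connected network: observed haplotypes plus inferred intermediates.

    ``graph`` is an undirected unit-step graph; node attribute ``kind`` is
    ``"observed"`` or ``"inferred"``, observed nodes carry ``count`` and
    ``representative_id``, and every node carries ``seq``.  Edge attribute
    ``edge_type`` is ``"observed-step"`` or ``"ambiguous-loop"``.
    """

    network_id: int
    graph: nx.Graph
    observed: list[str] = field(default_factory=list)

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def is_singleton(self) -> bool:
        return self.n_observed == 1 and self.graph.number_of_nodes() == 1


def infer_intermediates(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences along the path from ``seq_a`` to ``seq_b``.

    The differing sites are applied one at a time in ascending site order,
    yielding ``j - 1`` intermediates for a ``j``-step pair.  The choice of
    site order is an arbitrary deterministic convention; component structure
    and path lengths do not depend on it.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("length mismatch")
    diff = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if x != y]
    if not diff:
        raise ValueError("identical sequences: duplicate haplotypes must be collapsed upstream")
    out = []
    cur = list(seq_a)
    for site in diff[:-1]:
        cur[site] = seq_b[site]
        out.append("".join(cur))
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_networks(
    table: HaplotypeTable,
    limit: ConnectionLimit | int,
    steps: pd.DataFrame | None = None,
) -> list[HaplotypeNetwork]:
    """Build statistical-parsimony networks from a haplotype table.

    ``limit`` is a :class:`ConnectionLimit` or a fixed maximum step count,
    which decouples network building from the probability model.  Pairs are
    processed level by level in increasing step distance; within a level,
    component membership is snapshotted at the level start so that every
    equal-length alternative join between two components is retained (the
    first as ``observed-step``, the rest as ``ambiguous-loop``).  Networks
    are numbered by descending observed size, ties broken by smallest
    member code.
    """
    j_max = limit.j_max if isinstance(limit, ConnectionLimit) else int(limit)
    if j_max < 0:
        raise ValueError("connection limit must be non-negative")
    codes = table.codes
    seq_of = {h.code: h.seq for h in table}

    graph = nx.Graph()
    for h in table:
        graph.add_node(
            h.code, kind="observed", seq=h.seq, count=h.count,
            representative_id=h.representative_id,
        )

    uf = _UnionFind(codes)
    # per-component map from node sequence -> node name (observed nodes
    # included so a coinciding inferred sequence reuses them); merged on union
    interm: dict[str, dict[str, str]] = {c: {seq_of[c]: c} for c in codes}
    counter = itertools.count(1)

    if len(table) > 1:
        D = steps if steps is not None else distance_matrix(table, metric="steps")
        pairs: dict[int, list[tuple[str, str]]] = {}
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                d = int(D.loc[a, b])
                if 1 <= d <= j_max:
                    pairs.setdefault(d, []).append((a, b))

        for d in sorted(pairs):
            snapshot = {c: uf.find(c) for c in codes}
            joined_at_level: set[frozenset] = set()
            for a, b in pairs[d]:
                ra, rb = snapshot[a], snapshot[b]
                if ra == rb:
                    continue  # already connected at a shorter distance
                key = frozenset((ra, rb))
                edge_type = "observed-step" if key not in joined_at_level else "ambiguous-loop"
                if edge_type == "ambiguous-loop":
                    log.info("ambiguous %d-step alternative connection %s-%s", d, a, b)
                joined_at_level.add(key)
                _add_chain(graph, uf, interm, seq_of, counter, a, b, edge_type)
                uf.union(a, b)

    # assemble components into numbered networks
    comp_nodes: dict[str, set] = {}
    for node, data in graph.nodes(data=True):
        anchor = node if data["kind"] == "observed" else data["anchor"]
        comp_nodes.setdefault(uf.find(anchor), set()).add(node)

    nets = []
    for root, nodes in comp_nodes.items():
        obs = sorted(n for n in nodes if graph.nodes[n]["kind"] == "observed")
        nets.append((obs, nodes))
    nets.sort(key=lambda t: (-len(t[0]), t[0][0]))

    out = []
    for i, (obs, nodes) in enumerate(nets, start=1):
        sub = graph.subgraph(nodes).copy()
        for n in sub.nodes:
            sub.nodes[n].pop("anchor", None)
        out.append(HaplotypeNetwork(network_id=i, graph=sub, observed=obs))
    return out


def _add_chain(graph, uf, interm, seq_of, counter, a, b, edge_type):
    """Insert the unit-step chain for pair (a, b), sharing inferred nodes."""
    seq_a, seq_b = seq_of[a], seq_of[b]
    # merge the two components' sequence->node maps under the surviving roots
    ra, rb = uf.find(a), uf.find(b)
    merged = interm.get(ra, {}) if ra == rb else {**interm.get(ra, {}), **interm.get(rb, {})}
    chain = [a]
    for seq in infer_intermediates(seq_a, seq_b):
        node = merged.get(seq)
        if node is None:
            node = f"mv{next(counter)}"
            graph.add_node(node, kind="inferred", seq=seq, count=0, anchor=a)
            merged[seq] = node
        chain.append(node)
    chain.append(b)
    for u, v in zip(chain, chain[1:]):
        if not graph.has_edge(u, v):
            graph.add_edge(u, v, edge_type=edge_type)
    interm[ra] = merged
    interm[rb] = merged


def membership(networks: list[HaplotypeNetwork]) -> dict[str, int]:
    """Map observed haplotype code -> network id."""
    out: dict[str, int] = {}
    for net in networks:
        for code in net.observed:
            out[code] = net.network_id
    return out


@dataclass
class NetworkStats:
    network_id: int
    n_observed: int
    n_inferred: int
    n_edges: int
    is_singleton: bool
    hub: str
    hub_degree: int
    n_direct: int        # observed haplotypes at unit-graph distance 1 from hub
    n_one_node_away: int  # observed haplotypes at graph distance 2 from hub
    degrees: dict[str, int] = field(default_factory=dict)


def network_stats(net: HaplotypeNetwork, table: HaplotypeTable) -> NetworkStats:
    """Node/edge counts, hub identification and hub-neighborhood tallies.

    The hub is the observed haplotype of maximum degree; ties are broken by
    record count, then code.
    """
    g = net.graph
    counts = {h.code: h.count for h in table}
    obs = net.observed
    hub = max(obs, key=lambda c: (g.degree(c), counts.get(c, 0), _neg_code(c)))
    dist = nx.single_source_shortest_path_length(g, hub)
    return NetworkStats(
        network_id=net.network_id,
        n_observed=len(obs),
        n_inferred=sum(1 for _, d in g.nodes(data=True) if d["kind"] == "inferred"),
        n_edges=g.number_of_edges(),
        is_singleton=net.is_singleton,
        hub=hub,
        hub_degree=g.degree(hub),
        n_direct=sum(1 for c in obs if dist.get(c) == 1),
        n_one_node_away=sum(1 for c in obs if dist.get(c) == 2),
        degrees={c: g.degree(c) for c in obs},
    )


class _neg_code(str):
    """Reverses lexicographic comparison so max() prefers the smallest code."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def write_graphml(networks: list[HaplotypeNetwork], path) -> None:
    g = nx.Graph()
    for net in networks:
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, network_id=net.network_id, **d)
        g.add_edges_from(net.graph.edges(data=True))
    nx.write_graphml(g, path)


def write_edgelist(networks: list[HaplotypeNetwork], path) -> None:
    rows = []
    for net in networks:
        for u, v, d in net.graph.edges(data=True):
            rows.append((net.network_id, u, v, d["edge_type"]))
    pd.DataFrame(rows, columns=["network", "node1", "node2", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(networks: list[HaplotypeNetwork], path) -> None:
    rows = []
    for net in networks:
        for n, d in net.graph.nodes(data=True):
            rows.append(
                (
                    net.network_id, n, d.get("representative_id", ""),
                    d.get("count", 0), d["kind"] == "inferred",
                )
            )
    pd.DataFrame(
        rows, columns=["network", "node", "representative_id", "count", "is_intermediate"]
    ).to_csv(path, sep="\t", index=False)
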