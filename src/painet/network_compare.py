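"""Comparison, centrality and layout for extracted item networks.

The two role-specific networks are compared as edge *sets* (identity by
unordered item pair, ignoring weight and sign), degree centrality is
the count of incident edges, and layout uses the Fruchterman-Reingold
force-directed algorithm — with the self-report coordinates reused
verbatim as reference coordinates for the proxy-report panel so the
two networks are directly comparable by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import networkx as nx
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

DOMAIN_COLORS = {
    "SC": "#1f77b4",  # blue — social contacts
    "PL": "#2ca02c",  # green — play
    "SL": "#9467bd",  # purple — school
    "MO": "#e377c2",  # pink — mobility
    "SR": "#d62728",  # red — self-reliance
    "CO": "#ffdd57",  # yellow — communication
    "LT": "#ff7f0e",  # orange — leisure time
    "AC": "#17becf",  # turquoise — acceptance
    "FI": "#8c564b",
}


@dataclass
class ItemNetwork:
    """Signed weighted item graph with optional domain labels/layout."""

    nodes: list[str]
    edges: pd.DataFrame  # item_i, item_j, rho
    domains: dict[str, str] = field(default_factory=dict)
    layout: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for _, row in self.edges.iterrows():
            if row["item_i"] not in node_set or row["item_j"] not in node_set:
                raise ValueError("edge references unknown node")
            if row["item_i"] == row["item_j"]:
                raise ValueError("self-loops are not allowed")
            if not -1 < row["rho"] < 1 or row["rho"] == 0:
                raise ValueError("edge weights must lie in (-1, 1) \\ {0}")

    @classmethod
    def from_edge_table(
        cls,
        edges: pd.DataFrame,
        nodes: list[str] | None = None,
        domains: dict[str, str] | None = None,
        retained_only: bool = True,
    ) -> "ItemNetwork":
        e = edges
        if retained_only and "retained" in e.columns:
            e = e[e["retained"]]
        e = e[["item_i", "item_j", "rho"]].reset_index(drop=True)
        if nodes is None:
            nodes = sorted(set(e["item_i"]) | set(e["item_j"]))
        return cls(nodes=list(nodes), edges=e, domains=dict(domains or {}))

    def edge_pairs(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in zip(self.edges["item_i"], self.edges["item_j"])
        }

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["item_i"], row["item_j"], weight=float(row["rho"]))
        return g


@dataclass(frozen=True)
class NetworkComparison:
    shared: set[frozenset]
    unique_to_a: set[frozenset]
    unique_to_b: set[frozenset]
    degrees_a: pd.Series
    degrees_b: pd.Series
    max_degree_a: list[str]
    max_degree_b: list[str]


def degree_centrality(g: ItemNetwork) -> tuple[pd.Series, list[str]]:
    """Incident-edge count per node, plus the max-degree node set
    (ties broken deterministically by item id order)."""
    deg = pd.Series(0, index=g.nodes, dtype=int)
    for _, row in g.edges.iterrows():
        deg[row["item_i"]] += 1
        deg[row["item_j"]] += 1
    if len(deg) == 0 or deg.max() == 0:
        return deg, []
    top = sorted(deg.index[deg == deg.max()])
    return deg, top


def compare(a: ItemNetwork, b: ItemNetwork) -> NetworkComparison:
    """Shared and unique edge sets; edge identity ignores weight/sign."""
    if set(a.nodes) != set(b.nodes):
        raise ValueError("networks must share the same node universe")
    ea, eb = a.edge_pairs(), b.edge_pairs()
    deg_a, top_a = degree_centrality(a)
    deg_b, top_b = degree_centrality(b)
    return NetworkComparison(
        shared=ea & eb,
        unique_to_a=ea - eb,
        unique_to_b=eb - ea,
        degrees_a=deg_a,
        degrees_b=deg_b,
        max_degree_a=top_a,
        max_degree_b=top_b,
    )


def fr_layout(
    g: ItemNetwork,
    reference: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    iterations: int = 100,
) -> dict[str, tuple[float, float]]:
    """Force-directed coordinates; with a reference, coordinates are
    copied verbatim (no re-optimization) so panels stay aligned."""
    if reference is not None:
        missing = set(g.nodes) - set(reference)
        if missing:
            raise ValueError(f"reference is missing nodes: {sorted(missing)}")
        return {n: tuple(reference[n]) for n in g.nodes}
    pos = nx.spring_layout(
        g.to_networkx(), seed=seed, iterations=iterations, weight=None
    )
    return {n: (float(x), float(y)) for n, (x, y) in pos.items()}


def render(
    g: ItemNetwork,
    coordinates: dict[str, tuple[float, float]],
    path=None,
    hide_isolated: bool = True,
    ax=None,
):
    """Draw the network: positive edges solid, negative dashed, nodes
    colored by domain; isolated nodes hidden by default."""
    missing = set(g.nodes) - set(coordinates)
    if missing:
        raise ValueError(f"coordinates missing for nodes: {sorted(missing)}")
    connected = {n for pair in g.edge_pairs() for n in pair}
    nodes = [n for n in g.nodes if (n in connected or not hide_isolated)]
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(7, 7))
    for _, row in g.edges.iterrows():
        xi, yi = coordinates[row["item_i"]]
        xj, yj = coordinates[row["item_j"]]
        ax.plot(
            [xi, xj],
            [yi, yj],
            linestyle="-" if row["rho"] > 0 else "--",
            color="0.4",
            linewidth=1 + 4 * abs(row["rho"]),
            zorder=1,
        )
    xs = [coordinates[n][0] for n in nodes]
    ys = [coordinates[n][1] for n in nodes]
    colors = [DOMAIN_COLORS.get(g.domains.get(n, ""), "#999999") for n in nodes]
    ax.scatter(xs, ys, s=450, c=colors, edgecolors="k", zorder=2)
    for n in nodes:
        ax.annotate(
            n, coordinates[n], ha="center", va="center", fontsize=7, zorder=3
        )
    ax.set_axis_off()
    if path is not None:
        plt.savefig(path, bbox_inches="tight", dpi=150)
        plt.close()
    return ax


def write_edge_list(g: ItemNetwork, path) -> None:
    g.edges.to_csv(path, index=False)


def read_edge_list(path, domains: dict[str, str] | None = None) -> ItemNetwork:
    """Read an edge-list CSV; a ``retained`` column, if present, filters
    the rows (so full extraction tables and bare lists both work)."""
    edges = pd.read_csv(path)
    return ItemNetwork.from_edge_table(edges, domains=domains, retained_only=True)


def write_graphml(g: ItemNetwork, path) -> None:
    nxg = g.to_networkx()
    nx.set_node_attributes(
        nxg, {n: g.domains.get(n, "") for n in g.nodes}, "domain"
    )
    nx.write_graphml(nxg, path)
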