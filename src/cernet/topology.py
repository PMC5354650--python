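"""Network topology: hubs, cross-subtype hub classes, k-cores, power-law
degree fit, hub sub-networks and the mutation overlay.

Hubs are the top decile of nodes by degree (ties at the boundary included,
so the call is independent of node order).  A hub is *common* when it is a
hub in at least three subtype networks, *specific* when it is a hub in
exactly one, and *intermediate* otherwise.  K-core indices are normalized by
each network's own maximal core so layers are comparable across subtypes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import hypergeom_upper_tail, rank_sum_test
from .cerna import CeRNANetwork
from .dysreg import DysregNetwork

__all__ = [
    "HubCatalog",
    "KCoreAssignment",
    "MutationOverlay",
    "identify_hubs",
    "classify_hubs",
    "kcore",
    "powerlaw_check",
    "fit_power_law",
    "hub_subnetwork",
    "mutation_overlay",
]


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return net.graph


def identify_hubs(net, fraction: float = 0.10) -> set:
    """Top-decile-by-degree hub set with inclusive boundary ties.

    The cutoff count is ``c = ceil(fraction * |V|)``; every node whose degree
    is at least the degree of the c-th node in descending degree order is a
    hub, so boundary ties are all included and the result is deterministic.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot identify hubs in an empty network")
    if not 0 < fraction <= 1:
        raise ValueError("hub fraction must be in (0, 1]")
    degrees = dict(g.degree())
    c = math.ceil(fraction * len(degrees))
    cutoff = sorted(degrees.values(), reverse=True)[c - 1]
    return {n for n, d in degrees.items() if d >= cutoff}


@dataclass
class HubCatalog:
    """Per-subtype hub sets with the cross-subtype classification."""

    hub_sets: dict[str, set]
    classification: dict[str, str]  # node -> common | specific | intermediate
    common_min_subtypes: int = 3
    degree_maps: dict[str, dict] = field(default_factory=dict)

    @property
    def common(self) -> set:
        return {n for n, c in self.classification.items() if c == "common"}

    @property
    def specific(self) -> set:
        return {n for n, c in self.classification.items() if c == "specific"}

    @property
    def intermediate(self) -> set:
        return {n for n, c in self.classification.items() if c == "intermediate"}

    def specific_to(self, subtype: str) -> set:
        return self.hub_sets[subtype] & self.specific

    def common_fraction(self, subtype: str) -> float:
        """Share of this subtype's hubs that are common hubs."""
        hubs = self.hub_sets[subtype]
        return len(hubs & self.common) / len(hubs) if hubs else float("nan")

    def to_table(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.classification):
            membership = sorted(s for s, hubs in self.hub_sets.items() if node in hubs)
            rows.append(
                {
                    "node": node,
                    "n_networks": len(membership),
                    "networks": ",".join(membership),
                    "class": self.classification[node],
                }
            )
        return pd.DataFrame(rows, columns=["node", "n_networks", "networks", "class"])


def classify_hubs(
    hub_sets: Mapping[str, set],
    common_min_subtypes: int = 3,
    strict_specific: bool = False,
    node_sets: Mapping[str, set] | None = None,
) -> HubCatalog:
    """Partition the union of hubs into common / specific / intermediate.

    Common: hub in at least ``common_min_subtypes`` networks.  Specific: hub
    in exactly one (with ``strict_specific`` the node must additionally be
    absent from every other network's node set, which requires
    ``node_sets``).  Everything else is intermediate.
    """
    if len(hub_sets) < 3:
        raise ValueError("hub classification needs at least 3 subtype networks")
    if strict_specific and node_sets is None:
        raise ValueError("strict_specific requires node_sets")
    union: set = set().union(*hub_sets.values())
    classification = {}
    for node in union:
        count = sum(node in hubs for hubs in hub_sets.values())
        if count >= common_min_subtypes:
            classification[node] = "common"
        elif count == 1:
            if strict_specific:
                home = next(s for s, hubs in hub_sets.items() if node in hubs)
                elsewhere = any(
                    node in nodes for s, nodes in node_sets.items() if s != home
                )
                classification[node] = "intermediate" if elsewhere else "specific"
            else:
                classification[node] = "specific"
        else:
            classification[node] = "intermediate"
    return HubCatalog(dict(hub_sets), classification, common_min_subtypes)


@dataclass
class KCoreAssignment:
    """Node -> maximal core index, with layers normalized by the graph's k_max."""

    core: dict
    k_max: int

    @property
    def normalized(self) -> dict:
        return {n: k / self.k_max for n, k in self.core.items()}

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "k": self.core[n], "layer": self.core[n] / self.k_max}
            for n in sorted(self.core)
        ]
        return pd.DataFrame(rows, columns=["node", "k", "layer"])


def kcore(net) -> KCoreAssignment:
    """K-core decomposition by iterative peeling.

    Each node's core index is the largest k such that it survives pruning of
    all vertices of degree < k; normalized layer = k / k_max of this network.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot decompose an empty graph")
    g = nx.Graph(g)  # core_number rejects multigraphs/self-loops
    g.remove_edges_from(nx.selfloop_edges(g))
    core = nx.core_number(g)
    k_max = max(core.values())
    if k_max == 0:
        # edgeless graph: every node peels at k=1 by convention k_max >= 1
        return KCoreAssignment({n: 0 for n in core}, 1)
    return KCoreAssignment(dict(core), k_max)


def fit_power_law(degree_counts: Mapping[int, int]) -> tuple[float, float]:
    """Least-squares log10-log10 fit of frequency vs degree.

    Returns ``(exponent, r_squared)`` where the fitted model is
    ``f(d) ~ C * d**(-exponent)``.  Degrees with zero frequency are excluded;
    at least two distinct positive degrees are required.
    """
    pts = [(d, c) for d, c in degree_counts.items() if d > 0 and c > 0]
    if len(pts) < 2:
        raise ValueError("power-law fit needs at least 2 distinct positive degrees")
    logd = np.log10([d for d, _ in pts])
    logf = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(logd, logf, 1)
    fitted = slope * logd + intercept
    ss_res = float(((logf - fitted) ** 2).sum())
    ss_tot = float(((logf - logf.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return -float(slope), r2


def powerlaw_check(net) -> tuple[float, float]:
    """Power-law check of the degree distribution; returns (exponent, R^2)."""
    g = _as_graph(net)
    degrees = [d for _, d in g.degree()]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 2:
        raise ValueError("degree distribution has a single distinct degree")
    if len(values) < 10:
        warnings.warn("fewer than 10 distinct degrees; power-law fit is unreliable")
    return fit_power_law(dict(zip(values.tolist(), counts.tolist())))


def hub_subnetwork(
    net: CeRNANetwork,
    hubs: Iterable,
    dysreg: DysregNetwork,
    hub_mirnas_only: bool = True,
    all_networks: Sequence[CeRNANetwork] | None = None,
    hub_fraction: float = 0.10,
) -> tuple[nx.Graph, list[tuple[str, str]]]:
    """Induced ceRNA sub-network on a hub set plus its miRNA regulators.

    miRNA hubs are called from the dys-regulatory network by the same
    top-decile rule applied to its miRNA-node degrees.  With
    ``hub_mirnas_only`` the dotted miRNA -> hub annotations are restricted to
    those hub miRNAs; otherwise every regulator of a hub is annotated.  When
    ``all_networks`` is given, each ceRNA edge carries a ``multiplicity``
    attribute counting the subtype networks that contain it.
    """
    hubs = set(hubs)
    missing = hubs - set(net.graph.nodes)
    if missing:
        raise ValueError(f"hubs absent from the network: {sorted(missing)[:5]}")
    sub = nx.Graph(net.graph.subgraph(hubs))
    if all_networks is not None:
        for a, b in sub.edges:
            sub.edges[a, b]["multiplicity"] = sum(
                1 for other in all_networks if other.graph.has_edge(a, b)
            )

    mirna_degrees = {m: dysreg.graph.out_degree(m) for m in dysreg.mirnas}
    mirna_edges: list[tuple[str, str]] = []
    if mirna_degrees:
        c = math.ceil(hub_fraction * len(mirna_degrees))
        cutoff = sorted(mirna_degrees.values(), reverse=True)[c - 1]
        hub_mirnas = {m for m, d in mirna_degrees.items() if d >= cutoff}
        allowed = hub_mirnas if hub_mirnas_only else set(mirna_degrees)
        mirna_edges = sorted(
            (m, t)
            for m in allowed
            for t in dysreg.graph.successors(m)
            if t in hubs
        )
    return sub, mirna_edges


def union_subnetwork(networks: Mapping[str, CeRNANetwork], hubs: Iterable) -> nx.Graph:
    """Union of the induced sub-networks on ``hubs`` across subtype networks.

    Collects every ceRNA edge between two hub nodes from any of the given
    networks; each edge carries a ``multiplicity`` attribute (number of
    subtype networks containing it) and each node a ``rna_class``.
    """
    hubs = set(hubs)
    union = nx.Graph()
    union.add_nodes_from(hubs)
    for net in networks.values():
        for a, b in net.graph.subgraph(hubs & set(net.graph.nodes)).edges:
            if union.has_edge(a, b):
                union.edges[a, b]["multiplicity"] += 1
            else:
                union.add_edge(a, b, multiplicity=1)
            for node in (a, b):
                union.nodes[node]["rna_class"] = net.graph.nodes[node].get("rna_class")
    return union


@dataclass(frozen=True)
class MutationOverlay:
    n_mutated_in_network: int
    degree_p: float  # one-sided rank-sum: mutated degrees > others
    hub_enrichment_p: float  # hypergeometric: mutated among hubs
    mean_layer_mutated: float
    mean_layer_other: float


def mutation_overlay(
    net, mutated_genes: Iterable, hubs: Iterable, kcores: KCoreAssignment
) -> MutationOverlay | None:
    """Relate mutated genes to network connectivity.

    (1) one-sided Wilcoxon rank-sum comparing degrees of mutated vs
    non-mutated nodes, (2) hypergeometric enrichment of mutated genes among
    the hubs (universe = network nodes), (3) mean normalized k-core layer of
    mutated vs non-mutated nodes.  Returns None with a warning when no
    mutated gene is in the network.
    """
    g = _as_graph(net)
    nodes = set(g.nodes)
    mutated = set(mutated_genes) & nodes
    hubs = set(hubs)
    if not mutated:
        warnings.warn("no mutated gene present in the network; overlay undefined")
        return None
    other = nodes - mutated
    degrees = dict(g.degree())
    if other:
        res = rank_sum_test(
            np.array([degrees[n] for n in sorted(mutated)], dtype=float),
            np.array([degrees[n] for n in sorted(other)], dtype=float),
            alternative="greater",
        )
        degree_p = res.pvalue
    else:
        degree_p = 1.0
    enrich_p = hypergeom_upper_tail(len(nodes), len(mutated), len(hubs), len(mutated & hubs))
    layers = kcores.normalized
    mean_mut = float(np.mean([layers[n] for n in mutated if n in layers]))
    mean_other = float(np.mean([layers[n] for n in other if n in layers])) if other else float("nan")
    return MutationOverlay(len(mutated), degree_p, enrich_p, mean_mut, mean_other)
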