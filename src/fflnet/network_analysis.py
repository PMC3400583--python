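"""Merged regulatory network construction and topology analyses.

Merged FFLs are expanded back into their constituent typed edges and unioned
into one network with per-class node typing, per-relation edge typing and
per-edge provenance (which merged FFLs contributed it). On top of that sit
the topology analyses: degree summaries on the undirected simple projection,
top-quantile hub calling, composite-FFL and pathway-seeded subnetworks,
TF↔miRNA feedback loops, k-clique (clique percolation) communities and node
ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .ffl_discovery import COMPOSITE_FFL, MergedFFL, MIRNA_FFL, TF_FFL
from .regulome_io import (GENE, GENE_GENE, MIRNA, MIRNA_GENE, MIRNA_TF,
                          RELATION_CLASSES, RELATIONS, TF, TF_GENE, TF_MIRNA,
                          ValidationError)

logger = logging.getLogger("fflnet")

DEFAULT_HUB_QUANTILE = 0.20
MIN_CLASS_SIZE_FOR_HUBS = 5
DEFAULT_COMMUNITY_K = 3


class RegulatoryNetwork:
    """Typed node/edge graph with per-edge provenance.

    Nodes carry a class (gene / miRNA / TF); dual-role nodes are stored once
    under their primary role (gene, when a node is both a disease gene and a
    TF) with the secondary roles retained in ``extra_roles``. Edges are keyed
    by (source, target, relation), gene-gene edges canonicalised.
    """

    def __init__(self):
        self.node_classes: dict[str, str] = {}
        self.extra_roles: dict[str, set[str]] = {}
        self._edges: dict[tuple[str, str, str], set] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node: str, node_class: str) -> None:
        prev = self.node_classes.get(node)
        if prev is None:
            self.node_classes[node] = node_class
        elif prev != node_class:
            # dual role: gene is the primary class by convention
            primary = GENE if GENE in (prev, node_class) else prev
            other = node_class if primary != node_class else prev
            self.node_classes[node] = primary
            self.extra_roles.setdefault(node, set()).add(other)

    def add_edge(self, source: str, target: str, relation: str,
                 provenance=None) -> None:
        if relation not in RELATION_CLASSES:
            raise ValidationError(f"unknown relation {relation!r}")
        if relation == GENE_GENE and source > target:
            source, target = target, source
        for ep in (source, target):
            if ep not in self.node_classes:
                raise ValidationError(f"edge endpoint {ep!r} not in network")
        prov = self._edges.setdefault((source, target, relation), set())
        if provenance is not None:
            prov.add(provenance)

    # -- accessors ---------------------------------------------------------

    def edge_keys(self) -> list[tuple[str, str, str]]:
        return sorted(self._edges)

    def provenance(self, source: str, target: str, relation: str) -> set:
        if relation == GENE_GENE and source > target:
            source, target = target, source
        return set(self._edges[(source, target, relation)])

    @property
    def n_nodes(self) -> int:
        return len(self.node_classes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def nodes_of_class(self, node_class: str) -> set[str]:
        return {n for n, c in self.node_classes.items() if c == node_class}

    def edge_counts_by_relation(self) -> dict[str, int]:
        out = {r: 0 for r in RELATIONS}
        for _, _, rel in self._edges:
            out[rel] += 1
        return out

    def to_undirected_simple(self) -> nx.Graph:
        """Direction ignored; parallel relations between one endpoint pair
        collapse to a single adjacency."""
        g = nx.Graph()
        g.add_nodes_from(self.node_classes)
        for src, tgt, _ in self._edges:
            g.add_edge(src, tgt)
        return g

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_per_class": {c: len(self.nodes_of_class(c))
                                for c in (GENE, MIRNA, TF)},
            "edges_per_relation": self.edge_counts_by_relation(),
        }


# ---------------------------------------------------------------------------
# construction from merged FFLs
# ---------------------------------------------------------------------------

def _expand_merged(m: MergedFFL):
    """Yield (source, target, relation, src_class, tgt_class) for one merged
    FFL's constituent edges."""
    if m.ffl_class in (TF_FFL, COMPOSITE_FFL):
        yield m.tf, m.mirna, TF_MIRNA, TF, MIRNA
    if m.ffl_class in (MIRNA_FFL, COMPOSITE_FFL):
        yield m.mirna, m.tf, MIRNA_TF, MIRNA, TF
    for t in m.targets:
        if m.arity == "3-node":
            yield m.tf, t, TF_GENE, TF, GENE
            yield m.mirna, t, MIRNA_GENE, MIRNA, GENE
        else:
            g1, g2 = t
            yield g1, g2, GENE_GENE, GENE, GENE
            # the merged record no longer distinguishes which cross edges
            # were present; both regulators connect to both pair members
            for g in (g1, g2):
                yield m.tf, g, TF_GENE, TF, GENE
                yield m.mirna, g, MIRNA_GENE, MIRNA, GENE


def build_network(merged: Sequence[MergedFFL]) -> RegulatoryNetwork:
    """Union of all merged FFLs' nodes and typed edges, with provenance.

    Idempotent: adding the same FFL twice yields an identical network.
    """
    net = RegulatoryNetwork()
    for m in merged:
        key = (m.tf, m.mirna, m.arity)
        for src, tgt, rel, scls, tcls in _expand_merged(m):
            net.add_node(src, scls)
            net.add_node(tgt, tcls)
            net.add_edge(src, tgt, rel, provenance=key)
    logger.info("build_network: %d nodes, %d edges from %d merged FFLs",
                net.n_nodes, net.n_edges, len(merged))
    return net


def build_network_from_ffls(ffls) -> RegulatoryNetwork:
    """Build directly from unmerged FFL3/FFL4 instances, preserving which
    optional 4-node cross edges were actually observed."""
    net = RegulatoryNetwork()
    for f in ffls:
        key = (f.tf, f.mirna, f.arity)
        for src, tgt, rel in f.edges():
            scls, tcls = RELATION_CLASSES[rel]
            net.add_node(src, scls)
            net.add_node(tgt, tcls)
            net.add_edge(src, tgt, rel, provenance=key)
    return net


def composite_subnetwork(merged: Sequence[MergedFFL]) -> RegulatoryNetwork:
    """The network built from composite-class FFLs only (its edge set is a
    subset of the full network's)."""
    return build_network([m for m in merged
                          if m.ffl_class == COMPOSITE_FFL])


def seeded_subnetwork(merged: Sequence[MergedFFL],
                      seeds: set[str]) -> RegulatoryNetwork:
    """Network from exactly the merged FFLs touching a seed node (as TF,
    miRNA, or any joint target / pair member)."""
    if not seeds:
        raise ValidationError("seeds must be non-empty")

    def touches(m: MergedFFL) -> bool:
        if m.tf in seeds or m.mirna in seeds:
            return True
        for t in m.targets:
            members = t if isinstance(t, tuple) else (t,)
            if seeds & set(members):
                return True
        return False

    return build_network([m for m in merged if touches(m)])


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def degree_summary(network: RegulatoryNetwork) -> dict:
    """Per-class degree stats on the undirected simple projection, plus the
    fraction-of-nodes-per-degree table."""
    g = network.to_undirected_simple()
    out: dict = {"per_class": {}, "degree_distribution": {}}
    degrees = dict(g.degree())
    for cls in (GENE, MIRNA, TF):
        vals = sorted(degrees[n] for n in network.nodes_of_class(cls))
        if not vals:
            continue
        out["per_class"][cls] = {
            "n": len(vals),
            "min": vals[0],
            "max": vals[-1],
            "mean": sum(vals) / len(vals),
        }
    if degrees:
        n = len(degrees)
        table: dict[int, float] = {}
        for d in degrees.values():
            table[d] = table.get(d, 0) + 1
        out["degree_distribution"] = {str(d): c / n
                                      for d, c in sorted(table.items())}
    return out


@dataclass(frozen=True)
class HubReport:
    node_class: str
    cutoff: int
    hubs: tuple[str, ...]
    quantile: float


def find_hubs(network: RegulatoryNetwork,
              quantile: float = DEFAULT_HUB_QUANTILE) -> list[HubReport]:
    """Per-class top-quantile hub calling with a median guard.

    The cutoff is the smallest degree among the top-ceil(quantile * n) nodes
    of the class by degree; hubs are the nodes with degree >= cutoff whose
    degree also strictly exceeds the class median (so degree-uniform classes
    yield no hubs). Classes with fewer than 5 nodes are skipped.
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0, 1)")
    import math
    import statistics
    g = network.to_undirected_simple()
    degrees = dict(g.degree())
    reports = []
    for cls in (GENE, MIRNA, TF):
        nodes = sorted(network.nodes_of_class(cls))
        if not nodes:
            continue
        if len(nodes) < MIN_CLASS_SIZE_FOR_HUBS:
            logger.warning("find_hubs: class %s has %d nodes (<%d), skipped",
                           cls, len(nodes), MIN_CLASS_SIZE_FOR_HUBS)
            continue
        degs = sorted((degrees[n] for n in nodes), reverse=True)
        k = math.ceil(quantile * len(nodes))
        cutoff = degs[k - 1]
        median = statistics.median(degs)
        hubs = tuple(sorted(n for n in nodes
                            if degrees[n] >= cutoff and degrees[n] > median))
        reports.append(HubReport(cls, cutoff, hubs, quantile))
    return reports


def feedback_loops(source) -> list[tuple[str, str]]:
    """Unique (tf, mirna) pairs with reciprocal regulation (TF→miRNA and
    miRNA→TF). Accepts a RegulatoryNetwork or an EdgeStore."""
    if isinstance(source, RegulatoryNetwork):
        keys = set(source.edge_keys())
        t2m = {(s, t) for s, t, r in keys if r == TF_MIRNA}
        m2t = {(t, s) for s, t, r in keys if r == MIRNA_TF}
    else:
        t2m = {(e.source, e.target) for e in source.by_relation(TF_MIRNA)}
        m2t = {(e.target, e.source) for e in source.by_relation(MIRNA_TF)}
    return sorted(t2m & m2t)


@dataclass(frozen=True)
class Community:
    members: frozenset[str]
    k: int


def k_clique_communities(network: RegulatoryNetwork | nx.Graph,
                         k: int = DEFAULT_COMMUNITY_K) -> list[Community]:
    """Clique-percolation communities on the undirected simple projection.

    Communities are unions of k-cliques reachable through (k-1)-node
    overlaps; a node may belong to several communities. k = 2 reduces to
    connected components (of nodes with at least one edge).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    g = network.to_undirected_simple() \
        if isinstance(network, RegulatoryNetwork) else network
    comms = nx.community.k_clique_communities(g, k)
    out = [Community(frozenset(c), k) for c in comms]
    return sorted(out, key=lambda c: (-len(c.members), sorted(c.members)))


def ablate_nodes(network: RegulatoryNetwork,
                 removed: set[str]) -> tuple[RegulatoryNetwork, dict]:
    """Remove nodes and their incident edges; report component counts
    before/after (on the undirected simple projection)."""
    before = nx.number_connected_components(network.to_undirected_simple())
    out = RegulatoryNetwork()
    for node, cls in network.node_classes.items():
        if node not in removed:
            out.add_node(node, cls)
            for extra in network.extra_roles.get(node, ()):
                out.add_node(node, extra)
    for src, tgt, rel in network.edge_keys():
        if src in removed or tgt in removed:
            continue
        for prov in (network.provenance(src, tgt, rel) or {None}):
            out.add_edge(src, tgt, rel, provenance=prov)
    after = nx.number_connected_components(out.to_undirected_simple())
    return out, {"components_before": before, "components_after": after,
                 "removed": sorted(removed & set(network.node_classes))}
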