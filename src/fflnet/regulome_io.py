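"""Readers, writers and containers for regulatory nodes and edges.

The package works over three node classes — protein-coding genes, mature
miRNAs and transcription factors (TFs) — connected by five kinds of
regulatory relationship:

* ``TF-gene``     transcriptional regulation of a gene
* ``TF-miRNA``    transcriptional regulation of a miRNA
* ``miRNA-gene``  post-transcriptional repression of a gene
* ``miRNA-TF``    post-transcriptional repression of a TF gene
* ``gene-gene``   coexpression (undirected)

This module houses the typed edge container (:class:`EdgeStore`), flat-file
readers for node catalogs and edge tables, the TargetScan-style target
prediction filter, and network writers/readers (SIF, GraphML, edge-TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

logger = logging.getLogger("fflnet")

# ---------------------------------------------------------------------------
# relations and node classes
# ---------------------------------------------------------------------------

GENE = "gene"
MIRNA = "miRNA"
TF = "TF"

TF_GENE = "TF-gene"
TF_MIRNA = "TF-miRNA"
MIRNA_GENE = "miRNA-gene"
MIRNA_TF = "miRNA-TF"
GENE_GENE = "gene-gene"

RELATIONS = (TF_GENE, TF_MIRNA, MIRNA_GENE, MIRNA_TF, GENE_GENE)

#: required (source class, target class) per relation
RELATION_CLASSES = {
    TF_GENE: (TF, GENE),
    TF_MIRNA: (TF, MIRNA),
    MIRNA_GENE: (MIRNA, GENE),
    MIRNA_TF: (MIRNA, TF),
    GENE_GENE: (GENE, GENE),
}


class ValidationError(ValueError):
    """Input violated a documented contract."""


@dataclass(frozen=True)
class NodeCatalog:
    """The three node universes.

    An identifier may appear in both ``genes`` and ``tfs`` (dual-role nodes:
    TF genes that are themselves disease candidates); class checks accept
    either role for such nodes.
    """

    genes: frozenset[str]
    mirnas: frozenset[str]
    tfs: frozenset[str]

    def classes_of(self, node: str) -> set[str]:
        roles = set()
        if node in self.genes:
            roles.add(GENE)
        if node in self.mirnas:
            roles.add(MIRNA)
        if node in self.tfs:
            roles.add(TF)
        return roles

    def has_role(self, node: str, role: str) -> bool:
        return role in self.classes_of(node)

    @property
    def dual_role(self) -> frozenset[str]:
        """Identifiers present in both the gene and TF catalogs."""
        return self.genes & self.tfs


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """One typed regulatory edge.

    ``gene-gene`` edges are undirected and are stored with lexicographically
    ordered endpoints; ``score`` is ``None`` when the input carried no score
    column (never coerced to 0).
    """

    source: str
    target: str
    relation: str
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self):
        if self.relation not in RELATION_CLASSES:
            raise ValidationError(f"unknown relation {self.relation!r}")
        if self.source == self.target:
            raise ValidationError(f"self-edge {self.source!r} not allowed")
        if self.relation == GENE_GENE and self.source > self.target:
            raise ValidationError(
                "gene-gene edge endpoints must be canonically ordered; "
                "use make_edge()"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation)


def make_edge(source: str, target: str, relation: str,
              score: Optional[float] = None) -> RegulatoryEdge:
    """Build an edge, canonicalising undirected gene-gene endpoints."""
    if relation == GENE_GENE and source > target:
        source, target = target, source
    return RegulatoryEdge(source, target, relation, score)


class EdgeStore:
    """Deduplicated set of typed edges whose endpoints live in a catalog.

    Duplicate ``(source, target, relation)`` triples collapse to one edge;
    the first non-``None`` score wins.
    """

    def __init__(self, catalog: NodeCatalog,
                 edges: Iterable[RegulatoryEdge] = ()):
        self.catalog = catalog
        self._edges: dict[tuple[str, str, str], RegulatoryEdge] = {}
        for e in edges:
            self.add(e)

    def add(self, edge: RegulatoryEdge) -> None:
        src_cls, tgt_cls = RELATION_CLASSES[edge.relation]
        if not self.catalog.has_role(edge.source, src_cls):
            raise ValidationError(
                f"{edge.source!r} lacks role {src_cls} required by "
                f"{edge.relation}")
        if not self.catalog.has_role(edge.target, tgt_cls):
            raise ValidationError(
                f"{edge.target!r} lacks role {tgt_cls} required by "
                f"{edge.relation}")
        prev = self._edges.get(edge.key)
        if prev is None or (prev.score is None and edge.score is not None):
            self._edges[edge.key] = edge

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(sorted(self._edges.values()))

    def __contains__(self, key) -> bool:
        if isinstance(key, RegulatoryEdge):
            key = key.key
        return key in self._edges

    def has(self, source: str, target: str, relation: str) -> bool:
        if relation == GENE_GENE and source > target:
            source, target = target, source
        return (source, target, relation) in self._edges

    def by_relation(self, relation: str) -> list[RegulatoryEdge]:
        return [e for e in self if e.relation == relation]

    def targets_of(self, source: str, relation: str) -> set[str]:
        return {e.target for e in self._edges.values()
                if e.source == source and e.relation == relation}

    def sources_of(self, target: str, relation: str) -> set[str]:
        return {e.source for e in self._edges.values()
                if e.target == target and e.relation == relation}

    def merge(self, other: "EdgeStore") -> "EdgeStore":
        out = EdgeStore(self.catalog)
        for e in self:
            out.add(e)
        for e in other:
            out.add(e)
        return out


@dataclass(frozen=True)
class TargetPredictionRecord:
    """One miRNA→target prediction with conservation and efficacy fields.

    ``total_context_score`` is the summed per-site context score: a negative
    number where more negative means stronger predicted repression.
    ``species_with_site`` is the set of species codes in which a conserved
    target site was found.
    """

    mirna: str
    target: str
    total_context_score: float
    species_with_site: frozenset[str]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path) -> frozenset[str]:
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(line)
    if not ids:
        raise ValidationError(f"empty identifier file: {path}")
    return frozenset(ids)


def load_node_catalog(genes_path, mirnas_path, tfs_path) -> NodeCatalog:
    """Load the three node universes from one-id-per-line text files."""
    genes = _read_id_file(Path(genes_path))
    mirnas = _read_id_file(Path(mirnas_path))
    tfs = _read_id_file(Path(tfs_path))
    cat = NodeCatalog(genes, mirnas, tfs)
    logger.info("node catalog: %d genes, %d miRNAs, %d TFs (%d dual-role)",
                len(genes), len(mirnas), len(tfs), len(cat.dual_role))
    return cat


def load_edge_table(path, relation: str, catalog: NodeCatalog,
                    strict: bool = False) -> EdgeStore:
    """Load a 2–3 column TSV (source, target[, score]) of one relation.

    In non-strict mode rows with out-of-catalog endpoints are dropped with a
    logged count; in strict mode they raise with the offending row number.
    A header row is detected by a non-numeric third column or a first cell
    equal to 'source'.
    """
    if relation not in RELATION_CLASSES:
        raise ValidationError(f"unknown relation {relation!r}")
    store = EdgeStore(catalog)
    dropped = 0
    src_cls, tgt_cls = RELATION_CLASSES[relation]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns")
            src, tgt = parts[0].strip(), parts[1].strip()
            if lineno == 1 and src.lower() == "source":
                continue
            score: Optional[float] = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: bad score {parts[2]!r}") from exc
            ok = (catalog.has_role(src, src_cls)
                  and catalog.has_role(tgt, tgt_cls))
            if not ok:
                if strict:
                    raise ValidationError(
                        f"{path}:{lineno}: endpoint not in catalog under "
                        f"required class for {relation}: {src!r} -> {tgt!r}")
                dropped += 1
                continue
            store.add(make_edge(src, tgt, relation, score))
    if dropped:
        logger.info("load_edge_table(%s): dropped %d out-of-catalog rows",
                    relation, dropped)
    return store


def load_target_predictions(path) -> list[TargetPredictionRecord]:
    """Read a TargetScan-style TSV: mirna, target, total_context_score,
    species (comma-joined codes)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "mirna":
                continue
            if len(parts) < 4:
                raise ValidationError(
                    f"{path}:{lineno}: expected 4 columns")
            records.append(TargetPredictionRecord(
                mirna=parts[0].strip(),
                target=parts[1].strip(),
                total_context_score=float(parts[2]),
                species_with_site=frozenset(
                    s.strip() for s in parts[3].split(",") if s.strip()),
            ))
    return records


#: species codes the TargetScan-style filter understands by default
KNOWN_SPECIES = frozenset({"hsa", "mmu", "rno", "cfa"})

#: default conservation requirement: human, mouse, rat, dog
DEFAULT_REQUIRED_SPECIES = frozenset({"hsa", "mmu", "rno", "cfa"})

DEFAULT_CONTEXT_SCORE_CUTOFF = -0.30


def filter_target_predictions(
    records: Iterable[TargetPredictionRecord],
    catalog: NodeCatalog,
    required_species: frozenset[str] = DEFAULT_REQUIRED_SPECIES,
    score_cutoff: float = DEFAULT_CONTEXT_SCORE_CUTOFF,
    known_species: frozenset[str] = KNOWN_SPECIES,
    keep_if: str = "le",
) -> EdgeStore:
    """Apply the conservation + context-score filter to predicted targets.

    A record is kept when its site is conserved in every required species and
    its total context score passes the cutoff. Context scores are negative
    with more-negative meaning stronger repression, so the default comparator
    ``keep_if='le'`` keeps scores ≤ cutoff (boundary inclusive); ``'ge'`` is
    available for score conventions where larger is stronger.

    Kept records are emitted as ``miRNA-gene`` or ``miRNA-TF`` edges according
    to the target's catalog class (both, for dual-role targets).
    """
    if not required_species:
        raise ValidationError("required_species must be non-empty")
    unknown = required_species - known_species
    if unknown:
        raise ValidationError(f"unknown species codes: {sorted(unknown)}")
    if keep_if not in ("le", "ge"):
        raise ValidationError("keep_if must be 'le' or 'ge'")
    store = EdgeStore(catalog)
    kept = dropped = 0
    for rec in records:
        bad = rec.species_with_site - known_species
        if bad:
            raise ValidationError(
                f"record {rec.mirna}->{rec.target}: unknown species {sorted(bad)}")
        passes_score = (rec.total_context_score <= score_cutoff
                        if keep_if == "le"
                        else rec.total_context_score >= score_cutoff)
        if not passes_score or not required_species <= rec.species_with_site:
            dropped += 1
            continue
        kept += 1
        roles = catalog.classes_of(rec.target)
        if GENE in roles:
            store.add(make_edge(rec.mirna, rec.target, MIRNA_GENE,
                                rec.total_context_score))
        if TF in roles:
            store.add(make_edge(rec.mirna, rec.target, MIRNA_TF,
                                rec.total_context_score))
    logger.info("filter_target_predictions: kept %d, dropped %d", kept, dropped)
    return store


# ---------------------------------------------------------------------------
# network writers / readers
# ---------------------------------------------------------------------------

def write_network(network, path, fmt: str = "tsv") -> None:
    """Write a RegulatoryNetwork as SIF, GraphML or edge-TSV.

    SIF lines are ``source<TAB>relation<TAB>target``; edge-TSV adds a header
    and a node-class sidecar section so the file round-trips classes exactly.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for src, tgt, rel in sorted(network.edge_keys()):
                fh.write(f"{src}\t{rel}\t{tgt}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#node\tclass\n")
            for node, cls in sorted(network.node_classes.items()):
                fh.write(f"#node\t{node}\t{cls}\n")
            fh.write("source\trelation\ttarget\n")
            for src, tgt, rel in sorted(network.edge_keys()):
                fh.write(f"{src}\t{rel}\t{tgt}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for node, cls in network.node_classes.items():
            g.add_node(node, node_class=cls)
        for src, tgt, rel in network.edge_keys():
            g.add_edge(src, tgt, relation=rel)
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "tsv", node_classes: dict | None = None):
    """Read a network written by :func:`write_network`.

    SIF carries no node classes, so they must be supplied (or are inferred
    from the relations, which is exact for non-dual-role nodes).
    """
    from .network_analysis import RegulatoryNetwork  # local: avoid cycle

    fmt = fmt.lower()
    path = Path(path)
    net = RegulatoryNetwork()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.add_node(node, data["node_class"])
        for src, tgt, data in g.edges(data=True):
            net.add_edge(src, tgt, data["relation"])
        return net
    if fmt not in ("sif", "tsv"):
        raise ValidationError(f"unknown network format {fmt!r}")
    classes = dict(node_classes or {})
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#node\t"):
                parts = line.split("\t")
                if len(parts) == 3:
                    classes[parts[1]] = parts[2]
                continue
            if line.startswith("#") or line.startswith("source\t"):
                continue
            src, rel, tgt = line.split("\t")
            triples.append((src, tgt, rel))
    for src, tgt, rel in triples:
        src_cls, tgt_cls = RELATION_CLASSES[rel]
        net.add_node(src, classes.get(src, src_cls))
        net.add_node(tgt, classes.get(tgt, tgt_cls))
        net.add_edge(src, tgt, rel)
    return net
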