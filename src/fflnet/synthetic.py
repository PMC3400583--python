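"""Seeded generators for every input the pipeline consumes, with recorded
ground truth.

The generators emulate the study's input classes at configurable scale:
regulatory edge sets with planted FFLs of each class and arity over
background edge noise, expression matrices with planted dependency chains,
promoter sequences with planted motif sites, and annotation maps with a
controlled pair-sharing rate. All randomness flows through
``numpy.random.default_rng(seed)`` (PCG64), recorded in output sidecars, so
every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .coexpression import ExpressionMatrix
from .ffl_discovery import COMPOSITE_FFL, FFL_CLASSES, MIRNA_FFL, TF_FFL
from .motif_scan import PWM, PromoterRecord
from .regulome_io import (EdgeStore, GENE, GENE_GENE, MIRNA, MIRNA_GENE,
                          MIRNA_TF, NodeCatalog, TF, TF_GENE, TF_MIRNA,
                          ValidationError, make_edge)

logger = logging.getLogger("fflnet")

RNG_ALGORITHM = "numpy.random.PCG64"

#: default background densities per relation (sparse, so planted structure
#: dominates but incidental FFLs can occur, as in real edge sets)
DEFAULT_DENSITIES = {
    TF_GENE: 0.05,
    TF_MIRNA: 0.05,
    MIRNA_GENE: 0.05,
    MIRNA_TF: 0.05,
    GENE_GENE: 0.05,
}


@dataclass
class RegulomeSimSpec:
    """Scale, background densities and planted-FFL counts for one simulated
    regulome. ``planted`` maps (ffl_class, arity) -> count, e.g.
    ``{("TF-FFL", "3-node"): 5}``."""

    n_tf: int = 20
    n_mirna: int = 15
    n_gene: int = 40
    background_density: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    planted: dict = field(default_factory=dict)
    #: joint targets (3-node) or coexpressed pairs (4-node) per planted
    #: regulator pair; >1 makes planted pairs detectable by the
    #: co-targeting significance filter
    targets_per_ffl: int = 1
    seed: int = 0

    def __post_init__(self):
        for rel, d in self.background_density.items():
            if not 0 <= d <= 1:
                raise ValidationError(f"density for {rel} outside [0, 1]")
        for (cls, arity), cnt in self.planted.items():
            if cls not in FFL_CLASSES or arity not in ("3-node", "4-node"):
                raise ValidationError(f"bad planted key {(cls, arity)!r}")
            if cnt < 0:
                raise ValidationError("planted counts must be >= 0")
        if self.targets_per_ffl < 1:
            raise ValidationError("targets_per_ffl must be >= 1")


@dataclass
class PlantedTruth:
    """What was planted: FFL descriptors and the exact planted edges."""

    ffls: list  # dicts: {class, arity, tf, mirna, gene | gene_pair}
    edges: list  # (source, target, relation) triples

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rng": RNG_ALGORITHM, "ffls": self.ffls,
                       "edges": self.edges}, fh, indent=2)


def _catalog(spec: RegulomeSimSpec) -> NodeCatalog:
    return NodeCatalog(
        genes=frozenset(f"G{i:03d}" for i in range(spec.n_gene)),
        mirnas=frozenset(f"miR-{i:03d}" for i in range(spec.n_mirna)),
        tfs=frozenset(f"TF{i:03d}" for i in range(spec.n_tf)),
    )


def gen_regulome(spec: RegulomeSimSpec) -> tuple[EdgeStore, PlantedTruth]:
    """Plant the requested FFLs, then sprinkle background edges.

    Each planted 3-node FFL gets a fresh (TF, miRNA, gene) triple with its
    class-defining regulator edges; each 4-node FFL gets a fresh gene pair
    with the required template edges plus one optional cross edge chosen at
    random. Background edges are added afterwards per relation density and
    never remove planted edges (background may create incidental FFLs; the
    truth records planted ones only).
    """
    rng = np.random.default_rng(spec.seed)
    catalog = _catalog(spec)
    tfs = sorted(catalog.tfs)
    mirnas = sorted(catalog.mirnas)
    genes = sorted(catalog.genes)

    n_plants = sum(spec.planted.values())
    k = spec.targets_per_ffl
    genes_needed = sum(cnt * k * (1 if arity == "3-node" else 2)
                       for (cls, arity), cnt in spec.planted.items())
    if (n_plants > min(spec.n_tf, spec.n_mirna)
            or genes_needed > spec.n_gene):
        raise ValidationError(
            "node counts too small to host the requested planted FFLs")

    # disjoint node assignment keeps planted FFLs unambiguous
    tf_pool = list(rng.permutation(tfs))
    mir_pool = list(rng.permutation(mirnas))
    gene_pool = list(rng.permutation(genes))

    store = EdgeStore(catalog)
    truth = PlantedTruth([], [])

    def add(src, tgt, rel):
        store.add(make_edge(src, tgt, rel))
        truth.edges.append((src, tgt, rel))

    for (cls, arity), cnt in sorted(spec.planted.items()):
        for _ in range(cnt):
            tf, mi = tf_pool.pop(), mir_pool.pop()
            if cls in (TF_FFL, COMPOSITE_FFL):
                add(tf, mi, TF_MIRNA)
            if cls in (MIRNA_FFL, COMPOSITE_FFL):
                add(mi, tf, MIRNA_TF)
            for _ in range(k):
                if arity == "3-node":
                    g = gene_pool.pop()
                    add(tf, g, TF_GENE)
                    add(mi, g, MIRNA_GENE)
                    truth.ffls.append({"class": cls, "arity": arity,
                                       "tf": tf, "mirna": mi, "gene": g})
                else:
                    g1, g2 = sorted((gene_pool.pop(), gene_pool.pop()))
                    add(g1, g2, GENE_GENE)
                    add(tf, g1, TF_GENE)
                    add(mi, g2, MIRNA_GENE)
                    # one of the two optional cross edges, at random
                    if rng.random() < 0.5:
                        add(tf, g2, TF_GENE)
                    else:
                        add(mi, g1, MIRNA_GENE)
                    truth.ffls.append({"class": cls, "arity": arity,
                                       "tf": tf, "mirna": mi,
                                       "gene_pair": [g1, g2]})

    pools = {
        TF_GENE: (tfs, genes), TF_MIRNA: (tfs, mirnas),
        MIRNA_GENE: (mirnas, genes), MIRNA_TF: (mirnas, tfs),
        GENE_GENE: (genes, genes),
    }
    for rel in sorted(spec.background_density):
        density = spec.background_density[rel]
        if density <= 0:
            continue
        srcs, tgts = pools[rel]
        mask = rng.random((len(srcs), len(tgts))) < density
        for i, j in zip(*np.nonzero(mask)):
            s, t = srcs[i], tgts[j]
            if s == t:
                continue
            store.add(make_edge(s, t, rel))
    logger.info("gen_regulome: %d planted FFLs, %d edges total",
                len(truth.ffls), len(store))
    return store, truth


def gen_expression(dependency_edges: Sequence[tuple[str, str]],
                   n_samples: int = 200, noise_sd: float = 0.5,
                   seed: int = 0, n_genes: Optional[int] = None
                   ) -> ExpressionMatrix:
    """Forest of parent→child Gaussian dependency chains.

    Root genes are standard normal; each child is its parent plus Gaussian
    noise of standard deviation ``noise_sd``, rescaled to unit variance so
    that ``noise_sd`` acts as a per-edge relative noise level (the
    parent-child correlation is 1/sqrt(1 + noise_sd^2) at every depth and
    all dependence vanishes in the large-noise limit). Independent
    standard-normal genes are appended up to ``n_genes`` when requested.
    Cyclic dependency input is rejected.
    """
    rng = np.random.default_rng(seed)
    children: dict[str, list[str]] = {}
    parents: dict[str, str] = {}
    nodes: list[str] = []
    for parent, child in dependency_edges:
        if child in parents:
            raise ValidationError(
                f"{child!r} has two parents; dependencies must form a forest")
        parents[child] = parent
        children.setdefault(parent, []).append(child)
        for g in (parent, child):
            if g not in nodes:
                nodes.append(g)
    # cycle check by following parent links
    for g in nodes:
        seen = set()
        while g in parents:
            if g in seen:
                raise ValidationError("cyclic dependency input")
            seen.add(g)
            g = parents[g]

    values: dict[str, np.ndarray] = {}

    def realise(g: str) -> np.ndarray:
        if g not in values:
            if g in parents:
                raw = realise(parents[g]) + \
                    rng.normal(0.0, noise_sd, n_samples)
                values[g] = raw / np.sqrt(1.0 + noise_sd ** 2)
            else:
                values[g] = rng.normal(0.0, 1.0, n_samples)
        return values[g]

    for g in nodes:
        realise(g)
    if n_genes is not None:
        i = 0
        while len(nodes) < n_genes:
            name = f"IND{i:03d}"
            if name not in values:
                nodes.append(name)
                values[name] = rng.normal(0.0, 1.0, n_samples)
            i += 1
    mat = np.vstack([values[g] for g in nodes]) if nodes else \
        np.empty((0, n_samples))
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(nodes, samples, mat)


def gen_promoters(pwm: PWM, n_background: int,
                  plants: Sequence[tuple[str, str, int]] = (),
                  length: int = 500, seed: int = 0
                  ) -> list[PromoterRecord]:
    """Uniform-nucleotide background promoters plus consensus plants.

    ``plants`` entries are (node, species, offset); the PWM consensus is
    written at the offset into an otherwise-random sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def random_seq() -> list[str]:
        return list(rng.choice(bases, size=length))

    records = []
    for node, species, offset in plants:
        if offset < 0 or offset + pwm.length > length:
            raise ValidationError(
                f"plant offset {offset} invalid for length {length}")
        seq = random_seq()
        seq[offset:offset + pwm.length] = list(pwm.consensus)
        records.append(PromoterRecord(node, species, "".join(seq)))
    for i in range(n_background):
        records.append(PromoterRecord(f"BG{i:03d}", "hsa",
                                      "".join(random_seq())))
    return records


def gen_annotations(ids: Sequence[str], n_terms: int,
                    sharing_rate: float, seed: int = 0,
                    pair_list: Sequence[tuple[str, str]] = ()
                    ) -> dict[str, set[str]]:
    """Annotation map in which a designated fraction of ``pair_list`` shares
    at least one term.

    Every id first receives its own private term; each designated pair then
    receives a shared term with probability ``sharing_rate``.
    """
    if not 0 <= sharing_rate <= 1:
        raise ValidationError("sharing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    annotation = {i: {f"T_priv_{i}"} for i in ids}
    terms = [f"T{j:03d}" for j in range(max(n_terms, 1))]
    for idx, (a, b) in enumerate(pair_list):
        annotation.setdefault(a, {f"T_priv_{a}"})
        annotation.setdefault(b, {f"T_priv_{b}"})
        if rng.random() < sharing_rate:
            term = terms[idx % len(terms)] + f"_shared_{idx}"
            annotation[a].add(term)
            annotation[b].add(term)
    return annotation


# ---------------------------------------------------------------------------
# file emission (the generators double as fixture writers for the CLI)
# ---------------------------------------------------------------------------

def write_regulome(store: EdgeStore, truth: PlantedTruth, outdir) -> dict:
    """Emit node catalogs, per-relation edge TSVs and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ids in (("genes", store.catalog.genes),
                      ("mirnas", store.catalog.mirnas),
                      ("tfs", store.catalog.tfs)):
        p = outdir / f"{name}.txt"
        p.write_text("\n".join(sorted(ids)) + "\n")
        paths[name] = str(p)
    for rel in (TF_GENE, TF_MIRNA, MIRNA_GENE, MIRNA_TF, GENE_GENE):
        p = outdir / f"edges_{rel.replace('-', '_')}.tsv"
        with open(p, "w") as fh:
            for e in store.by_relation(rel):
                fh.write(f"{e.source}\t{e.target}\n")
        paths[rel] = str(p)
    truth.to_json(outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    with open(outdir / "sidecar.json", "w") as fh:
        json.dump({"rng": RNG_ALGORITHM}, fh)
    return paths
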