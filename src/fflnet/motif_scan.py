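"""Match-style PWM scanning of promoter windows.

TF→gene and TF→miRNA edges are predicted by scanning TSS-proximal promoter
windows (default −1500/+500) with position weight matrices, scoring every
window on both strands with the information-weighted similarity used by the
Match family of tools:

    matrix_score = (Current − Min) / (Max − Min)
    Current      = Σ_i I(i) · f(i, b_i)

where f(i, b) is the column-normalised base frequency, I(i) an information
weight per position, and Min/Max the analogous sums using the per-position
minimum/maximum frequencies. The core score applies the same formula to the
five consecutive positions of highest information content. A predicted pair
is kept only when it has at least one hit in every required species
(human/mouse/rat conservation by default).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .regulome_io import (EdgeStore, GENE, MIRNA, NodeCatalog, TF, TF_GENE,
                          TF_MIRNA, ValidationError, make_edge)

logger = logging.getLogger("fflnet")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CORE_LENGTH = 5
DEFAULT_CORE_CUTOFF = 1.00
DEFAULT_MATRIX_CUTOFF = 0.95
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_WINDOW = (-1500, 500)
ALT_WINDOW = (-1000, 500)  # upstream-1kb variant


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position count matrix with its information weights and core block.

    ``counts`` has shape (4, L) with rows ordered A, C, G, T. Frequencies are
    computed per column after adding ``pseudocount`` to every cell, making
    scores invariant to a positive rescaling of the counts. The information
    weight is I(i) = Σ_b f(i,b)·ln(4·f(i,b)); the core is the 5-position
    (or full-length, if shorter) window maximising Σ I(i), leftmost on ties.
    """

    name: str
    counts: tuple  # tuple of 4 tuples for hashability
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        m = np.asarray(self.counts, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValidationError(f"PWM {self.name}: counts must be 4 x L")
        if np.any(m < 0) or np.any(m.sum(axis=0) <= 0):
            raise ValidationError(
                f"PWM {self.name}: counts must be nonnegative with positive "
                "column sums")

    @property
    def length(self) -> int:
        return len(self.counts[0])

    @property
    def frequencies(self) -> np.ndarray:
        m = np.asarray(self.counts, dtype=float) + self.pseudocount
        return m / m.sum(axis=0, keepdims=True)

    @property
    def information_vector(self) -> np.ndarray:
        f = self.frequencies
        return (f * np.log(4.0 * f)).sum(axis=0)

    @property
    def core_positions(self) -> range:
        info = self.information_vector
        w = min(CORE_LENGTH, self.length)
        sums = [info[i:i + w].sum() for i in range(self.length - w + 1)]
        start = int(np.argmax(sums))  # argmax is leftmost on ties
        return range(start, start + w)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmin(axis=0))


def make_pwm(name: str, counts, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    m = np.asarray(counts, dtype=float)
    return PWM(name, tuple(tuple(row) for row in m), pseudocount)


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter window sequence for one node in one species."""

    node: str
    species: str
    sequence: str
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        if re.search(r"[^ACGTN]", self.sequence):
            raise ValidationError(
                f"promoter {self.node}/{self.species}: sequence must be over "
                "A/C/G/T/N")


@dataclass(frozen=True)
class MotifHit:
    """One PWM match: window offset (0-based on the given sequence), strand,
    and the two similarity scores."""

    tf: str
    node: str
    species: str
    position: int
    strand: str
    core_score: float
    matrix_score: float


def similarity_scores(pwm: PWM, window: str) -> tuple[float, float]:
    """Core and matrix similarity of one window, each normalised to [0, 1].

    The window must have the matrix length and contain no N (the scanner
    skips N windows before scoring).
    """
    if len(window) != pwm.length:
        raise ValidationError(
            f"window length {len(window)} != matrix length {pwm.length}")
    if "N" in window:
        raise ValidationError("window contains N; N windows are not scored")
    f = pwm.frequencies
    info = pwm.information_vector
    idx = np.fromiter((_BASE_INDEX[b] for b in window), dtype=int,
                      count=pwm.length)
    pos = np.arange(pwm.length)
    cur = info * f[idx, pos]
    lo = info * f.min(axis=0)
    hi = info * f.max(axis=0)

    def _norm(sel) -> float:
        rng = hi[sel].sum() - lo[sel].sum()
        if rng <= 0:  # fully uniform matrix: every window is a perfect match
            return 1.0
        return float((cur[sel].sum() - lo[sel].sum()) / rng)

    core = list(pwm.core_positions)
    return _norm(core), _norm(slice(None))


def scan_promoters(pwms: Sequence[PWM], promoters: Sequence[PromoterRecord],
                   core_cutoff: float = DEFAULT_CORE_CUTOFF,
                   matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF
                   ) -> list[MotifHit]:
    """All window positions on both strands passing both score cutoffs.

    Reverse-strand windows are scored on the reverse complement; positions
    always refer to the window start on the forward sequence. Floating-point
    comparisons use a 1e-12 slack so exact-consensus hits pass a 1.0 cutoff.
    """
    eps = 1e-12
    hits: list[MotifHit] = []
    for pwm in pwms:
        for prom in promoters:
            L = pwm.length
            seq = prom.sequence
            for pos in range(len(seq) - L + 1):
                window = seq[pos:pos + L]
                if "N" in window:
                    continue
                for strand, w in (("+", window),
                                  ("-", reverse_complement(window))):
                    core, matrix = similarity_scores(pwm, w)
                    if (core >= core_cutoff - eps
                            and matrix >= matrix_cutoff - eps):
                        hits.append(MotifHit(pwm.name, prom.node,
                                             prom.species, pos, strand,
                                             core, matrix))
    return hits


def conserved_tf_edges(hits_by_species: Mapping[str, Iterable[MotifHit]],
                       required_species: frozenset[str],
                       catalog: NodeCatalog) -> EdgeStore:
    """TF→node edges for pairs hit in every required species.

    Positions need not align across species; only pair-level presence is
    required. Edges are typed TF-gene or TF-miRNA by the target's catalog
    class (both for dual-role targets is impossible here because miRNA and
    gene catalogs are disjoint universes by construction).
    """
    if not required_species:
        raise ValidationError("required_species must be non-empty")
    missing = set(required_species) - set(hits_by_species)
    if missing:
        raise ValidationError(
            f"no hits supplied for required species: {sorted(missing)}")
    pair_sets = []
    for sp in sorted(required_species):
        pair_sets.append({(h.tf, h.node) for h in hits_by_species[sp]})
    conserved = set.intersection(*pair_sets) if pair_sets else set()
    store = EdgeStore(catalog)
    for tf, node in sorted(conserved):
        roles = catalog.classes_of(node)
        if MIRNA in roles:
            store.add(make_edge(tf, node, TF_MIRNA))
        if GENE in roles:
            store.add(make_edge(tf, node, TF_GENE))
    logger.info("conserved_tf_edges: %d conserved pairs -> %d edges",
                len(conserved), len(store))
    return store


# ---------------------------------------------------------------------------
# I/O: TRANSFAC flat files, simple TSV matrices, promoter FASTA, hit tables
# ---------------------------------------------------------------------------

def read_transfac(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Parse the TRANSFAC matrix flat-file dialect.

    Recognised records: ``ID`` or ``NA`` (matrix name), ``P0``/``PO`` column
    header, numbered position rows (``01  A-count C-count G-count T-count``),
    ``//`` record separator. Other fields are ignored.
    """
    pwms = []
    name: Optional[str] = None
    rows: list[list[float]] = []

    def flush():
        nonlocal name, rows
        if name is not None and rows:
            pwms.append(make_pwm(name, np.array(rows).T, pseudocount))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            tag = line[:2]
            if line.startswith("//"):
                flush()
            elif tag in ("ID", "NA") and name is None:
                name = line.split(None, 1)[1].strip()
            elif tag in ("P0", "PO"):
                continue
            elif re.match(r"^\d+\s", line):
                fields = line.split()
                rows.append([float(x) for x in fields[1:5]])
    flush()
    if not pwms:
        raise ValidationError(f"no matrices parsed from {path}")
    return pwms


def read_pwm_tsv(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Simple TSV alternative: blocks of '>name' then one line per position
    with four counts (A C G T)."""
    pwms = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None and rows:
                    pwms.append(make_pwm(name, np.array(rows).T, pseudocount))
                name, rows = line[1:].strip(), []
            else:
                rows.append([float(x) for x in line.split("\t")])
    if name is not None and rows:
        pwms.append(make_pwm(name, np.array(rows).T, pseudocount))
    return pwms


def read_promoter_fasta(path, window=DEFAULT_WINDOW) -> list[PromoterRecord]:
    """Read promoters from FASTA with headers ``nodeID|species|window``
    (window part optional, as 'up:down')."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise ValidationError(
                f"promoter FASTA header {rec.id!r}: expected nodeID|species")
        win = window
        if len(parts) >= 3 and ":" in parts[2]:
            up, down = parts[2].split(":")
            win = (int(up), int(down))
        records.append(PromoterRecord(parts[0], parts[1],
                                      str(rec.seq).upper(), win))
    return records


def write_hits(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tnode\tspecies\tposition\tstrand\tcore_score\t"
                 "matrix_score\n")
        for h in sorted(hits, key=lambda h: (h.tf, h.node, h.species,
                                             h.position, h.strand)):
            fh.write(f"{h.tf}\t{h.node}\t{h.species}\t{h.position}\t"
                     f"{h.strand}\t{h.core_score:.6f}\t{h.matrix_score:.6f}\n")
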