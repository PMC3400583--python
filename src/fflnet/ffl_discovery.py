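"""Feed-forward loop (FFL) enumeration, classification, significance testing
and merging.

A 3-node FFL is a TF and a miRNA jointly regulating one target gene
(TF→gene and miRNA→gene), with at least one regulatory relation between the
two regulators. The relation pattern between the regulators defines three
mutually exclusive classes:

* ``TF-FFL``        TF→miRNA only
* ``miRNA-FFL``     miRNA→TF only
* ``composite-FFL`` both directions (a TF↔miRNA feedback loop)

The 4-node FFL extends this with a coexpressed gene pair: the gene-gene
edge plus TF→g1 and miRNA→g2 are required, and at least one of TF→g2 /
miRNA→g1 must also be present.

Random TF–miRNA pairings are filtered by a cumulative hypergeometric
co-targeting test with Benjamini–Hochberg FDR control (q < 0.05), and
FFLs sharing one (TF, miRNA) regulation are merged into a single record
carrying the list of joint targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import comb
from typing import Iterable, Literal, Optional, Sequence

from scipy.stats import hypergeom

from .enrichment_stats import bh_fdr
from .regulome_io import (EdgeStore, GENE, MIRNA_GENE, MIRNA_TF, TF_GENE,
                          TF_MIRNA, ValidationError)

logger = logging.getLogger("fflnet")

TF_FFL = "TF-FFL"
MIRNA_FFL = "miRNA-FFL"
COMPOSITE_FFL = "composite-FFL"
FFL_CLASSES = (TF_FFL, MIRNA_FFL, COMPOSITE_FFL)

DEFAULT_ALPHA = 0.05
EXACT_TOTAL_LIMIT = 100  # rational-arithmetic hypergeometric path


@dataclass(frozen=True, order=True)
class FFL3:
    tf: str
    mirna: str
    gene: str
    ffl_class: str = field(compare=False)

    @property
    def arity(self) -> str:
        return "3-node"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf, self.mirna)

    def edges(self) -> list[tuple[str, str, str]]:
        """The constituent (source, target, relation) triples."""
        out = [(self.tf, self.gene, TF_GENE),
               (self.mirna, self.gene, MIRNA_GENE)]
        if self.ffl_class in (TF_FFL, COMPOSITE_FFL):
            out.append((self.tf, self.mirna, TF_MIRNA))
        if self.ffl_class in (MIRNA_FFL, COMPOSITE_FFL):
            out.append((self.mirna, self.tf, MIRNA_TF))
        return out


@dataclass(frozen=True, order=True)
class FFL4:
    tf: str
    mirna: str
    gene_pair: tuple[str, str]  # canonically ordered
    ffl_class: str = field(compare=False)
    #: which of the optional cross edges are present: TF→g2, miRNA→g1 under
    #: a labeling where TF→g1 and miRNA→g2 hold
    tf_targets: frozenset[str] = field(compare=False, default=frozenset())
    mirna_targets: frozenset[str] = field(compare=False, default=frozenset())

    @property
    def arity(self) -> str:
        return "4-node"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf, self.mirna)

    def edges(self) -> list[tuple[str, str, str]]:
        g1, g2 = self.gene_pair
        out = [(g1, g2, "gene-gene")]
        out += [(self.tf, g, TF_GENE) for g in sorted(self.tf_targets)]
        out += [(self.mirna, g, MIRNA_GENE)
                for g in sorted(self.mirna_targets)]
        if self.ffl_class in (TF_FFL, COMPOSITE_FFL):
            out.append((self.tf, self.mirna, TF_MIRNA))
        if self.ffl_class in (MIRNA_FFL, COMPOSITE_FFL):
            out.append((self.mirna, self.tf, MIRNA_TF))
        return out


@dataclass(frozen=True)
class CoTargetTest:
    """Hypergeometric co-targeting record for one (miRNA, TF) pair."""

    mirna: str
    tf: str
    m: int       # genes targeted by the miRNA
    n: int       # genes regulated by the TF
    x: int       # jointly targeted genes
    total: int   # common target universe size
    p: float
    q: Optional[float] = None


@dataclass(frozen=True)
class MergedFFL:
    """All FFLs sharing one (TF, miRNA) regulation: the pair plus its joint
    target list (genes for 3-node, canonical gene pairs for 4-node)."""

    tf: str
    mirna: str
    ffl_class: str
    targets: tuple
    arity: str

    def __post_init__(self):
        if not self.targets:
            raise ValidationError("MergedFFL requires at least one target")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("MergedFFL targets must be deduplicated")


# ---------------------------------------------------------------------------
# classification and enumeration
# ---------------------------------------------------------------------------

def classify_pair(tf: str, mirna: str, store: EdgeStore) -> Optional[str]:
    """FFL class from the regulator-pair relation pattern, or None."""
    t2m = store.has(tf, mirna, TF_MIRNA)
    m2t = store.has(mirna, tf, MIRNA_TF)
    if t2m and m2t:
        return COMPOSITE_FFL
    if t2m:
        return TF_FFL
    if m2t:
        return MIRNA_FFL
    return None


def _regulator_pairs(store: EdgeStore) -> dict[tuple[str, str], str]:
    """(tf, mirna) -> class, for every pair with a regulator relation."""
    pairs: dict[tuple[str, str], str] = {}
    cands = {(e.source, e.target) for e in store.by_relation(TF_MIRNA)}
    cands |= {(e.target, e.source) for e in store.by_relation(MIRNA_TF)}
    for tf, mirna in cands:
        cls = classify_pair(tf, mirna, store)
        if cls is not None:
            pairs[(tf, mirna)] = cls
    return pairs


def enumerate_3node(store: EdgeStore,
                    allowed_pairs: Optional[set[tuple[str, str]]] = None
                    ) -> list[FFL3]:
    """All 3-node FFLs, in canonical (tf, mirna, gene) order.

    ``allowed_pairs`` restricts output to significance-passing (tf, mirna)
    pairs when provided.
    """
    out = []
    for (tf, mirna), cls in _regulator_pairs(store).items():
        if allowed_pairs is not None and (tf, mirna) not in allowed_pairs:
            continue
        joint = (store.targets_of(tf, TF_GENE)
                 & store.targets_of(mirna, MIRNA_GENE))
        out.extend(FFL3(tf, mirna, g, cls) for g in joint)
    return sorted(out)


def enumerate_4node(store: EdgeStore,
                    allowed_pairs: Optional[set[tuple[str, str]]] = None
                    ) -> list[FFL4]:
    """All 4-node FFLs; each unordered gene pair reported once per
    (tf, mirna), even when both labelings satisfy the template."""
    gg = [(e.source, e.target) for e in store.by_relation("gene-gene")]
    out = []
    for (tf, mirna), cls in _regulator_pairs(store).items():
        if allowed_pairs is not None and (tf, mirna) not in allowed_pairs:
            continue
        tf_t = store.targets_of(tf, TF_GENE)
        mi_t = store.targets_of(mirna, MIRNA_GENE)
        for g1, g2 in gg:
            ok = False
            for a, b in ((g1, g2), (g2, g1)):
                # required: TF→a and miRNA→b; optional-but-one: TF→b or miRNA→a
                if (a in tf_t and b in mi_t
                        and (b in tf_t or a in mi_t)):
                    ok = True
                    break
            if ok:
                out.append(FFL4(tf, mirna, (g1, g2), cls,
                                frozenset({g1, g2} & tf_t),
                                frozenset({g1, g2} & mi_t)))
    return sorted(out)


# ---------------------------------------------------------------------------
# co-targeting significance
# ---------------------------------------------------------------------------

def cotarget_pvalue(m: int, n: int, x: int, total: int,
                    exact: bool | None = None) -> float:
    """Upper-tail cumulative hypergeometric P(X >= x) for the overlap of an
    m-set and an n-set drawn from a universe of ``total`` genes.

    ``exact=True`` (default for total <= 100) evaluates the tail in rational
    arithmetic; larger problems use the scipy survival function.
    """
    if not (0 <= x <= min(m, n) <= total) or m > total or n > total:
        raise ValidationError(
            f"invalid hypergeometric bounds m={m} n={n} x={x} total={total}")
    if x == 0:
        return 1.0
    if exact is None:
        exact = total <= EXACT_TOTAL_LIMIT
    if exact:
        denom = comb(total, n)
        num = sum(comb(m, k) * comb(total - m, n - k)
                  for k in range(x, min(m, n) + 1))
        return float(Fraction(num, denom))
    return float(hypergeom.sf(x - 1, total, m, n))


def cotarget_tests(store: EdgeStore,
                   pairs: Optional[Iterable[tuple[str, str]]] = None,
                   background: Optional[EdgeStore] = None,
                   total_override: Optional[int] = None) -> list[CoTargetTest]:
    """Run the co-targeting test for every candidate (tf, mirna) pair.

    Counts m (miRNA targets), n (TF-regulated genes) and x (joint targets)
    are taken from ``background`` when a genome-wide background store is
    supplied, else from the analysis store itself. ``total`` is the size of
    the intersection of all miRNA-targeted genes and all TF-regulated genes
    in that universe (gene-class targets only), overridable.
    """
    src = background if background is not None else store
    mirna_targets: dict[str, set[str]] = {}
    tf_targets: dict[str, set[str]] = {}
    for e in src.by_relation(MIRNA_GENE):
        mirna_targets.setdefault(e.source, set()).add(e.target)
    for e in src.by_relation(TF_GENE):
        tf_targets.setdefault(e.source, set()).add(e.target)
    all_mi = set().union(*mirna_targets.values()) if mirna_targets else set()
    all_tf = set().union(*tf_targets.values()) if tf_targets else set()
    universe = all_mi & all_tf
    total = total_override if total_override is not None else len(universe)
    logger.info("cotarget_tests: universe %d (%s)", total,
                "override" if total_override is not None else "computed")
    if pairs is None:
        pairs = sorted(_regulator_pairs(store))
    tests = []
    for tf, mirna in pairs:
        mset = mirna_targets.get(mirna, set()) & universe
        nset = tf_targets.get(tf, set()) & universe
        m, n, x = len(mset), len(nset), len(mset & nset)
        if total == 0 or m == 0 or n == 0:
            p = 1.0
        else:
            p = cotarget_pvalue(m, n, x, total)
        tests.append(CoTargetTest(mirna, tf, m, n, x, total, p))
    return tests


def significant_pairs(tests: Sequence[CoTargetTest],
                      alpha: float = DEFAULT_ALPHA) -> list[CoTargetTest]:
    """BH-adjust the co-targeting p-values and keep q < alpha (strict)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if not tests:
        return []
    qs = bh_fdr([t.p for t in tests])
    adjusted = [replace(t, q=q) for t, q in zip(tests, qs)]
    return [t for t in adjusted if t.q < alpha]


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_ffls(ffls: Sequence[FFL3] | Sequence[FFL4]) -> list[MergedFFL]:
    """Group FFLs of one arity by their (tf, mirna) regulation.

    The total target count over the merged records equals the number of
    input FFLs; the class is identical across members by construction.
    """
    arities = {f.arity for f in ffls}
    if len(arities) > 1:
        raise ValidationError("merge_ffls requires a single arity")
    groups: dict[tuple[str, str], list] = {}
    classes: dict[tuple[str, str], str] = {}
    for f in ffls:
        groups.setdefault(f.pair, []).append(
            f.gene if isinstance(f, FFL3) else f.gene_pair)
        classes[f.pair] = f.ffl_class
    out = []
    for pair in sorted(groups):
        targets = tuple(dict.fromkeys(sorted(groups[pair])))
        out.append(MergedFFL(pair[0], pair[1], classes[pair], targets,
                             next(iter(arities))))
    return out


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def format_target(t) -> str:
    return "|".join(t) if isinstance(t, tuple) else t


def write_merged_ffls(merged: Sequence[MergedFFL], path) -> None:
    """TSV: arity, class, tf, mirna, semicolon-joined targets (gene pairs
    joined by '|')."""
    with open(path, "w") as fh:
        fh.write("arity\tclass\ttf\tmirna\ttargets\n")
        for m in merged:
            ts = ";".join(format_target(t) for t in m.targets)
            fh.write(f"{m.arity}\t{m.ffl_class}\t{m.tf}\t{m.mirna}\t{ts}\n")


def write_cotarget_tests(tests: Sequence[CoTargetTest], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttf\tm\tn\tx\ttotal\tp\tq\n")
        for t in tests:
            q = "" if t.q is None else f"{t.q:.6g}"
            fh.write(f"{t.mirna}\t{t.tf}\t{t.m}\t{t.n}\t{t.x}\t{t.total}\t"
                     f"{t.p:.6g}\t{q}\n")
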