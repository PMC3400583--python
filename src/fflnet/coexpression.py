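"""Mutual-information coexpression inference with DPI pruning.

Gene–gene coexpression edges are inferred ARACNE-style: all-pairs mutual
information (MI), a permutation-calibrated significance threshold (default
P = 1e-7), then data-processing-inequality (DPI) pruning that removes the
weakest edge of each MI triangle within a relative tolerance (default 0.15)
to discard likely indirect interactions.

The MI estimator bins the copula transform (average ranks mapped to (0,1))
into equal-frequency cells, which makes the estimate exactly invariant to
strictly monotone transforms of either variable. Calibrating a 1e-7 tail
empirically would need >=1e7 permutations; by default an exponential tail is
fitted to the top 1% of the permutation null and extrapolated, with
``exact_tail=True`` available when the permutation budget covers the target
tail.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .regulome_io import (EdgeStore, GENE_GENE, NodeCatalog, ValidationError,
                          make_edge)

logger = logging.getLogger("fflnet")

MIN_SAMPLES = 8

DEFAULT_MI_PVALUE = 1.0e-7
DEFAULT_DPI_TOLERANCE = 0.15
DEFAULT_N_PERMUTATIONS = 100_000
TAIL_FRACTION = 0.01  # top fraction of the null used for the exponential fit


@dataclass
class ExpressionMatrix:
    """genes x samples expression values with no missing entries."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("values shape does not match genes x samples")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if len(self.samples) < MIN_SAMPLES:
            raise ValidationError(
                f"need >= {MIN_SAMPLES} samples for MI estimation")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def load_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header = sample ids).

    Rows with missing entries are rejected with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.isna().any(axis=1)
    if bad.any():
        logger.info("load_expression: dropping %d rows with missing values",
                    int(bad.sum()))
        df = df.loc[~bad]
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy(dtype=float))


@dataclass
class CoexpressionParams:
    """Tuning knobs for the MI pipeline (defaults follow the stringent
    published settings: P = 1e-7, DPI tolerance 0.15)."""

    mi_pvalue: float = DEFAULT_MI_PVALUE
    dpi_tolerance: float = DEFAULT_DPI_TOLERANCE
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    bins: int | str = "auto"
    seed: int = 0
    exact_tail: bool = False

    def __post_init__(self):
        if not 0 < self.mi_pvalue <= 1:
            raise ValidationError("mi_pvalue must be in (0, 1]")
        if not 0 <= self.dpi_tolerance <= 1:
            raise ValidationError("dpi_tolerance must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.exact_tail and self.n_permutations < 1 / self.mi_pvalue:
            raise ValidationError(
                "exact empirical calibration needs n_permutations >= "
                "1/mi_pvalue")


def _n_bins(n: int, bins: int | str) -> int:
    if bins == "auto":
        return max(2, round(n ** (1 / 3)))
    b = int(bins)
    if b < 2:
        raise ValidationError("bins must be >= 2")
    return b


def _bin_ranks(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels from average ranks (copula transform)."""
    u = rankdata(x, method="average") / (len(x) + 1)
    return np.minimum((u * n_bins).astype(int), n_bins - 1)


def mutual_information(x, y, bins: int | str = "auto") -> float:
    """MI in nats on equal-frequency rank bins.

    Invariant to strictly monotone transforms of either input; a constant
    vector occupies a single bin and yields MI = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValidationError(f"need >= {MIN_SAMPLES} samples")
    b = _n_bins(n, bins)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    bx = _bin_ranks(x, b)
    by = _bin_ranks(y, b)
    joint = np.zeros((b, b))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def null_mi_sample(n_samples: int, params: CoexpressionParams) -> np.ndarray:
    """Permutation-null MI draws: MI between independently shuffled rank
    sequences of length ``n_samples``, deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    base = np.arange(n_samples, dtype=float)
    out = np.empty(params.n_permutations)
    for i in range(params.n_permutations):
        out[i] = mutual_information(rng.permutation(base),
                                    rng.permutation(base), params.bins)
    return out


def mi_threshold(n_samples: int, params: CoexpressionParams,
                 null: np.ndarray | None = None) -> float:
    """MI value whose null exceedance probability is ``params.mi_pvalue``.

    When the permutation budget covers the target tail (or ``exact_tail``),
    the empirical (1 - p) quantile of the null sample is returned. Otherwise
    an exponential right tail is fitted to the top ``TAIL_FRACTION`` of the
    null and extrapolated:  P(MI > t) = q0 * exp(-(t - t0)/beta).
    """
    if params.mi_pvalue >= 1.0:
        return 0.0
    if null is None:
        null = null_mi_sample(n_samples, params)
    null = np.sort(np.asarray(null, dtype=float))
    n = len(null)
    if params.exact_tail or params.mi_pvalue >= 1.0 / n:
        return float(np.quantile(null, 1.0 - params.mi_pvalue))
    t0 = float(np.quantile(null, 1.0 - TAIL_FRACTION))
    tail = null[null > t0]
    if len(tail) == 0:  # degenerate null (e.g. all zeros)
        return float(null[-1])
    beta = float(np.mean(tail - t0))
    if beta <= 0:
        return t0
    return t0 + beta * math.log(TAIL_FRACTION / params.mi_pvalue)


def apply_dpi(mi_edges: dict[tuple[str, str], float],
              tolerance: float = DEFAULT_DPI_TOLERANCE
              ) -> dict[tuple[str, str], float]:
    """DPI pruning on a weighted gene-gene edge dict (canonical pair keys).

    For every triangle (i, j, k), edge (i, k) is marked for removal iff
    MI_ik < min(MI_ij, MI_jk) * (1 - tolerance). Marks are evaluated against
    the pre-pruning weights (two-pass), so the result is independent of edge
    order and pruning is idempotent.
    """
    if not 0 <= tolerance <= 1:
        raise ValidationError("tolerance must be in [0, 1]")
    edges = {(min(a, b), max(a, b)): w for (a, b), w in mi_edges.items()}
    neighbors: dict[str, set[str]] = {}
    for a, b in edges:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    doomed = set()
    for (a, b), w_ab in edges.items():
        for c in neighbors[a] & neighbors[b]:
            w_ac = edges[(min(a, c), max(a, c))]
            w_bc = edges[(min(b, c), max(b, c))]
            if w_ab < min(w_ac, w_bc) * (1.0 - tolerance):
                doomed.add((a, b))
                break
    return {k: w for k, w in edges.items() if k not in doomed}


def infer_coexpression(matrix: ExpressionMatrix,
                       params: CoexpressionParams | None = None,
                       catalog: NodeCatalog | None = None) -> EdgeStore:
    """All-pairs MI -> significance threshold -> DPI, as an EdgeStore.

    The returned store's catalog contains the matrix genes (or the supplied
    catalog); edge scores are the MI values. Reproducible given the seed.
    """
    params = params or CoexpressionParams()
    if len(matrix.genes) < 3:
        raise ValidationError("need at least 3 genes")
    thr = mi_threshold(matrix.n_samples, params)
    mi_edges: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(len(matrix.genes)), 2):
        mi = mutual_information(matrix.values[i], matrix.values[j],
                                params.bins)
        if mi > thr:
            a, b = sorted((matrix.genes[i], matrix.genes[j]))
            mi_edges[(a, b)] = mi
    kept = apply_dpi(mi_edges, params.dpi_tolerance)
    logger.info("infer_coexpression: threshold %.4f, %d/%d edges kept "
                "after DPI", thr, len(kept), len(mi_edges))
    if catalog is None:
        catalog = NodeCatalog(frozenset(matrix.genes), frozenset(),
                              frozenset())
    store = EdgeStore(catalog)
    for (a, b), w in sorted(kept.items()):
        store.add(make_edge(a, b, GENE_GENE, w))
    return store


def write_null_sample(null: np.ndarray, path) -> None:
    """Dump the permutation null (one MI per line) for threshold audit."""
    np.savetxt(path, np.asarray(null), fmt="%.8f", header="null_mi")
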