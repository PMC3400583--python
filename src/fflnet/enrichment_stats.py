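"""Statistical comparisons: permutation target enrichment, one-sided KS,
Fisher's exact test, shared-annotation testing and BH FDR.

These are the supporting tests used around the FFL analysis: does a miRNA
have more targets inside a candidate gene set than in random draws of the
same size; are similarity scores of co-targeted gene pairs stochastically
greater than those of random pairs; do co-targeted pairs share functional
annotation more often than random pairs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .regulome_io import ValidationError

logger = logging.getLogger("fflnet")

DEFAULT_N_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class TargetEnrichmentResult:
    """Permutation enrichment of one miRNA's targets in the candidate set.

    ``empirical_p`` uses the add-one correction (r + 1)/(N + 1) with r the
    number of permutations whose count >= observed, so it is never 0.
    """

    mirna: str
    observed: int
    null_mean: float
    empirical_p: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValidationError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("at least one count must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def permutation_target_enrichment(
    targets_of: Mapping[str, set],
    candidates: set,
    universe: set,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[list[TargetEnrichmentResult], dict]:
    """Per-miRNA permutation test of target counts in a candidate gene set.

    For each miRNA, ``observed`` is the number of its targets inside
    ``candidates``; the null redraws ``len(candidates)`` genes uniformly
    without replacement from ``universe`` ``n_perm`` times. The summary
    includes a paired t-test across miRNAs of observed counts against their
    per-miRNA null means (one plausible reading of a population-level
    "more targets than random" comparison); the per-miRNA empirical
    p-values are the primary output.
    """
    if not candidates <= universe:
        raise ValidationError("candidates must be a subset of universe")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    k = len(candidates)
    mirnas = sorted(targets_of)
    target_sets = {m: set(targets_of[m]) & universe for m in mirnas}
    counts = np.zeros((n_perm, len(mirnas)), dtype=int)
    for i in range(n_perm):
        draw = set(rng.choice(uni, size=k, replace=False))
        for j, m in enumerate(mirnas):
            counts[i, j] = len(target_sets[m] & draw)
    results = []
    for j, m in enumerate(mirnas):
        obs = len(target_sets[m] & candidates)
        r = int((counts[:, j] >= obs).sum())
        results.append(TargetEnrichmentResult(
            mirna=m, observed=obs, null_mean=float(counts[:, j].mean()),
            empirical_p=(r + 1) / (n_perm + 1),
            n_permutations=n_perm, seed=seed))
    observed = np.array([r.observed for r in results], dtype=float)
    null_means = np.array([r.null_mean for r in results])
    if len(results) >= 2 and np.ptp(observed - null_means) > 0:
        t_stat, t_p = stats.ttest_rel(observed, null_means,
                                      alternative="greater")
    else:
        t_stat, t_p = float("nan"), float("nan")
    summary = {
        "n_mirnas": len(results),
        "mean_observed": float(observed.mean()) if len(results) else math.nan,
        "mean_null": float(null_means.mean()) if len(results) else math.nan,
        "paired_t_statistic": float(t_stat),
        "paired_t_pvalue": float(t_p),
        "n_permutations": n_perm,
        "seed": seed,
    }
    return results, summary


def ks_greater(scores_a: Sequence[float],
               scores_b: Sequence[float]) -> tuple[float, float]:
    """One-sided two-sample KS test of "a stochastically greater than b".

    Returns D+ = sup_x (F_b(x) - F_a(x)) over right-continuous ECDFs and the
    asymptotic one-sided p-value exp(-2 D^2 mn/(m+n)). Identical samples give
    exactly (0, 1).
    """
    a = np.sort(np.asarray(scores_a, dtype=float))
    b = np.sort(np.asarray(scores_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    d = float(max(np.max(fb - fa), 0.0))
    mn = len(a) * len(b) / (len(a) + len(b))
    p = min(1.0, math.exp(-2.0 * mn * d * d))
    return d, p


def fisher_exact(table: ContingencyTable2x2,
                 alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (odds ratio, p)."""
    if alternative not in ("greater", "two-sided"):
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    odds, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(odds), float(p)


def shared_annotation_test(
    observed_pairs: Sequence[tuple[str, str]],
    null_pairs: Sequence[tuple[str, str]],
    annotation: Mapping[str, set],
    mode: str = "intersect",
) -> tuple[ContingencyTable2x2, float, float]:
    """Do observed pairs share annotation more often than null pairs?

    A pair "shares" iff its two term sets intersect (``mode='intersect'``)
    or are identical (``mode='exact'``). Pairs with an unannotated member
    are dropped with a logged count. Returns the 2x2 table
    (shared/unshared x observed/null) and the right-tailed Fisher result.
    """
    if mode not in ("intersect", "exact"):
        raise ValidationError("mode must be 'intersect' or 'exact'")

    def shares(p) -> bool | None:
        t1, t2 = annotation.get(p[0]), annotation.get(p[1])
        if not t1 or not t2:
            return None
        return bool(set(t1) & set(t2)) if mode == "intersect" else \
            set(t1) == set(t2)

    def count(pairs):
        shared = unshared = dropped = 0
        for p in pairs:
            s = shares(p)
            if s is None:
                dropped += 1
            elif s:
                shared += 1
            else:
                unshared += 1
        return shared, unshared, dropped

    so, uo, do = count(observed_pairs)
    sn, un, dn = count(null_pairs)
    if do or dn:
        logger.info("shared_annotation_test: dropped %d observed and %d "
                    "null pairs lacking annotation", do, dn)
    if so + uo == 0 or sn + un == 0:
        raise ValidationError("all pairs in one group were unannotated")
    table = ContingencyTable2x2(so, uo, sn, un)
    odds, p = fisher_exact(table, "greater")
    return table, odds, p


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must be in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def write_results_with_sidecar(rows: Iterable[Mapping], path,
                               params: Mapping) -> None:
    """Write a result TSV plus a JSON sidecar recording seeds/parameters."""
    rows = list(rows)
    from pathlib import Path
    path = Path(path)
    with open(path, "w") as fh:
        if rows:
            cols = list(rows[0])
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(dict(params), fh, indent=2, sort_keys=True)
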