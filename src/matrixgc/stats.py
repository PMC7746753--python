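"""Validation statistics: Fisher tissue contrasts, Monte Carlo DEG
enrichment, and permutation-control exclusion of enrichment terms."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, inf, nan
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Bound/expressed 2x2 table: a = bound & expressed, b = bound & not
    expressed, c = not bound & expressed, d = not bound & not expressed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class DegTestResult:
    """Monte Carlo permutation test of DEG percentage in a candidate set."""

    observed_pct: float
    null_pcts: tuple[float, ...]
    empirical_p: float
    n_permutations: int
    alpha: float
    n_candidates_used: int

    @property
    def observed_fraction(self) -> float:
        return self.observed_pct / 100.0


@dataclass(frozen=True)
class TermFilterResult:
    """Enrichment terms kept vs excluded by the permutation control."""

    kept_terms: frozenset[str]
    excluded_terms: frozenset[str]


def tissue_contingency(
    bound: Iterable[str],
    all_genes: Iterable[str],
    expression: Mapping[str, float],
    cutoff: float = 0.0,
) -> ContingencyTable2x2:
    """Tabulate bound-status against expression for one tissue.

    A gene is expressed iff its value is strictly greater than ``cutoff``
    (default 0, so an exact zero counts as not expressed). Genes without
    expression data are dropped with a logged count; ``bound`` must be a
    subset of ``all_genes``.
    """
    bound_set = set(bound)
    universe = set(all_genes)
    stray = bound_set - universe
    if stray:
        raise ValueError(f"bound genes not in all_genes: {sorted(stray)[:5]}")
    with_data = [g for g in universe if g in expression]
    n_dropped = len(universe) - len(with_data)
    if n_dropped:
        log.info("tissue_contingency: dropped %d gene(s) without expression data", n_dropped)
    if not with_data:
        raise ValueError("no genes with expression data")
    a = b = c = d = 0
    for g in with_data:
        expressed = expression[g] > cutoff
        if g in bound_set:
            a += expressed
            b += not expressed
        else:
            c += expressed
            d += not expressed
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities, under fixed margins, of
    every table no more probable than the observed one. The computation is in
    exact integer arithmetic (each table's probability has the common
    denominator C(n, a+c), so only the integer numerators C(r1, x) * C(r2,
    a+c-x) need comparing), which avoids any floating-point tie tolerance.

    Returns (odds_ratio, p). The sample odds ratio a*d / (b*c) is +inf when
    b*c == 0 and a*d > 0, and NaN (undefined) when both products are zero;
    degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    ad, bc = a * d, b * c
    if bc > 0:
        odds = ad / bc
    elif ad > 0:
        odds = inf
    else:
        odds = nan
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    num_sum = 0
    for x in range(lo, hi + 1):
        num_x = comb(r1, x) * comb(r2, c1 - x)
        if num_x <= num_obs:
            num_sum += num_x
    p = num_sum / comb(n, c1)
    return odds, min(1.0, float(p))


def monte_carlo_deg(
    candidates: Iterable[str],
    de_table: Mapping[str, float],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DegTestResult:
    """Permutation test of the DEG percentage in a candidate gene set.

    The observed statistic is the percentage of candidates (restricted to
    genes present in ``de_table``) with differential-expression p <= alpha.
    Each of ``n_perm`` permutations draws an equal-sized gene set without
    replacement from the whole ``de_table`` universe and records the same
    percentage. The empirical p-value uses the add-one convention
    (1 + #{null >= observed}) / (1 + n_perm), so it is never zero and ties
    count against the candidate set.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    universe = list(de_table.keys())
    pvals = np.array([de_table[g] for g in universe])
    sig = pvals <= alpha
    cand_set = set(candidates)
    used = [g for g in universe if g in cand_set]
    n_outside = len(cand_set) - len(used)
    if not used:
        raise ValueError(
            f"none of the {len(cand_set)} candidate genes are present in the DE table"
        )
    if n_outside:
        log.info("monte_carlo_deg: %d candidate gene(s) absent from DE table, dropped", n_outside)
    k = len(used)
    index = {g: i for i, g in enumerate(universe)}
    observed_pct = 100.0 * sig[[index[g] for g in used]].mean()
    rng = np.random.default_rng(seed)
    null_pcts = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=k, replace=False)
        null_pcts[i] = 100.0 * sig[draw].mean()
    empirical_p = (1 + int((null_pcts >= observed_pct).sum())) / (1 + n_perm)
    return DegTestResult(
        observed_pct=float(observed_pct),
        null_pcts=tuple(float(x) for x in null_pcts),
        empirical_p=float(empirical_p),
        n_permutations=n_perm,
        alpha=alpha,
        n_candidates_used=k,
    )


def exclude_control_terms(
    disorder_terms: Iterable[str],
    control_term_sets: Iterable[Iterable[str]],
) -> TermFilterResult:
    """Drop disorder-enriched terms that also surfaced in any control set.

    Terms significantly enriched in randomly generated size-matched control
    gene sets are treated as false-positive-prone and removed from the
    disorder results wherever they overlap.
    """
    disorder = frozenset(disorder_terms)
    control_union: set[str] = set()
    for s in control_term_sets:
        control_union.update(s)
    excluded = frozenset(disorder & control_union)
    return TermFilterResult(kept_terms=disorder - excluded, excluded_terms=excluded)
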