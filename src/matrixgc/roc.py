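"""ROC calibration of the PWM percent threshold against control gene sets.

Positives are top-ranked ChIP target genes; negatives are size-matched random
draws (without replacement) from the zero-score pool, repeated ``n_bootstrap``
times (10 by default) and averaged point-wise. At each threshold t on the grid
(5..100 step 5 by default) a gene counts as classified bound iff its promoter
has at least one PWM match at percent score >= t that passes the active GC
filter. TPR is the bound fraction of positives, FPR the bootstrap-averaged
bound fraction of negatives; the curve is anchored at (0,0) and (1,1), sorted
by FPR and integrated by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from matrixgc.matrix_gc import best_qualifying_score
from matrixgc.motif import PWM
from matrixgc.seqio import PromoterSeq

DEFAULT_GRID = tuple(range(5, 101, 5))


@dataclass(frozen=True)
class ControlSets:
    """Positive genes and the zero-score pool negatives are resampled from."""

    positives: tuple[str, ...]
    negative_pool: tuple[str, ...]
    sizes: tuple[int, ...] = (100, 200, 300)
    n_bootstrap: int = 10

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negative_pool)
        if overlap:
            raise ValueError(f"positives and negative pool overlap: {sorted(overlap)[:5]}...")
        for s in self.sizes:
            if s > len(self.negative_pool):
                raise ValueError(f"size {s} exceeds negative pool ({len(self.negative_pool)})")


@dataclass(frozen=True)
class RocCurve:
    """Threshold-stratified (FPR, TPR) points with trapezoidal AUC."""

    thresholds: tuple[float, ...]
    points: tuple[tuple[float, float], ...]  # (fpr, tpr), anchors included, sorted by fpr
    auc: float
    gc_threshold: float | None = None


def gene_tpr_fpr(bound_fraction_positives: float, bound_fraction_negatives: float) -> tuple[float, float]:
    """Map per-threshold bound fractions to an (FPR, TPR) point."""
    for v in (bound_fraction_positives, bound_fraction_negatives):
        if not 0 <= v <= 1:
            raise ValueError(f"bound fraction must be in [0, 1], got {v}")
    return (bound_fraction_negatives, bound_fraction_positives)


def roc_from_rates(
    thresholds: np.ndarray | tuple[float, ...],
    tprs: np.ndarray,
    fprs: np.ndarray,
    gc_threshold: float | None = None,
) -> RocCurve:
    """Assemble an anchored, sorted curve from per-threshold rates."""
    pts = list(zip(np.asarray(fprs, dtype=float), np.asarray(tprs, dtype=float)))
    pts.extend([(0.0, 0.0), (1.0, 1.0)])
    pts.sort()
    fpr_sorted = np.array([p[0] for p in pts])
    tpr_sorted = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr_sorted, fpr_sorted))
    return RocCurve(
        thresholds=tuple(float(t) for t in thresholds),
        points=tuple((float(f), float(t)) for f, t in pts),
        auc=auc,
        gc_threshold=gc_threshold,
    )


def _qualifying_scores(promoters: list[PromoterSeq], pwm: PWM, gc_threshold: float | None, flank: int) -> np.ndarray:
    return np.array([best_qualifying_score(p.seq, pwm, gc_threshold, flank=flank) for p in promoters])


def build_roc(
    positives: list[PromoterSeq],
    negative_pool: list[PromoterSeq],
    pwm: PWM,
    gc_threshold: float | None = 60.0,
    flank: int = 100,
    grid: tuple[float, ...] = DEFAULT_GRID,
    n_bootstrap: int = 10,
    sample_size: int | None = None,
    seed: int = 0,
) -> RocCurve:
    """Bootstrap-averaged gene-level ROC curve over the threshold grid.

    ``sample_size`` (default: the number of positives) genes are drawn without
    replacement from ``negative_pool`` in each of ``n_bootstrap`` replicates;
    per-threshold FPRs are averaged across replicates. Deterministic given
    ``seed``.
    """
    if not positives:
        raise ValueError("build_roc requires a non-empty positive set")
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0 or np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing")
    if np.any((grid_arr < 0) | (grid_arr > 100)):
        raise ValueError("grid thresholds must lie in [0, 100]")
    if sample_size is None:
        sample_size = len(positives)
    if sample_size > len(negative_pool):
        raise ValueError(f"sample_size {sample_size} exceeds negative pool ({len(negative_pool)})")

    pos_scores = _qualifying_scores(positives, pwm, gc_threshold, flank)
    pool_scores = _qualifying_scores(negative_pool, pwm, gc_threshold, flank)

    tprs = (pos_scores[:, None] >= grid_arr[None, :]).mean(axis=0)
    rng = np.random.default_rng(seed)
    neg_fracs = np.zeros((n_bootstrap, grid_arr.size))
    for r in range(n_bootstrap):
        draw = rng.choice(len(pool_scores), size=sample_size, replace=False)
        neg_fracs[r] = (pool_scores[draw, None] >= grid_arr[None, :]).mean(axis=0)
    fprs = neg_fracs.mean(axis=0)
    return roc_from_rates(grid_arr, tprs, fprs, gc_threshold=gc_threshold)


def compare_gc_settings(
    positives: list[PromoterSeq],
    negative_pool: list[PromoterSeq],
    pwm: PWM,
    gc_thresholds: tuple[float | None, ...] = (None, 50.0, 60.0),
    flank: int = 100,
    grid: tuple[float, ...] = DEFAULT_GRID,
    n_bootstrap: int = 10,
    sample_size: int | None = None,
    seed: int = 0,
) -> list[RocCurve]:
    """One ROC curve per GC setting, with identical bootstrap seeds so the
    comparison is paired (``None`` means PWM-only, no GC filter)."""
    return [
        build_roc(
            positives,
            negative_pool,
            pwm,
            gc_threshold=gc,
            flank=flank,
            grid=grid,
            n_bootstrap=n_bootstrap,
            sample_size=sample_size,
            seed=seed,
        )
        for gc in gc_thresholds
    ]
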