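"""The combined Matrix-GC classifier.

A promoter is scanned with a PWM at a percent-score threshold (default 65%);
each match's context window — the match itself plus 100 bp flanks, 215 bp when
not clipped at a promoter edge — must reach a GC-content threshold (default
60%) for the match to count. A gene is called bound if at least one match
passes both filters. The GC requirement encodes the binder's documented
preference for GC-rich neighbourhoods and suppresses spurious PWM hits in
AT-rich sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from matrixgc.motif import PWM, MotifMatch, encode, scan_sequence, _window_percent_scores
from matrixgc.seqio import PromoterSeq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatrixGcConfig:
    """Thresholds and geometry of the combined filter.

    ``pwm_threshold`` and ``gc_threshold`` are percentages; ``upstream`` is
    the promoter length in bp and ``flank`` the GC context flank on each side
    of a match.
    """

    pwm_threshold: float = 65.0
    gc_threshold: float = 60.0
    upstream: int = 1000
    flank: int = 100

    def __post_init__(self) -> None:
        for name in ("pwm_threshold", "gc_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.upstream <= 0 or self.flank <= 0:
            raise ValueError("upstream and flank must be positive")


@dataclass(frozen=True)
class GcWindow:
    """Half-open GC context bounds around one match, with its GC content."""

    start: int
    end: int
    clipped: bool
    gc_percent: float | None = None


@dataclass(frozen=True)
class BindingCall:
    """Bound/not-bound verdict for one gene with its best passing match."""

    gene: str
    bound: bool
    n_passing_matches: int
    best_percent_score: float | None
    best_gc: float | None


def gc_content(seq: str) -> float:
    """GC percentage over the A/C/G/T characters of ``seq``.

    N (and any other non-ACGT symbol) is excluded from both numerator and
    denominator; a sequence with no A/C/G/T at all has no defined GC content.
    """
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    idx = encode(seq)
    acgt = int((idx != 255).sum())
    if acgt == 0:
        raise ValueError("gc_content undefined: sequence has no A/C/G/T characters")
    gc = int(((idx == 1) | (idx == 2)).sum())  # C=1, G=2
    return 100.0 * gc / acgt


def gc_window(seq_len: int, match_position: int, width: int = 15, flank: int = 100) -> GcWindow:
    """Context window bounds for a match at ``match_position``.

    The window is the match plus ``flank`` bases each side, truncated at the
    sequence boundaries (``clipped`` records whether truncation occurred).
    """
    if not 0 <= match_position <= seq_len - width:
        raise ValueError(
            f"match_position {match_position} out of range for seq_len {seq_len}, width {width}"
        )
    start = max(0, match_position - flank)
    end = min(seq_len, match_position + width + flank)
    clipped = (start != match_position - flank) or (end != match_position + width + flank)
    return GcWindow(start=start, end=end, clipped=clipped)


def match_gc(seq: str, match_position: int, width: int, flank: int) -> GcWindow:
    """GC window for one match with its GC content computed."""
    win = gc_window(len(seq), match_position, width=width, flank=flank)
    try:
        gc = gc_content(seq[win.start:win.end])
    except ValueError:
        gc = None  # all-N context: match cannot pass the GC filter
    return GcWindow(start=win.start, end=win.end, clipped=win.clipped, gc_percent=gc)


def classify_gene(promoter: PromoterSeq, pwm: PWM, config: MatrixGcConfig = MatrixGcConfig()) -> BindingCall:
    """Apply the combined filter to one promoter.

    A match passes when its percent score is >= ``config.pwm_threshold`` and
    its context GC is >= ``config.gc_threshold``; the gene is bound iff at
    least one match passes. ``best_*`` report the passing match with the
    highest percent score.
    """
    matches = scan_sequence(pwm, promoter.seq, threshold=config.pwm_threshold)
    passing: list[MotifMatch] = []
    for m in matches:
        win = match_gc(promoter.seq, m.position, pwm.width, config.flank)
        if win.gc_percent is not None and win.gc_percent >= config.gc_threshold:
            passing.append(
                MotifMatch(
                    position=m.position,
                    strand=m.strand,
                    percent_score=m.percent_score,
                    matched_seq=m.matched_seq,
                    gc_percent=win.gc_percent,
                )
            )
    if passing:
        best = max(passing, key=lambda m: m.percent_score)
        return BindingCall(
            gene=promoter.gene,
            bound=True,
            n_passing_matches=len(passing),
            best_percent_score=best.percent_score,
            best_gc=best.gc_percent,
        )
    return BindingCall(promoter.gene, False, 0, None, None)


def classify_gene_set(
    promoters: list[PromoterSeq],
    pwm: PWM,
    config: MatrixGcConfig = MatrixGcConfig(),
) -> tuple[list[BindingCall], dict]:
    """Classify a cohort and summarize the bound percentage.

    Returns one call per promoter (input order) and a summary dict with the
    bound count and the bound percentage rounded to 2 decimals.
    """
    if not promoters:
        raise ValueError("classify_gene_set requires at least one promoter")
    names = [p.gene for p in promoters]
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dupes = {n for n in names if n in seen or seen.add(n)}
        raise ValueError(f"duplicate gene names in cohort: {sorted(dupes)}")
    calls = [classify_gene(p, pwm, config) for p in promoters]
    n_bound = sum(c.bound for c in calls)
    summary = {
        "n_genes": len(calls),
        "n_bound": n_bound,
        "bound_percentage": round(100.0 * n_bound / len(calls), 2),
    }
    return calls, summary


def best_qualifying_score(
    seq: str,
    pwm: PWM,
    gc_threshold: float | None,
    flank: int = 100,
) -> float:
    """Highest percent score among matches passing the GC filter.

    Scans at threshold 0 so every valid window is considered; with
    ``gc_threshold=None`` the GC filter is disabled (PWM-only). Returns -inf
    when no window qualifies. This is the per-gene score the ROC module
    thresholds: the gene is classified bound at percent threshold t iff the
    returned value is >= t.
    """
    w = pwm.width
    if len(seq) < w:
        return float("-inf")
    idx = encode(seq)
    scores, valid = _window_percent_scores(pwm, idx)
    if gc_threshold is not None:
        # vectorized per-window context GC over clipped [i-flank, i+w+flank)
        is_gc = ((idx == 1) | (idx == 2)).astype(np.int64)
        is_acgt = (idx != 255).astype(np.int64)
        gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
        acgt_cum = np.concatenate([[0], np.cumsum(is_acgt)])
        pos = np.arange(len(scores))
        lo = np.maximum(0, pos - flank)
        hi = np.minimum(len(idx), pos + w + flank)
        gc_n = gc_cum[hi] - gc_cum[lo]
        acgt_n = acgt_cum[hi] - acgt_cum[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc_pct = np.where(acgt_n > 0, 100.0 * gc_n / np.maximum(acgt_n, 1), np.nan)
        valid = valid & (acgt_n > 0) & (gc_pct >= gc_threshold)
    if not valid.any():
        return float("-inf")
    return float(np.nanmax(np.where(valid, scores, np.nan)))
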