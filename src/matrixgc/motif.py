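"""Position frequency/weight matrices and percent-scored sequence scanning.

The motif model is a 4 x W count matrix (rows A, C, G, T). Scanning converts
it to a log-odds position weight matrix against an explicit background with an
additive pseudocount, and every window's raw log-odds sum S is reported on a
min-max percent scale::

    percent = 100 * (S - Smin) / (Smax - Smin)

where Smin/Smax are the minimal/maximal raw scores the matrix can produce
(column-wise min/max sums). 100% is therefore the consensus sequence and 0%
the anti-consensus; the binding threshold used downstream is a point on this
scale (65% by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte -> row index; 255 marks anything that is not A/C/G/T (incl. N)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# row permutation sending each base to its complement (A<->T, C<->G)
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as row indices; non-ACGT symbols become 255."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: per-position base counts, rows A,C,G,T."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"PFM counts must be 4 x W, got shape {counts.shape}")
        if counts.shape[1] < 1:
            raise ValueError("PFM width must be >= 1")
        if np.any(counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            bad = np.flatnonzero(counts.sum(axis=0) <= 0).tolist()
            raise ValueError(f"PFM columns with zero total count: {bad}")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Column-wise argmax base string (ties resolved A<C<G<T)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log-odds weight matrix with its attainable raw-score bounds."""

    weights: np.ndarray
    smin: float = field(init=False)
    smax: float = field(init=False)

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        if weights.ndim != 2 or weights.shape[0] != 4:
            raise ValueError(f"PWM weights must be 4 x W, got shape {weights.shape}")
        object.__setattr__(self, "smin", float(weights.min(axis=0).sum()))
        object.__setattr__(self, "smax", float(weights.max(axis=0).sum()))

    @property
    def width(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class MotifMatch:
    """One scored motif hit within a scanned sequence.

    ``gc_percent`` is filled by the Matrix-GC layer; the scanner leaves it
    None.
    """

    position: int
    strand: str
    percent_score: float
    matched_seq: str
    gc_percent: float | None = None


def read_pfm(path: str | Path) -> PFM:
    """Read a 4-row PFM from a labelled tabular file or a JASPAR block.

    Accepted per-base lines look like ``A  4 17 0 ...`` or JASPAR's
    ``A [ 4 17 0 ... ]``; a leading ``>`` header line is skipped.
    """
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">") or line.startswith("#"):
                continue
            m = re.match(r"^([ACGTacgt])[\s:|]*\[?([-\d.\seE]+)\]?\s*$", line)
            if m is None:
                raise ValueError(f"{path}: line {lineno}: cannot parse PFM row: {line!r}")
            base = m.group(1).upper()
            if base in rows:
                raise ValueError(f"{path}: line {lineno}: duplicate row for base {base}")
            rows[base] = [float(x) for x in m.group(2).split()]
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ValueError(f"{path}: missing PFM rows for bases {missing}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged PFM rows, widths {sorted(widths)}")
    return PFM(counts=np.array([rows[b] for b in BASES]))


def write_pfm(path: str | Path, pfm: PFM) -> None:
    with open(path, "w") as fh:
        for i, base in enumerate(BASES):
            fh.write(base + "\t" + "\t".join(f"{x:g}" for x in pfm.counts[i]) + "\n")


def build_pwm(
    pfm: PFM,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> PWM:
    """Convert a PFM to a log2-odds PWM.

    Each weight is::

        w[b, j] = log2( (n[b, j] + pc * bg[b]) / (N[j] + pc) / bg[b] )

    with ``n`` the counts, ``N[j]`` the column total, ``pc`` the pseudocount
    and ``bg`` the background base probabilities (uniform by default). The
    pseudocount keeps zero counts finite and is spread across bases in
    proportion to the background.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,):
        raise ValueError("background must be a 4-vector")
    if np.any(background <= 0):
        raise ValueError("background probabilities must all be > 0")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError(f"background must sum to 1, got {background.sum()}")
    counts = pfm.counts
    col_tot = counts.sum(axis=0)
    probs = (counts + pseudocount * background[:, None]) / (col_tot + pseudocount)
    return PWM(weights=np.log2(probs / background[:, None]))


def percent_score(pwm: PWM, kmer: str) -> float:
    """Min-max normalized score of one W-mer, in [0, 100].

    Degenerate matrices with Smax == Smin (every window identical) score 100.
    Callers must pre-filter windows containing N or other symbols.
    """
    if len(kmer) != pwm.width:
        raise ValueError(f"kmer length {len(kmer)} != motif width {pwm.width}")
    idx = encode(kmer)
    if np.any(idx == 255):
        raise ValueError(f"kmer contains non-ACGT symbols: {kmer!r}")
    raw = float(pwm.weights[idx, np.arange(pwm.width)].sum())
    if pwm.smax == pwm.smin:
        return 100.0
    return 100.0 * (raw - pwm.smin) / (pwm.smax - pwm.smin)


def _window_percent_scores(pwm: PWM, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Percent scores of every window of an encoded sequence.

    Returns (scores, valid) arrays of length len(idx) - W + 1; ``valid`` is
    False for windows containing a non-ACGT symbol, whose score is NaN.
    """
    w = pwm.width
    n_win = len(idx) - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    bad = (idx == 255)
    # window is valid iff no bad symbol in [i, i+w)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (bad_cum[w:] - bad_cum[:-w]) == 0
    safe = np.where(bad, 0, idx).astype(np.intp)
    raw = np.zeros(n_win)
    for j in range(w):
        raw += pwm.weights[safe[j:j + n_win], j]
    if pwm.smax == pwm.smin:
        scores = np.full(n_win, 100.0)
    else:
        scores = 100.0 * (raw - pwm.smin) / (pwm.smax - pwm.smin)
    scores[~valid] = np.nan
    return scores, valid


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold: float = 65.0,
    both_strands: bool = False,
) -> list[MotifMatch]:
    """Report every window scoring at or above ``threshold`` percent.

    Overlapping matches are all retained. Windows containing any non-ACGT
    symbol are skipped (and counted in a log line). With ``both_strands`` the
    reverse complement of each window is scored too and reported with strand
    '-'; positions always refer to the scanned (forward) sequence. Output is
    sorted by position, '+' before '-'. A sequence shorter than the motif
    yields an empty list.
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    w = pwm.width
    if len(seq) < w:
        return []
    idx = encode(seq)
    scores, valid = _window_percent_scores(pwm, idx)
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.info("scan: skipped %d window(s) containing non-ACGT symbols", n_skipped)
    matches: list[MotifMatch] = []
    strands: list[tuple[np.ndarray, str]] = [(scores, "+")]
    if both_strands:
        # scoring the revcomp of each window == scanning with the
        # reverse-complemented matrix (rows complemented, columns reversed)
        rc_pwm = PWM(weights=pwm.weights[_COMPLEMENT_ROWS][:, ::-1])
        rc_scores, _ = _window_percent_scores(rc_pwm, idx)
        strands.append((rc_scores, "-"))
    for strand_scores, strand in strands:
        hits = np.flatnonzero(valid & (strand_scores >= threshold))
        for pos in hits:
            matches.append(
                MotifMatch(
                    position=int(pos),
                    strand=strand,
                    percent_score=float(strand_scores[pos]),
                    matched_seq=seq[pos:pos + w].upper(),
                )
            )
    matches.sort(key=lambda m: (m.position, m.strand != "+"))
    return matches
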