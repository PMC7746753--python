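"""Independent brute-force oracles used by the test suite.

Everything here is written against the *definitions* (plain Python loops,
exact rational arithmetic) and deliberately shares no code path with the
package internals it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def pwm_weight(counts_col, base_idx: int, pseudocount: float, background) -> float:
    """Scalar log2-odds weight recomputed directly from the definition."""
    n_b = counts_col[base_idx]
    total = sum(counts_col)
    bg = background[base_idx]
    prob = (n_b + pseudocount * bg) / (total + pseudocount)
    return math.log2(prob / bg)


def percent_score_brute(weights, kmer: str) -> float:
    """Column-sum percent score via plain Python loops."""
    w = len(kmer)
    raw = 0.0
    for j, b in enumerate(kmer):
        raw += weights[BASES.index(b)][j]
    smin = sum(min(weights[i][j] for i in range(4)) for j in range(w))
    smax = sum(max(weights[i][j] for i in range(4)) for j in range(w))
    if smax == smin:
        return 100.0
    return 100.0 * (raw - smin) / (smax - smin)


def scan_brute(weights, seq: str, threshold: float, both_strands: bool = False):
    """Exhaustive window enumeration; returns (pos, strand, score, kmer)."""
    w = len(weights[0])
    out = []
    for i in range(len(seq) - w + 1):
        kmer = seq[i:i + w].upper()
        if any(b not in BASES for b in kmer):
            continue
        s = percent_score_brute(weights, kmer)
        if s >= threshold:
            out.append((i, "+", s, kmer))
        if both_strands:
            s_rc = percent_score_brute(weights, revcomp(kmer))
            if s_rc >= threshold:
                out.append((i, "-", s_rc, kmer))
    out.sort(key=lambda m: (m[0], m[1] != "+"))
    return out


def gc_brute(seq: str) -> float:
    acgt = sum(b in BASES for b in seq.upper())
    gc = sum(b in "GC" for b in seq.upper())
    return 100.0 * gc / acgt


def classify_brute(seq: str, weights, pwm_threshold: float, gc_threshold: float, flank: int):
    """Full Matrix-GC decision by exhaustive enumeration: (bound, n_passing)."""
    w = len(weights[0])
    n_passing = 0
    for pos, _strand, _score, _kmer in scan_brute(weights, seq, pwm_threshold):
        lo = max(0, pos - flank)
        hi = min(len(seq), pos + w + flank)
        window = seq[lo:hi]
        if sum(b in BASES for b in window.upper()) == 0:
            continue
        if gc_brute(window) >= gc_threshold:
            n_passing += 1
    return n_passing >= 1, n_passing


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration in exact
    rational arithmetic (factorial formula, no shared code with the package)."""
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)

    def pmf(x: int) -> Fraction:
        return Fraction(
            math.factorial(r1) * math.factorial(r2) * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(x) * math.factorial(r1 - x) * math.factorial(c1 - x)
            * math.factorial(r2 - c1 + x) * math.factorial(n),
        )

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return min(total, Fraction(1))


def trapezoid(points) -> float:
    """Hand trapezoid rule over (x, y) points sorted by x."""
    pts = sorted(points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def induced_degree_matrix_oracle(edges, gene_set):
    """Induced degrees via adjacency-matrix row sums (numpy-free)."""
    genes = list(gene_set)
    index = {g: i for i, g in enumerate(genes)}
    k = len(genes)
    adj = [[0] * k for _ in range(k)]
    for u, v in edges:
        if u in index and v in index and u != v:
            adj[index[u]][index[v]] = 1
            adj[index[v]][index[u]] = 1
    return {g: sum(adj[index[g]]) for g in genes}
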