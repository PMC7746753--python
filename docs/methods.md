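# Methods

## Model and procedure

The classifier targets DNA binders whose occupancy depends jointly on a
sequence motif and on the GC richness of the surrounding region — the
archetype is MeCP2, which binds methyl-CpG-containing motifs preferentially in
GC-dense neighbourhoods. Two features are combined:

1. **Motif similarity.** A 4 × W position frequency matrix (W = 15 by
   default) is converted to a log2-odds position weight matrix against an
   explicit background with an additive pseudocount (default 0.01,
   distributed across bases in proportion to the background). Window scores
   are min–max normalized to a 0–100% scale using the matrix's attainable
   score bounds (column-wise min/max sums), so thresholds are comparable
   across matrices of different widths and information content. The default
   binding threshold is 65%.
2. **Context GC.** Each match's context window — the match plus 100 bp flanks
   on each side, 215 bp when interior — must reach 60% GC.

A gene is *bound* iff its promoter (1000 bp upstream of the TSS) contains at
least one match passing both filters. No minimum match count is imposed and
overlapping matches are all retained: the downstream unit of analysis is the
gene, for which only "≥ 1 passing match" matters.

Assumptions worth stating: the promoter is a fixed-length upstream window of
a single TSS per gene (no isoform selection); scanning is forward-strand only
by default because the promoter is already oriented 5′→3′ toward the TSS
(both-strand scanning is an explicit flag); the background model is
position-independent.

## Threshold calibration (ROC)

ROC curves operate at the gene level: at percent threshold t a gene counts as
classified bound iff it has ≥ 1 match at percent ≥ t passing the active GC
filter. True-positive rates come from top-ranked ChIP target genes; false-
positive rates are averaged point-wise over 10 bootstrapped size-matched
draws (without replacement) from the zero-score gene pool. The threshold grid
is 5–100% in steps of 5. Curves are anchored at (0,0) and (1,1), sorted by
FPR and integrated by the trapezoid rule. Averaging FPRs point-wise (rather
than averaging per-replicate AUCs) was chosen because the per-threshold rates
are the plotted object; with equal replicate sizes it coincides with pooling.

## Statistics

**Tissue contrast.** For each tissue, genes split into a 2 × 2 table by bound
status × expressed status ("expressed" = expression strictly greater than 0;
an exact zero counts as not expressed). Fisher's exact test is two-sided —
the scientific question ("is the proportion of expressed genes the same in
both groups?") is two-sided — and is computed by exhaustive hypergeometric
enumeration in exact integer arithmetic: every candidate table's probability
shares the denominator C(n, a+c), so tables are compared by their integer
numerators C(r1, x)·C(r2, a+c−x), with no floating-point tie tolerance. The
sample odds ratio a·d/(b·c) is reported as +inf when b·c = 0 with a·d > 0 and
as NaN when both products vanish. Raw p-values are reported across
tissues/gene-sets with no multiplicity correction; downstream users should
correct as appropriate.

**Monte Carlo DEG enrichment.** The observed statistic is the percentage of
candidate genes (restricted to genes present in the DE table) with DE
p ≤ 0.05. Each of 1000 permutations draws an equal-sized set without
replacement from the whole DE-table universe. The empirical p-value uses the
add-one convention (1 + #{null ≥ observed}) / (1 + N), so it is bounded below
by 1/(N+1) and ties count against the candidate set (conservative). Because
both the observed and the null statistics are discrete percentages, ties are
common and the realized type-I error sits somewhat below the nominal level;
the calibration study therefore uses large sets (2,000 candidates from a
20,000-gene universe over 500 repetitions, with permutations scaled to 200)
so that discreteness does not dominate the rejection rate, which lands near
0.04–0.05 at nominal 0.05.

**Term exclusion.** Enrichment terms (GO/pathway identifiers, treated as
opaque strings) that were significantly enriched in any randomly generated
size-matched control set are excluded from disorder results wherever they
overlap. The toolkit does not compute enrichment itself; it consumes tabular
term lists.

**Network null and hubs.** The connectivity of a gene set is the mean degree
of its members within the induced subgraph (genes absent from the PPI graph
count with degree 0). The null repeats this for 20 random size-matched draws
from a user-chosen universe; a set is significantly connected iff its
observed mean strictly exceeds the maximum control-run mean. A protein is a
hub iff its within-network degree is at least the control mean plus one; the
boundary is inclusive. Edge lists are undirected, unweighted and
deduplicated, with an optional confidence-score filter.

## Synthetic data

The fixture generators produce every input class with recorded ground truth:

- **Promoter cohorts**: i.i.d. background bases at a target GC probability
  (default 40%), with consensus sites planted at Bernoulli rates per class.
  The 215 bp context of a planted site is synthesized to hit a target GC
  (default 70% for positives) within 2 percentage points by computing the
  exact number of G/C flank bases required; targets the motif's own
  composition cannot reach are a generation error rather than a silent
  miss. Planted sites sit at least one flank-width from the promoter edges so
  their context is never clipped.
- **Expression matrices**: per tissue, an exact count of genes (rounded
  fraction) gets log-normal expression; the rest are exactly 0, matching the
  strict "> 0 means expressed" convention.
- **DE tables**: background genes get p ~ U(0,1); each planted enriched gene
  gets p ≤ α with a configurable probability (the effect size).
- **PPI graphs**: Erdős–Rényi G(n, p) with an optional planted clique, whose
  members have within-clique degree clique_size − 1 by construction.

Every generator is a pure function of its parameters and seed. What these
fixtures deliberately do *not* emulate: real genomic base composition (CpG
islands, repeats, N runs), correlated expression across tissues, and
scale-free PPI degree distributions. Passing tests therefore demonstrate
algorithmic correctness and calibration under controlled conditions, not
performance on real genomes, where promoter GC structure and motif abundance
differ substantially.

## Numerical choices and edge cases

- Windows containing any non-ACGT symbol are skipped during scanning (counted
  in a log line); N is excluded from both numerator and denominator of GC
  content, and an all-N window cannot pass the GC filter.
- Context windows at promoter edges are truncated, not discarded, with GC
  computed over the available bases and the clipping recorded.
- Promoters overlapping a chromosome start are clipped with the realized
  length reported, rather than rejected.
- A degenerate PWM with Smax = Smin scores every window 100%.
- Deterministic seeding throughout (`numpy.random.default_rng`); the CLI fans
  a single `--seed` out to fixed per-stage offsets so stages are
  independently reproducible, and every pipeline run writes its resolved
  configuration (with hash and package version) beside its outputs.
- Scan-time tie handling: thresholds compare with ≥, so a window scoring
  exactly the threshold is a match; significance of network connectivity uses
  a strict >, so an observed mean equal to the control maximum is not
  significant; the hub rule is inclusive (degree = mean + 1 is a hub).

## Problem sizes

The test suite and the reproduction script run on synthetic cohorts of
40–200 promoters of 400–1000 bp, 500-table Fisher enumeration suites
(n ≤ 30), a 500-repetition Monte Carlo calibration with 200 permutations per
test, and 200-node random graphs — sizes at which every result is either
closed-form or independently recomputable by brute force, while a full run of
the suite completes in well under a minute.

## Known limitations

- Whether the GC filter should apply to any match or only the best-scoring
  match is ambiguous in principle; this implementation filters *any* match,
  so a gene with one high-GC match is bound regardless of other matches.
- Multi-isoform genes need a TSS chosen upstream of this toolkit; gene tables
  carry exactly one TSS per gene.
- Percent scores are min–max normalized, not p-value calibrated; a fixed
  percent threshold corresponds to different rarities for matrices of
  different information content.
- The ROC unit is the gene, not the window; window-level calibration would
  need site-resolution truth, which ChIP-derived gene rankings do not give.
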