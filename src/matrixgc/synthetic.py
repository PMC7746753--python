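"""Synthetic fixtures with known ground truth for every input class.

Each generator is a pure function of its parameters and seed, and the truth
it returns is sufficient to predict every downstream module's output without
re-deriving the randomness: promoter cohorts record where (and whether) a
motif was planted and the realized context GC; expression matrices record
which entries are exactly zero; DE tables record the enriched genes; PPI
graphs record the planted clique.

Promoter backgrounds are i.i.d. bases at a target GC probability — they do not
emulate real genomic base composition (CpG islands, repeats, N runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from matrixgc.motif import PFM
from matrixgc.seqio import PromoterSeq

# A fixed 4 x 15 demonstration PFM (synthetic; GC/CpG-rich consensus evoking a
# methyl-CpG binder's preference). Dominant base 12 counts, others 1, so the
# consensus is unambiguous and single-base degradations give intermediate
# percent scores.
DEMO_CONSENSUS = "CCGCCGGCAGCGGCG"


def demo_pfm(consensus: str = DEMO_CONSENSUS, dominant: float = 12.0, other: float = 1.0) -> PFM:
    """Synthetic PFM whose column-wise argmax spells ``consensus``."""
    from matrixgc.motif import BASE_INDEX

    counts = np.full((4, len(consensus)), other)
    for j, b in enumerate(consensus):
        counts[BASE_INDEX[b], j] = dominant
    return PFM(counts=counts)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a promoter cohort with planted motif sites.

    Positives and negatives receive a planted consensus site with their
    respective Bernoulli rates; the 215 bp context around a planted site is
    synthesized to hit the target window GC within 2 percentage points. The
    remaining background is i.i.d. with per-base GC probability
    ``background_gc / 100``.
    """

    n_positive: int
    n_negative: int
    promoter_len: int = 1000
    consensus: str = DEMO_CONSENSUS
    plant_rate_pos: float = 1.0
    plant_rate_neg: float = 0.0
    gc_context_pos: float = 70.0
    gc_context_neg: float = 70.0
    background_gc: float = 40.0
    flank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plant_rate_pos", "plant_rate_neg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gc_context_pos", "gc_context_neg", "background_gc"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.promoter_len < len(self.consensus) + 2 * self.flank:
            raise ValueError(
                "promoter_len must fit a planted site with full flanks "
                f"({len(self.consensus) + 2 * self.flank} bp)"
            )


def _random_bases(rng: np.random.Generator, n: int, gc_prob: float) -> np.ndarray:
    """i.i.d. bases with P(G or C) = gc_prob, uniform within each pair."""
    is_gc = rng.random(n) < gc_prob
    pick = rng.integers(0, 2, size=n)
    out = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    return out


def _planted_flanks(rng: np.random.Generator, consensus: str, gc_target: float, flank: int) -> tuple[str, str, float]:
    """Flank sequence pair whose combined window hits ``gc_target`` GC.

    The exact number of G/C flank bases needed is computed from the motif's
    own GC count; an unreachable target (outside what 2*flank flank bases can
    compensate, beyond a 2-point tolerance) is a generation error.
    """
    w = len(consensus)
    window_len = w + 2 * flank
    motif_gc = sum(b in "GC" for b in consensus)
    target_gc_bases = round(gc_target / 100.0 * window_len)
    flank_gc = min(2 * flank, max(0, target_gc_bases - motif_gc))
    realized = 100.0 * (motif_gc + flank_gc) / window_len
    if abs(realized - gc_target) > 2.0:
        raise ValueError(
            f"window GC target {gc_target}% infeasible with motif GC {motif_gc}/{w}: "
            f"closest attainable is {realized:.2f}%"
        )
    bases = rng.permutation(np.array(["S"] * flank_gc + ["W"] * (2 * flank - flank_gc)))
    pick = rng.integers(0, 2, size=2 * flank)
    actual = np.where(bases == "S", np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    left = "".join(actual[:flank])
    right = "".join(actual[flank:])
    return left, right, realized


def generate_promoter_cohort(spec: SyntheticCohortSpec) -> tuple[list[PromoterSeq], pd.DataFrame]:
    """Promoter cohort plus a truth table.

    Truth columns: gene, label ('positive'/'negative'), planted (bool),
    plant_pos (-1 when unplanted), window_gc (NaN when unplanted).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    w = len(spec.consensus)
    promoters: list[PromoterSeq] = []
    rows = []
    groups = [
        ("positive", spec.n_positive, spec.plant_rate_pos, spec.gc_context_pos, "POS"),
        ("negative", spec.n_negative, spec.plant_rate_neg, spec.gc_context_neg, "NEG"),
    ]
    for label, n, plant_rate, gc_target, prefix in groups:
        for i in range(n):
            gene = f"{prefix}{i:04d}"
            seq_arr = _random_bases(rng, spec.promoter_len, spec.background_gc / 100.0)
            planted = bool(rng.random() < plant_rate)
            plant_pos = -1
            window_gc = float("nan")
            if planted:
                plant_pos = int(rng.integers(spec.flank, spec.promoter_len - w - spec.flank + 1))
                left, right, window_gc = _planted_flanks(rng, spec.consensus, gc_target, spec.flank)
                insert = left + spec.consensus + right
                start = plant_pos - spec.flank
                seq_arr[start:start + len(insert)] = list(insert)
            seq = "".join(seq_arr)
            promoters.append(PromoterSeq(gene=gene, seq=seq))
            rows.append({
                "gene": gene,
                "label": label,
                "planted": planted,
                "plant_pos": plant_pos,
                "window_gc": window_gc,
            })
    return promoters, pd.DataFrame(rows)


def generate_expression_matrix(
    n_genes: int,
    tissues: list[str],
    frac_expressed_per_tissue: float | list[float],
    seed: int = 0,
    log_mean: float = 1.0,
    log_sigma: float = 1.0,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Gene x tissue matrix with an exact count of non-zero entries per tissue.

    Expressed entries are log-normal (parameters in log space); the rest are
    exactly 0, matching the strict "> 0 means expressed" convention used by
    the tissue contrast.
    """
    if gene_names is None:
        gene_names = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    if np.isscalar(frac_expressed_per_tissue):
        fracs = [float(frac_expressed_per_tissue)] * len(tissues)
    else:
        fracs = [float(f) for f in frac_expressed_per_tissue]
    if len(fracs) != len(tissues) or any(not 0 <= f <= 1 for f in fracs):
        raise ValueError("frac_expressed_per_tissue must give one value in [0,1] per tissue")
    rng = np.random.default_rng(seed)
    data = {}
    for tissue, frac in zip(tissues, fracs):
        n_expr = round(frac * n_genes)
        col = np.zeros(n_genes)
        idx = rng.choice(n_genes, size=n_expr, replace=False)
        col[idx] = rng.lognormal(mean=log_mean, sigma=log_sigma, size=n_expr)
        data[tissue] = col
    return pd.DataFrame(data, index=pd.Index(gene_names, name="gene"))


def generate_de_table(
    n_genes: int,
    enriched_set_size: int,
    effect: float,
    alpha: float = 0.05,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """DE result table (gene, pvalue) with a planted enriched set.

    Non-enriched genes get p ~ Uniform(0, 1); each enriched gene gets
    p <= alpha with probability ``effect`` (and p ~ Uniform(alpha, 1)
    otherwise). ``effect`` must be at least the baseline rate ``alpha``.
    Returns the table and the enriched gene list.
    """
    if not alpha <= effect <= 1:
        raise ValueError(f"effect must be in [alpha, 1] = [{alpha}, 1], got {effect}")
    if enriched_set_size > n_genes:
        raise ValueError("enriched_set_size exceeds n_genes")
    if gene_names is None:
        gene_names = [f"G{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    pvals = rng.uniform(0, 1, size=n_genes)
    enriched_idx = rng.choice(n_genes, size=enriched_set_size, replace=False)
    hit = rng.random(enriched_set_size) < effect
    pvals[enriched_idx] = np.where(
        hit,
        rng.uniform(0, alpha, size=enriched_set_size),
        rng.uniform(alpha, 1, size=enriched_set_size),
    )
    table = pd.DataFrame({"gene": gene_names, "pvalue": pvals})
    enriched = [gene_names[i] for i in sorted(enriched_idx)]
    return table, enriched


def generate_ppi(
    n_nodes: int,
    edge_prob: float,
    planted_clique_size: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Erdos-Renyi G(n, p) protein graph with an optional planted clique.

    Nodes are named P0000, P0001, ...; the clique occupies the first
    ``planted_clique_size`` nodes (returned as the second element).
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    if planted_clique_size > n_nodes:
        raise ValueError("planted_clique_size exceeds n_nodes")
    names = [f"P{i:04d}" for i in range(n_nodes)]
    g_idx = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(seed))
    g = nx.relabel_nodes(g_idx, dict(enumerate(names)))
    g.add_nodes_from(names)
    clique = names[:planted_clique_size]
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            g.add_edge(clique[i], clique[j])
    return g, clique


def write_truth_table(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_expression_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def write_de_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_edge_list(path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")
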