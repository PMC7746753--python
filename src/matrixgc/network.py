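"""PPI connectivity null via size-matched random gene sets, and hub calling.

The "degree of connectivity" of a gene set is the mean degree of its members
within the subgraph the set induces (genes absent from the graph count with
degree 0). The null repeats this for random size-matched draws from a gene
universe; a set is significantly connected when its observed mean exceeds the
maximum control-run mean, and a protein is a hub when its within-network
degree is at least the control mean plus one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class ConnectivityNull:
    set_size: int
    n_runs: int
    run_means: tuple[float, ...]
    min_degree: float
    max_degree: float
    mean_of_means: float


@dataclass(frozen=True)
class HubCall:
    protein: str
    degree: int
    control_mean: float
    is_hub: bool


def read_edge_list(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read a 2- or 3-column TSV edge list into an undirected simple graph.

    Self-loops are dropped and duplicate edges (either orientation) collapse.
    A third column is treated as a confidence score and filtered with
    ``min_score`` when given.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 columns")
            u, v = parts[0], parts[1]
            if u == v:
                continue
            if min_score is not None and len(parts) >= 3 and float(parts[2]) < min_score:
                continue
            g.add_edge(u, v)
    return g


def induced_degrees(graph: nx.Graph, gene_set: Iterable[str]) -> dict[str, int]:
    """Degree of each gene within the subgraph induced by ``gene_set``.

    Genes absent from the graph get degree 0.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("gene_set must be non-empty")
    sub = graph.subgraph([g for g in genes if g in graph])
    return {g: (sub.degree(g) if g in sub else 0) for g in genes}


def mean_induced_degree(graph: nx.Graph, gene_set: Iterable[str]) -> float:
    degs = induced_degrees(graph, gene_set)
    return float(np.mean(list(degs.values())))


def connectivity_null(
    graph: nx.Graph,
    universe: Iterable[str],
    set_size: int,
    n_runs: int = 20,
    seed: int = 0,
) -> ConnectivityNull:
    """Mean induced degree of ``n_runs`` random size-matched gene sets.

    Draws are without replacement from ``universe``; the extremes and the
    mean of the per-run means are recorded. Deterministic given ``seed``.
    """
    pool = list(dict.fromkeys(universe))
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(pool)}")
    if set_size < 1 or n_runs < 1:
        raise ValueError("set_size and n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_means = []
    for _ in range(n_runs):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        run_means.append(mean_induced_degree(graph, [pool[i] for i in idx]))
    return ConnectivityNull(
        set_size=set_size,
        n_runs=n_runs,
        run_means=tuple(run_means),
        min_degree=float(min(run_means)),
        max_degree=float(max(run_means)),
        mean_of_means=float(np.mean(run_means)),
    )


def assess_significance(observed_mean_degree: float, null: ConnectivityNull) -> tuple[bool, dict]:
    """Significant iff the observed mean degree strictly exceeds the maximum
    control-run mean (i.e. lies outside the control range)."""
    significant = observed_mean_degree > null.max_degree
    report = {
        "observed_mean_degree": observed_mean_degree,
        "null_min": null.min_degree,
        "null_max": null.max_degree,
        "null_mean": null.mean_of_means,
        "set_size": null.set_size,
        "n_runs": null.n_runs,
        "significant": significant,
    }
    return significant, report


def call_hubs(degrees: Mapping[str, int], null: ConnectivityNull) -> list[HubCall]:
    """Hub calls sorted by degree descending (ties alphabetical).

    A protein is a hub iff its degree is at least the control mean plus one
    (inclusive boundary).
    """
    control_mean = null.mean_of_means
    calls = [
        HubCall(
            protein=p,
            degree=int(d),
            control_mean=control_mean,
            is_hub=d >= control_mean + 1,
        )
        for p, d in degrees.items()
    ]
    calls.sort(key=lambda h: (-h.degree, h.protein))
    return calls
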