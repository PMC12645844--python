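"""Gene interaction networks and group statistics derived from attention.

After training, each sample's post-softmax attention weights define a
directed gene interaction network: whenever the attention a query gene i
pays to a key gene j exceeds a threshold in any head, an edge j -> i is
drawn (information flows from the key to the query), and edges found by
several heads/layers are merged keeping the maximum weight.  Per-sample
degree statistics then name *hub* genes (out-degree above mean + 2 sd) and
*attractor* genes (in-degree above mean + 2 sd).  Comparing how often each
gene is selected in two patient groups, Fisher's exact test with
Benjamini-Hochberg correction and a proportion-ratio cutoff yields the
*core* genes of each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .io_preprocess import GeneSetCollection

__all__ = [
    "GeneInteractionNetwork",
    "DegreeStats",
    "build_network",
    "write_network",
    "find_hub_attractor",
    "selection_counts",
    "core_genes",
    "aggregate_attention_scores",
    "differential_attention",
    "enrichment",
]


@dataclass
class GeneInteractionNetwork:
    """Per-sample directed network: edge key -> query with max attention weight."""

    sample_id: str
    gene_ids: list[str]
    graph: nx.DiGraph


@dataclass
class DegreeStats:
    mu_out: float
    sd_out: float
    mu_in: float
    sd_in: float


def build_network(
    attn: np.ndarray,
    gene_ids: list[str],
    sample_id: str = "",
    threshold: float = 0.01,
    layers: str | list[int] = "all",
    include_self: bool = False,
) -> GeneInteractionNetwork:
    """Threshold one sample's attention tensor into a directed network.

    `attn` has shape (n_layers, n_heads, n_genes, n_genes) with
    ``attn[l, h, i, j]`` the weight query gene i places on key gene j.  Per
    head an edge j -> i is created wherever the weight strictly exceeds
    `threshold`; the union over heads (and the selected layers) keeps the
    maximum weight per edge.  Self-edges are excluded by default so degree
    statistics are not dominated by the diagonal.
    """
    attn = np.asarray(attn, dtype=float)
    if attn.ndim != 4:
        raise ValueError("attention tensor must be (n_layers, n_heads, n_genes, n_genes)")
    n_genes = attn.shape[-1]
    if n_genes != len(gene_ids):
        raise ValueError("gene list does not match tensor size")
    layer_idx = range(attn.shape[0]) if layers == "all" else list(layers)
    merged = attn[list(layer_idx)].max(axis=(0, 1))  # max over layers and heads
    graph = nx.DiGraph()
    graph.add_nodes_from(gene_ids)
    qi, kj = np.nonzero(merged > threshold)
    for i, j in zip(qi, kj):
        if not include_self and i == j:
            continue
        graph.add_edge(gene_ids[j], gene_ids[i], weight=float(merged[i, j]))
    return GeneInteractionNetwork(sample_id, list(gene_ids), graph)


def write_network(net: GeneInteractionNetwork, path, fmt: str = "tsv") -> None:
    """Export a network as edge-list TSV (source, target, weight) or GraphML."""
    from pathlib import Path

    path = Path(path)
    if fmt == "tsv":
        lines = [f"{a}\t{b}\t{d['weight']}" for a, b, d in net.graph.edges(data=True)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def find_hub_attractor(net: GeneInteractionNetwork) -> tuple[set[str], set[str], DegreeStats]:
    """Hubs: out-degree > mu + 2 sd; attractors: in-degree > mu + 2 sd (strict)."""
    nodes = net.gene_ids
    out_deg = np.array([net.graph.out_degree(g) for g in nodes], dtype=float)
    in_deg = np.array([net.graph.in_degree(g) for g in nodes], dtype=float)
    stats = DegreeStats(
        mu_out=float(out_deg.mean()) if len(nodes) else 0.0,
        sd_out=float(out_deg.std()) if len(nodes) else 0.0,
        mu_in=float(in_deg.mean()) if len(nodes) else 0.0,
        sd_in=float(in_deg.std()) if len(nodes) else 0.0,
    )
    hubs = {g for g, d in zip(nodes, out_deg) if d > stats.mu_out + 2 * stats.sd_out}
    attractors = {g for g, d in zip(nodes, in_deg) if d > stats.mu_in + 2 * stats.sd_in}
    return hubs, attractors, stats


def selection_counts(selections: list[set[str]], gene_ids: list[str]) -> pd.Series:
    """Per gene, the number of samples whose selected set contains it."""
    counts = pd.Series(0, index=gene_ids, dtype=int)
    for sel in selections:
        for g in sel:
            counts[g] += 1
    return counts


def core_genes(
    counts_a: pd.Series,
    n_a: int,
    counts_b: pd.Series,
    n_b: int,
    ratio_cutoff: float = 2.0,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Group-specific core genes from selection frequencies.

    For each gene a 2x2 table [selected/not x group] is tested with
    Fisher's exact test (two-sided), p-values are BH-adjusted across genes,
    and the proportion ratio r = (p_A + eps) / (p_B + eps) is computed with
    pseudocount eps = 0.5 / group size.  A gene is core for the group with
    the higher proportion when max(r, 1/r) > ratio_cutoff and adjusted
    p < fdr_cutoff.  Genes selected in neither group are dropped before
    testing.  Returns a table with columns (gene, count_a, count_b,
    prop_a, prop_b, ratio, p, p_adj, core_group).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups must be nonempty")
    genes = [g for g in counts_a.index if counts_a[g] + counts_b[g] > 0]
    if not genes:
        return pd.DataFrame(
            columns=["gene", "count_a", "count_b", "prop_a", "prop_b", "ratio", "p", "p_adj", "core_group"]
        )
    rows = []
    eps_a, eps_b = 0.5 / n_a, 0.5 / n_b
    for g in genes:
        ca, cb = int(counts_a[g]), int(counts_b[g])
        table = [[ca, n_a - ca], [cb, n_b - cb]]
        p = fisher_exact(table, alternative="two-sided")[1]
        pa, pb = ca / n_a, cb / n_b
        r = (pa + eps_a) / (pb + eps_b)
        rows.append((g, ca, cb, pa, pb, r, p))
    df = pd.DataFrame(rows, columns=["gene", "count_a", "count_b", "prop_a", "prop_b", "ratio", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    abs_ratio = np.maximum(df["ratio"], 1.0 / df["ratio"])
    significant = (abs_ratio > ratio_cutoff) & (df["p_adj"] < fdr_cutoff)
    df["core_group"] = np.where(~significant, "", np.where(df["ratio"] > 1.0, "A", "B"))
    return df


# ---------------------------------------------------------------------------
# differential attention


def aggregate_attention_scores(attn: np.ndarray, mode: str = "incoming_mean") -> np.ndarray:
    """Per-sample, per-gene scalar attention summaries.

    `attn` is (n_samples, n_layers, n_heads, n_genes, n_genes).  Modes:
    ``incoming_mean`` (attention received as key, averaged over layers,
    heads and queries — consistent with attractor semantics),
    ``outgoing_mean`` (attention paid as query), or ``symmetric_mean``.
    """
    attn = np.asarray(attn, dtype=float)
    if attn.ndim != 5:
        raise ValueError("expected (n_samples, n_layers, n_heads, n_genes, n_genes)")
    incoming = attn.mean(axis=(1, 2, 3))  # average over layers, heads, queries
    if mode == "incoming_mean":
        return incoming
    outgoing = attn.mean(axis=(1, 2, 4))
    if mode == "outgoing_mean":
        return outgoing
    if mode == "symmetric_mean":
        return 0.5 * (incoming + outgoing)
    raise ValueError(f"unknown aggregate mode {mode!r}")


def differential_attention(
    attn_multitask: np.ndarray,
    attn_singletask: np.ndarray,
    gene_ids: list[str],
    aggregate: str = "incoming_mean",
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-gene comparison of aggregate attention between two model variants.

    Welch's two-sided t-test across samples per gene, BH-corrected.
    Returns (gene, score_mtl, score_stl, t, p, p_adj, direction) where
    direction is "up" for genes with significantly increased attention in
    the multitask variant, "down" for decreased, "" otherwise.
    """
    a = np.asarray(attn_multitask, dtype=float)
    b = np.asarray(attn_singletask, dtype=float)
    if a.shape[-1] != len(gene_ids) or b.shape[-1] != len(gene_ids):
        raise ValueError("tensors must cover the declared gene list")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 samples per setting for the t-test")
    scores_a = aggregate_attention_scores(a, aggregate)
    scores_b = aggregate_attention_scores(b, aggregate)
    t_stat, p = ttest_ind(scores_a, scores_b, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = scores_a.mean(axis=0), scores_b.mean(axis=0)
    direction = np.where(
        p_adj < fdr_cutoff, np.where(mean_a > mean_b, "up", "down"), ""
    )
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "score_mtl": mean_a,
            "score_stl": mean_b,
            "t": t_stat,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )


# ---------------------------------------------------------------------------
# over-representation


def enrichment(
    query_genes: set[str] | list[str], gene_sets: GeneSetCollection, universe: set[str] | list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    p = P(overlap >= observed) drawing |query| genes from the universe;
    BH correction across sets.  Set members outside the universe are
    ignored.
    """
    query = set(query_genes)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.sets.items():
        members_in = set(members) & universe
        K = len(members_in)
        k = len(query & members_in)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((name, k, K, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df
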