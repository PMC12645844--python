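"""Gene embeddings pretrained on a protein-protein interaction graph.

Genes that interact physically or functionally tend to act in shared
pathways, so a random-walk embedding of the PPI graph (node2vec) gives each
gene a dense vector that encodes its network neighbourhood.  These vectors
initialise the transformer's gene tokens.  Two ablation utilities are
provided: purely random initial embeddings, and embeddings trained on a
degree-preserving randomisation of the graph (double-edge swaps), which
keeps the degree sequence but destroys the biological wiring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneEmbeddingTable",
    "read_edge_list",
    "write_edge_list",
    "pretrain_node2vec",
    "randomize_graph",
    "random_init_embeddings",
]


@dataclass
class GeneEmbeddingTable:
    """One d_g-dimensional vector per gene, aligned with the model's gene list."""

    gene_ids: list[str]
    vectors: np.ndarray  # (n_genes, d_g)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.gene_ids):
            raise ValueError("vectors must be (n_genes, d_g)")
        if self.vectors.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.vectors, index=self.gene_ids).to_csv(path, sep="\t", header=False)

    @classmethod
    def read(cls, path: str | Path) -> "GeneEmbeddingTable":
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls(list(df.index.map(str)), df.to_numpy(dtype=float))


def read_edge_list(path: str | Path, min_weight: float | None = None) -> nx.Graph:
    """Read an undirected weighted edge list (gene_a<TAB>gene_b[<TAB>weight]).

    `min_weight` drops low-confidence edges (STRING convention: scores in
    0..1000, a typical cutoff is 700). Self-loops are discarded.
    """
    graph = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: edge line needs two gene identifiers")
        a, b = parts[0], parts[1]
        w = float(parts[2]) if len(parts) > 2 else 1.0
        if a == b:
            continue
        if min_weight is not None and w < min_weight:
            continue
        graph.add_edge(a, b, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{a}\t{b}\t{d.get('weight', 1.0)}" for a, b, d in graph.edges(data=True)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# node2vec


def _simulate_walks(
    graph: nx.Graph,
    rng: np.random.Generator,
    p: float,
    q: float,
    walk_length: int,
    num_walks: int,
    weighted: bool,
) -> list[list[int]]:
    """Second-order biased random walks (return parameter p, in-out parameter q)."""
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    nbrs: list[list[int]] = [sorted(index[m] for m in graph.neighbors(n)) for n in nodes]
    nbr_sets = [set(ns) for ns in nbrs]
    if weighted:
        weights = [
            np.array([graph[nodes[i]][nodes[j]].get("weight", 1.0) for j in nbrs[i]], dtype=float)
            for i in range(len(nodes))
        ]
    else:
        weights = [np.ones(len(ns)) for ns in nbrs]

    walks: list[list[int]] = []
    order = np.arange(len(nodes))
    for _ in range(num_walks):
        rng.shuffle(order)
        for start in order:
            if not nbrs[start]:
                continue
            walk = [int(start)]
            while len(walk) < walk_length:
                cur = walk[-1]
                cur_nbrs = nbrs[cur]
                if not cur_nbrs:
                    break
                w = weights[cur].copy()
                if len(walk) > 1 and (p != 1.0 or q != 1.0):
                    prev = walk[-2]
                    prev_nbrs = nbr_sets[prev]
                    for k, nxt in enumerate(cur_nbrs):
                        if nxt == prev:
                            w[k] /= p
                        elif nxt not in prev_nbrs:
                            w[k] /= q
                w /= w.sum()
                walk.append(int(cur_nbrs[int(rng.choice(len(cur_nbrs), p=w))]))
            walks.append(walk)
    return walks


def _skipgram_factorize(
    walks: list[list[int]],
    n_nodes: int,
    dim: int,
    window: int,
    rng: np.random.Generator,
    negatives: int = 1,
) -> np.ndarray:
    """Embed nodes by factorising the walk co-occurrence shifted-PPMI matrix.

    Skip-gram with negative sampling implicitly factorises
    PMI(center, context) - log(#negatives); computing that matrix from the
    walk corpus and taking its truncated SVD gives the closed-form optimum,
    which is far more stable than stochastic training on the small corpora
    produced by gene-scale graphs.  The default shift of 1 (plain PPMI)
    preserves the weak co-occurrence contrasts of small dense graphs that a
    larger shift would zero out entirely.
    """
    cooc = np.zeros((n_nodes, n_nodes))
    for walk in walks:
        arr = np.asarray(walk, dtype=np.int64)
        L = len(arr)
        for off in range(1, min(window, L - 1) + 1):
            np.add.at(cooc, (arr[:-off], arr[off:]), 1.0)
            np.add.at(cooc, (arr[off:], arr[:-off]), 1.0)
    total = cooc.sum()
    if total == 0:
        return rng.normal(scale=1.0 / np.sqrt(dim), size=(n_nodes, dim))
    row = cooc.sum(axis=1, keepdims=True)
    col = cooc.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / (row @ col))
    sppmi = np.maximum(np.where(np.isfinite(pmi), pmi, -np.inf) - np.log(negatives), 0.0)
    u, s, _ = np.linalg.svd(sppmi, full_matrices=False)
    k = min(dim, len(s))
    emb = u[:, :k] * np.sqrt(s[:k])
    if k < dim:  # tiny graphs: pad with seeded noise to the requested width
        emb = np.concatenate([emb, rng.normal(scale=1e-3, size=(n_nodes, dim - k))], axis=1)
    return emb


def pretrain_node2vec(
    graph: nx.Graph,
    gene_ids: list[str] | None = None,
    dim: int = 32,
    p: float = 1.0,
    q: float = 1.0,
    walk_length: int = 80,
    num_walks: int = 10,
    window: int = 5,
    weighted: bool = False,
    seed: int = 0,
) -> GeneEmbeddingTable:
    """Pretrain gene embeddings with node2vec on a PPI graph.

    Deterministic given `seed`.  When `gene_ids` is provided the returned
    table covers exactly that list; genes absent from the graph receive
    seeded random-normal fallback vectors of scale 1/sqrt(dim), so the
    expression matrix — not the graph — dictates the gene universe.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot pretrain embeddings on an empty graph")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    walks = _simulate_walks(graph, rng, p, q, walk_length, num_walks, weighted)
    W = _skipgram_factorize(walks, len(nodes), dim, window, rng)

    if gene_ids is None:
        gene_ids = [str(n) for n in nodes]
    vectors = np.empty((len(gene_ids), dim))
    fallback_rng = np.random.default_rng(seed + 1)
    for row, g in enumerate(gene_ids):
        if g in index:
            vectors[row] = W[index[g]]
        else:
            vectors[row] = fallback_rng.normal(scale=1.0 / np.sqrt(dim), size=dim)
    return GeneEmbeddingTable([str(g) for g in gene_ids], vectors)


def randomize_graph(graph: nx.Graph, n_swaps: int, seed: int = 0, max_tries_factor: int = 100) -> nx.Graph:
    """Degree-preserving randomisation via double-edge swaps.

    Each swap exchanges the endpoints of two randomly chosen edges,
    rejecting moves that would create self-loops or duplicate edges, so the
    degree sequence is exactly preserved.  Graphs with no legal swap (e.g.
    a triangle) are returned unchanged after the attempt budget is spent.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to swap")
    out = graph.copy()
    if n_swaps <= 0:
        return out
    try:
        nx.double_edge_swap(out, nswap=n_swaps, max_tries=max_tries_factor * n_swaps, seed=seed)
    except nx.NetworkXException:
        # too few nodes or attempt budget exhausted: return what we have
        # (any completed swaps already preserved the degree sequence)
        pass
    return out


def random_init_embeddings(gene_ids: list[str], dim: int = 32, seed: int = 0) -> GeneEmbeddingTable:
    """Seeded random-normal gene embeddings (no-pretraining ablation)."""
    rng = np.random.default_rng(seed)
    vectors = rng.normal(scale=1.0 / np.sqrt(dim), size=(len(gene_ids), dim))
    return GeneEmbeddingTable([str(g) for g in gene_ids], vectors)
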