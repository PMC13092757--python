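"""Type-specific graph augmentation: protected edge deletion and feature masking.

Nodes split into the sensitive set S_s (incident to at least one sensitive
edge) and its complement S_n. Two perturbed views of the response graph
are drawn per step; in every view the label-critical structure survives
untouched: sensitive edges are never deleted, high-similarity edges are
never deleted, and feature rows of S_s nodes are never masked. The
deletion pool is the resistant edges plus the low-similarity half of each
similarity relation; masking zeroes an exact count of feature dimensions
per S_n node. Sampling is count-based (exactly round(rate * pool) items),
so realized rates equal requested rates and every view is reproducible
from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ResponseGraph


@dataclass(frozen=True)
class NodePartition:
    sensitive: frozenset[int]
    non_sensitive: frozenset[int]


@dataclass
class AugmentedView:
    """A perturbed copy of the response graph plus how it was produced."""

    graph: ResponseGraph
    features: np.ndarray | None
    seed: int
    edge_rate: float
    mask_rate: float
    deleted_edges: list[tuple[str, int, int]] = field(default_factory=list)
    masked_dims: dict[int, np.ndarray] = field(default_factory=dict)


def partition_nodes(graph: ResponseGraph) -> NodePartition:
    """S_s = nodes incident to >= 1 sensitive edge; S_n = the rest."""
    if "sensitive" not in graph.relations:
        raise ValueError("graph has no 'sensitive' relation")
    adj = graph.relations["sensitive"].tocoo()
    sens = set(int(i) for i in adj.row) | set(int(j) for j in adj.col)
    all_nodes = set(range(graph.n_nodes))
    return NodePartition(sensitive=frozenset(sens),
                         non_sensitive=frozenset(all_nodes - sens))


def _deletion_pool(graph: ResponseGraph,
                   protect_resistant: bool = False) -> list[tuple[str, int, int]]:
    """Edges eligible for deletion, as (relation, src, dst) units.

    Resistant edges are pooled as forward units (the inverse follows its
    forward edge); similarity relations contribute their low-similarity
    half as undirected (i < j) units.
    """
    pool: list[tuple[str, int, int]] = []
    if not protect_resistant and "resistant" in graph.relations:
        coo = graph.relations["resistant"].tocoo()
        pool.extend(("resistant", int(i), int(j)) for i, j in zip(coo.row, coo.col))
    for rel in ("cell_sim", "drug_sim"):
        if rel not in graph.relations:
            continue
        scores = graph.similarity_scores.get(rel, {})
        und = sorted({(min(i, j), max(i, j)) for (i, j) in scores})
        ranked = sorted(und, key=lambda e: (scores.get(e, scores.get((e[1], e[0]), 0.0)), e))
        low_half = ranked[: len(ranked) // 2]
        pool.extend((rel, i, j) for i, j in low_half)
    return sorted(pool)


def delete_edges(graph: ResponseGraph, partition: NodePartition, rate: float,
                 seed: int, protect_resistant: bool = False,
                 ) -> tuple[ResponseGraph, list[tuple[str, int, int]]]:
    """Remove exactly round(rate * pool) pool edges, uniformly at random.

    Sensitive edges and the high-similarity half of each similarity
    relation are never in the pool, hence never removed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = graph.copy()
    pool = _deletion_pool(graph, protect_resistant=protect_resistant)
    n_remove = int(np.floor(rate * len(pool) + 0.5))
    if n_remove == 0:
        return out, []
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_remove, replace=False)]
    lil = {rel: out.relations[rel].tolil() for rel in out.relations}
    for rel, i, j in chosen:
        if rel == "resistant":
            lil["resistant"][i, j] = 0.0
            lil["resistant_inv"][j, i] = 0.0
        else:  # similarity: undirected, drop both directions
            lil[rel][i, j] = 0.0
            lil[rel][j, i] = 0.0
    out.relations = {rel: m.tocsr() for rel, m in lil.items()}
    for rel in out.relations:
        out.relations[rel].eliminate_zeros()
    return out, chosen


def mask_features(features: np.ndarray, partition: NodePartition, rate: float,
                  seed: int, ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Zero round(rate * F) feature dimensions of every S_n node.

    Dimensions are drawn independently per node; S_s rows are bit-identical
    to the input.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = np.asarray(features, dtype=np.float64).copy()
    f_dim = out.shape[1]
    n_mask = int(np.floor(rate * f_dim + 0.5))
    masked: dict[int, np.ndarray] = {}
    if n_mask == 0:
        return out, masked
    rng = np.random.default_rng(seed)
    for node in sorted(partition.non_sensitive):
        dims = np.sort(rng.choice(f_dim, size=n_mask, replace=False))
        out[node, dims] = 0.0
        masked[node] = dims
    return out, masked


def make_views(graph: ResponseGraph, edge_rate: float = 0.40,
               mask_rate: float = 0.30, seed: int = 0,
               features: np.ndarray | None = None,
               protect_resistant: bool = False,
               ) -> tuple[AugmentedView, AugmentedView]:
    """Draw the two augmented views G1, G2 with independent sub-seeds.

    Sub-seeds are (seed*2+1, seed*2+2); the default rates (0.40, 0.30) are
    the shipped configuration.
    """
    if features is None:
        features = graph.features
    partition = partition_nodes(graph)
    views = []
    for sub_seed in (seed * 2 + 1, seed * 2 + 2):
        pruned, deleted = delete_edges(graph, partition, edge_rate, sub_seed,
                                       protect_resistant=protect_resistant)
        if features is not None:
            feats, masked = mask_features(features, partition, mask_rate, sub_seed)
        else:
            feats, masked = None, {}
        views.append(AugmentedView(graph=pruned, features=feats, seed=sub_seed,
                                   edge_rate=edge_rate, mask_rate=mask_rate,
                                   deleted_edges=deleted, masked_dims=masked))
    return views[0], views[1]
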