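"""Relational graph convolution over the directed response graph.

Each layer updates node i as

    h_i' = sigma( sum_r sum_{j in N_i^r} (1 / c_{i,r}) W_r h_j  +  W_0 h_i )

where N_i^r are the *incoming* neighbours of i under relation r (messages
flow along edge direction), W_r is a relation-specific weight, W_0 the
self-connection and c_{i,r} = |N_i^r| the in-degree normalizer. The final
node embedding averages the retained per-layer hidden states, treating
each layer as one feature source.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .autodiff import Parameter, Tensor, stack_mean
from .datasets import ResponseGraph
from .nn import Module, glorot


def normalized_message_operators(graph: ResponseGraph) -> dict[str, np.ndarray]:
    """Per-relation dense operators M_r with (M_r @ H)_i = (1/c_{i,r}) sum_{j->i} h_j."""
    ops = {}
    for rel, adj in graph.relations.items():
        at = np.asarray(adj.T.todense() if sp.issparse(adj) else adj.T, dtype=np.float64)
        indeg = at.sum(axis=1)
        at = at / np.where(indeg == 0, 1.0, indeg)[:, None]
        ops[rel] = at
    return ops


class RGCNLayer(Module):
    def __init__(self, relations: tuple[str, ...], width: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.relation_names = tuple(relations)
        self.rel_weights = [Parameter(glorot(rng, width, width)) for _ in relations]
        self.self_weight = Parameter(glorot(rng, width, width))
        self.activation = activation

    def __call__(self, h: Tensor, operators: dict[str, np.ndarray]) -> Tensor:
        missing = set(operators) - set(self.relation_names)
        if missing:
            raise KeyError(f"graph relations {sorted(missing)} have no weights in this layer")
        out = h @ self.self_weight
        for name, w in zip(self.relation_names, self.rel_weights):
            if name not in operators:
                continue  # relation absent from this graph: no messages
            out = out + Tensor(operators[name]) @ (h @ w)
        if self.activation == "relu":
            out = out.relu()
        elif self.activation != "identity":
            raise ValueError(f"unknown activation {self.activation!r}")
        return out


class RGCNEmbedding(Module):
    """l stacked relational layers; embedding = mean of per-layer states."""

    def __init__(self, relations: tuple[str, ...], width: int, n_layers: int,
                 rng: np.random.Generator, activation: str = "relu"):
        if n_layers < 1:
            raise ValueError("need at least one layer")
        self.layers = [RGCNLayer(relations, width, rng, activation)
                       for _ in range(n_layers)]

    def __call__(self, x: Tensor, operators: dict[str, np.ndarray]) -> Tensor:
        states = []
        h = x
        for layer in self.layers:
            h = layer(h, operators)
            states.append(h)
        return stack_mean(states)


# -- functional forms used by tests and oracles -----------------------------


def rgcn_layer(h_in: np.ndarray, graph: ResponseGraph,
               rel_weights: dict[str, np.ndarray], self_weight: np.ndarray,
               activation: str = "relu") -> np.ndarray:
    """One relational layer as a plain array function (no gradients)."""
    for rel in graph.relations:
        if rel not in rel_weights:
            raise KeyError(f"relation {rel!r} present in graph but absent from params")
    ops = normalized_message_operators(graph)
    out = h_in @ self_weight
    for rel, op in ops.items():
        out = out + op @ (h_in @ rel_weights[rel])
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def embed_graph(graph: ResponseGraph, embedding: RGCNEmbedding) -> np.ndarray:
    """Run the stacked layers on the graph's own feature matrix X = [C; D]."""
    if graph.features is None:
        raise ValueError("graph has no node features; set graph.features = [C; D] first")
    ops = normalized_message_operators(graph)
    return embedding(Tensor(graph.features), ops).data
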