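"""Shared graph attention over the augmented views and the joint loss.

A two-layer multi-head graph attention network (hidden layer concatenates
the K head outputs, output layer averages them) encodes both augmented
views with the *same* parameters. The per-view attention output T is
fused with the relational embedding H by elementwise product, and the two
fused views are averaged into the prediction embedding X.

The training objective is L = L1 + L2:

* L1 (alignment) pulls the two views' fused embeddings together — mean
  row-wise Euclidean distance — and pulls each view's per-dimension
  standard deviation toward an anchor phi (the average standard deviation
  of the unperturbed-graph embeddings, recomputed each epoch and treated
  as a constant): L1 = w1 * mean_i ||X1_i - X2_i|| + w2 * sum_d [(s1_d -
  phi)^2 + (s2_d - phi)^2].
* L2 (focal) is the class-imbalance-aware classification loss
  mean[-alpha (1 - p_t)^gamma log p_t] on sensitive(1)/resistant(0) pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .autodiff import Parameter, Tensor, concat
from .nn import MLP, Module, glorot

LEAKY_SLOPE = 0.2
PROB_CLAMP = 1e-7


def attention_mask(adjacencies, n_nodes: int) -> np.ndarray:
    """Boolean attend-to mask: union of the given adjacencies, symmetrized,
    plus self-loops (so isolated nodes attend to themselves)."""
    union = np.zeros((n_nodes, n_nodes), dtype=bool)
    for adj in adjacencies:
        dense = np.asarray(adj.todense() if sp.issparse(adj) else adj) != 0
        union |= dense | dense.T
    union |= np.eye(n_nodes, dtype=bool)
    return union


class GATHead(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(glorot(rng, in_dim, out_dim))
        self.att_src = Parameter(glorot(rng, out_dim, 1, shape=(out_dim, 1)))
        self.att_dst = Parameter(glorot(rng, out_dim, 1, shape=(out_dim, 1)))

    def attention(self, t: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        wt = t @ self.weight
        e_src = wt @ self.att_src              # (N, 1)
        e_dst = (wt @ self.att_dst).transpose()  # (1, N)
        logits = (e_src + e_dst).leaky_relu(LEAKY_SLOPE)
        alpha = logits.masked_row_softmax(mask)
        return alpha, wt

    def __call__(self, t: Tensor, mask: np.ndarray) -> Tensor:
        alpha, wt = self.attention(t, mask)
        return alpha @ wt


class GATLayer(Module):
    """K heads; ``combine`` is 'concat' (hidden) or 'mean' (output layer)."""

    def __init__(self, in_dim: int, head_dim: int, n_heads: int,
                 rng: np.random.Generator, combine: str = "concat"):
        if combine not in ("concat", "mean"):
            raise ValueError(f"unknown combine {combine!r}")
        self.heads = [GATHead(in_dim, head_dim, rng) for _ in range(n_heads)]
        self.combine = combine

    def __call__(self, t: Tensor, mask: np.ndarray) -> Tensor:
        outs = [h(t, mask) for h in self.heads]
        if self.combine == "concat":
            return concat([o.relu() for o in outs], axis=1)
        mean = outs[0]
        for o in outs[1:]:
            mean = mean + o
        return (mean * (1.0 / len(outs))).relu()


class GATEncoder(Module):
    """One concatenating hidden layer + one averaging output layer, width F.

    The same encoder instance (same parameter storage) is applied to the
    original graph and to both augmented views.
    """

    def __init__(self, f_dim: int, n_heads: int, rng: np.random.Generator):
        if f_dim % n_heads != 0:
            raise ValueError(f"F={f_dim} must be divisible by K={n_heads}")
        self.hidden = GATLayer(f_dim, f_dim // n_heads, n_heads, rng, combine="concat")
        self.out = GATLayer(f_dim, f_dim, n_heads, rng, combine="mean")

    def __call__(self, features: Tensor, mask: np.ndarray) -> Tensor:
        return self.out(self.hidden(features, mask), mask)


def gat_encode(features: np.ndarray, adjacency: np.ndarray,
               encoder: GATEncoder) -> np.ndarray:
    """Encode plain arrays: adjacency is unioned/symmetrized with self-loops."""
    mask = attention_mask([adjacency], features.shape[0])
    return encoder(Tensor(np.asarray(features, dtype=np.float64)), mask).data


def fuse_embeddings(t: Tensor | np.ndarray, h: Tensor | np.ndarray) -> Tensor:
    """Per-node fusion of attention output and relational embedding: T .* H."""
    t = t if isinstance(t, Tensor) else Tensor(t)
    h = h if isinstance(h, Tensor) else Tensor(h)
    if t.shape != h.shape:
        raise ValueError(f"shape mismatch: T {t.shape} vs H {h.shape}")
    return t * h


def fuse_views(t1: Tensor, t2: Tensor, h: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Fuse both views with H; the prediction embedding is their mean."""
    x1 = fuse_embeddings(t1, h)
    x2 = fuse_embeddings(t2, h)
    return x1, x2, (x1 + x2) * 0.5


def _row_norms(diff: Tensor, eps: float = 1e-12) -> Tensor:
    # sqrt(x + eps) - sqrt(eps): exact 0 for identical rows, smooth at 0
    sq = (diff * diff).sum(axis=1)
    return (sq + eps).sqrt() - np.sqrt(eps)


def alignment_loss(x1: Tensor | np.ndarray, x2: Tensor | np.ndarray,
                   phi_target: float, omega1: float = 1.0,
                   omega2: float = 1.0) -> Tensor:
    """Statistics-anchored view-alignment loss L1 (see module docstring)."""
    x1 = x1 if isinstance(x1, Tensor) else Tensor(x1)
    x2 = x2 if isinstance(x2, Tensor) else Tensor(x2)
    if x1.shape != x2.shape:
        raise ValueError(f"view shapes differ: {x1.shape} vs {x2.shape}")
    mean_dist = _row_norms(x1 - x2).mean()
    s1 = x1.std(axis=0)
    s2 = x2.std(axis=0)
    std_term = ((s1 - phi_target).pow(2.0)).sum() + ((s2 - phi_target).pow(2.0)).sum()
    return mean_dist * omega1 + std_term * omega2


def std_anchor(h: np.ndarray) -> float:
    """phi: average per-dimension standard deviation of the reference embeddings."""
    return float(np.std(np.asarray(h), axis=0).mean())


def focal_loss(p: Tensor | np.ndarray, y: np.ndarray, alpha_t: float = 0.25,
               gamma: float = 2.0) -> Tensor:
    """Mean focal loss -alpha_t (1 - p_t)^gamma log(p_t).

    p_t is the predicted probability of the true class. gamma=0, alpha_t=1
    reduces to binary cross-entropy. Probabilities at exactly 0 or 1 are
    clamped to [1e-7, 1 - 1e-7] with a warning.
    """
    p = p if isinstance(p, Tensor) else Tensor(p)
    y = np.asarray(y, dtype=np.float64).reshape(p.shape)
    if np.any(p.data <= 0.0) or np.any(p.data >= 1.0):
        warnings.warn("probabilities at 0/1 clamped to avoid log(0)")
        p = _clamp(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    log_pt = p_t.log()
    if gamma == 0.0:
        weighted = log_pt * (-alpha_t)
    else:
        weighted = (1.0 - p_t).pow(gamma) * log_pt * (-alpha_t)
    return weighted.mean()


def _clamp(p: Tensor, lo: float, hi: float) -> Tensor:
    clipped = np.clip(p.data, lo, hi)
    inside = (p.data > lo) & (p.data < hi)

    def bwd(g):
        p._accumulate(g * inside)

    return Tensor(clipped, p.requires_grad, (p,), bwd if p.requires_grad else None)


def total_loss(l1: Tensor, l2: Tensor) -> Tensor:
    """L = L1 + L2, refusing non-finite terms by name."""
    for name, term in (("L1 (alignment)", l1), ("L2 (focal)", l2)):
        data = term.data if isinstance(term, Tensor) else np.asarray(term)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"{name} is non-finite")
    l1 = l1 if isinstance(l1, Tensor) else Tensor(l1)
    l2 = l2 if isinstance(l2, Tensor) else Tensor(l2)
    return l1 + l2


class PairScorer(Module):
    """sigmoid(MLP([X_cell || X_drug])) with two hidden layers."""

    def __init__(self, f_dim: int, rng: np.random.Generator,
                 hidden: tuple[int, int] = (64, 32)):
        self.mlp = MLP([2 * f_dim, hidden[0], hidden[1], 1], rng)

    def __call__(self, x: Tensor, cell_index: np.ndarray,
                 drug_index: np.ndarray) -> Tensor:
        xc = x.gather_rows(np.asarray(cell_index, dtype=np.intp))
        xd = x.gather_rows(np.asarray(drug_index, dtype=np.intp))
        logits = self.mlp(concat([xc, xd], axis=1))
        return logits.sigmoid().reshape(-1)


def score_pairs(x: Tensor | np.ndarray, pairs: list[tuple[int, int]],
                scorer: PairScorer) -> np.ndarray:
    """Probabilities for (cell_node_index, drug_node_index) pairs."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    n = x.shape[0]
    cells = np.array([c for c, _ in pairs], dtype=np.intp)
    drugs = np.array([d for _, d in pairs], dtype=np.intp)
    if len(pairs) and (cells.max() >= n or drugs.max() >= n or cells.min() < 0 or drugs.min() < 0):
        raise IndexError("pair index outside the node registry")
    return scorer(x, cells, drugs).data
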