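"""Per-view convolutional encoding of multi-omics profiles.

Each of the six omics views passes through its own small 1-D convolution
stack (channels 1->8, kernel 7, stride 2), ReLU, adaptive average pooling
to 16 positions and a linear head to F/6 features; the six blocks are
concatenated in the fixed view order (transcriptomics, proteomics, copy
number, mutations, methylation, metabolomics) into one F-dimensional cell
embedding. Disabled views contribute an all-zero block of the same width,
so the embedding dimension is stable across view ablations.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .autodiff import Tensor, concat
from .datasets import VIEW_NAMES, OmicsProfileSet
from .nn import Conv1d, Linear, Module, adaptive_avg_pool

CONV_CHANNELS = 8
CONV_KERNEL = 7
CONV_STRIDE = 2
POOL_TARGET = 16


class ViewEncoder(Module):
    """Conv -> ReLU -> adaptive pool -> linear head for one omics view."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        if in_dim < CONV_KERNEL:
            raise ValueError(f"view width {in_dim} is below the convolution kernel {CONV_KERNEL}")
        self.in_dim = in_dim
        self.conv = Conv1d(CONV_CHANNELS, CONV_KERNEL, CONV_STRIDE, rng)
        self.head = Linear(POOL_TARGET * CONV_CHANNELS, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x).relu()
        pooled = adaptive_avg_pool(h, POOL_TARGET)
        return self.head(pooled)


class OmicsEncoder(Module):
    """Six per-view transforms concatenated into an (n_c, F) matrix."""

    def __init__(self, view_dims: dict[str, int], f_dim: int, rng: np.random.Generator):
        if f_dim % len(VIEW_NAMES) != 0:
            raise ValueError(f"F={f_dim} must be divisible by {len(VIEW_NAMES)}")
        missing = set(VIEW_NAMES) - set(view_dims)
        if missing:
            raise ValueError(f"missing view dims for {sorted(missing)}")
        self.f_dim = f_dim
        self.block = f_dim // len(VIEW_NAMES)
        self.views = [ViewEncoder(view_dims[name], self.block, rng) for name in VIEW_NAMES]

    def __call__(self, omics: OmicsProfileSet | dict[str, np.ndarray],
                 enabled_views: tuple[str, ...] = VIEW_NAMES) -> Tensor:
        return encode_cells(omics, self, enabled_views)


def encode_cells(omics: OmicsProfileSet | dict[str, np.ndarray],
                 encoder: OmicsEncoder,
                 enabled_views: tuple[str, ...] = VIEW_NAMES) -> Tensor:
    """Encode every cell line into an F-dimensional row.

    ``enabled_views`` selects which views contribute; the others emit zero
    blocks of width F/6 so downstream shapes never change.
    """
    views = omics.views if isinstance(omics, OmicsProfileSet) else omics
    if not enabled_views:
        raise ValueError("at least one omics view must be enabled")
    unknown = set(enabled_views) - set(VIEW_NAMES)
    if unknown:
        raise ValueError(f"unknown views {sorted(unknown)}")
    n_cells = next(iter(views.values())).shape[0]
    blocks = []
    for name, view_enc in zip(VIEW_NAMES, encoder.views):
        if name not in enabled_views:
            blocks.append(Tensor(np.zeros((n_cells, encoder.block))))
            continue
        mat = np.asarray(views[name], dtype=np.float64)
        if mat.shape[1] != view_enc.in_dim:
            raise ValueError(
                f"view {name!r} has width {mat.shape[1]}, encoder expects {view_enc.in_dim}")
        blocks.append(view_enc(Tensor(mat)))
    return concat(blocks, axis=1)


def ablate_views(config, drop: tuple[str, ...] | list[str]):
    """Return a config whose dropped views contribute zero blocks.

    ``config`` is any dataclass with an ``enabled_views`` field (e.g.
    :class:`drpgraph.config.ModelConfig`). Dropping every view is an error.
    """
    drop = set(drop)
    unknown = drop - set(VIEW_NAMES)
    if unknown:
        raise ValueError(f"unknown views {sorted(unknown)}")
    remaining = tuple(v for v in config.enabled_views if v not in drop)
    if not remaining:
        raise ValueError("cannot drop all omics views")
    return replace(config, enabled_views=remaining)
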