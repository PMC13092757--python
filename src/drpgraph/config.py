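"""Model and training configuration.

Defaults are the shipped operating point: F = 96-dimensional embeddings,
2 relational layers, K = 3 attention heads, edge-deletion rate 0.40 and
feature-masking rate 0.30, focal loss with alpha = 0.25 / gamma = 2, and
IC50 thresholds (-3, 3) on log10 IC50. Every field is a YAML key and a
CLI flag.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datasets import VIEW_NAMES


@dataclass(frozen=True)
class ModelConfig:
    # embedding widths
    f_dim: int = 96
    rgcn_layers: int = 2
    gat_heads: int = 3
    # graph construction
    low_threshold: float = -3.0
    high_threshold: float = 3.0
    use_similarity: bool = True
    similarity_k: int = 5
    protect_resistant: bool = False
    enabled_views: tuple[str, ...] = VIEW_NAMES
    # augmentation
    edge_rate: float = 0.40
    mask_rate: float = 0.30
    # objective
    omega1: float = 1.0
    omega2: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    score_source: str = "fused"  # {fused, original}
    scorer_hidden: tuple[int, int] = (64, 32)
    # optimization
    lr: float = 1e-3
    weight_decay: float = 1e-5
    max_epochs: int = 300
    min_epochs: int = 100  # early stopping armed only after this epoch
    patience: int = 30
    val_fraction: float = 0.10

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["enabled_views"] = list(self.enabled_views)
        d["scorer_hidden"] = list(self.scorer_hidden)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        if "enabled_views" in d:
            d["enabled_views"] = tuple(d["enabled_views"])
        if "scorer_hidden" in d:
            d["scorer_hidden"] = tuple(d["scorer_hidden"])
        return cls(**d)

    @property
    def relations(self) -> tuple[str, ...]:
        base = ("sensitive", "resistant", "sensitive_inv", "resistant_inv")
        return base + (("cell_sim", "drug_sim") if self.use_similarity else ())
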