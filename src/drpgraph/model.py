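"""End-to-end model: encoders + relational embedding + augmented-view objective.

One training step:

1. Encode omics views into C and drug graphs into D; stack X0 = [C; D].
2. Run the relational graph convolution on the (training-edge) response
   graph to get H, and the statistics anchor phi from H.
3. Draw two augmented views (protected edge deletion + feature masking,
   fresh sub-seeds each epoch); encode each with the *shared* graph
   attention encoder; fuse with H (elementwise product) into X1, X2 and
   the prediction embedding X = (X1 + X2) / 2.
4. L = L1(X1, X2; phi) + focal(scores(X, train pairs), labels); Adam step.

Inference re-runs the same pipeline without perturbation (the attention
encoder sees the original graph) and scores pairs from the fused
embedding (or from H when ``score_source='original'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import make_views, partition_nodes
from .autodiff import Tensor, concat
from .config import ModelConfig
from .datasets import (VIEW_NAMES, OmicsProfileSet, ResponseGraph,
                       ResponseRecord, attach_similarity_edges,
                       build_response_graph)
from .drugs import DrugEncoder, MolecularGraph, morgan_fingerprints, smiles_to_graph
from .evaluation import binary_labels, evaluate
from .nn import Adam, Module
from .objective import (GATEncoder, PairScorer, alignment_loss,
                        attention_mask, focal_loss, fuse_views, std_anchor,
                        total_loss)
from .omics import OmicsEncoder
from .rgcn import RGCNEmbedding, normalized_message_operators


@dataclass
class PreparedData:
    """Standardized inputs shared by training and inference."""

    views: dict[str, np.ndarray]
    cell_ids: list[str]
    drug_ids: list[str]
    drug_graphs: list[MolecularGraph]
    fingerprints: np.ndarray
    records: list[ResponseRecord]  # sensitive/resistant only


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    l1: list[float] = field(default_factory=list)
    l2: list[float] = field(default_factory=list)
    val_aupr: list[float] = field(default_factory=list)
    best_epoch: int = -1


class DrugResponseModel(Module):
    def __init__(self, config: ModelConfig, view_dims: dict[str, int], seed: int):
        rng = np.random.default_rng(seed)
        self.config = config
        self.omics_encoder = OmicsEncoder(view_dims, config.f_dim, rng)
        self.drug_encoder = DrugEncoder(config.f_dim, rng)
        self.rgcn = RGCNEmbedding(config.relations, config.f_dim,
                                  config.rgcn_layers, rng)
        self.gat = GATEncoder(config.f_dim, config.gat_heads, rng)
        self.scorer = PairScorer(config.f_dim, rng, hidden=config.scorer_hidden)

    def node_features(self, data: PreparedData) -> Tensor:
        c = self.omics_encoder(data.views, self.config.enabled_views)
        d = self.drug_encoder(data.drug_graphs)
        return concat([c, d], axis=0)


def prepare_data(omics: OmicsProfileSet, smiles: list[tuple[str, str]],
                 records: list[ResponseRecord]) -> PreparedData:
    """Impute (median), z-score each view, parse drugs, drop uncorrelated pairs."""
    views: dict[str, np.ndarray] = {}
    for name in VIEW_NAMES:
        mat = np.asarray(omics.views[name], dtype=np.float64).copy()
        if np.isnan(mat).any():
            med = np.nanmedian(mat, axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            idx = np.where(np.isnan(mat))
            mat[idx] = med[idx[1]]
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        views[name] = (mat - mu) / np.where(sd == 0, 1.0, sd)
    drug_ids = [d for d, _ in smiles]
    graphs = [smiles_to_graph(s, drug_id=d) for d, s in smiles]
    fps = morgan_fingerprints([s for _, s in smiles])
    labeled = [r for r in records if r.label in ("sensitive", "resistant")]
    return PreparedData(views=views, cell_ids=list(omics.cell_ids),
                        drug_ids=drug_ids, drug_graphs=graphs,
                        fingerprints=fps, records=labeled)


def build_training_graph(data: PreparedData, train_records: list[ResponseRecord],
                         config: ModelConfig) -> ResponseGraph:
    """Response graph holding only *training* response edges plus similarity."""
    graph = build_response_graph(data.cell_ids, data.drug_ids, train_records)
    if config.use_similarity:
        cell_feats = np.concatenate([data.views[v] for v in VIEW_NAMES], axis=1)
        attach_similarity_edges(graph, cell_feats, data.fingerprints,
                                k=config.similarity_k)
    return graph


def pair_indices(records: list[ResponseRecord], graph: ResponseGraph) -> np.ndarray:
    return np.array([[graph.node_index(r.cell_id), graph.node_index(r.drug_id)]
                     for r in records], dtype=np.intp)


def _forward_inference(model: DrugResponseModel, data: PreparedData,
                       graph: ResponseGraph) -> np.ndarray:
    """Deterministic unperturbed forward pass; returns the scoring embedding."""
    x0 = model.node_features(data)
    ops = normalized_message_operators(graph)
    h = model.rgcn(x0, ops)
    if model.config.score_source == "original":
        return h.data
    mask = attention_mask(graph.relations.values(), graph.n_nodes)
    t = model.gat(x0, mask)
    return (t * h).data


def predict(model: DrugResponseModel, data: PreparedData, graph: ResponseGraph,
            records: list[ResponseRecord]) -> np.ndarray:
    """Response probabilities for (cell, drug) pairs under the trained model."""
    x = _forward_inference(model, data, graph)
    idx = pair_indices(records, graph)
    return model.scorer(Tensor(x), idx[:, 0], idx[:, 1]).data


def train_model(data: PreparedData, train_records: list[ResponseRecord],
                config: ModelConfig, seed: int,
                ) -> tuple[DrugResponseModel, TrainHistory]:
    """Fit the joint objective on the given training pairs.

    A stratified ``val_fraction`` of the training pairs is held out for
    early stopping on validation AUPR; the best parameters are restored.
    """
    y_all = binary_labels(train_records)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training fold contains a single class")

    rng = np.random.default_rng(seed)
    n = len(train_records)
    n_val = int(round(config.val_fraction * n))
    order = rng.permutation(n)
    val_idx = order[:n_val]
    fit_idx = order[n_val:]
    if n_val and len(np.unique(y_all[val_idx])) < 2:
        # rotate until the validation slice holds both classes
        for shift in range(1, n):
            val_idx = order[shift:shift + n_val]
            rest = np.setdiff1d(order, val_idx, assume_unique=False)
            if len(np.unique(y_all[val_idx])) == 2:
                fit_idx = rest
                break
    fit_records = [train_records[i] for i in fit_idx]
    val_records = [train_records[i] for i in val_idx]

    graph = build_training_graph(data, fit_records, config)
    view_dims = {k: v.shape[1] for k, v in data.views.items()}
    model = DrugResponseModel(config, view_dims, seed=seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    fit_pairs = pair_indices(fit_records, graph)
    y_fit = binary_labels(fit_records)
    partition = partition_nodes(graph)
    ops = normalized_message_operators(graph)

    history = TrainHistory()
    best_state: dict | None = None
    best_val = -np.inf
    patience_left = config.patience

    for epoch in range(config.max_epochs):
        x0 = model.node_features(data)
        h = model.rgcn(x0, ops)
        phi = std_anchor(h.data)  # stop-gradient anchor, refreshed per epoch

        epoch_seed = (seed * 1_000_003 + epoch) % (2**31 - 1)
        v1, v2 = make_views(graph, edge_rate=config.edge_rate,
                            mask_rate=config.mask_rate, seed=epoch_seed,
                            features=x0.data,
                            protect_resistant=config.protect_resistant)
        t_views = []
        for view in (v1, v2):
            mask_nodes = np.ones((graph.n_nodes, x0.shape[1]))
            for node, dims in view.masked_dims.items():
                mask_nodes[node, dims] = 0.0
            feats = x0 * mask_nodes  # differentiable masking of the shared X0
            att_mask = attention_mask(view.graph.relations.values(), graph.n_nodes)
            t_views.append(model.gat(feats, att_mask))
        x1, x2, x = fuse_views(t_views[0], t_views[1], h)

        l1 = alignment_loss(x1, x2, phi_target=phi, omega1=config.omega1,
                            omega2=config.omega2)
        p = model.scorer(x, fit_pairs[:, 0], fit_pairs[:, 1])
        l2 = focal_loss(p, y_fit, alpha_t=config.focal_alpha,
                        gamma=config.focal_gamma)
        loss = total_loss(l1, l2)

        opt.zero_grad()
        loss.backward()
        opt.step()

        history.loss.append(float(loss.data))
        history.l1.append(float(l1.data))
        history.l2.append(float(l2.data))

        if val_records:
            val_scores = predict(model, data, graph, val_records)
            val_metrics = evaluate(val_scores, binary_labels(val_records))
            val_aupr = val_metrics["aupr"]
        else:
            val_aupr = -history.loss[-1]
        history.val_aupr.append(float(val_aupr))

        if val_aupr > best_val + 1e-6:
            best_val = val_aupr
            best_state = model.state_dict()
            history.best_epoch = epoch
            patience_left = config.patience
        elif epoch >= config.min_epochs:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def save_checkpoint(model: DrugResponseModel, view_dims: dict[str, int],
                    path) -> None:
    """Single-file checkpoint: versioned header, config and all weights."""
    import json

    from dataclasses import asdict

    header = {"format": "drpgraph-checkpoint", "version": 1,
              "config": asdict(model.config), "view_dims": view_dims}
    header["config"]["enabled_views"] = list(model.config.enabled_views)
    header["config"]["scorer_hidden"] = list(model.config.scorer_hidden)
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> DrugResponseModel:
    import json

    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        if header.get("format") != "drpgraph-checkpoint":
            raise ValueError(f"{path} is not a drpgraph checkpoint")
        state = {k: npz[k] for k in npz.files if k != "__header__"}
    config = ModelConfig.from_dict(header["config"])
    model = DrugResponseModel(config, header["view_dims"], seed=0)
    model.load_state_dict(state)
    return model


def run_fold(data: PreparedData, train_records: list[ResponseRecord],
             test_records: list[ResponseRecord], config: ModelConfig,
             seed: int):
    """Train on one fold and score its test pairs.

    Returns (test scores, test labels, history, model, graph). The graph
    used for scoring carries only training response edges, so test pairs
    are never visible to message passing.
    """
    model, history = train_model(data, train_records, config, seed)
    graph = build_training_graph(data, train_records, config)
    scores = predict(model, data, graph, test_records)
    return scores, binary_labels(test_records), history, model, graph


def raw_pair_features(data: PreparedData, records: list[ResponseRecord],
                      max_fp: int = 256) -> np.ndarray:
    """Concatenated standardized omics + truncated fingerprint per pair.

    The flat feature representation the logistic reference model consumes.
    """
    cell_feats = np.concatenate([data.views[v] for v in VIEW_NAMES], axis=1)
    cell_index = {c: i for i, c in enumerate(data.cell_ids)}
    drug_index = {d: i for i, d in enumerate(data.drug_ids)}
    fps = data.fingerprints[:, :max_fp]
    rows = [np.concatenate([cell_feats[cell_index[r.cell_id]],
                            fps[drug_index[r.drug_id]]]) for r in records]
    return np.stack(rows)
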