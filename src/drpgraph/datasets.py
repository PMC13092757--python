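"""Reading omics/drug/response tables and assembling the response graph.

The central object is the directed heterogeneous response graph: cell-line
and drug nodes, one adjacency matrix per relation. Sensitive and resistant
screening outcomes are kept in *separate* adjacencies (a pair can carry at
most one), inverse relations are materialized so messages reach both node
types, and optional within-type similarity edges connect each node to its
k nearest neighbours under cosine (cells) or Tanimoto (drugs) similarity.

Sensitivity labels come from thresholds on log10 IC50: below the low
threshold the cell line is sensitive to the drug, above the high threshold
resistant, strictly between the two the pair is recorded but treated as
uncorrelated and excluded from training edges and the classification loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Fixed view order: transcriptomics, proteomics, copy number, mutations,
#: DNA methylation, metabolomics.
VIEW_NAMES = (
    "transcriptomics",
    "proteomics",
    "copy_number",
    "mutations",
    "methylation",
    "metabolomics",
)

SENSITIVE = "sensitive"
RESISTANT = "resistant"
UNCORRELATED = "uncorrelated"

#: Full relation set of the heterogeneous graph.
RELATIONS = ("sensitive", "resistant", "sensitive_inv", "resistant_inv",
             "cell_sim", "drug_sim")

DEFAULT_LOW_THRESHOLD = -3.0
DEFAULT_HIGH_THRESHOLD = 3.0


@dataclass
class ResponseRecord:
    cell_id: str
    drug_id: str
    log_ic50: float
    label: str | None = None


@dataclass
class LabelSummary:
    """Labeled records plus class counts and any rejected rows."""

    records: list[ResponseRecord]
    counts: dict[str, int]
    rejected: list[ResponseRecord] = field(default_factory=list)


@dataclass
class OmicsProfileSet:
    """Six row-aligned per-view feature matrices for one cell-line cohort."""

    views: dict[str, np.ndarray]
    cell_ids: list[str]

    def __post_init__(self):
        n = len(self.cell_ids)
        for name, mat in self.views.items():
            if mat.shape[0] != n:
                raise ValueError(f"view {name!r} has {mat.shape[0]} rows, expected {n}")
            if mat.shape[1] == 0:
                raise ValueError(f"view {name!r} has zero columns")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def concatenated(self) -> np.ndarray:
        """All views side by side in the fixed view order."""
        return np.concatenate([self.views[v] for v in VIEW_NAMES if v in self.views], axis=1)


@dataclass
class SimilarityEdges:
    """Symmetric binary k-NN adjacency plus per-edge similarity scores."""

    adjacency: sp.csr_matrix
    scores: dict[tuple[int, int], float]


@dataclass
class ResponseGraph:
    """Directed heterogeneous multigraph over cell and drug nodes.

    Node order is cells first then drugs, 0-based. ``relations`` maps a
    relation name to an (N, N) binary sparse adjacency with A[src, dst]=1.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    relations: dict[str, sp.csr_matrix]
    features: np.ndarray | None = None
    similarity_scores: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_cells + self.n_drugs

    @property
    def node_ids(self) -> list[str]:
        return list(self.cell_ids) + list(self.drug_ids)

    def node_index(self, node_id: str) -> int:
        if not hasattr(self, "_index"):
            self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        return self._index[node_id]

    def node_type(self, index: int) -> str:
        return "cell" if index < self.n_cells else "drug"

    def copy(self) -> "ResponseGraph":
        return ResponseGraph(
            cell_ids=list(self.cell_ids),
            drug_ids=list(self.drug_ids),
            relations={k: v.copy() for k, v in self.relations.items()},
            features=None if self.features is None else self.features.copy(),
            similarity_scores={k: dict(v) for k, v in self.similarity_scores.items()},
        )

    def edge_list(self) -> pd.DataFrame:
        """All edges as (src, dst, relation) rows, for export/inspection."""
        rows = []
        ids = self.node_ids
        for rel, adj in self.relations.items():
            coo = adj.tocoo()
            for i, j in zip(coo.row, coo.col):
                rows.append((ids[i], ids[j], rel))
        return pd.DataFrame(rows, columns=["src", "dst", "relation"])


# ---------------------------------------------------------------------------
# labeling


def label_responses(records: list[ResponseRecord],
                    low_threshold: float = DEFAULT_LOW_THRESHOLD,
                    high_threshold: float = DEFAULT_HIGH_THRESHOLD) -> LabelSummary:
    """Assign sensitive/resistant/uncorrelated labels from log10 IC50.

    log_ic50 < low_threshold -> sensitive; log_ic50 > high_threshold ->
    resistant; strictly in between -> uncorrelated. Records with a
    non-finite IC50 are collected in ``rejected`` rather than dropped
    silently.
    """
    if not low_threshold < high_threshold:
        raise ValueError(f"low_threshold {low_threshold} must be < high_threshold {high_threshold}")
    labeled: list[ResponseRecord] = []
    rejected: list[ResponseRecord] = []
    counts = {SENSITIVE: 0, RESISTANT: 0, UNCORRELATED: 0}
    for rec in records:
        if not np.isfinite(rec.log_ic50):
            rejected.append(rec)
            continue
        if rec.log_ic50 < low_threshold:
            label = SENSITIVE
        elif rec.log_ic50 > high_threshold:
            label = RESISTANT
        else:
            label = UNCORRELATED
        counts[label] += 1
        labeled.append(ResponseRecord(rec.cell_id, rec.drug_id, rec.log_ic50, label))
    return LabelSummary(records=labeled, counts=counts, rejected=rejected)


# ---------------------------------------------------------------------------
# graph assembly


def build_response_graph(cells: OmicsProfileSet | list[str],
                         drug_ids: list[str],
                         labeled: list[ResponseRecord]) -> ResponseGraph:
    """Build the directed response graph from labeled records.

    Sensitive and resistant records each contribute one cell->drug edge in
    their own adjacency plus the materialized inverse (drug->cell) edge;
    uncorrelated records contribute nothing. Similarity edges and node
    features are attached later.
    """
    cell_ids = cells.cell_ids if isinstance(cells, OmicsProfileSet) else list(cells)
    cell_idx = {c: i for i, c in enumerate(cell_ids)}
    drug_idx = {d: i for i, d in enumerate(drug_ids)}
    n = len(cell_ids) + len(drug_ids)

    seen: dict[tuple[str, str], str] = {}
    rows = {SENSITIVE: ([], []), RESISTANT: ([], [])}
    for rec in labeled:
        if rec.label is None:
            raise ValueError(f"record ({rec.cell_id}, {rec.drug_id}) is unlabeled")
        if rec.cell_id not in cell_idx:
            raise KeyError(f"unknown cell ID {rec.cell_id!r}")
        if rec.drug_id not in drug_idx:
            raise KeyError(f"unknown drug ID {rec.drug_id!r}")
        key = (rec.cell_id, rec.drug_id)
        if key in seen:
            if seen[key] != rec.label:
                raise ValueError(
                    f"conflicting labels for pair {key}: {seen[key]} vs {rec.label}")
            continue
        seen[key] = rec.label
        if rec.label == UNCORRELATED:
            continue
        src = cell_idx[rec.cell_id]
        dst = len(cell_ids) + drug_idx[rec.drug_id]
        rows[rec.label][0].append(src)
        rows[rec.label][1].append(dst)

    relations: dict[str, sp.csr_matrix] = {}
    for rel in (SENSITIVE, RESISTANT):
        r, c = rows[rel]
        adj = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))
        relations[rel] = adj
        relations[rel + "_inv"] = adj.T.tocsr()
    return ResponseGraph(cell_ids=list(cell_ids), drug_ids=list(drug_ids),
                         relations=relations)


def compute_similarity_edges(features: np.ndarray, k: int,
                             metric: str = "cosine") -> SimilarityEdges:
    """Symmetric k-nearest-neighbour similarity adjacency within one node type.

    Each node is linked to its k most similar other nodes; the union of the
    directed top-k choices is taken, so degrees range from k to 2k. Scores
    are kept per edge so augmentation can pool the low-similarity half for
    deletion. All-zero feature rows have similarity 0 against everything
    (with a warning) and still receive edges through top-k ties.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of rows {n}")
    if not np.all(np.isfinite(features)):
        raise ValueError("similarity features must be finite")

    if metric == "cosine":
        norms = np.linalg.norm(features, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero feature rows: similarity set to 0")
        safe = np.where(zero, 1.0, norms)
        unit = features / safe[:, None]
        sim = unit @ unit.T
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
    elif metric == "tanimoto":
        binary = (features > 0).astype(np.float64)
        inter = binary @ binary.T
        card = binary.sum(axis=1)
        union = card[:, None] + card[None, :] - inter
        zero = card == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero fingerprint rows: similarity set to 0")
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(union > 0, inter / np.where(union == 0, 1.0, union), 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    np.fill_diagonal(sim, -np.inf)  # exclude self-similarity
    scores: dict[tuple[int, int], float] = {}
    rows_i, rows_j = [], []
    for i in range(n):
        top = np.argpartition(-sim[i], k)[:k]
        for j in top:
            j = int(j)
            for a, b in ((i, j), (j, i)):  # symmetrize by union
                if (a, b) not in scores:
                    scores[(a, b)] = max(float(sim[i, j]), 0.0) if np.isfinite(sim[i, j]) else 0.0
                    rows_i.append(a)
                    rows_j.append(b)
    adj = sp.csr_matrix((np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n))
    return SimilarityEdges(adjacency=adj, scores=scores)


def attach_similarity_edges(graph: ResponseGraph,
                            cell_features: np.ndarray | None = None,
                            drug_features: np.ndarray | None = None,
                            k: int = 5) -> ResponseGraph:
    """Add cell-cell (cosine) and drug-drug (Tanimoto) similarity relations in place."""
    n = graph.n_nodes
    nc = graph.n_cells
    for name, feats, metric, offset in (
        ("cell_sim", cell_features, "cosine", 0),
        ("drug_sim", drug_features, "tanimoto", nc),
    ):
        if feats is None:
            continue
        sim = compute_similarity_edges(feats, k=k, metric=metric)
        coo = sim.adjacency.tocoo()
        adj = sp.csr_matrix(
            (coo.data, (coo.row + offset, coo.col + offset)), shape=(n, n))
        graph.relations[name] = adj
        graph.similarity_scores[name] = {
            (i + offset, j + offset): s for (i, j), s in sim.scores.items()}
    return graph


# ---------------------------------------------------------------------------
# file I/O


def read_omics_tables(paths: dict[str, str | Path],
                      sep: str | None = None) -> tuple[OmicsProfileSet, list[str]]:
    """Read one CSV/TSV per omics view and align them on shared cell IDs.

    Each table has a header of feature names and cell IDs in the first
    column. Views are restricted to the intersection of cell IDs (dropped
    IDs are returned), missing values are median-imputed per column, and
    each column is z-scored (constant columns map to 0).
    """
    frames: dict[str, pd.DataFrame] = {}
    for view, path in paths.items():
        path = Path(path)
        use_sep = sep or ("\t" if path.suffix in {".tsv", ".tab"} else ",")
        frames[view] = pd.read_csv(path, sep=use_sep, index_col=0)

    common: set[str] | None = None
    for df in frames.values():
        ids = set(df.index.astype(str))
        common = ids if common is None else (common & ids)
    if not common:
        counts = {v: len(df) for v, df in frames.items()}
        raise ValueError(f"no cell IDs shared across views; per-view counts: {counts}")

    cell_ids = sorted(common)
    dropped = sorted({str(i) for df in frames.values() for i in df.index} - common)

    views: dict[str, np.ndarray] = {}
    for view, df in frames.items():
        df.index = df.index.astype(str)
        mat = df.loc[cell_ids].to_numpy(dtype=np.float64)
        med = np.nanmedian(mat, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        idx = np.where(np.isnan(mat))
        mat[idx] = med[idx[1]]
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        mat = (mat - mu) / np.where(sd == 0, 1.0, sd)
        views[view] = mat
    return OmicsProfileSet(views=views, cell_ids=cell_ids), dropped


def read_response_table(path: str | Path) -> list[ResponseRecord]:
    """Read a (cell_id, drug_id, log10_ic50) CSV into unlabeled records."""
    df = pd.read_csv(path)
    cols = list(df.columns[:3])
    return [ResponseRecord(str(r[cols[0]]), str(r[cols[1]]), float(r[cols[2]]))
            for _, r in df.iterrows()]


def read_smiles_table(path: str | Path) -> list[tuple[str, str]]:
    """Read (drug_id, smiles) pairs from a 2-column CSV or .smi file."""
    path = Path(path)
    if path.suffix == ".smi":
        pairs = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            drug_id = parts[1] if len(parts) > 1 else smiles
            pairs.append((drug_id, smiles))
        return pairs
    df = pd.read_csv(path)
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def write_edge_list(graph: ResponseGraph, path: str | Path) -> None:
    graph.edge_list().to_csv(path, sep="\t", index=False)
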