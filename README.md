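# drpgraph

Drug-response prediction for cancer cell lines on a directed heterogeneous
cell-line/drug graph, with multi-omics encoders, relation-aware graph
convolution and type-specific graph augmentation.

## Who this is for

Computational pharmacogenomics groups who have (i) per-cell-line omics
tables (transcriptomics, proteomics, copy-number variation, mutations, DNA
methylation, metabolomics), (ii) drug structures as SMILES, and (iii) a
screening table of log10 IC50 values, and who want to predict which
(cell line, drug) pairs are *sensitive* under heavy class imbalance
(sensitive responses are typically ~10% of labeled pairs).

## The model

Responses are thresholded on log10 IC50: `< −3` sensitive, `> 3` resistant,
in between uncorrelated (recorded but excluded from training). Cell lines
and drugs are nodes of a directed multigraph G = (V, E, R) whose relations
are the sensitive and resistant response edges (one adjacency matrix each,
with materialized inverses) plus within-type k-NN similarity edges (cosine
over concatenated omics for cells, Tanimoto over Morgan fingerprints for
drugs).

* **Cell encoder** — each omics view c_t, c_p, c_c, c_m, c_d, c_e passes
  through its own 1-D convolutional transform g_*; the cell embedding is
  `c = concat[g_t(c_t), …, g_e(c_e)] ∈ R^F` (F = 96).
* **Drug encoder** — SMILES → molecular graph (atoms/bonds) → two-layer
  graph convolution φ(·) with mean readout → R^F.
* **Relational embedding** — per layer,
  `h_i' = σ(Σ_r Σ_{j∈N_i^r} (1/c_{i,r}) W_r h_j + W_0 h_i)` with one weight
  matrix per relation and in-degree normalizer c_{i,r}; node embeddings H
  average the per-layer states (depth l = 2).
* **Augmented views** — nodes incident to a sensitive edge form the
  protected set S_s. Two views G1, G2 are drawn per epoch by deleting a
  fixed fraction (40%) of the non-critical edge pool (resistant +
  low-similarity edges) and zeroing 30% of the feature dimensions of each
  non-protected node. A shared K = 3-head graph attention encoder produces
  T1, T2; fusion X_v = T_v ⊙ H, and X = (X1 + X2)/2 feeds a small MLP that
  scores pairs.
* **Objective** — `L = L1 + L2` where
  `L1 = ω1·mean_i‖X1_i − X2_i‖ + ω2·Σ_d[(s1_d − φ)² + (s2_d − φ)²]`
  aligns the views and anchors their per-dimension standard deviations to
  φ (the average std of the unperturbed embeddings), and
  `L2 = mean[−α_t (1 − p_t)^γ log p_t]` is the focal loss (α_t = 0.25,
  γ = 2) on sensitive(1)/resistant(0) pairs.

Everything runs on numpy through a small reverse-mode autodiff engine in
`drpgraph.autodiff`; no GPU or deep-learning framework is required.

## Worked example

```python
from drpgraph import ModelConfig, generate_cohort, make_splits, evaluate, prepare_data
from drpgraph.model import run_fold

cohort = generate_cohort(n_cells=100, n_drugs=80, k_latent=8,
                         noise_sd=0.3, target_prevalence=0.10, seed=1)
data = prepare_data(cohort.omics, cohort.smiles, cohort.responses)
plan = make_splits(data.records, mode="random_pair", n_folds=5, seed=1)
tr, te = plan.folds[0]
scores, labels, history, model, graph = run_fold(
    data, [data.records[i] for i in tr], [data.records[i] for i in te],
    ModelConfig(), seed=1)
print(evaluate(scores, labels))
```

prints (seed 1):

```
{'auc': 0.9404907226562501, 'aupr': 0.7189394445579477,
 'accuracy': 0.93125, 'precision': 0.7325581395348837,
 'recall': 0.4921875, 'f1': 0.5887850467289719}
```

i.e. on a synthetic cohort with 10% sensitive prevalence, held-out pairs
are ranked with AUC ≈ 0.94 and AUPR ≈ 0.72 (an uninformative scorer would
sit at AUPR ≈ 0.10, the prevalence). A logistic regression on the raw
concatenated omics + fingerprint features reaches AUC ≈ 0.74 on the same
split; the DeLong test puts the difference at p ≪ 0.001.

The same pipeline is available from the shell:

```sh
drpgraph simulate --out cohort/ --n-cells 100 --n-drugs 80 --seed 1
drpgraph train --data-dir cohort/ --out-dir run/ \
    --edge-rate 0.4 --mask-rate 0.3 --layers 2 --heads 3
drpgraph evaluate --data-dir cohort/ --run-dir run/
drpgraph ablate --data-dir cohort/ --out sweep.csv --grid edge_rate=0,0.2,0.4,0.6,0.8
```

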