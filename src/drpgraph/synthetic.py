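"""Synthetic desk-scale cohorts with the statistical structure the model assumes.

Cell lines live on a shared k-dimensional latent U; each omics view is a
random linear readout of U plus view-specific Gaussian noise. Drugs are
sampled from a packaged library of valid SMILES and their latent V is the
leading principal directions of their hashed circular fingerprints, so
chemical structure is genuinely informative about response. The response
score is the bilinear form s = U Vᵀ + b; pairs in the top quantile of s
get a planted log10 IC50 below the sensitive threshold, the bottom band
gets one above the resistant threshold, and a middle band falls strictly
between the thresholds (uncorrelated), so downstream threshold labeling
recovers the planted classes exactly.

Everything is a pure function of the seed: the same seed reproduces every
field bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (VIEW_NAMES, OmicsProfileSet, ResponseRecord,
                       DEFAULT_HIGH_THRESHOLD, DEFAULT_LOW_THRESHOLD,
                       SENSITIVE, RESISTANT, UNCORRELATED)
from .drugs import morgan_fingerprints

DEFAULT_VIEW_DIMS = (64, 48, 48, 48, 48, 16)


@dataclass
class SyntheticTruth:
    """Planted generative state, exported so tests can score any predictor."""

    cell_latents: np.ndarray   # U (n_c, k)
    drug_latents: np.ndarray   # V (n_d, k)
    bias: float
    scores: np.ndarray         # s = U Vᵀ + b (n_c, n_d)
    noise_sd: float
    seed: int


@dataclass
class SyntheticCohort:
    omics: OmicsProfileSet
    smiles: list[tuple[str, str]]          # (drug_id, SMILES)
    responses: list[ResponseRecord]        # labeled
    truth: SyntheticTruth

    @property
    def drug_ids(self) -> list[str]:
        return [d for d, _ in self.smiles]


def load_smiles_library() -> list[tuple[str, str]]:
    """The packaged library of valid small-molecule SMILES (>=400 entries)."""
    with resources.files("drpgraph.data").joinpath("drug_smiles.csv").open() as fh:
        df = pd.read_csv(fh)
    return [(str(a), str(b)) for a, b in zip(df["drug_id"], df["smiles"])]


def _drug_latents_from_structure(smiles: list[str], k: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Leading fingerprint principal directions, standardized per component."""
    fps = morgan_fingerprints(smiles)
    centered = fps - fps.mean(axis=0)
    # SVD sign fixed deterministically so latents do not flip between runs
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs = np.where(signs == 0, 1.0, signs)
    scores = u[:, :k] * s[:k] * signs[:k]
    sd = scores.std(axis=0)
    scores = scores / np.where(sd == 0, 1.0, sd)
    if scores.shape[1] < k:  # more latent dims than informative directions
        extra = rng.standard_normal((scores.shape[0], k - scores.shape[1]))
        scores = np.concatenate([scores, extra], axis=1)
    return scores


def generate_cohort(n_cells: int = 192, n_drugs: int = 352, k_latent: int = 8,
                    view_dims: tuple[int, ...] = DEFAULT_VIEW_DIMS,
                    noise_sd: float = 0.5, target_prevalence: float = 0.10,
                    seed: int = 0, uncorrelated_frac: float = 0.2,
                    bias: float = 0.0) -> SyntheticCohort:
    """Generate a cohort of ``n_cells`` cell lines screened against ``n_drugs``.

    ``target_prevalence`` is the sensitive fraction among *labeled*
    (sensitive + resistant) pairs; ``uncorrelated_frac`` of all pairs is
    planted in the middle IC50 band and excluded from that denominator.
    """
    if n_cells < 1 or n_drugs < 1 or k_latent < 1:
        raise ValueError("all dimensions must be >= 1")
    if not 0.0 < target_prevalence < 0.5:
        raise ValueError("target_prevalence must lie in (0, 0.5)")
    if len(view_dims) != len(VIEW_NAMES):
        raise ValueError(f"need {len(VIEW_NAMES)} view dims, got {len(view_dims)}")
    for name, d in zip(VIEW_NAMES, view_dims):
        if d < k_latent:
            raise ValueError(
                f"view {name!r} has {d} columns < k_latent={k_latent}; latent not recoverable")

    rng = np.random.default_rng(seed)
    library = load_smiles_library()
    if n_drugs > len(library):
        raise ValueError(f"n_drugs={n_drugs} exceeds the packaged library ({len(library)})")
    order = rng.permutation(len(library))[:n_drugs]
    smiles = [library[i] for i in order]

    cell_ids = [f"CELL{i:04d}" for i in range(n_cells)]
    u_lat = rng.standard_normal((n_cells, k_latent))
    v_lat = _drug_latents_from_structure([s for _, s in smiles], k_latent, rng)

    views: dict[str, np.ndarray] = {}
    for name, d in zip(VIEW_NAMES, view_dims):
        w = rng.standard_normal((k_latent, d)) / np.sqrt(k_latent)
        views[name] = u_lat @ w + noise_sd * rng.standard_normal((n_cells, d))
    omics = OmicsProfileSet(views=views, cell_ids=cell_ids)

    scores = u_lat @ v_lat.T + bias
    flat = scores.ravel()
    n_pairs = flat.size
    sens_frac = target_prevalence * (1.0 - uncorrelated_frac)
    c_hi = np.quantile(flat, 1.0 - sens_frac)
    c_lo = np.quantile(flat, 1.0 - sens_frac - uncorrelated_frac)

    # monotone decreasing map from score band to log10 IC50 band:
    # high score -> sensitive (IC50 < low threshold), middle -> uncorrelated,
    # low -> resistant (IC50 > high threshold)
    lo_t, hi_t = DEFAULT_LOW_THRESHOLD, DEFAULT_HIGH_THRESHOLD
    log_ic50 = np.empty(n_pairs)
    eps = 0.1

    def band_map(values, v_lo, v_hi, out_lo, out_hi):
        span = max(v_hi - v_lo, 1e-12)
        frac = np.clip((values - v_lo) / span, 0.0, 1.0)
        return out_hi - frac * (out_hi - out_lo)  # decreasing in the score

    sens = flat > c_hi
    res = flat < c_lo
    unc = ~(sens | res)
    smax, smin = flat.max(), flat.min()
    log_ic50[sens] = band_map(flat[sens], c_hi, max(smax, c_hi + 1e-9),
                              2 * lo_t + eps, lo_t - eps)
    log_ic50[unc] = band_map(flat[unc], c_lo, c_hi, lo_t + eps, hi_t - eps)
    log_ic50[res] = band_map(flat[res], min(smin, c_lo - 1e-9), c_lo,
                             hi_t + eps, 2 * hi_t - eps)

    drug_ids = [d for d, _ in smiles]
    responses = []
    idx = 0
    for i, cid in enumerate(cell_ids):
        for j, did in enumerate(drug_ids):
            v = log_ic50[idx]
            label = SENSITIVE if v < lo_t else (RESISTANT if v > hi_t else UNCORRELATED)
            responses.append(ResponseRecord(cid, did, float(v), label))
            idx += 1

    truth = SyntheticTruth(cell_latents=u_lat, drug_latents=v_lat, bias=float(bias),
                           scores=scores, noise_sd=noise_sd, seed=seed)
    return SyntheticCohort(omics=omics, smiles=smiles, responses=responses, truth=truth)


def degrade_cohort(cohort: SyntheticCohort, missing_frac: float,
                   seed: int = 0) -> SyntheticCohort:
    """Set an exact fraction of omics entries to NaN, uniformly at random.

    Per view, exactly round(missing_frac * size) entries go missing. The
    planted truth is untouched; the same seed gives the same mask.
    """
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    if missing_frac == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    views: dict[str, np.ndarray] = {}
    for name in VIEW_NAMES:
        mat = cohort.omics.views[name].copy()
        n_miss = int(np.floor(missing_frac * mat.size + 0.5))
        flat_idx = rng.choice(mat.size, size=n_miss, replace=False)
        mat.ravel()[flat_idx] = np.nan
        views[name] = mat
    omics = OmicsProfileSet(views=views, cell_ids=list(cohort.omics.cell_ids))
    return SyntheticCohort(omics=omics, smiles=list(cohort.smiles),
                           responses=list(cohort.responses), truth=cohort.truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the same CSV formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in VIEW_NAMES:
        mat = cohort.omics.views[name]
        df = pd.DataFrame(mat, index=cohort.omics.cell_ids,
                          columns=[f"{name[:4]}_f{j}" for j in range(mat.shape[1])])
        p = out / f"omics_{name}.csv"
        df.to_csv(p, float_format="%.10g")
        paths[name] = p
    smi = pd.DataFrame(cohort.smiles, columns=["drug_id", "smiles"])
    paths["smiles"] = out / "drugs.csv"
    smi.to_csv(paths["smiles"], index=False)
    resp = pd.DataFrame([(r.cell_id, r.drug_id, r.log_ic50) for r in cohort.responses],
                        columns=["cell_id", "drug_id", "log10_ic50"])
    paths["responses"] = out / "responses.csv"
    resp.to_csv(paths["responses"], index=False, float_format="%.10g")
    return paths
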