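"""Calibration and power simulations for the association pipeline.

These drivers answer the two questions any evidence-thresholded network
method must face before interpretation:

* calibration — how often does the evidence threshold admit an edge, or a
  whole triangle motif, when nothing is planted?
* power — how often is a planted taxon-module-symptom triangle of a given
  latent strength recovered end to end?

Each replicate draws a fresh synthetic cohort, runs the analysis stages
(prevalence filter, closure, CLR, nuisance adjustment) and evaluates the
JZS Bayes factor of every cross-modality pair through the same engine the
pipeline uses.  Within-modality (taxon-taxon, module-module) edges cannot
take part in triangles and are skipped here, which changes nothing about
the motif counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import jzs_log10_bf_many
from .preprocess import (
    DEFAULT_COVARIATES,
    adjust_nuisance,
    clr_transform,
    prevalence_filter,
    qc_filter_samples,
    to_relative,
)
from .simulate import CohortSpec, PlantedMotif, generate_cohort

__all__ = [
    "null_edge_rate",
    "no_motif_zero_rate",
    "planted_recovery_rate",
    "cross_modal_motif_count",
]

_PRIME = 2_147_483_647  # keeps derived seeds below 2**31


def _replicate_seed(base_seed: int, rep: int) -> int:
    return (1_000_003 * (base_seed + 1) + rep) % _PRIME


def null_edge_rate(
    n: int = 57,
    n_rep: int = 1000,
    rscale: float = 0.354,
    threshold: float = 0.5,
    seed: int = 1,
) -> float:
    """Fraction of independent standard-normal pairs crossing the threshold.

    The false-edge rate of the evidence rule on raw (unadjusted) data at
    sample size ``n``; at the defaults this estimates the per-pair type-I
    behaviour of log10 BF10 >= 0.5.
    """
    rng = np.random.default_rng(_replicate_seed(seed, 0))
    x = rng.standard_normal((n_rep, n))
    y = rng.standard_normal((n_rep, n))
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    r = (x * y).sum(axis=1) / np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
    bf = jzs_log10_bf_many(n, r, rscale)
    return float((bf >= threshold).mean())


def _adjusted_blocks(
    spec: CohortSpec,
    prevalence_min: int = 15,
    qc_min_features: int = 15,
    covariates=DEFAULT_COVARIATES,
):
    """Generate one cohort and run it through the preprocessing stages.

    Returns (taxa residuals, module residuals, scores frame).  The QC cut
    is expressed against the emulated prevalent-feature tables (59 genera),
    not the raw annotation universe the absolute study cut refers to.
    """
    taxa, modules, meta, truth = generate_cohort(spec)
    kept = qc_filter_samples(taxa, modules, qc_min_features)
    out = []
    for table in (taxa.subset_samples(kept), modules.subset_samples(kept)):
        filtered = prevalence_filter(table, prevalence_min)
        clr = clr_transform(to_relative(filtered))
        out.append(adjust_nuisance(clr, meta.subset_samples(kept), covariates).data)
    samples = out[0].index
    scores = meta.frame.loc[samples, ["hads_d", "weimus"]].astype(float)
    return out[0], out[1], scores, truth


def _corr_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A = A / np.sqrt((A**2).sum(axis=0))
    B = B / np.sqrt((B**2).sum(axis=0))
    return A.T @ B


def cross_modal_motif_count(
    spec: CohortSpec,
    rscale: float = 0.354,
    threshold: float = 0.5,
    prevalence_min: int = 15,
    qc_min_features: int = 15,
) -> int:
    """Number of taxon-module-symptom triangles in one synthetic cohort."""
    ta, ma, scores, _ = _adjusted_blocks(spec, prevalence_min, qc_min_features)
    T, M, S = (f.to_numpy(dtype=float) for f in (ta, ma, scores))
    n = T.shape[0]
    r_tm = _corr_cross(T, M)
    r_tp = _corr_cross(T, S)
    r_mp = _corr_cross(M, S)
    flat = np.concatenate([r_tm.ravel(), r_tp.ravel(), r_mp.ravel()])
    bf = jzs_log10_bf_many(n, np.clip(flat, -1 + 1e-10, 1 - 1e-10), rscale)
    k_tm, k_tp = r_tm.size, r_tp.size
    a_tm = (bf[:k_tm] >= threshold).reshape(r_tm.shape)
    a_tp = (bf[k_tm:k_tm + k_tp] >= threshold).reshape(r_tp.shape)
    a_mp = (bf[k_tm + k_tp:] >= threshold).reshape(r_mp.shape)
    count = 0
    for p in range(S.shape[1]):
        count += int((np.outer(a_tp[:, p], a_mp[:, p]) & a_tm).sum())
    return count


def no_motif_zero_rate(
    n_rep: int = 200,
    seed: int = 1,
    rscale: float = 0.354,
    threshold: float = 0.5,
) -> float:
    """Fraction of no-motif cohorts in which zero false triangles appear."""
    zero = 0
    for rep in range(n_rep):
        spec = CohortSpec(seed=_replicate_seed(seed, rep))
        zero += cross_modal_motif_count(spec, rscale=rscale, threshold=threshold) == 0
    return zero / n_rep


def planted_recovery_rate(
    rho: float = 0.5,
    n_rep: int = 200,
    seed: int = 1,
    rscale: float = 0.354,
    threshold: float = 0.5,
    return_correlations: bool = False,
):
    """Fraction of cohorts in which a single planted motif is fully recovered.

    Recovery means all three planted pairwise edges (taxon-module,
    taxon-symptom, module-symptom) reach log10 BF10 >= ``threshold`` after
    the full preprocessing chain.  Optionally also returns the mean
    absolute realised Pearson correlations of the three planted pairs.
    """
    motif = PlantedMotif(taxon=5, module=10, symptom="weimus", rho=rho)
    recovered = 0
    realized = np.zeros(3)
    used = 0
    for rep in range(n_rep):
        spec = CohortSpec(
            planted_motifs=(motif,), seed=_replicate_seed(seed, 1_000_000 + rep)
        )
        ta, ma, scores, truth = _adjusted_blocks(spec)
        expected = truth.motifs[0]
        if (expected["taxon_node"] not in ta.columns
                or expected["module_node"] not in ma.columns):
            continue  # planted feature lost to the prevalence filter
        used += 1
        x = ta[expected["taxon_node"]].to_numpy()
        y = ma[expected["module_node"]].to_numpy()
        s = scores["weimus"].to_numpy()
        r = np.array([
            _corr_cross(x[:, None], y[:, None])[0, 0],
            _corr_cross(x[:, None], s[:, None])[0, 0],
            _corr_cross(y[:, None], s[:, None])[0, 0],
        ])
        realized += np.abs(r)
        bf = jzs_log10_bf_many(len(x), r, rscale)
        recovered += bool((bf >= threshold).all())
    rate = recovered / used if used else float("nan")
    if return_correlations:
        return rate, realized / max(used, 1)
    return rate
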