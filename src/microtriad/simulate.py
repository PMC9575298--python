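"""Synthetic IBD-cohort generator with planted taxon-module-symptom triangles.

Emits the post-annotation data the analysis consumes — a genus-level count
table, a functional-module count table and a clinical metadata table — with
the statistical structure the pipeline assumes:

* compositional counts: per-sample log-scale signals pass through a softmax
  and a multinomial draw at realistic sequencing depth;
* a rank-abundance profile with abundance-dependent presence: the most
  abundant features are present in every sample, rare ones drop out, which
  reproduces the prevalence structure of prevalent-feature tables;
* nuisance-covariate effects on feature subsets, on the CLR scale;
* planted triangles: a shared latent factor z per motif loads on one taxon,
  one module and one symptom score with loading sqrt(|rho|) each, the
  minimal mechanism giving all three pairwise correlations magnitude |rho|.
  A negative rho flips the sign of the feature loadings (below-average
  abundance associated with higher symptom severity, the pattern the
  analysis is designed to detect).

Symptom scores are scaled to the observed clinical moments (HADS-D mean 6.5,
SD 4.5 on 0-21; WEIMuS mean 31.5, SD 14.7 on 0-68), rounded and clipped.
Everything is reproducible from the cohort's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, MetadataTable

__all__ = [
    "CovariateEffect",
    "PlantedMotif",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "planted_truth",
]

PP_NODES = {"hads": "HADS-D", "weimus": "WEIMuS"}
SCORE_COLUMNS = {"hads": "hads_d", "weimus": "weimus"}
SCORE_MOMENTS = {"hads": (6.5, 4.5, 0, 21), "weimus": (31.5, 14.7, 0, 68)}

# clinical marker moments of the study population
CRP_MEAN, CRP_SD = 21.2, 24.8          # mg/l
FCAL_MEAN, FCAL_SD = 365.0, 282.0      # ug/g


@dataclass(frozen=True)
class CovariateEffect:
    """A covariate shifting a feature subset by ``effect`` CLR units per SD."""

    covariate: str
    modality: str          # "taxon" or "module"
    features: tuple[int, ...]
    effect: float


@dataclass(frozen=True)
class PlantedMotif:
    """A latent taxon-module-symptom triangle with target pair correlation rho."""

    taxon: int
    module: int
    symptom: str           # "hads" or "weimus"
    rho: float

    def __post_init__(self) -> None:
        if self.symptom not in PP_NODES:
            raise ValueError(f"unknown symptom {self.symptom!r}")
        if not (0 < abs(self.rho) < 1):
            raise ValueError("target |rho| must lie strictly in (0, 1)")


DEFAULT_COVARIATE_EFFECTS = (
    CovariateEffect("age", "taxon", (2, 7, 11, 19), 0.5),
    CovariateEffect("age", "module", (3, 8, 15, 22), 0.5),
    CovariateEffect("steroid", "taxon", (4, 9, 16, 25), 0.5),
    CovariateEffect("steroid", "module", (5, 12, 21, 30), 0.5),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study-sized defaults: 57 samples, 59 prevalent genera, 209 modules."""

    n_samples: int = 57
    n_taxa: int = 59
    n_modules: int = 209
    depth: int = 1_000_000
    covariate_effects: tuple[CovariateEffect, ...] = DEFAULT_COVARIATE_EFFECTS
    planted_motifs: tuple[PlantedMotif, ...] = ()
    noise_sd: float = 1.0
    zero_inflation: float = 0.3
    n_low_richness: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        for symptom in PP_NODES:
            load = sum(abs(m.rho) for m in self.planted_motifs if m.symptom == symptom)
            if load > 0.95:
                raise ValueError(
                    f"total planted |rho| on {symptom} is {load:.2f}; infeasible "
                    "against unit score variance"
                )
        for m in self.planted_motifs:
            if not (0 <= m.taxon < self.n_taxa):
                raise ValueError(f"planted taxon index {m.taxon} out of range")
            if not (0 <= m.module < self.n_modules):
                raise ValueError(f"planted module index {m.module} out of range")


@dataclass
class GroundTruth:
    """What was planted: motifs (by node name), covariate loadings, latent z."""

    motifs: list[dict]
    covariate_loadings: dict
    z: pd.DataFrame


def _taxon_name(j: int) -> str:
    return f"tax_{j + 1:03d}"


def _module_name(j: int) -> str:
    return f"mod_{j + 1:03d}"


def _dropout_probability(n_features: int, zero_inflation: float) -> np.ndarray:
    """Per-feature absence probability, increasing with rarity.

    Zero for the most abundant quartile, then quadratic in the abundance
    rank, capped at 0.8 so every feature can still reach the 15-sample
    prevalence bar; the feature-average equals ``zero_inflation``.
    """
    q = np.arange(n_features) / max(n_features - 1, 1)
    c = zero_inflation / 0.140625  # normalises the mean of max(0, q-1/4)^2
    return np.minimum(0.8, c * np.maximum(0.0, q - 0.25) ** 2)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[AbundanceTable, AbundanceTable, MetadataTable, GroundTruth]:
    """Draw one synthetic cohort.

    Returns the genus count table, the module count table, the metadata
    table and the ground truth.  Identical specs give byte-identical
    outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # ---- metadata ------------------------------------------------------
    age = np.clip(rng.normal(40.0, 16.0, n), 18.0, 85.0).round(1)
    sex = (rng.random(n) < 36 / 62).astype(int)           # 1 = female
    diagnosis = np.where(rng.random(n) < 51 / 62, "CD", "UC")
    mu, sigma = _lognormal_params(CRP_MEAN, CRP_SD)
    crp = np.round(rng.lognormal(mu, sigma, n), 1)
    mu, sigma = _lognormal_params(FCAL_MEAN, FCAL_SD)
    fcal = np.round(rng.lognormal(mu, sigma, n), 0)
    fcal_missing = rng.random(n) < 4 / 57
    fcal = np.where(fcal_missing, np.nan, fcal)
    flag_rates = {
        "steroid": 0.34,
        "mesalamine": 0.30,
        "immunosuppressant": 0.21,
        "contraceptive": 0.15,
        "antidepressant": 0.065,
        "ppi": 0.25,
    }
    flags = {}
    for name, rate in flag_rates.items():
        column = (rng.random(n) < rate).astype(int)
        # every medication class has at least one user and one non-user in
        # the emulated cohort, keeping the adjustment design full rank
        if column.sum() == 0:
            column[rng.integers(n)] = 1
        elif column.sum() == n:
            column[rng.integers(n)] = 0
        flags[name] = column
    covariate_values = {"age": age, "sex": sex, "crp": crp, **flags}

    # ---- latent motif factors -----------------------------------------
    motif_ids = [f"z{k}" for k in range(len(spec.planted_motifs))]
    z = rng.normal(size=(n, len(spec.planted_motifs)))

    # ---- symptom scores ------------------------------------------------
    scores = {}
    for symptom in PP_NODES:
        shared = np.zeros(n)
        total = 0.0
        for k, motif in enumerate(spec.planted_motifs):
            if motif.symptom == symptom:
                shared += np.sqrt(abs(motif.rho)) * z[:, k]
                total += abs(motif.rho)
        raw = shared + np.sqrt(max(0.0, 1.0 - total)) * rng.normal(size=n)
        mean, sd, lo, hi = SCORE_MOMENTS[symptom]
        scores[SCORE_COLUMNS[symptom]] = np.clip(np.round(mean + sd * raw), lo, hi).astype(int)

    # ---- abundance blocks ---------------------------------------------
    def block(n_features: int, modality: str, base_slope: float) -> tuple[np.ndarray, dict]:
        base = -base_slope * np.log(np.arange(1, n_features + 1))
        signal = base + rng.normal(0.0, spec.noise_sd, size=(n, n_features))
        loadings: dict[str, np.ndarray] = {}
        for eff in spec.covariate_effects:
            if eff.modality != modality:
                continue
            values = np.asarray(covariate_values[eff.covariate], dtype=float)
            sd = values.std()
            if sd == 0:
                continue
            standardized = (values - values.mean()) / sd
            vec = loadings.setdefault(eff.covariate, np.zeros(n_features))
            for j in eff.features:
                signal[:, j] += eff.effect * standardized
                vec[j] += eff.effect
        for k, motif in enumerate(spec.planted_motifs):
            target = motif.taxon if modality == "taxon" else motif.module
            # loading sqrt(|rho|) against total unit variance: lam/(lam^2+sd^2)^0.5
            lam = spec.noise_sd * np.sqrt(abs(motif.rho) / (1.0 - abs(motif.rho)))
            sign = np.sign(motif.rho) if modality == "taxon" else 1.0
            signal[:, target] += sign * lam * z[:, k]
        composition = np.exp(signal - signal.max(axis=1, keepdims=True))
        composition /= composition.sum(axis=1, keepdims=True)
        depths = np.maximum(
            1, np.round(spec.depth * rng.lognormal(-0.03125, 0.25, n))
        ).astype(np.int64)
        counts = np.empty((n, n_features), dtype=np.int64)
        for i in range(n):
            counts[i] = rng.multinomial(depths[i], composition[i])
        dropout = _dropout_probability(n_features, spec.zero_inflation)
        counts[rng.random((n, n_features)) < dropout] = 0
        return counts.astype(float), loadings

    taxa_counts, taxa_loadings = block(spec.n_taxa, "taxon", base_slope=1.2)
    module_counts, module_loadings = block(spec.n_modules, "module", base_slope=0.8)

    # ---- low-richness samples (fail sample QC by construction) ---------
    if spec.n_low_richness:
        low = rng.choice(n, size=spec.n_low_richness, replace=False)
        taxa_counts[np.ix_(low, np.arange(25, spec.n_taxa))] = 0
        module_counts[np.ix_(low, np.arange(30, spec.n_modules))] = 0

    taxa = AbundanceTable(
        pd.DataFrame(taxa_counts, index=sample_ids,
                     columns=[_taxon_name(j) for j in range(spec.n_taxa)]),
        modality="taxon", unit="count",
    )
    modules = AbundanceTable(
        pd.DataFrame(module_counts, index=sample_ids,
                     columns=[_module_name(j) for j in range(spec.n_modules)]),
        modality="module", unit="count",
    )
    meta = MetadataTable(
        pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "diagnosis": diagnosis,
                "crp": crp,
                "fcal": fcal,
                **flags,
                **scores,
            },
            index=pd.Index(sample_ids, name="sample"),
        )
    )
    truth = GroundTruth(
        motifs=planted_truth(spec),
        covariate_loadings={"taxon": taxa_loadings, "module": module_loadings},
        z=pd.DataFrame(z, index=sample_ids, columns=motif_ids),
    )
    return taxa, modules, meta, truth


def planted_truth(spec: CohortSpec) -> list[dict]:
    """Deterministic expected-motif list (deduplicated, by node name)."""
    seen = set()
    out = []
    for motif in spec.planted_motifs:
        key = (motif.taxon, motif.module, motif.symptom)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            {
                "taxon_node": _taxon_name(motif.taxon),
                "module_node": _module_name(motif.module),
                "pp_node": PP_NODES[motif.symptom],
                "rho": motif.rho,
            }
        )
    return out


def standard_fixture_spec(seed: int = 1) -> CohortSpec:
    """The small standard cohort used by the test-suite fixtures.

    One planted motif at target |rho| = 0.5 between an abundant taxon, an
    abundant module and fatigue.  The default seed gives a draw in which
    the planted signal is realised in all three pairwise associations, so
    the fixture carries a recoverable known truth.
    """
    return CohortSpec(
        planted_motifs=(PlantedMotif(taxon=5, module=10, symptom="weimus", rho=0.5),),
        seed=seed,
    )
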