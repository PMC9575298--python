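"""Sample QC, prevalence filtering, CLR transformation and nuisance adjustment.

Microbiome abundance tables are compositional: only relative information is
carried, so standard correlations on raw proportions are spurious.  The
pipeline therefore (1) removes samples with too few annotated features,
(2) removes rare features to keep the later multiple regression
well-conditioned, (3) maps each sample to the centred log-ratio (CLR) scale
``clr(p)_j = ln p_j - mean_k ln p_k``, and (4) regresses each CLR feature on
a fixed set of nuisance covariates (age, sex, diagnosis, inflammation and
medication), carrying the residuals into all association analyses.

The three transformation stages are also exposed as scikit-learn style
transformers (:class:`PrevalenceFilter`, :class:`CLRTransformer`,
:class:`NuisanceAdjuster`) so they compose with sklearn pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, MetadataTable, TableValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TransformedTable",
    "PipelineConfig",
    "DEFAULT_COVARIATES",
    "qc_filter_samples",
    "prevalence_filter",
    "to_relative",
    "clr_transform",
    "adjust_nuisance",
    "covariate_effect_report",
    "design_matrix",
    "PrevalenceFilter",
    "CLRTransformer",
    "NuisanceAdjuster",
]

#: the ten nuisance variables adjusted for: demographics, diagnosis,
#: systemic inflammation and six medication classes
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "diagnosis",
    "crp",
    "steroid",
    "mesalamine",
    "immunosuppressant",
    "contraceptive",
    "antidepressant",
    "ppi",
)


@dataclass
class TransformedTable:
    """A samples x features real matrix on CLR or residual scale."""

    data: pd.DataFrame
    stage: str  # "clr" or "adjusted"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("transformed table contains non-finite values")
        if self.stage == "clr":
            rowsums = values.sum(axis=1)
            if np.abs(rowsums).max() > 1e-9 * max(1.0, np.abs(values).max()):
                raise TableValidationError("CLR rows do not sum to zero")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)


@dataclass
class PipelineConfig:
    """Tunable constants of the analysis.

    Defaults are the study constants: samples need at least 50 annotated
    features per modality, features must be present in at least 15 samples,
    the JZS prior scale is 0.354 (sqrt(2)/4, the standard "medium" width for
    one continuous covariate) and edges require log10 BF10 >= 0.5.
    """

    prevalence_min: int = 15
    qc_min_features: int = 50
    rscale: float = 0.354
    bf_log10_threshold: float = 0.5
    pseudocount_policy: str = "half-min"
    bf_method: str = "regression"  # or "stretched-beta"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prevalence_min < 1:
            raise ValueError("prevalence_min must be >= 1")
        if self.rscale <= 0:
            raise ValueError("rscale must be positive")
        if self.bf_log10_threshold < 0:
            raise ValueError("bf_log10_threshold must be >= 0")
        if len(self.covariates) != 10:
            raise ValueError(
                f"exactly 10 nuisance covariates must be named, got "
                f"{len(self.covariates)}: {list(self.covariates)}"
            )
        logger.info("nuisance covariates: %s", ", ".join(self.covariates))


# ---------------------------------------------------------------------------
# sample QC and filtering


def qc_filter_samples(
    taxa: AbundanceTable,
    modules: AbundanceTable,
    min_features: int,
) -> list:
    """Samples whose nonzero-feature count reaches ``min_features`` in both tables.

    Samples with too few annotated genera or modules carry too little
    information for the downstream regression and are removed.  Order is
    preserved from the taxa table.
    """
    shared = [s for s in taxa.sample_ids if s in set(modules.sample_ids)]
    if not shared:
        raise TableValidationError("taxa and module tables share no samples")
    taxa_nz = (taxa.data.loc[shared] > 0).sum(axis=1)
    mod_nz = (modules.data.loc[shared] > 0).sum(axis=1)
    keep = [s for s in shared if taxa_nz[s] >= min_features and mod_nz[s] >= min_features]
    logger.info(
        "sample QC: %d of %d samples retained (>= %d nonzero features in both tables)",
        len(keep), len(shared), min_features,
    )
    return keep


def prevalence_filter(table: AbundanceTable, min_prevalence: int) -> AbundanceTable:
    """Keep features with a nonzero value in at least ``min_prevalence`` samples."""
    if table.shape[0] < min_prevalence:
        raise TableValidationError(
            f"table has {table.shape[0]} samples, fewer than the prevalence "
            f"threshold {min_prevalence}"
        )
    prevalence = (table.data > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    if len(keep) == 0:
        raise TableValidationError(
            f"no {table.modality} features present in >= {min_prevalence} samples; "
            "reduce the prevalence threshold"
        )
    logger.info(
        "prevalence filter (%s): %d of %d features present in >= %d samples",
        table.modality, len(keep), table.shape[1], min_prevalence,
    )
    return AbundanceTable(
        table.data[keep],
        modality=table.modality,
        unit=table.unit,
        feature_annotation=table.feature_annotation,
    )


def to_relative(table: AbundanceTable, allow_relative: bool = False) -> AbundanceTable:
    """Close each sample to relative abundances (rows sum to 1)."""
    if table.unit == "relative":
        if allow_relative:
            return table
        raise TableValidationError("table is already on the relative scale")
    sums = table.data.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0].tolist()
        raise TableValidationError(f"all-zero sample rows: {bad}")
    return AbundanceTable(
        table.data.div(sums, axis=0),
        modality=table.modality,
        unit="relative",
        feature_annotation=table.feature_annotation,
    )


# ---------------------------------------------------------------------------
# CLR


def _replace_zeros(rel: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Multiplicative zero replacement followed by re-closure.

    ``half-min`` replaces zeros by half the smallest nonzero relative
    abundance in the whole table of that modality, the usual simple
    multiplicative strategy keeping the CLR well-defined.
    """
    values = rel.to_numpy(dtype=float)
    if policy == "half-min":
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise TableValidationError("table is entirely zero")
        pseudo = 0.5 * nonzero.min()
    else:
        raise ValueError(f"unknown pseudocount policy {policy!r}")
    filled = np.where(values == 0, pseudo, values)
    filled = filled / filled.sum(axis=1, keepdims=True)
    return pd.DataFrame(filled, index=rel.index, columns=rel.columns)


def clr_transform(table: AbundanceTable, policy: str = "half-min") -> TransformedTable:
    """Centred log-ratio transform of a relative abundance table.

    ``clr(p)_j = ln p'_j - mean_k ln p'_k`` where ``p'`` is the zero-replaced,
    re-closed composition over the (already filtered) feature set of the
    table's modality.  Each transformed row sums to zero.
    """
    if table.unit != "relative":
        raise TableValidationError("clr_transform expects a relative table")
    if (table.data.sum(axis=1) == 0).any():
        bad = table.data.index[table.data.sum(axis=1) == 0].tolist()
        raise TableValidationError(f"all-zero sample rows: {bad}")
    filled = _replace_zeros(table.data, policy)
    logs = np.log(filled.to_numpy(dtype=float))
    clr = logs - logs.mean(axis=1, keepdims=True)
    return TransformedTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        stage="clr",
        provenance={"modality": table.modality, "pseudocount_policy": policy},
    )


# ---------------------------------------------------------------------------
# nuisance adjustment


def design_matrix(meta: MetadataTable, covariates: Sequence[str]) -> pd.DataFrame:
    """Covariate design matrix (no intercept column) for the given samples.

    Sex, diagnosis and the medication flags are already 0/1 coded by
    :class:`~microtriad.tables.MetadataTable`; CRP enters untransformed.
    Rows with any missing covariate are returned with NaN and are dropped by
    the caller.
    """
    missing = [c for c in covariates if c not in meta.frame.columns]
    if missing:
        raise TableValidationError(f"metadata lacks covariate columns: {missing}")
    return meta.frame[list(covariates)].astype(float)


def _fit_design(
    t: TransformedTable,
    meta: MetadataTable,
    covariates: Sequence[str],
    min_residual_df: int = 3,
) -> tuple[np.ndarray, pd.DataFrame, list]:
    """Shared validation: aligned design with intercept, complete samples."""
    design = design_matrix(meta.subset_samples(t.sample_ids), covariates)
    complete = design.notna().all(axis=1)
    dropped = design.index[~complete].tolist()
    if dropped:
        logger.info(
            "dropping %d samples with missing covariates before adjustment: %s",
            len(dropped), dropped,
        )
    design = design.loc[complete]
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    n, p = X.shape
    if n - p < min_residual_df:
        raise TableValidationError(
            f"residual degrees of freedom {n - p} below the minimum "
            f"{min_residual_df} (n={n}, predictors={p - 1} plus intercept)"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        collinear = _collinear_columns(X, ["intercept", *covariates])
        raise TableValidationError(
            f"rank-deficient covariate design; collinear columns: {collinear}"
        )
    return X, design, dropped


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def adjust_nuisance(
    t: TransformedTable,
    meta: MetadataTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> TransformedTable:
    """Residualise every feature on the nuisance covariates.

    Fits, feature-wise, ordinary least squares with intercept on the
    covariate design and returns the residual matrix.  All downstream
    association analyses run on these residuals.
    """
    X, design, dropped = _fit_design(t, meta, covariates)
    Y = t.data.loc[design.index].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    provenance = dict(t.provenance)
    provenance.update(
        covariates=list(covariates),
        n_samples=len(design),
        dropped_samples=dropped,
    )
    return TransformedTable(
        pd.DataFrame(resid, index=design.index, columns=t.data.columns),
        stage="adjusted",
        provenance=provenance,
    )


def covariate_effect_report(
    t: TransformedTable,
    meta: MetadataTable,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-feature t-statistics for each covariate and model R-squared.

    Mirrors the post-hoc inspection of the adjustment model: one OLS fit per
    feature, reporting ``t = coefficient / SE`` per covariate and the
    variance explained by the full nuisance model.
    """
    import statsmodels.api as sm

    X, design, _ = _fit_design(t, meta, covariates)
    Y = t.data.loc[design.index]
    rows = {}
    for feature in Y.columns:
        fit = sm.OLS(Y[feature].to_numpy(dtype=float), X).fit()
        row = {f"t_{c}": fit.tvalues[k + 1] for k, c in enumerate(covariates)}
        row["r_squared"] = fit.rsquared
        rows[feature] = row
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "feature"
    return report


# ---------------------------------------------------------------------------
# sklearn-style transformers

try:  # sklearn is optional: the transformers degrade to plain classes
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep: bool = True) -> dict:
            return {k: v for k, v in vars(self).items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

    class TransformerMixin:  # type: ignore[no-redef]
        def fit_transform(self, X, y=None, **kw):
            return self.fit(X, y, **kw).transform(X)


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop features present in fewer than ``min_prevalence`` samples.

    Operates on a samples x features DataFrame; the surviving feature set is
    learned in :meth:`fit` and applied in :meth:`transform`.
    """

    def __init__(self, min_prevalence: int = 15):
        self.min_prevalence = min_prevalence

    def fit(self, X: pd.DataFrame, y=None):
        prevalence = (X > 0).sum(axis=0)
        self.feature_names_ = list(prevalence[prevalence >= self.min_prevalence].index)
        if not self.feature_names_:
            raise TableValidationError(
                f"no features present in >= {self.min_prevalence} samples"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.feature_names_]


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Close rows to proportions and apply the centred log-ratio transform."""

    def __init__(self, pseudocount_policy: str = "half-min"):
        self.pseudocount_policy = pseudocount_policy

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table = AbundanceTable(pd.DataFrame(X), modality="taxon", unit="count")
        rel = to_relative(table)
        return clr_transform(rel, policy=self.pseudocount_policy).data


class NuisanceAdjuster(BaseEstimator, TransformerMixin):
    """Residualise features on nuisance covariates supplied as metadata."""

    def __init__(self, metadata: MetadataTable | None = None,
                 covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.metadata = metadata
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None):
        if self.metadata is None:
            raise ValueError("NuisanceAdjuster requires metadata")
        t = TransformedTable(pd.DataFrame(X), stage="adjusted")
        self.design_columns_ = list(self.covariates)
        _fit_design(t, self.metadata, self.covariates)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        t = TransformedTable(pd.DataFrame(X), stage="adjusted")
        return adjust_nuisance(t, self.metadata, self.covariates).data
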