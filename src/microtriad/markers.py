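"""Alpha diversity and bivariate marker-symptom associations.

Checks whether depression (HADS-D) and fatigue (WEIMuS) severity track
systemic inflammation (CRP), luminal inflammation (faecal calprotectin) or
gut microbial alpha diversity (Shannon index).  Markers enter raw — not CLR
transformed and not residualised — and each marker-symptom pair is tested
with the same JZS Bayes factor engine as the network edges, on
pairwise-complete observations (calprotectin is missing for some samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import classify_evidence, pair_log10_bf, spearman_rho
from .tables import AbundanceTable, MetadataTable, TableValidationError

__all__ = ["shannon_index", "shannon_per_sample", "marker_panel", "marker_associations"]

SYMPTOMS = ("hads_d", "weimus")
MARKERS = ("crp", "fcal", "shannon")


def shannon_index(p: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i of a relative-abundance vector.

    Natural-log units; zero-abundance entries contribute nothing, so the
    index is invariant to padding with absent taxa.  Maximal (ln k) for a
    uniform composition over k taxa.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise TableValidationError("negative entry in composition")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise TableValidationError(f"composition sums to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_per_sample(table: AbundanceTable) -> pd.Series:
    """Shannon index of every sample of a relative genus table.

    Diversity is computed on the QC-passed, pre-prevalence-filter relative
    abundances: within-sample diversity should not depend on the aggressive
    cross-sample prevalence cut.
    """
    if table.unit != "relative":
        raise TableValidationError("shannon_per_sample expects a relative table")
    values = table.data.to_numpy(dtype=float)
    rows = [shannon_index(row / row.sum()) for row in values]
    return pd.Series(rows, index=table.data.index, name="shannon")


def marker_panel(taxa_relative: AbundanceTable, meta: MetadataTable) -> pd.DataFrame:
    """Per-sample marker/score panel: shannon, crp, fcal, hads_d, weimus."""
    shannon = shannon_per_sample(taxa_relative)
    panel = meta.subset_samples(shannon.index).frame[["crp", "fcal", "hads_d", "weimus"]].copy()
    panel.insert(0, "shannon", shannon)
    return panel


def marker_associations(panel: pd.DataFrame, rscale: float = 0.354,
                        method: str = "regression") -> pd.DataFrame:
    """Bayesian association of each marker with each symptom score.

    Returns one row per (marker, symptom) pair with n_obs, log10_bf,
    Spearman rho and the evidence class, using the identical Bayes factor
    code path as the association network.
    """
    rows = []
    for marker in MARKERS:
        for symptom in SYMPTOMS:
            x = panel[marker].to_numpy(dtype=float)
            y = panel[symptom].to_numpy(dtype=float)
            log10_bf, n_obs = pair_log10_bf(x, y, rscale=rscale, method=method)
            rows.append(
                {
                    "marker": marker,
                    "symptom": symptom,
                    "n_obs": n_obs,
                    "log10_bf": log10_bf,
                    "rho": spearman_rho(x, y),
                    "evidence": classify_evidence(log10_bf),
                }
            )
    return pd.DataFrame(rows)
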