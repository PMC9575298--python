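"""Abundance tables, sample metadata and KEGG-style module definitions.

The on-disk dialect throughout is tab-separated UTF-8 text with samples as
rows and features as columns, which is the shape both taxonomic (mOTU-style,
pooled at genus level) and functional (KO / KEGG-module) profiler exports
take after annotation.  Floats are written with six significant digits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "MetadataTable",
    "ModuleDefinition",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_module_definitions",
    "write_module_definitions",
    "merge_module_definitions",
    "aggregate_ko_counts",
]

MODALITIES = ("taxon", "module", "ko")
UNITS = ("count", "relative")

#: columns of a metadata table, in canonical order
METADATA_COLUMNS = (
    "age",
    "sex",
    "diagnosis",
    "crp",
    "fcal",
    "steroid",
    "mesalamine",
    "immunosuppressant",
    "contraceptive",
    "antidepressant",
    "ppi",
    "hads_d",
    "weimus",
)

_BINARY_FLAGS = (
    "steroid",
    "mesalamine",
    "immunosuppressant",
    "contraceptive",
    "antidepressant",
    "ppi",
)


class TableValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class AbundanceTable:
    """A samples x features matrix of non-negative counts or relative abundances.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as index and feature identifiers
        as columns.  Values must be non-negative and finite.
    modality
        ``"taxon"``, ``"module"`` or ``"ko"``.
    unit
        ``"count"`` or ``"relative"``.  Relative rows must sum to at most 1.
    feature_annotation
        Optional map from feature id to a group label (phylum for taxa,
        KEGG pathway for modules).
    """

    data: pd.DataFrame
    modality: str
    unit: str = "count"
    feature_annotation: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise TableValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.unit not in UNITS:
            raise TableValidationError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample identifiers: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate feature identifiers: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableValidationError("abundance table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.unit == "relative":
            sums = values.sum(axis=1)
            if (sums > 1 + 1e-9).any():
                bad = self.data.index[np.argmax(sums)]
                raise TableValidationError(
                    f"relative abundances of sample {bad!r} sum to more than 1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        """Restrict to the given samples, preserving their order."""
        return AbundanceTable(
            self.data.loc[list(sample_ids)],
            modality=self.modality,
            unit=self.unit,
            feature_annotation=self.feature_annotation,
        )


@dataclass
class MetadataTable:
    """Per-sample covariates, clinical markers and psychometric scores.

    Holds a validated DataFrame indexed by sample id with the columns in
    :data:`METADATA_COLUMNS`.  CRP (mg/l) and faecal calprotectin (ug/g) may
    be missing (NaN); everything else must be present.  HADS-D is the
    depression subscale of the Hospital Anxiety and Depression Scale
    (0-21); WEIMuS is the Wuerzburg fatigue inventory (0-68).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.duplicated().any():
            raise TableValidationError("duplicate sample identifiers in metadata")
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"metadata is missing columns: {missing}")
        df = df[list(METADATA_COLUMNS)].copy()

        df["sex"] = _coerce_binary(df["sex"], "sex", {"f": 1, "m": 0, "female": 1, "male": 0})
        df["diagnosis"] = _coerce_binary(
            df["diagnosis"], "diagnosis", {"cd": 0, "uc": 1}
        )
        for flag in _BINARY_FLAGS:
            df[flag] = _coerce_binary(df[flag], flag, {})

        for col in ("age", "crp", "fcal", "hads_d", "weimus"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("age", "hads_d", "weimus"):
            if df[col].isna().any():
                bad = df.index[df[col].isna()].tolist()
                raise TableValidationError(f"missing {col} for samples {bad}")
        for col in ("age", "crp", "fcal"):
            df[col] = df[col].astype(float)
        for col in ("hads_d", "weimus"):
            if not (df[col] == df[col].round()).all():
                raise TableValidationError(f"{col} scores must be integers")
            df[col] = df[col].astype(int)
        if (df["age"] <= 0).any():
            raise TableValidationError("age must be positive")
        if ((df["hads_d"] < 0) | (df["hads_d"] > 21)).any():
            bad = df.index[(df["hads_d"] < 0) | (df["hads_d"] > 21)].tolist()
            raise TableValidationError(f"hads_d outside [0, 21] for samples {bad}")
        if ((df["weimus"] < 0) | (df["weimus"] > 68)).any():
            bad = df.index[(df["weimus"] < 0) | (df["weimus"] > 68)].tolist()
            raise TableValidationError(f"weimus outside [0, 68] for samples {bad}")
        self.frame = df

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def subset_samples(self, sample_ids: Iterable) -> "MetadataTable":
        return MetadataTable(self.frame.loc[list(sample_ids)])


def _coerce_binary(series: pd.Series, name: str, aliases: Mapping[str, int]) -> pd.Series:
    out = []
    for sid, value in series.items():
        key = str(value).strip().lower()
        if key in aliases:
            out.append(aliases[key])
        elif key in {"0", "0.0", "1", "1.0"}:
            out.append(int(float(key)))
        else:
            raise TableValidationError(
                f"unknown {name} code {value!r} for sample {sid!r}"
            )
    return pd.Series(out, index=series.index, dtype=int)


@dataclass(frozen=True)
class ModuleDefinition:
    """A functional module: a named set of KEGG-orthology (KO) members."""

    module_id: str
    ko_ids: frozenset[str]
    source: str = "kegg"  # "kegg" or "scfa_extension"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise TableValidationError(
                f"module {self.module_id!r} has an empty KO list"
            )
        if self.source not in ("kegg", "scfa_extension"):
            raise TableValidationError(
                f"unknown module source {self.source!r}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(path: str | Path, modality: str, unit: str = "count") -> AbundanceTable:
    """Read a TSV abundance table (first column sample ids, header feature ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    converted_cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            sid = raw.index[bad.to_numpy().argmax()]
            raise TableValidationError(
                f"{path}: malformed numeric cell at sample {sid!r}, feature {col!r}"
            )
        if converted.isna().any():
            sid = raw.index[converted.isna().to_numpy().argmax()]
            raise TableValidationError(
                f"{path}: empty cell at sample {sid!r}, feature {col!r}; "
                "abundance tables must be dense"
            )
        converted_cols[col] = converted.astype(float)
    data = pd.DataFrame(converted_cols, index=raw.index.astype(str))
    return AbundanceTable(data, modality=modality, unit=unit)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a TSV abundance table with 6-significant-digit floats."""
    table.data.to_csv(path, sep="\t", float_format="%.6g", index_label="sample")


def read_sample_metadata(path: str | Path) -> MetadataTable:
    """Read the per-sample metadata TSV; empty CRP/fcal cells become missing."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return MetadataTable(df)


def write_sample_metadata(meta: MetadataTable, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", float_format="%.6g", index_label="sample")


def read_module_definitions(path: str | Path) -> dict[str, ModuleDefinition]:
    """Read module definitions: module_id <TAB> label <TAB> KO1,KO2[,...] [<TAB> source]."""
    path = Path(path)
    defs: dict[str, ModuleDefinition] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableValidationError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields"
                )
            module_id, label, ko_field = parts[0], parts[1], parts[2]
            source = parts[3] if len(parts) > 3 else "kegg"
            ko_ids = frozenset(k.strip() for k in ko_field.split(",") if k.strip())
            if module_id in defs:
                raise TableValidationError(
                    f"{path}:{lineno}: duplicate module id {module_id!r}"
                )
            defs[module_id] = ModuleDefinition(module_id, ko_ids, source=source, label=label)
    return defs


def write_module_definitions(defs: Mapping[str, ModuleDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for mod in defs.values():
            kos = ",".join(sorted(mod.ko_ids))
            handle.write(f"{mod.module_id}\t{mod.label}\t{kos}\t{mod.source}\n")


def merge_module_definitions(
    kegg: Mapping[str, ModuleDefinition],
    scfa: Mapping[str, ModuleDefinition],
) -> dict[str, ModuleDefinition]:
    """Union of curated KEGG modules and the SCFA-production extension.

    The manually curated KEGG module set lacks the short-chain fatty acid
    production pathways, which are supplied as an extension set.  On an id
    collision the KEGG version is kept and a warning is emitted.
    """
    merged = dict(kegg)
    for module_id, mod in scfa.items():
        if module_id in merged:
            warnings.warn(
                f"module id {module_id!r} defined in both sources; keeping the "
                "KEGG version",
                stacklevel=2,
            )
            continue
        merged[module_id] = mod
    return merged


def aggregate_ko_counts(
    ko_table: AbundanceTable,
    defs: Mapping[str, ModuleDefinition],
) -> AbundanceTable:
    """Sum KO counts into module abundances.

    Module abundance per sample is the sum of read counts over the module's
    KO members.  KOs absent from the table contribute zero; modules whose
    members are all absent yield all-zero columns (removed later by
    prevalence filtering).  KOs shared between modules count in each.
    """
    if not defs:
        raise TableValidationError("no module definitions supplied")
    if ko_table.unit != "count":
        raise TableValidationError("KO aggregation expects a count table")
    data = ko_table.data
    out = {}
    for module_id, mod in defs.items():
        members = [k for k in mod.ko_ids if k in data.columns]
        if members:
            out[module_id] = data[members].sum(axis=1)
        else:
            out[module_id] = pd.Series(0.0, index=data.index)
    annotation = {m.module_id: m.label for m in defs.values() if m.label}
    return AbundanceTable(
        pd.DataFrame(out, index=data.index),
        modality="module",
        unit="count",
        feature_annotation=annotation or None,
    )
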