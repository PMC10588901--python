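"""Data model and I/O for tabular severity-assessment datasets.

A dataset is one row per animal (or per animal x timepoint), a handful of
reserved metadata columns, and an arbitrary set of numeric parameter columns
(behavioral and biochemical readouts). Missing values are allowed and are
carried as NaN throughout; they are never treated as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Reserved metadata column names; every other column is a parameter.
METADATA_COLUMNS = ("animal_id", "model", "group", "age_bracket", "sex")

#: Tokens mapped to the missing marker on load.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na", "N/A")

VALID_SEX = ("female", "male", "unknown")


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class AnimalRecord:
    """Metadata for one animal (or one animal x timepoint row)."""

    animal_id: str
    model: str = ""
    group: str = ""
    age_bracket: str = ""
    sex: str = "unknown"

    def __post_init__(self):
        if self.sex not in VALID_SEX:
            raise DatasetError(
                f"invalid sex {self.sex!r} for animal {self.animal_id!r}; "
                f"expected one of {VALID_SEX}"
            )


@dataclass
class StudyConfig:
    """All tunable settings of the severity-assessment workflow.

    Defaults follow the reference workflow: parameters with more than 20%
    missing data are dropped, Spearman |r| > 0.5 with p < 0.05 flags a
    significant pair and |r| > 0.7 a redundant one, the resampled PCA uses
    100 draws of a random 80% training subset and keeps components with
    SD > 1, and cluster thresholds come from 100 resamples with 95%
    confidence borders.
    """

    group_burden_map: dict = field(default_factory=dict)  # group -> 0 | 1 | "exclude"
    exclusion_list: dict = field(default_factory=dict)  # parameter -> reason text
    post_correlation_exclusions: dict = field(default_factory=dict)
    keep_rules: list = field(default_factory=list)  # ordered keep-preference
    allowed_groups: list = field(default_factory=list)  # empty = accept any
    r_significant: float = 0.5
    r_redundant: float = 0.7
    p_cut: float = 0.05
    missingness_cut: float = 0.2
    train_fraction: float = 0.8
    n_resamples: int = 100
    sd_threshold: float = 1.0
    k: int | None = None
    cluster_resamples: int = 100
    ci_level: float = 0.95
    stratify: bool = True
    composite_variant: str = "rank_sum"  # or "score_sum"
    freeze_components: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("train_fraction", "missingness_cut"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DatasetError(f"{name} must lie in (0, 1], got {v}")
        for name in ("r_significant", "r_redundant", "p_cut", "sd_threshold"):
            if getattr(self, name) <= 0:
                raise DatasetError(f"{name} must be positive")
        if not (0 < self.ci_level < 1):
            raise DatasetError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.k is not None and self.k < 1:
            raise DatasetError(f"k must be >= 1, got {self.k}")
        if self.composite_variant not in ("rank_sum", "score_sum"):
            raise DatasetError(f"unknown composite variant {self.composite_variant!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


class ParameterTable:
    """Animals x parameters matrix with per-animal metadata.

    Thin wrapper around two aligned pandas objects: ``meta`` (one row per
    animal, reserved metadata columns) and ``values`` (float matrix, NaN for
    missing). Row order is preserved from the source file.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        values: pd.DataFrame,
        units: Mapping[str, str] | None = None,
    ):
        if list(meta.index) != list(values.index):
            raise DatasetError("metadata and value rows are misaligned")
        if meta["animal_id"].duplicated().any():
            dupes = meta.loc[meta["animal_id"].duplicated(), "animal_id"].tolist()
            raise DatasetError(f"duplicate animal_id: {sorted(set(dupes))}")
        if values.columns.duplicated().any():
            raise DatasetError("duplicate parameter names")
        self.meta = meta.reset_index(drop=True)
        self.values = values.astype(float).reset_index(drop=True)
        self.units = dict(units or {})

    # -- basic interface ---------------------------------------------------
    @property
    def animal_ids(self) -> list[str]:
        return self.meta["animal_id"].tolist()

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_animals(self) -> int:
        return len(self.meta)

    @property
    def records(self) -> list[AnimalRecord]:
        return [
            AnimalRecord(
                animal_id=str(r.animal_id),
                model=str(r.model),
                group=str(r.group),
                age_bracket=str(r.age_bracket),
                sex=str(r.sex),
            )
            for r in self.meta.itertuples()
        ]

    def subset_rows(self, mask) -> "ParameterTable":
        mask = np.asarray(mask, dtype=bool)
        return ParameterTable(
            self.meta.loc[mask].reset_index(drop=True),
            self.values.loc[mask].reset_index(drop=True),
            self.units,
        )

    def select_parameters(self, names: Sequence[str]) -> "ParameterTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise DatasetError(f"unknown parameters: {missing}")
        units = {k: v for k, v in self.units.items() if k in names}
        return ParameterTable(self.meta.copy(), self.values[list(names)].copy(), units)

    def filter(self, *, model: str | None = None, age_bracket: str | None = None,
               group: str | None = None) -> "ParameterTable":
        """Subset rows by model / age bracket / group label."""
        mask = np.ones(self.n_animals, dtype=bool)
        if model is not None:
            mask &= (self.meta["model"] == model).to_numpy()
        if age_bracket is not None:
            mask &= (self.meta["age_bracket"] == age_bracket).to_numpy()
        if group is not None:
            mask &= (self.meta["group"] == group).to_numpy()
        return self.subset_rows(mask)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat([self.meta, self.values], axis=1)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False, na_rep="NA")

    def copy(self) -> "ParameterTable":
        return ParameterTable(self.meta.copy(), self.values.copy(), dict(self.units))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ParameterTable {self.n_animals} animals x {len(self.parameters)} parameters>"


def table_from_dataframe(df: pd.DataFrame, config: StudyConfig | None = None,
                         source: str = "<dataframe>") -> ParameterTable:
    """Split a raw dataframe into metadata and validated numeric parameters."""
    if "animal_id" not in df.columns:
        raise DatasetError(f"{source}: missing required column 'animal_id'")
    meta = pd.DataFrame(index=df.index)
    meta["animal_id"] = df["animal_id"].astype(str)
    for col in METADATA_COLUMNS[1:]:
        if col in df.columns:
            meta[col] = df[col].astype(str).replace("nan", "")
        else:
            meta[col] = ""
    meta.loc[meta["sex"] == "", "sex"] = "unknown"

    dupes = meta["animal_id"][meta["animal_id"].duplicated()].unique().tolist()
    if dupes:
        raise DatasetError(f"{source}: duplicate animal_id {dupes}")

    if config is not None and config.allowed_groups:
        unknown = sorted(set(meta["group"]) - set(config.allowed_groups) - {""})
        if unknown:
            raise DatasetError(
                f"{source}: unknown group labels {unknown}; "
                f"allowed: {sorted(config.allowed_groups)}"
            )

    param_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    values = pd.DataFrame(index=df.index)
    for col in param_cols:
        raw = df[col]
        if raw.dtype == object:
            cleaned = raw.replace(list(MISSING_TOKENS), np.nan)
        else:
            cleaned = raw
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = numeric.isna() & cleaned.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetError(
                f"{source}: non-numeric value {cleaned.iloc[row]!r} in parameter "
                f"column {col!r}, row {row + 1} (animal {meta['animal_id'].iloc[row]!r})"
            )
        values[col] = numeric.astype(float)
    return ParameterTable(meta, values)


def load_table(path: str | Path, config: StudyConfig | None = None) -> ParameterTable:
    """Read a CSV/TSV file into a validated :class:`ParameterTable`.

    The delimiter is taken from the file extension (``.tsv`` -> tab). Missing
    value tokens ("", "NA", "NaN", ...) become NaN; any other non-numeric
    token in a parameter column is a hard error naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)
    return table_from_dataframe(df, config, source=str(path))


def combine_tables(tables: Iterable[ParameterTable], dedupe: bool = True) -> ParameterTable:
    """Union several tables into one combined dataset.

    Parameter columns are unioned; cells absent from a source table become
    missing. With ``dedupe`` on, an animal_id appearing in several tables
    (e.g. a naive control group shared between subprojects) is kept once;
    conflicting metadata for the same id is a hard error, and its parameter
    values are merged (a non-missing cell wins over a missing one,
    conflicting non-missing cells are an error).
    """
    tables = list(tables)
    if not tables:
        raise DatasetError("no tables to combine")
    frames = [t.to_dataframe() for t in tables]
    all_params: list[str] = []
    for t in tables:
        for p in t.parameters:
            if p not in all_params:
                all_params.append(p)
    combined = pd.concat(frames, axis=0, ignore_index=True, sort=False)

    if dedupe and combined["animal_id"].duplicated().any():
        rows = []
        for aid, grp in combined.groupby("animal_id", sort=False):
            meta_part = grp[list(METADATA_COLUMNS)].drop_duplicates()
            if len(meta_part) > 1:
                raise DatasetError(
                    f"animal_id {aid!r} appears with conflicting metadata:\n{meta_part}"
                )
            merged = grp.iloc[0].copy()
            for p in all_params:
                if p not in grp.columns:
                    continue
                vals = pd.to_numeric(grp[p], errors="coerce").dropna().unique()
                if len(vals) > 1:
                    raise DatasetError(
                        f"animal_id {aid!r} has conflicting values for {p!r}: {vals}"
                    )
                merged[p] = vals[0] if len(vals) else np.nan
            rows.append(merged)
        combined = pd.DataFrame(rows).reset_index(drop=True)

    for p in all_params:
        if p not in combined.columns:
            combined[p] = np.nan
    combined = combined[list(METADATA_COLUMNS) + all_params]
    units: dict[str, str] = {}
    for t in tables:
        units.update(t.units)
    out = table_from_dataframe(combined, source="<combined>")
    out.units = units
    return out
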