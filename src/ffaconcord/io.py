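"""Reading, writing and validating concentration tables.

The universal container is :class:`SampleTable`: a wide pandas DataFrame with
metadata columns (``sample_id``, ``species``, ``group``, ``sex``, ``age``,
``education_years``) followed by one column per analyte holding µg/mL
concentrations.  Long-format files (``sample_id, analyte_id, value``) are
pivoted to the same shape on read.  Non-numeric concentration cells (e.g.
``n.d.``) become missing values with a warning; negative concentrations are a
hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import AnalytePanel, normalize_analyte_name

__all__ = [
    "SampleTable",
    "read_concentration_table",
    "read_concentration_workbook",
    "harmonize_panels",
    "drop_sparse_analytes",
    "META_COLUMNS",
]

META_COLUMNS = ("sample_id", "species", "group", "sex", "age", "education_years")


@dataclass
class SampleTable:
    """Samples x analytes concentration matrix with group labels and covariates."""

    data: pd.DataFrame
    analytes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValueError("SampleTable requires 'sample_id' and 'group' columns")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id values: {dupes}")
        if df["group"].isna().any():
            raise ValueError("every sample must carry a group label")
        if not self.analytes:
            self.analytes = [c for c in df.columns if c not in META_COLUMNS]
        if not self.analytes:
            raise ValueError("SampleTable needs at least one analyte column")
        missing_cols = [a for a in self.analytes if a not in df.columns]
        if missing_cols:
            raise ValueError(f"analyte columns absent from data: {missing_cols}")
        conc = df[self.analytes]
        if (conc < 0).any().any():
            raise ValueError("concentrations must be non-negative where present")

    # -- accessors ---------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def concentrations(self, analyte_id: str, group: str | None = None) -> pd.Series:
        """Non-missing concentrations of one analyte, optionally for one group."""
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        return df.set_index("sample_id")[analyte_id].dropna()

    def restrict(self, analyte_ids) -> "SampleTable":
        """Copy restricted to the given analytes, keeping metadata."""
        ids = [a for a in analyte_ids]
        meta = [c for c in META_COLUMNS if c in self.data.columns]
        return SampleTable(self.data[meta + ids].copy(), ids)

    def subset_groups(self, groups) -> "SampleTable":
        keep = self.data["group"].isin(list(groups))
        return SampleTable(self.data[keep].reset_index(drop=True).copy(),
                           list(self.analytes))

    # -- serialization -----------------------------------------------------
    def to_wide_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_long(self) -> pd.DataFrame:
        meta = [c for c in META_COLUMNS if c in self.data.columns]
        return self.data.melt(id_vars=meta, value_vars=self.analytes,
                              var_name="analyte_id", value_name="value")

    def to_long_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def _coerce_concentrations(df: pd.DataFrame, analytes: list[str]) -> pd.DataFrame:
    """Force analyte columns numeric; non-numeric cells -> NaN with a warning."""
    n_coerced = 0
    out = df.copy()
    for col in analytes:
        raw = out[col]
        num = pd.to_numeric(raw, errors="coerce")
        n_coerced += int((raw.notna() & num.isna()).sum())
        out[col] = num
    if n_coerced:
        warnings.warn(f"{n_coerced} non-numeric concentration cell(s) set to missing")
    return out


def _read_frame(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_concentration_table(path, dialect: str = "wide",
                             normalize_names: bool = True) -> SampleTable:
    """Read a wide or long CSV/TSV concentration table into a SampleTable.

    Parameters
    ----------
    path : path-like
        CSV (or TSV, by extension) file.
    dialect : {"wide", "long"}
        Wide: one row per sample, one column per analyte.  Long: columns
        ``sample_id``, ``analyte_id``, ``value`` plus optional metadata.
    normalize_names : bool
        Map analyte column names / ids through the synonym dictionary.
    """
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_frame(path)
    if dialect == "long":
        required = {"sample_id", "analyte_id", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long dialect requires columns {sorted(required)}")
        meta = [c for c in META_COLUMNS if c in df.columns]
        wide = df.pivot_table(index=meta, columns="analyte_id", values="value",
                              aggfunc="first").reset_index()
        wide.columns.name = None
        df = wide
    analytes = [c for c in df.columns if c not in META_COLUMNS]
    if not analytes:
        raise ValueError("no analyte columns found")
    if normalize_names:
        mapping = {a: normalize_analyte_name(a) for a in analytes}
        df = df.rename(columns=mapping)
        analytes = list(dict.fromkeys(mapping.values()))
    df = _coerce_concentrations(df, analytes)
    return SampleTable(df, analytes)


def read_concentration_workbook(path, normalize_names: bool = True
                                ) -> dict[str, SampleTable]:
    """Read an XLSX workbook with one cohort per sheet (wide layout)."""
    sheets = pd.read_excel(path, sheet_name=None)
    out: dict[str, SampleTable] = {}
    for name, df in sheets.items():
        analytes = [c for c in df.columns if c not in META_COLUMNS]
        if not analytes:
            raise ValueError(f"sheet {name!r} has no analyte columns")
        if normalize_names:
            mapping = {a: normalize_analyte_name(str(a)) for a in analytes}
            df = df.rename(columns=mapping)
            analytes = list(dict.fromkeys(mapping.values()))
        df = _coerce_concentrations(df, analytes)
        out[name] = SampleTable(df, analytes)
    return out


def harmonize_panels(a: SampleTable, b: SampleTable
                     ) -> tuple[AnalytePanel, SampleTable, SampleTable]:
    """Restrict two tables to their shared analyte panel in canonical order.

    Raises on an empty intersection (the cohorts would have nothing to
    compare).
    """
    shared = set(a.analytes) & set(b.analytes)
    if not shared:
        raise ValueError("analyte panels are disjoint; nothing to harmonize")
    panel = AnalytePanel.canonical(shared)
    ids = list(panel)
    return panel, a.restrict(ids), b.restrict(ids)


def drop_sparse_analytes(table: SampleTable, max_missing_frac: float = 0.2
                         ) -> tuple[SampleTable, list[str]]:
    """Drop analytes missing in more than `max_missing_frac` of any group.

    Remaining missing values are left in place for pairwise per-analyte
    exclusion downstream.
    """
    dropped: list[str] = []
    for analyte in table.analytes:
        for g in table.groups:
            vals = table.data.loc[table.data["group"] == g, analyte]
            if len(vals) and vals.isna().mean() > max_missing_frac:
                dropped.append(analyte)
                break
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} analyte(s) exceeding "
            f"{max_missing_frac:.0%} missingness in a group: {dropped}")
    keep = [a for a in table.analytes if a not in dropped]
    if not keep:
        raise ValueError("all analytes dropped by the missing-data policy")
    return table.restrict(keep), dropped
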