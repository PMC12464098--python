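"""Species-level table: reading, validation, standardization, incidence.

One row per cultivated alien species. The canonical columns are

* ``species_id`` — unique name string,
* ``naturalized`` — 0/1 outcome (established self-sustaining populations),
* nine origin indicator columns (TDWG level-1 continents; a species may be
  native to several continents),
* ``native_range_size`` — number of TDWG level-3 "botanical countries"
  (at most 369) the species is native to,
* seven growth-form indicator columns (a species may carry several),
* continuous traits ``seed_mass`` (mg), ``height`` (m), ``sla`` (mm2/mg),
* phylogenetic distance indices ``pd_mean``, ``pd_min`` and optionally
  ``pd_wmean`` (branch-length units, typically My),
* ``suitability`` — count of grid cells projected climatically suitable.

Trait cells may be missing; missingness is preserved (never coerced to 0)
and handled per-model as complete-case analysis downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

#: TDWG level-1 continents used as origin indicators.
CONTINENTS = (
    "europe",
    "africa",
    "asia_temperate",
    "asia_tropical",
    "australasia",
    "pacific",
    "northern_america",
    "southern_america",
    "antarctic",
)

#: Growth-form categories (a species may belong to more than one).
GROWTH_FORMS = (
    "short_lived_herb",
    "long_lived_herb",
    "woody",
    "aquatic",
    "climber",
    "epiphyte",
    "parasite",
)

ORIGIN_COLUMNS = tuple(f"origin_{c}" for c in CONTINENTS)
GROWTH_FORM_COLUMNS = tuple(f"gf_{g}" for g in GROWTH_FORMS)

#: Continuous characteristics (candidates for standardization / log10).
CONTINUOUS_TRAITS = (
    "native_range_size",
    "seed_mass",
    "height",
    "sla",
    "pd_mean",
    "pd_min",
    "pd_wmean",
    "suitability",
)

FLAG_COLUMNS = ("naturalized",) + ORIGIN_COLUMNS + GROWTH_FORM_COLUMNS
REQUIRED_COLUMNS = ("species_id", "naturalized")

MAX_NATIVE_RANGE = 369  # number of TDWG level-3 regions

_NA_VALUES = ["", "NA"]


@dataclass
class ColumnMapping:
    """Maps canonical field names to source-file headers, with optional
    per-variable pre-transform.

    Parameters
    ----------
    columns
        ``canonical name -> source header``. Canonical names absent from the
        map are assumed to appear verbatim in the file.
    transforms
        ``canonical name -> "identity" | "log10"``. A ``log10`` entry is
        applied by :func:`standardize` before scaling (heavy-tailed traits
        such as seed mass or range size are commonly log-transformed first).
    """

    columns: dict[str, str] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.transforms.items() if v not in ("identity", "log10")}
        if bad:
            raise ConfigurationError(f"unknown transform tags: {bad}")
        seen: dict[str, str] = {}
        for canon, src in self.columns.items():
            if src in seen.values():
                raise ConfigurationError(
                    f"source column {src!r} mapped to more than one canonical field"
                )
            seen[canon] = src

    def source(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def transform(self, canonical: str) -> str:
        return self.transforms.get(canonical, "identity")


class NaturalizationSummary(NamedTuple):
    n_total: int
    n_naturalized: int
    fraction: float


@dataclass
class StandardizationParams:
    """Per-variable (mean, sd) recorded when columns are scaled to z-scores,
    plus the pre-transform that was applied. Applying then inverting the
    transform is the identity."""

    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)

    def apply(self, name: str, values: np.ndarray | float) -> np.ndarray | float:
        mean, sd = self.params[name]
        x = np.asarray(values, dtype=float)
        if self.transforms.get(name, "identity") == "log10":
            x = np.log10(x)
        out = (x - mean) / sd
        return float(out) if np.ndim(values) == 0 else out

    def invert(self, name: str, values: np.ndarray | float) -> np.ndarray | float:
        mean, sd = self.params[name]
        x = np.asarray(values, dtype=float) * sd + mean
        if self.transforms.get(name, "identity") == "log10":
            x = 10.0 ** x
        return float(x) if np.ndim(values) == 0 else x

    def to_file(self, path: str | Path) -> None:
        lines = []
        for name, (mean, sd) in self.params.items():
            tr = self.transforms.get(name, "identity")
            lines.append(f"{name}\tmean={mean!r}\tsd={sd!r}\ttransform={tr}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "StandardizationParams":
        params: dict[str, tuple[float, float]] = {}
        transforms: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            name, *fields = line.split("\t")
            kv = dict(f.split("=", 1) for f in fields)
            params[name] = (float(kv["mean"]), float(kv["sd"]))
            transforms[name] = kv.get("transform", "identity")
        return cls(params=params, transforms=transforms)


@dataclass
class SpeciesTable:
    """A validated species-level table.

    ``df`` holds canonical columns; ``provenance`` records where the data
    came from and which column mapping was used.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate(self.df, standardized=self.provenance.get("standardized", ()))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def copy(self) -> "SpeciesTable":
        return SpeciesTable(self.df.copy(), dict(self.provenance))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, na_rep="NA")


def validate(df: pd.DataFrame, standardized: Iterable[str] = ()) -> None:
    """Check the domain invariants of a species table; raise on violation.

    Columns listed in ``standardized`` are z-scores and exempt from the
    raw-scale domain checks (positivity, count ranges, PD ordering).
    """
    standardized = set(standardized)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} is missing")
    if len(df) == 0:
        raise ValidationError("species table has no records")

    ids = df["species_id"]
    if ids.isna().any():
        raise ValidationError("species_id contains missing values")
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate species_id values: {list(dup[:5])}")

    for col in FLAG_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        # naturalized must be present; other flags may be missing columns but
        # not missing cells once the column exists
        bad = ~vals.isin([0, 1])
        if col != "naturalized":
            bad &= vals.notna()
        if bad.any():
            rows = list(df.index[bad][:10] + 1)
            raise ValidationError(
                f"column {col!r} has non-binary values in rows {rows}"
            )

    if "native_range_size" in df.columns and "native_range_size" not in standardized:
        nrs = pd.to_numeric(df["native_range_size"], errors="coerce")
        neg = nrs.notna() & (nrs < 0)
        if neg.any():
            raise ValidationError("native_range_size must be non-negative")
        over = nrs.notna() & (nrs > MAX_NATIVE_RANGE)
        if over.any():
            raise ValidationError(
                f"native_range_size exceeds the {MAX_NATIVE_RANGE} TDWG level-3 regions"
            )
        origin_cols = [c for c in ORIGIN_COLUMNS if c in df.columns]
        if origin_cols:
            has_origin = df[origin_cols].fillna(0).sum(axis=1) > 0
            zero_range = nrs.fillna(1) == 0
            conflict = has_origin & zero_range
            if conflict.any():
                rows = list(df.index[conflict][:10] + 1)
                raise ValidationError(
                    f"native_range_size is 0 despite origin flags in rows {rows}"
                )
        if (nrs.notna() & (nrs == 0)).any():
            warnings.warn(
                "native_range_size of 0 encountered (accepted; e.g. hybrids of "
                "horticultural origin)",
                stacklevel=2,
            )

    for col in ("seed_mass", "height", "sla", "suitability", "pd_mean", "pd_min", "pd_wmean"):
        if col not in df.columns or col in standardized:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        strict_positive = col in ("seed_mass", "height", "sla")
        bad = vals.notna() & ((vals <= 0) if strict_positive else (vals < 0))
        if bad.any():
            rows = list(df.index[bad][:10] + 1)
            raise ValidationError(f"column {col!r} out of domain in rows {rows}")

    if standardized & {"pd_min", "pd_mean", "pd_wmean"}:
        return
    if "pd_min" in df.columns and "pd_mean" in df.columns:
        both = df["pd_min"].notna() & df["pd_mean"].notna()
        viol = both & (df["pd_min"] > df["pd_mean"] + 1e-9)
        if viol.any():
            rows = list(df.index[viol][:10] + 1)
            raise ValidationError(f"pd_min > pd_mean in rows {rows}")
    if "pd_min" in df.columns and "pd_wmean" in df.columns:
        both = df["pd_min"].notna() & df["pd_wmean"].notna()
        viol = both & (df["pd_min"] > df["pd_wmean"] + 1e-9)
        if viol.any():
            rows = list(df.index[viol][:10] + 1)
            raise ValidationError(f"pd_min > pd_wmean in rows {rows}")


def read_species_table(
    path: str | Path, mapping: ColumnMapping | None = None
) -> SpeciesTable:
    """Read and validate a species table from CSV.

    Missing values are encoded as an empty cell or ``NA`` and preserved as
    missing. Rows violating a binary-flag invariant raise
    :class:`ValidationError` naming the offending rows (1-based, excluding
    the header).
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"species table not found: {path}")
    raw = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})

    rename: dict[str, str] = {}
    known = ["species_id", *FLAG_COLUMNS, *CONTINUOUS_TRAITS]
    for canon in known:
        src = mapping.source(canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in mapping.columns:
            raise ConfigurationError(
                f"mapped column {src!r} (for field {canon!r}) not found in {path.name}"
            )
    df = raw.rename(columns=rename)
    if "species_id" in df.columns:
        df["species_id"] = df["species_id"].astype(str)

    numeric_cols = [c for c in df.columns if c in FLAG_COLUMNS or c in CONTINUOUS_TRAITS]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise ValidationError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column {col!r}, row {row}"
            )
        df[col] = coerced

    table = SpeciesTable(
        df,
        provenance={
            "source": str(path),
            "column_mapping": dict(mapping.columns),
            "transforms": dict(mapping.transforms),
        },
    )
    return table


def standardize(
    table: SpeciesTable,
    variables: Iterable[str],
    transforms: dict[str, str] | None = None,
) -> tuple[SpeciesTable, StandardizationParams]:
    """Scale the named continuous variables to mean 0, sd 1 (sample sd,
    denominator n-1), over non-missing entries.

    A ``log10`` pre-transform is applied first for variables tagged so,
    either via ``transforms`` or the transform tags recorded when the table
    was read. Returns a new table plus the parameters needed to apply the
    identical scaling to new values (e.g. counterfactual mediator counts).
    """
    df = table.df.copy()
    transforms = {**table.provenance.get("transforms", {}), **(transforms or {})}
    params = StandardizationParams()
    for name in variables:
        if name not in df.columns:
            raise ConfigurationError(f"unknown variable {name!r}")
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        tr = transforms.get(name, "identity")
        if tr == "log10":
            if np.nanmin(vals) <= 0:
                raise ValidationError(
                    f"variable {name!r} has non-positive values; log10 undefined"
                )
            vals = np.log10(vals)
        ok = ~np.isnan(vals)
        if np.unique(vals[ok]).size < 2:
            raise ValidationError(f"constant variable {name!r}: sd = 0")
        mean = float(np.mean(vals[ok]))
        sd = float(np.std(vals[ok], ddof=1))
        if not math.isfinite(sd) or sd == 0:
            raise ValidationError(f"constant variable {name!r}: sd = 0")
        out = np.full_like(vals, np.nan)
        out[ok] = (vals[ok] - mean) / sd
        df[name] = out
        params.params[name] = (mean, sd)
        params.transforms[name] = tr
    prov = dict(table.provenance)
    prov["standardized"] = sorted(
        set(prov.get("standardized", ())) | set(params.params)
    )
    new = SpeciesTable(df, prov)
    return new, params


def naturalization_summary(table: SpeciesTable) -> NaturalizationSummary:
    """Count species, naturalized species, and the naturalization fraction."""
    y = table.df["naturalized"]
    n_total = int(len(y))
    n_nat = int((y == 1).sum())
    return NaturalizationSummary(n_total, n_nat, n_nat / n_total)
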