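"""Tidy isotope tables: data model, readers/writers, validation.

The canonical on-disk format is a tidy CSV (RFC-4180, UTF-8, header required)
with one row per analysed individual and columns::

    species, ecosystem, role, d15N, d13C, tissue [, provenance, ...]

``role`` is ``consumer`` or ``baseline``; the baseline taxon (e.g. a
macrophyte) anchors the community's isotope scale.  Unknown extra columns are
preserved in each sample's ``extra`` mapping and otherwise ignored, so
provenance or field metadata survive a round trip.
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSample",
    "SpeciesGroup",
    "CommunityDataset",
    "SchemaError",
    "EmptyInputError",
    "RowParseError",
    "Finding",
    "read_isotope_table",
    "write_community",
    "write_results",
    "validate_dataset",
]

REQUIRED_COLUMNS = ("species", "ecosystem", "role", "d15N", "d13C", "tissue")
ROLES = ("consumer", "baseline")
PROVENANCES = ("resident", "donor")


class SchemaError(ValueError):
    """The table is missing a required column or uses an unknown category."""


class EmptyInputError(ValueError):
    """The table has a header but no data rows."""


class RowParseError(ValueError):
    """A data row holds a non-numeric isotope value; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class IsotopeSample:
    """One individual's measurement in the delta-13C / delta-15N plane.

    Values are per-mil (permil) deviations from the international standards
    (VPDB for carbon, atmospheric N2 for nitrogen).
    """

    species: str
    ecosystem: str
    role: str  # "consumer" | "baseline"
    d15N: float
    d13C: float
    tissue: str = ""
    provenance: str = "resident"  # "resident" | "donor"
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.provenance not in PROVENANCES:
            raise SchemaError(
                f"unknown provenance {self.provenance!r}; expected one of {PROVENANCES}"
            )
        if not (np.isfinite(self.d15N) and np.isfinite(self.d13C)):
            raise ValueError(
                f"non-finite isotope value for {self.species}: "
                f"d15N={self.d15N}, d13C={self.d13C}"
            )


@dataclass
class SpeciesGroup:
    """All samples of one species within one ecosystem."""

    species: str
    samples: list[IsotopeSample]

    def __post_init__(self):
        if not self.samples:
            raise ValueError(f"species group {self.species!r} has no samples")
        eco = {s.ecosystem for s in self.samples}
        sp = {s.species for s in self.samples}
        if sp != {self.species} or len(eco) != 1:
            raise ValueError(
                f"group {self.species!r}: samples must share species and ecosystem"
            )

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def ecosystem(self) -> str:
        return self.samples[0].ecosystem

    @property
    def role(self) -> str:
        return self.samples[0].role

    @property
    def provenance(self) -> str:
        return self.samples[0].provenance

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array with columns (d13C, d15N) — biplot convention."""
        return np.array([[s.d13C, s.d15N] for s in self.samples], dtype=float)

    @property
    def d15N(self) -> np.ndarray:
        return np.array([s.d15N for s in self.samples], dtype=float)

    @property
    def d13C(self) -> np.ndarray:
        return np.array([s.d13C for s in self.samples], dtype=float)


@dataclass
class CommunityDataset:
    """One ecosystem's species groups plus its designated baseline taxon."""

    ecosystem: str
    groups: dict[str, SpeciesGroup]
    baseline_species: str | None = None

    def __iter__(self) -> Iterable[SpeciesGroup]:
        return iter(self.groups.values())

    def __contains__(self, species: str) -> bool:
        return species in self.groups

    def group(self, species: str) -> SpeciesGroup:
        try:
            return self.groups[species]
        except KeyError:
            raise KeyError(
                f"species {species!r} not in ecosystem {self.ecosystem!r}"
            ) from None

    @property
    def baseline(self) -> SpeciesGroup:
        if self.baseline_species is None or self.baseline_species not in self.groups:
            raise KeyError(f"ecosystem {self.ecosystem!r} has no baseline group")
        return self.groups[self.baseline_species]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self:
            for s in g.samples:
                row = {
                    "species": s.species,
                    "ecosystem": s.ecosystem,
                    "role": s.role,
                    "d15N": s.d15N,
                    "d13C": s.d13C,
                    "tissue": s.tissue,
                    "provenance": s.provenance,
                }
                row.update(s.extra)
                rows.append(row)
        return pd.DataFrame(rows)


Source = Union[str, os.PathLike, IO[str]]


def read_isotope_table(source: Source) -> CommunityDataset:
    """Read a tidy isotope CSV into a :class:`CommunityDataset`.

    One :class:`SpeciesGroup` is created per distinct species; row counts are
    preserved exactly (no silent filtering).  Malformed rows raise
    :class:`RowParseError` with their 1-based file line number.

    Raises
    ------
    SchemaError
        A required column is absent, or the file mixes ecosystems.
    EmptyInputError
        Header only, no data rows.
    RowParseError
        Non-numeric ``d15N``/``d13C`` in a data row.
    """
    df = pd.read_csv(source, dtype=str, skip_blank_lines=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError("isotope table has a header but no data rows")

    extra_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c != "provenance"
    ]
    has_prov = "provenance" in df.columns

    samples: list[IsotopeSample] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row[list(REQUIRED_COLUMNS)].isna().all():
            continue  # blank line
        vals = {}
        for col in ("d15N", "d13C"):
            raw = row[col]
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise RowParseError(
                    f"non-numeric {col} value {raw!r} for species {row['species']!r}",
                    line,
                ) from None
        samples.append(
            IsotopeSample(
                species=str(row["species"]),
                ecosystem=str(row["ecosystem"]),
                role=str(row["role"]),
                d15N=vals["d15N"],
                d13C=vals["d13C"],
                tissue="" if pd.isna(row["tissue"]) else str(row["tissue"]),
                provenance=(
                    str(row["provenance"])
                    if has_prov and not pd.isna(row["provenance"])
                    else "resident"
                ),
                extra={
                    c: row[c] for c in extra_cols if not pd.isna(row[c])
                },
            )
        )
    if not samples:
        raise EmptyInputError("isotope table has no non-blank data rows")

    ecosystems = {s.ecosystem for s in samples}
    if len(ecosystems) > 1:
        raise SchemaError(
            f"table mixes ecosystems {sorted(ecosystems)}; one community per file"
        )

    groups: dict[str, SpeciesGroup] = {}
    for s in samples:
        groups.setdefault(s.species, []).append(s)  # type: ignore[arg-type]
    groups = {sp: SpeciesGroup(sp, ss) for sp, ss in groups.items()}

    baseline = sorted({s.species for s in samples if s.role == "baseline"})
    return CommunityDataset(
        ecosystem=samples[0].ecosystem,
        groups=groups,
        baseline_species=baseline[0] if baseline else None,
    )


def write_community(ds, sink: Source, decimals: int | None = None) -> None:
    """Write a community (raw or standardized) back to the tidy CSV schema."""
    df = ds.to_frame()
    if decimals is not None:
        for col in ("d15N", "d13C"):
            df[col] = df[col].round(decimals)
    df.to_csv(sink, index=False)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    sink: Source,
    format: str = "csv",
    decimals: int = 2,
) -> None:
    """Write a bundle of result tables to ``sink``.

    ``tables`` maps table names (e.g. ``"layman"``, ``"overlap"``, ``"tp"``,
    ``"mixing"``) to data frames.  Numeric columns are rounded to ``decimals``
    places (default 2).  With ``format="csv"`` and more than one table,
    ``sink`` must be a directory (one ``<name>.csv`` per table); JSON output
    nests all tables in one document keyed by name.
    """
    if not tables:
        raise ValueError("empty result bundle: nothing to write")
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}")

    def _round(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(decimals)
        return out

    if format == "json":
        doc = {
            name: json.loads(_round(df).to_json(orient="records"))
            for name, df in tables.items()
        }
        if hasattr(sink, "write"):
            json.dump(doc, sink, indent=1)
        else:
            with open(sink, "w") as fh:
                json.dump(doc, fh, indent=1)
        return

    if isinstance(sink, (str, os.PathLike)) and os.path.isdir(sink):
        for name, df in tables.items():
            _round(df).to_csv(os.path.join(sink, f"{name}.csv"), index=False)
        return
    if len(tables) == 1:
        ((_, df),) = tables.items()
        _round(df).to_csv(sink, index=False)
        return
    raise ValueError("multiple CSV tables need a directory sink")


@dataclass(frozen=True)
class Finding:
    """One validation finding; validation reports, it never raises."""

    code: str  # "missing_baseline" | "small_group" | "duplicate_species"
    species: str | None
    message: str


def validate_dataset(ds: CommunityDataset) -> list[Finding]:
    """Enumerate conditions that would break downstream stages.

    Findings cover a missing/undeclared baseline group and groups too small
    to fit a covariance ellipse (n < 3).  Duplicate species labels cannot
    survive the grouped container, but a baseline declared under a label that
    is absent from the groups is reported.
    """
    findings: list[Finding] = []
    if ds.baseline_species is None:
        findings.append(
            Finding("missing_baseline", None, "no baseline species declared")
        )
    elif ds.baseline_species not in ds.groups:
        findings.append(
            Finding(
                "missing_baseline",
                ds.baseline_species,
                f"declared baseline {ds.baseline_species!r} has no samples",
            )
        )
    for g in ds:
        if g.n < 3:
            findings.append(
                Finding(
                    "small_group",
                    g.species,
                    f"{g.species}: n={g.n} insufficient for ellipse fitting (need 3)",
                )
            )
    return findings
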