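"""Reading, validation and cleaning of multi-source occurrence tables.

An occurrence record is the atomic datum: one dated observation of a species,
attributed to one of three provenance classes (literature & collections,
citizen science, structured sampling), optionally georeferenced in decimal
degrees at a stated spatial resolution. Records that cannot be dated are
unusable for last-observation statistics and are dropped — counted, never
silently — by :func:`clean_records`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Source",
    "Resolution",
    "OccurrenceRecord",
    "Dialect",
    "DEFAULT_DIALECT",
    "CleaningReport",
    "Inventory",
    "canonical_species",
    "read_occurrences",
    "write_occurrences",
    "clean_records",
    "species_inventory",
]

#: Earliest plausible record year accepted by default during cleaning.
DEFAULT_MIN_YEAR = 1700


class Source(str, enum.Enum):
    """Provenance class of a record."""

    LITERATURE = "literature_collections"
    CITIZEN_SCIENCE = "citizen_science"
    SAMPLING = "sampling"


class Resolution(str, enum.Enum):
    """Spatial resolution class of the stated coordinates."""

    RES_1KM = "res_1km"
    RES_3KM = "res_3km"
    RES_10KM = "res_10km"
    UNKNOWN = "unknown"


def canonical_species(name: str) -> str:
    """Canonicalise a taxon name: trim, collapse whitespace, normalise case.

    Matching is exact on the canonical form — no fuzzy synonymy. The regional
    checklists this package targets use a fixed nomenclature, so
    ``" erebia  Eriphyle "`` and ``"Erebia eriphyle"`` are the same species
    but distinct spellings are distinct taxa.
    """
    squeezed = " ".join(name.split())
    if not squeezed:
        return squeezed
    return squeezed[0].upper() + squeezed[1:].lower()


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated, sourced, optionally georeferenced observation of a species.

    ``year`` is ``None`` when the record could not be dated; such records are
    removed by :func:`clean_records`. ``latitude``/``longitude`` are decimal
    degrees and are either both present or both absent. ``year_assigned``
    marks literature/collection records whose year was imputed from the
    publication year rather than the sampling event.
    """

    species: str
    year: int | None
    source: Source
    latitude: float | None = None
    longitude: float | None = None
    resolution: Resolution = Resolution.UNKNOWN
    year_assigned: bool = False

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"{self.species}: latitude and longitude must be both present "
                "or both absent"
            )

    @property
    def georeferenced(self) -> bool:
        return self.latitude is not None


# ---------------------------------------------------------------------------
# Column dialect


@dataclass(frozen=True)
class Dialect:
    """Column-mapping configuration for delimited occurrence tables.

    Maps header names to the semantic fields and value tokens to the source /
    resolution enums, so tables with divergent headers (e.g. a deposited
    archive vs. generator output) parse without code changes. ``delimiter``
    ``None`` auto-detects comma vs. tab from the header line.
    """

    species_col: str = "species"
    year_col: str = "year"
    source_col: str = "source"
    lat_col: str = "lat"
    lon_col: str = "lon"
    resolution_col: str = "resolution"
    year_assigned_col: str = "year_assigned"
    delimiter: str | None = None
    source_map: Mapping[str, Source] = field(
        default_factory=lambda: {s.value: s for s in Source}
    )
    resolution_map: Mapping[str, Resolution] = field(
        default_factory=lambda: {r.value: r for r in Resolution}
    )
    true_tokens: frozenset[str] = frozenset({"1", "true", "yes", "y"})

    def map_source(self, token: str) -> Source:
        key = token.strip()
        try:
            return self.source_map[key]
        except KeyError:
            raise ValueError(
                f"unknown source token {token!r}; dialect knows "
                f"{sorted(self.source_map)}"
            ) from None

    def map_resolution(self, token: object) -> Resolution:
        if token is None or (isinstance(token, float) and math.isnan(token)):
            return Resolution.UNKNOWN
        key = str(token).strip()
        if not key:
            return Resolution.UNKNOWN
        return dict(self.resolution_map).get(key, Resolution.UNKNOWN)


DEFAULT_DIALECT = Dialect()


def _parse_year(value: object) -> int | None:
    """Lenient year parse: unparseable or blank values become missing."""
    if value is None:
        return None
    if isinstance(value, float):
        if math.isnan(value):
            return None
        return int(value) if value.is_integer() else None
    text = str(value).strip()
    if not text:
        return None
    try:
        return int(float(text)) if float(text).is_integer() else None
    except ValueError:
        return None


def _parse_coord(value: object) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def read_occurrences(
    path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> list[OccurrenceRecord]:
    """Read a delimited occurrence table into records, order preserved.

    The file must have a header row containing at least the species and
    source columns (hard error naming the missing column otherwise). Years
    that cannot be parsed become missing rather than errors; a record with
    only one of lat/lon is treated as not georeferenced.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep=dialect.delimiter,
        engine="python" if dialect.delimiter is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    if frame.shape[1] == 0 or (frame.shape[0] == 0 and frame.shape[1] == 0):
        raise ValueError(f"{path}: empty occurrence table")
    for col, label in ((dialect.species_col, "species"), (dialect.source_col, "source")):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r} ({label})")

    def cell(row: pd.Series, col: str) -> object:
        return row[col] if col in frame.columns else None

    records: list[OccurrenceRecord] = []
    for _, row in frame.iterrows():
        lat = _parse_coord(cell(row, dialect.lat_col))
        lon = _parse_coord(cell(row, dialect.lon_col))
        if (lat is None) != (lon is None):
            lat = lon = None
        flag_raw = cell(row, dialect.year_assigned_col)
        flag = (
            str(flag_raw).strip().lower() in dialect.true_tokens
            if flag_raw is not None
            else False
        )
        records.append(
            OccurrenceRecord(
                species=canonical_species(str(row[dialect.species_col])),
                year=_parse_year(cell(row, dialect.year_col)),
                source=dialect.map_source(str(row[dialect.source_col])),
                latitude=lat,
                longitude=lon,
                resolution=dialect.map_resolution(cell(row, dialect.resolution_col)),
                year_assigned=flag,
            )
        )
    if not records:
        raise ValueError(f"{path}: empty occurrence table")
    return records


def write_occurrences(
    records: Iterable[OccurrenceRecord],
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
) -> None:
    """Emit records as delimited text readable back with the same dialect."""
    inverse_source = {v: k for k, v in dict(dialect.source_map).items()}
    inverse_res = {v: k for k, v in dict(dialect.resolution_map).items()}
    rows = []
    for r in records:
        rows.append(
            {
                dialect.species_col: r.species,
                dialect.year_col: "" if r.year is None else r.year,
                dialect.source_col: inverse_source[r.source],
                dialect.lat_col: "" if r.latitude is None else repr(r.latitude),
                dialect.lon_col: "" if r.longitude is None else repr(r.longitude),
                dialect.resolution_col: inverse_res.get(r.resolution, r.resolution.value),
                dialect.year_assigned_col: "1" if r.year_assigned else "0",
            }
        )
    sep = dialect.delimiter or ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Cleaning


@dataclass
class CleaningReport:
    """Tally of what cleaning kept and dropped, and of the retained set.

    ``counts_by_source`` maps each source to ``(count, percentage of
    retained)``. ``n_distinct_years`` and the min/max year are both exposed
    because "years covered" is often reported as the count of distinct record
    years, which for a sparse historical series is far below the span.
    """

    n_input: int
    n_retained: int
    n_dropped_no_year: int
    n_dropped_year_out_of_range: int
    n_year_assigned: int
    n_georeferenced: int
    counts_by_resolution: dict[str, int]
    counts_by_source: dict[str, tuple[int, float]]
    n_distinct_years: int
    year_min: int | None
    year_max: int | None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def clean_records(
    records: Sequence[OccurrenceRecord],
    end_year: int | None = None,
    min_year: int = DEFAULT_MIN_YEAR,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Drop undatable or out-of-bounds records; never hard-fails.

    Records without a year are removed (they cannot enter any of the
    downstream year-based statistics); records with a year outside
    ``[min_year, end_year]`` are rejected as implausible. Everything else is
    retained, including non-georeferenced records (excluded only from
    gridding) and year-assigned records (flag carried through).

    ``end_year`` defaults to the maximum year present in the input.
    """
    years_present = [r.year for r in records if r.year is not None]
    if end_year is None:
        end_year = max(years_present) if years_present else None

    retained: list[OccurrenceRecord] = []
    n_no_year = 0
    n_out_of_range = 0
    for r in records:
        if r.year is None:
            n_no_year += 1
        elif r.year < min_year or (end_year is not None and r.year > end_year):
            n_out_of_range += 1
        else:
            retained.append(r)

    by_source = Counter(r.source for r in retained)
    n_ret = len(retained)
    counts_by_source = {
        s.value: (by_source[s], 100.0 * by_source[s] / n_ret if n_ret else 0.0)
        for s in Source
    }
    years = sorted({r.year for r in retained})
    report = CleaningReport(
        n_input=len(records),
        n_retained=n_ret,
        n_dropped_no_year=n_no_year,
        n_dropped_year_out_of_range=n_out_of_range,
        n_year_assigned=sum(r.year_assigned for r in retained),
        n_georeferenced=sum(r.georeferenced for r in retained),
        counts_by_resolution={
            res.value: sum(r.resolution is res for r in retained) for res in Resolution
        },
        counts_by_source=counts_by_source,
        n_distinct_years=len(years),
        year_min=years[0] if years else None,
        year_max=years[-1] if years else None,
    )
    return retained, report


# ---------------------------------------------------------------------------
# Species inventory


@dataclass
class Inventory:
    """Per-source species sets and the missing-species tallies against the union."""

    by_source: dict[Source, set[str]]
    union: set[str]
    missing_by_source: dict[Source, set[str]]

    def missing_counts(self) -> dict[Source, int]:
        return {s: len(miss) for s, miss in self.missing_by_source.items()}


def species_inventory(records: Iterable[OccurrenceRecord]) -> Inventory:
    """Which species each source has recorded, and which it misses.

    A source "misses" a species when the species appears in the union of all
    sources but has no record from that source. An empty record list yields
    empty sets, not an error.
    """
    by_source: dict[Source, set[str]] = {s: set() for s in Source}
    for r in records:
        by_source[r.source].add(r.species)
    union = set().union(*by_source.values())
    missing = {s: union - seen for s, seen in by_source.items()}
    return Inventory(by_source=by_source, union=union, missing_by_source=missing)
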