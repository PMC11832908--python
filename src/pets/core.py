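"""The PETS statistic: per-species and community extinction potential.

PETS (Potential Extinction upon Time Series) scores each species by the
fraction of its known regional history during which it has gone unobserved:

    absence_fraction = (Y_end - y_last) / (Y_end - y_first)

where ``Y_end`` is the final survey year, ``y_last`` the species' most recent
record year and ``y_first`` its earliest. A species seen this year scores 0;
a species unseen since shortly after discovery approaches 1. The statistic
adapts the classic binary extinction-rate idea to continuous
time-since-last-observation data; it flags local-extinction candidates, it
does not prove extinction.

At the community level the per-species spans are aggregated either as the
pooled ratio (sum of absence spans over sum of total spans — the ratio of the
summed "absence" bar lengths to the summed full bar lengths on a persistence
plot) or as the mean of the per-species fractions. Both are computed; the
pooled ratio is the default.

A key use is source-exclusion sensitivity: recompute the statistic with a
recent, high-volume source (typically citizen science) removed to see how
much that source's recent confirmations suppress apparent extinction.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Collection, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .records import OccurrenceRecord, Source

__all__ = [
    "SpeciesTimeline",
    "PetsSpeciesResult",
    "PetsCommunityResult",
    "TimelineMatrix",
    "TimelineBuild",
    "build_timelines",
    "pets_species",
    "pets_community",
    "species_last_seen_before",
    "timeline_matrix",
    "plot_timeline",
]

#: Cell states of the persistence/absence matrix.
NO_RECORD = "no_record"
MULTIPLE_SOURCES = "multiple_sources"
YEAR_ASSIGNED = "year_assigned"


@dataclass(frozen=True)
class SpeciesTimeline:
    """Per-species record years split by source, with the derived span bounds.

    ``first_record``/``last_occasion`` are the min/max over all retained
    sources; ``end_year`` is the final survey year closing the series.
    """

    species: str
    years_by_source: dict[Source, tuple[int, ...]]
    first_record: int
    last_occasion: int
    end_year: int

    def __post_init__(self) -> None:
        if not (self.first_record <= self.last_occasion <= self.end_year):
            raise ValueError(
                f"{self.species}: need first_record <= last_occasion <= end_year, "
                f"got {self.first_record}, {self.last_occasion}, {self.end_year}"
            )

    @property
    def all_years(self) -> tuple[int, ...]:
        return tuple(sorted({y for ys in self.years_by_source.values() for y in ys}))


@dataclass(frozen=True)
class PetsSpeciesResult:
    """Absence fraction of one species, with the integer spans behind it."""

    species: str
    absence_years: int
    presence_span: int
    absence_fraction: float


@dataclass(frozen=True)
class PetsCommunityResult:
    """Community extinction potential with its per-species breakdown.

    ``community_extinction_potential`` is a percentage under the requested
    aggregation; both aggregations are always carried (``pooled_pct``,
    ``mean_pct``) so the sensitivity of the headline number to the
    aggregation choice is visible. ``species_results`` is sorted by last
    occasion, most recently seen first, ties alphabetical.
    """

    community_extinction_potential: float
    aggregation: str
    pooled_pct: float
    mean_pct: float
    species_results: tuple[PetsSpeciesResult, ...]
    n_species: int
    excluded_sources: frozenset[Source] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.species_results],
                "absence_years": [r.absence_years for r in self.species_results],
                "presence_span": [r.presence_span for r in self.species_results],
                "absence_fraction": [r.absence_fraction for r in self.species_results],
            }
        )

    def as_dict(self) -> dict:
        return {
            "community_extinction_potential": self.community_extinction_potential,
            "aggregation": self.aggregation,
            "pooled_pct": self.pooled_pct,
            "mean_pct": self.mean_pct,
            "n_species": self.n_species,
            "excluded_sources": sorted(s.value for s in self.excluded_sources),
            "species": [
                {
                    "species": r.species,
                    "absence_years": r.absence_years,
                    "presence_span": r.presence_span,
                    "absence_fraction": r.absence_fraction,
                }
                for r in self.species_results
            ],
        }


class TimelineBuild(NamedTuple):
    timelines: list[SpeciesTimeline]
    dropped_species: list[str]


def build_timelines(
    records: Sequence[OccurrenceRecord],
    end_year: int,
    excluded_sources: Collection[Source] = (),
) -> TimelineBuild:
    """Assemble per-species timelines, optionally excluding whole sources.

    Records from excluded sources are removed first; species left with no
    record at all are omitted from the timelines and returned in
    ``dropped_species`` (sorted) so the effect of the exclusion on the
    community denominator is always visible.

    Raises ``ValueError`` if any record year exceeds ``end_year`` — the
    survey horizon must close the series.
    """
    excluded = frozenset(excluded_sources)
    dated = [r for r in records if r.year is not None]
    too_late = [r for r in dated if r.year > end_year]
    if too_late:
        raise ValueError(
            f"end_year={end_year} earlier than record year {max(r.year for r in too_late)}"
        )
    all_species = {r.species for r in dated}
    years: dict[str, dict[Source, set[int]]] = defaultdict(lambda: defaultdict(set))
    for r in dated:
        if r.source not in excluded:
            years[r.species][r.source].add(r.year)

    timelines = []
    for sp in sorted(years):
        by_source = {s: tuple(sorted(ys)) for s, ys in years[sp].items() if ys}
        flat = [y for ys in by_source.values() for y in ys]
        timelines.append(
            SpeciesTimeline(
                species=sp,
                years_by_source=by_source,
                first_record=min(flat),
                last_occasion=max(flat),
                end_year=end_year,
            )
        )
    dropped = sorted(all_species - set(years))
    return TimelineBuild(timelines, dropped)


def pets_species(timeline: SpeciesTimeline) -> PetsSpeciesResult:
    """Absence fraction of one species under the PETS formula.

    The literal formula gives exactly 1.0 for a species whose only record
    year precedes the end year (first = last < end): its entire known history
    is absence. The nominal range is therefore [0, 1], closed at 1 by these
    single-record species; a warning marks them. A species whose only record
    year IS the end year has zero span and scores 0 (nothing is known to be
    absent).
    """
    absence = timeline.end_year - timeline.last_occasion
    span = timeline.end_year - timeline.first_record
    if span == 0:
        return PetsSpeciesResult(timeline.species, 0, 0, 0.0)
    fraction = absence / span
    if fraction == 1.0:
        warnings.warn(
            f"{timeline.species}: single historical record "
            f"({timeline.first_record}); absence fraction is exactly 1",
            stacklevel=2,
        )
    return PetsSpeciesResult(timeline.species, absence, span, fraction)


def _sorted_results(timelines: Iterable[SpeciesTimeline]) -> list[PetsSpeciesResult]:
    ordered = sorted(timelines, key=lambda t: (-t.last_occasion, t.species))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [pets_species(t) for t in ordered]


def pets_community(
    timelines: Sequence[SpeciesTimeline],
    aggregation: str = "pooled_ratio",
    excluded_sources: Collection[Source] = (),
) -> PetsCommunityResult:
    """Community extinction potential (percentage) over a set of timelines.

    pooled_ratio: 100 x sum(absence years) / sum(presence spans), i.e. the
    ratio of summed time-since-last-record to summed time-since-first-record.
    mean_of_ratios: 100 x mean of per-species absence fractions. The two
    coincide whenever all species share the same first-record year.

    Zero-span species (only record in the end year) contribute nothing to
    either numerator or denominator of the pooled ratio and a 0 to the mean.
    Raises ``ValueError`` if the list is empty or every span is zero.
    """
    if aggregation not in ("pooled_ratio", "mean_of_ratios"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if not timelines:
        raise ValueError("no timelines: community PETS undefined")
    results = _sorted_results(timelines)
    spans = np.array([r.presence_span for r in results])
    absences = np.array([r.absence_years for r in results])
    if spans.sum() == 0:
        raise ValueError("degenerate community: every species has zero presence span")
    pooled = 100.0 * absences.sum() / spans.sum()
    mean = 100.0 * float(np.mean([r.absence_fraction for r in results]))
    value = pooled if aggregation == "pooled_ratio" else mean
    return PetsCommunityResult(
        community_extinction_potential=value,
        aggregation=aggregation,
        pooled_pct=pooled,
        mean_pct=mean,
        species_results=tuple(results),
        n_species=len(results),
        excluded_sources=frozenset(excluded_sources),
    )


def species_last_seen_before(
    timelines: Iterable[SpeciesTimeline], cutoff: int
) -> list[tuple[str, int]]:
    """Species whose most recent record predates ``cutoff``.

    Returns (species, last_occasion) pairs sorted by last occasion ascending
    (oldest disappearances first), then name. The classic screen for
    local-extinction candidates needing targeted resurvey.
    """
    hits = [
        (t.species, t.last_occasion) for t in timelines if t.last_occasion < cutoff
    ]
    return sorted(hits, key=lambda x: (x[1], x[0]))


# ---------------------------------------------------------------------------
# Persistence / absence timeline matrix


@dataclass
class TimelineMatrix:
    """Species x year raster of record states plus per-species spans.

    ``states`` has one row per species (ordered by last occasion, most recent
    first) and one column per year from the overall first record to the end
    year. Cell values: ``no_record``, a single source value, ``multiple_sources``
    (records from >1 source that year) or ``year_assigned`` (every record in
    the cell carries the imputed-year flag). ``spans`` gives first/last/end
    per species: [first, last] is the persistence span, (last, end] the
    absence span; together they partition the species' whole axis.
    """

    states: pd.DataFrame
    spans: pd.DataFrame
    end_year: int

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    @property
    def years(self) -> list[int]:
        return list(self.states.columns)


def timeline_matrix(
    records: Sequence[OccurrenceRecord], end_year: int
) -> TimelineMatrix:
    """Build the persistence plot's underlying matrix from cleaned records."""
    timelines, _ = build_timelines(records, end_year)
    if not timelines:
        raise ValueError("no dated records: cannot build a timeline matrix")
    order = sorted(timelines, key=lambda t: (-t.last_occasion, t.species))
    first_overall = min(t.first_record for t in order)
    years = list(range(first_overall, end_year + 1))

    cell_records: dict[tuple[str, int], list[OccurrenceRecord]] = defaultdict(list)
    for r in records:
        if r.year is not None:
            cell_records[(r.species, r.year)].append(r)

    states = pd.DataFrame(
        NO_RECORD, index=[t.species for t in order], columns=years, dtype=object
    )
    for (sp, year), rs in cell_records.items():
        if all(r.year_assigned for r in rs):
            state = YEAR_ASSIGNED
        else:
            sources = {r.source for r in rs}
            state = MULTIPLE_SOURCES if len(sources) > 1 else next(iter(sources)).value
        states.at[sp, year] = state

    spans = pd.DataFrame(
        {
            "first_record": [t.first_record for t in order],
            "last_occasion": [t.last_occasion for t in order],
            "end_year": end_year,
        },
        index=[t.species for t in order],
    )
    return TimelineMatrix(states=states, spans=spans, end_year=end_year)


_STATE_COLOURS = {
    NO_RECORD: "#ffffff",
    Source.CITIZEN_SCIENCE.value: "#d62728",
    Source.LITERATURE.value: "#2ca02c",
    Source.SAMPLING.value: "#1f77b4",
    YEAR_ASSIGNED: "#7f7f7f",
    MULTIPLE_SOURCES: "#9467bd",
}


def plot_timeline(matrix: TimelineMatrix, path: str, dpi: int = 150) -> None:
    """Render the matrix as a species x year raster with span shading.

    Light green shading marks each species' persistence span (first to last
    record), pink the absence span (last record to end year); squares mark
    record years coloured by source.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    species = matrix.species
    years = matrix.years
    n_sp, n_yr = len(species), len(years)
    fig, ax = plt.subplots(figsize=(max(6.0, n_yr / 18), max(3.0, n_sp / 7)))
    y0 = years[0]
    for i, sp in enumerate(species):
        row = matrix.spans.loc[sp]
        ax.barh(i, row.last_occasion - row.first_record, left=row.first_record,
                height=0.8, color="#d9f2d9", zorder=1)
        ax.barh(i, matrix.end_year - row.last_occasion, left=row.last_occasion,
                height=0.8, color="#fadadd", zorder=1)
    arr = matrix.states.to_numpy()
    for state, colour in _STATE_COLOURS.items():
        if state == NO_RECORD:
            continue
        ii, jj = np.nonzero(arr == state)
        ax.scatter(np.asarray(years)[jj], ii, marker="s", s=8, color=colour,
                   zorder=2, label=state.replace("_", " "))
    ax.set_yticks(range(n_sp))
    ax.set_yticklabels(species, fontsize=4)
    ax.invert_yaxis()
    ax.set_xlim(y0 - 1, matrix.end_year + 1)
    ax.set_xlabel("year")
    handles = [Patch(color="#d9f2d9", label="persistence"),
               Patch(color="#fadadd", label="absence")]
    ax.legend(handles=handles + ax.get_legend_handles_labels()[0],
              fontsize=5, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
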