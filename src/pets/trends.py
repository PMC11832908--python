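"""Yearly aggregation tables and period breakdowns of cleaned records.

These tables are the stable inputs to downstream trend models (e.g. GAM
smooths of records and richness over years by source); the model fitting
itself is deliberately out of scope here — this module guarantees only
reproducible, fully dense input tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import OccurrenceRecord, Source

__all__ = ["yearly_table", "PeriodSplit", "period_split"]


def yearly_table(records: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    """Per (year, source): record count, species richness, year-assigned count.

    The table is dense over the full cartesian product of the observed global
    year range and the three sources — absent combinations appear with zeros
    — so smoothers see the true shape of effort (including its gaps) rather
    than only the years a source happened to be active.

    Columns: year, source, n_records, n_species, n_year_assigned.
    """
    dated = [r for r in records if r.year is not None]
    if not dated:
        return pd.DataFrame(
            columns=["year", "source", "n_records", "n_species", "n_year_assigned"]
        )
    df = pd.DataFrame(
        {
            "year": [r.year for r in dated],
            "source": [r.source.value for r in dated],
            "species": [r.species for r in dated],
            "year_assigned": [r.year_assigned for r in dated],
        }
    )
    grouped = (
        df.groupby(["year", "source"])
        .agg(
            n_records=("species", "size"),
            n_species=("species", "nunique"),
            n_year_assigned=("year_assigned", "sum"),
        )
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [range(df["year"].min(), df["year"].max() + 1), [s.value for s in Source]],
        names=["year", "source"],
    )
    dense = (
        grouped.set_index(["year", "source"])
        .reindex(full, fill_value=0)
        .reset_index()
        .astype({"n_records": int, "n_species": int, "n_year_assigned": int})
    )
    return dense


@dataclass
class PeriodSplit:
    """Record counts before/after a split year, with source shares of "after".

    ``before`` is strictly earlier than ``split_year``; the split year itself
    falls in ``after`` (configurable upstream by passing ``split_year + 1``).
    ``after_by_source`` maps source -> (count, percentage of the after block,
    year-assigned sub-count); ``before_by_source`` likewise against the
    before block.
    """

    split_year: int
    n_before: int
    n_after: int
    pct_before: float
    pct_after: float
    before_by_source: dict[str, tuple[int, float, int]]
    after_by_source: dict[str, tuple[int, float, int]]

    def as_dict(self) -> dict:
        def expand(block: dict[str, tuple[int, float, int]]) -> dict:
            return {
                s: {"count": c, "pct": p, "n_year_assigned": ya}
                for s, (c, p, ya) in block.items()
            }

        return {
            "split_year": self.split_year,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "pct_before": self.pct_before,
            "pct_after": self.pct_after,
            "before_by_source": expand(self.before_by_source),
            "after_by_source": expand(self.after_by_source),
        }


def period_split(records: Sequence[OccurrenceRecord], split_year: int) -> PeriodSplit:
    """Partition cleaned records at a split year and tally source shares."""
    dated = [r for r in records if r.year is not None]
    before = [r for r in dated if r.year < split_year]
    after = [r for r in dated if r.year >= split_year]
    total = len(dated)

    def block(rs: list[OccurrenceRecord]) -> dict[str, tuple[int, float, int]]:
        out = {}
        for s in Source:
            sub = [r for r in rs if r.source is s]
            pct = 100.0 * len(sub) / len(rs) if rs else 0.0
            out[s.value] = (len(sub), pct, sum(r.year_assigned for r in sub))
        return out

    return PeriodSplit(
        split_year=split_year,
        n_before=len(before),
        n_after=len(after),
        pct_before=100.0 * len(before) / total if total else 0.0,
        pct_after=100.0 * len(after) / total if total else 0.0,
        before_by_source=block(before),
        after_by_source=block(after),
    )
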