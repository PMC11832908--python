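"""Per-species and community PETS, screens and the timeline matrix."""

from fractions import Fraction

import numpy as np
import pytest

from pets import (
    OccurrenceRecord,
    Source,
    SpeciesTimeline,
    build_timelines,
    pets_community,
    pets_species,
    species_last_seen_before,
    timeline_matrix,
)
from pets.core import MULTIPLE_SOURCES, NO_RECORD, YEAR_ASSIGNED

END = 2022


def _tl(species, years, end=END, source=Source.LITERATURE):
    return SpeciesTimeline(
        species=species,
        years_by_source={source: tuple(sorted(years))},
        first_record=min(years),
        last_occasion=max(years),
        end_year=end,
    )


def _rec(species, year, source=Source.LITERATURE, flag=False):
    return OccurrenceRecord(species, year, source, year_assigned=flag)


# The ten species of the study region whose last records predate 1996,
# with their printed first/last observation years (survey horizon 2022).
PRE_1996_SPECIES = [
    ("Polygonia egea", 1909, 1909),
    ("Coenonympha glycerion", 1950, 1950),
    ("Araschnia levana", 1956, 1956),
    ("Erebia eriphyle", 1968, 1986),
    ("Argynnis pandora", 1825, 1996),
    ("Leptidea juvernica", 1984, 1996),
    ("Limenitis camilla", 1898, 1996),
    ("Lycaeides argyrognomon", 1908, 1996),
    ("Pyronia tithonus", 1950, 1996),
    ("Thecla betulae", 1921, 1996),
]


class TestSpeciesFormula:
    @pytest.mark.parametrize("species,first,last", PRE_1996_SPECIES)
    def test_absence_fraction_matches_min_max_oracle(self, species, first, last):
        """The formula on first/last years equals the brute-force ratio of
        year-list extremes, in exact rational arithmetic."""
        years = sorted({first, last, (first + last) // 2} | {first})
        years = [y for y in years if first <= y <= last]
        result = pets_species(_tl(species, years))
        # independent oracle: plain min/max over the raw year list
        oracle = Fraction(END - max(years), END - min(years))
        assert Fraction(result.absence_years, result.presence_span) == oracle
        assert result.absence_fraction == pytest.approx(float(oracle))

    def test_erebia_eriphyle_is_36_over_54(self):
        result = pets_species(_tl("Erebia eriphyle", [1968, 1986]))
        assert (result.absence_years, result.presence_span) == (36, 54)
        assert result.absence_fraction == pytest.approx(36 / 54)

    def test_seen_in_end_year_scores_zero(self):
        assert pets_species(_tl("X x", [1900, END])).absence_fraction == 0.0

    def test_zero_iff_last_record_in_end_year(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            years = sorted(rng.choice(np.arange(1825, END + 1), 3, replace=False))
            frac = pets_species(_tl("X x", list(years))).absence_fraction
            assert (frac == 0.0) == (max(years) == END)

    def test_single_historical_record_scores_one_with_warning(self):
        with pytest.warns(UserWarning, match="single historical record"):
            result = pets_species(_tl("Polygonia egea", [1909]))
        assert result.absence_fraction == 1.0

    def test_only_record_in_end_year_has_zero_span_and_zero_fraction(self):
        result = pets_species(_tl("X x", [END]))
        assert result.presence_span == 0 and result.absence_fraction == 0.0


class TestBuildTimelines:
    def test_first_and_last_from_all_sources(self):
        records = [_rec("A a", 2000), _rec("A a", END, Source.CITIZEN_SCIENCE)]
        (tl,), dropped = build_timelines(records, END)
        assert (tl.first_record, tl.last_occasion) == (2000, END)
        assert dropped == []

    def test_exclusion_drops_species_only_in_that_source(self):
        records = [
            _rec("A a", 2010, Source.CITIZEN_SCIENCE),
            _rec("B b", 2010, Source.LITERATURE),
        ]
        timelines, dropped = build_timelines(
            records, END, {Source.CITIZEN_SCIENCE}
        )
        assert [t.species for t in timelines] == ["B b"]
        assert dropped == ["A a"]

    def test_end_year_before_record_year_is_hard_error(self):
        with pytest.raises(ValueError, match="end_year"):
            build_timelines([_rec("A a", 2010)], 2005)

    def test_exclusion_never_moves_fractions_down(self):
        """Removing a source can only shrink a retained species' record set,
        so its absence fraction never decreases."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            records = []
            for sp in ["A a", "B b", "C c"]:
                for src in Source:
                    for y in rng.choice(np.arange(1900, END + 1), rng.integers(0, 5)):
                        records.append(_rec(sp, int(y), src))
            if not records:
                continue
            before = {
                t.species: pets_species(t).absence_fraction
                for t in build_timelines(records, END).timelines
            }
            excl = Source(rng.choice([s.value for s in Source]))
            after = {
                t.species: pets_species(t).absence_fraction
                for t in build_timelines(records, END, {excl}).timelines
            }
            for sp, frac in after.items():
                assert frac >= before[sp]


class TestCommunity:
    def test_hand_worked_pooled_and_mean(self):
        # A: 2000-2022 (absence 0/22), B: 2000-2011 (absence 11/22)
        tls = [_tl("A a", [2000, END]), _tl("B b", [2000, 2011])]
        result = pets_community(tls)
        assert result.pooled_pct == pytest.approx(100 * 11 / 44)
        # equal first records -> equal denominators -> aggregations coincide
        assert result.mean_pct == pytest.approx(result.pooled_pct)

    def test_all_present_in_end_year_scores_zero(self):
        tls = [_tl("A a", [1900, END]), _tl("B b", [1950, END])]
        assert pets_community(tls).community_extinction_potential == 0.0

    def test_value_within_species_fraction_range(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tls = [
                _tl(f"S {i:02d} x", sorted(rng.choice(np.arange(1850, END + 1), 2, replace=False)))
                for i in range(rng.integers(2, 8))
            ]
            result = pets_community(tls)
            fracs = [r.absence_fraction for r in result.species_results]
            assert 100 * min(fracs) - 1e-9 <= result.pooled_pct <= 100 * max(fracs) + 1e-9

    def test_species_sorted_by_last_occasion_desc_then_name(self):
        tls = [
            _tl("B b", [1950, 2000]),
            _tl("A a", [1950, 2000]),
            _tl("C c", [1950, END]),
        ]
        result = pets_community(tls)
        assert [r.species for r in result.species_results] == ["C c", "A a", "B b"]

    def test_degenerate_community_is_hard_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            pets_community([_tl("A a", [END])])
        with pytest.raises(ValueError, match="no timelines"):
            pets_community([])

    def test_unknown_aggregation_rejected(self):
        with pytest.raises(ValueError, match="aggregation"):
            pets_community([_tl("A a", [1900, END])], "median")


class TestLastSeenBefore:
    def test_cutoff_below_first_record_is_empty(self):
        assert species_last_seen_before([_tl("A a", [1900, 1950])], 1800) == []

    def test_sorted_ascending_by_last_then_name(self):
        tls = [
            _tl("B b", [1900, 1950]),
            _tl("A a", [1900, 1950]),
            _tl("C c", [1900, 1920]),
            _tl("D d", [1900, END]),
        ]
        assert species_last_seen_before(tls, 1996) == [
            ("C c", 1920),
            ("A a", 1950),
            ("B b", 1950),
        ]


class TestTimelineMatrix:
    def test_single_source_cells_and_span_partition(self):
        records = [_rec("A a", 2010), _rec("A a", 2012)]
        m = timeline_matrix(records, END)
        assert m.states.loc["A a", 2010] == Source.LITERATURE.value
        assert m.states.loc["A a", 2011] == NO_RECORD
        row = m.spans.loc["A a"]
        assert (row.first_record, row.last_occasion, row.end_year) == (2010, 2012, END)

    def test_two_sources_in_one_year_marked_plural(self):
        records = [
            _rec("A a", 2015, Source.CITIZEN_SCIENCE),
            _rec("A a", 2015, Source.SAMPLING),
        ]
        m = timeline_matrix(records, END)
        assert m.states.loc["A a", 2015] == MULTIPLE_SOURCES

    def test_year_assigned_only_when_every_record_flagged(self):
        records = [
            _rec("A a", 1900, flag=True),
            _rec("B b", 1900, flag=True),
            _rec("B b", 1900, flag=False),
        ]
        m = timeline_matrix(records, END)
        assert m.states.loc["A a", 1900] == YEAR_ASSIGNED
        assert m.states.loc["B b", 1900] == Source.LITERATURE.value

    def test_every_record_year_maps_to_a_nonempty_cell(self, preset_cleaned):
        cleaned, _ = preset_cleaned
        m = timeline_matrix(cleaned, END)
        for r in cleaned:
            assert m.states.loc[r.species, r.year] != NO_RECORD

    def test_row_order_is_descending_last_occasion(self, preset_cleaned):
        cleaned, _ = preset_cleaned
        m = timeline_matrix(cleaned, END)
        last = m.spans["last_occasion"].to_numpy()
        assert all(last[:-1] >= last[1:])
        # sort oracle: same order as sorting the span table directly
        oracle = (
            m.spans.reset_index()
            .sort_values(["last_occasion", "index"], ascending=[False, True])["index"]
            .tolist()
        )
        assert m.species == oracle
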