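# Methods

## The model

The package treats a regional occurrence database as a set of dated,
sourced, optionally georeferenced records and asks, per species, how long it
has gone unobserved relative to how long it has been known. With integer
record years, first record *y*₍f₎, last record *y*₍l₎ and final survey year
*Y*:

    absence_fraction = (Y − y_l) / (Y − y_f).

Assumptions worth stating explicitly:

- **Years are atomic.** No within-year dating; a record year is an integer
  and spans are year differences. Two records in the same year are
  indistinguishable in time.
- **The survey horizon closes the series.** *Y* is a parameter, not data: it
  must be at least the latest record year (enforced) and should be the year
  recording effectively stopped. For historical reproduction it must be
  given explicitly; the CLI requires it.
- **Absence of records is the signal.** The statistic conflates
  non-occurrence with non-detection; it is an upper bound on "observed
  persistence", not an extinction probability. The synthetic recovery tests
  quantify exactly this: the estimated fraction is provably ≥ the true
  absence fraction, with equality under certain detection.

Edge cases and their resolutions:

- A species whose only record year equals *Y* has zero span; its fraction is
  defined as 0 (nothing is known to be absent).
- A species with a single record year before *Y* gets the literal formula
  value 1.0. The statistic's nominal range is therefore the closed [0, 1],
  attained at 1 only by such single-historical-record species; the
  implementation emits a warning rather than offsetting the denominator or
  clamping, so these species are visible rather than silently regularised.

## Community aggregation

Two aggregations are always computed:

- **pooled_ratio** (default): 100 × Σ absence / Σ span — the ratio of the
  summed absence-bar lengths to the summed full-bar lengths on the
  persistence plot. Long-known species weigh more; this matches the
  "ratio of summed line lengths" reading of the community value.
- **mean_of_ratios**: 100 × mean of per-species fractions — each species
  weighs equally; this is the aggregation implicit when per-species values
  feed a regression.

They coincide exactly when all species share a first-record year (equal
denominators), which the test suite uses as a cross-check. The headline
value reports the requested aggregation; both are always in the output.

## Source exclusion

Excluding a source removes its records before timelines are built. A
species left with no records is **dropped from the community** — the
formula needs a first record within the retained data — and the dropped
list is always reported so the alternative convention (assign fraction 1)
can be evaluated from the output. For retained species, removal can only
shrink the record set, so per-species fractions never decrease (a tested
invariant); community values therefore typically rise when a recent
high-volume source is excluded.

## Cleaning rules

Records without a year are dropped and counted (they cannot enter any
year-based statistic). Years outside [1700, *Y*] are rejected as
implausible, counted separately. Retained but non-georeferenced records
participate in every analysis except gridding. Imputed-year records
("year assigned" from a publication year) participate everywhere, carrying
only a flag; the timeline raster marks a species-year cell as year-assigned
only when *every* record in it is flagged. Species names match exactly
after whitespace collapsing and case normalisation — no fuzzy synonymy,
because the intended inputs follow fixed regional checklists. Cleaning is
idempotent and never hard-fails; all pathologies become counters in the
report, which also exposes both the distinct-record-year count and the
min–max span (two readings of "years covered" that diverge sharply for
sparse historical series).

## Gridding

Georeferenced records are projected from decimal degrees to a metric plane
and binned into half-open square cells ([x₀+is, x₀+(i+1)s) × …), so every
point has exactly one cell and a point on a shared edge belongs to the cell
it lower-bounds. The default projection is UTM zone 32N (covering NW
Italy, the kind of region the default scenario emulates); any UTM zone or a
pre-projected "planar" passthrough can be configured. The transverse
Mercator conversion is implemented in-package as the 6th-order Krüger
series in the third flattening; within a zone its truncation error is far
below a millimetre and the test suite checks it against an independently
coded USGS/Snyder-series oracle and nanodegree-level round-trips.
Coordinates more than 15° from the zone meridian or beyond ±84° latitude
are flagged out-of-domain and counted, not silently projected. Coarse-
resolution records are binned at their stated representative coordinates;
no dasymetric spreading. The region denominator for occupancy percentages
is an explicit cell mask when supplied, otherwise the union of occupied
cells — with opportunistic sources covering essentially the whole recorded
region, the union is a serviceable stand-in for a region mask.

## Trend tables

The yearly table is dense: every (year, source) pair in the global year
range appears, with zeros where a source was inactive, so downstream
smoothers see the true effort profile including its gaps. The period split
uses a strict-less convention ("before" = year < split year); the boundary
year sits in "after", and the opposite convention is one parameter away
(`split_year + 1`). Richness ≤ records per row, per-source totals equal
the cleaning report's, and before + after = total for any split — all
tested invariants. GAM/GLMM fitting on these tables is explicitly out of
scope; the guarantee is bit-stable inputs.

## The synthetic generator

The generator is a virtual-ecologist simulator: species with known
colonization year, true extinction year (or extant) and detectability in
[0, 1] are observed by three effort regimes, and record counts per
(species, year, source) are Poisson with mean effort(year) × detectability.
What it emulates:

- **literature & collections**: active through the whole series, base
  effort oscillating sinusoidally (collecting fashions), declining linearly
  after 1990 to a floor — so historical-only species get their last records
  from this source;
- **citizen science**: zero before an onset year (default 2000), then
  geometric growth (default ×1.3/yr) — recent, massive, region-wide;
- **sampling**: zero before 2000, constant thereafter, with records
  discarded outside a spatial sub-window — structured monitoring confined
  to a protected area.

Coordinates are isotropic normal draws around a per-species centre
(default spread 8 km), clipped to the region rectangle; the region is
specified in decimal degrees so generated tables carry the same coordinate
format as real ones and exercise the projection path. Resolution classes
are assigned by era (pre-1950 → 10 km, 1950–1999 → 3 km, later → 1 km),
mimicking how georeferencing precision improves over time; a fraction
(default 8%) of pre-1980 literature records carry the imputed-year flag.
Generation is deterministic for a fixed seed, byte-identical across runs.

The bundled preset (`default_scenario`) is a two-century scenario — 170
species, years 1825–2022, ten true extinctions spread over 1905–1992 plus
six later losses, 80% of species present from the start and the rest
colonising (or first becoming recordable) up to 2000, detectabilities
0.05 + 0.9·Beta(2,4). Effort constants were chosen analytically so the
generated volume lands in the regime where such analyses operate in
practice: a few tens of thousands of records with citizen science
contributing roughly half, literature about a quarter, and sampling the
rest, concentrated in ~40% of the region. Typical realisations give
~26 000 records and a pooled community extinction potential near 3%,
roughly doubling when the citizen-science source is excluded.

What the generator does **not** model — and hence what passing tests do not
show about real data: within-year phenology, observer home ranges and site
fidelity, spatially varying detectability, taxonomic drift and
misidentification, coordinate obfuscation buffers, and trait-driven
detection differences. Recovery results on synthetic data demonstrate the
statistic's behaviour under known truth, not the accuracy of any real-world
extinction claim.

## Numerical and design choices

- Spans and absence years are exact integers; fractions are formed only at
  output. The acceptance-level formula checks are done in rational
  arithmetic.
- Sorting ties (equal last record) break alphabetically for reproducible
  output everywhere a species ordering is emitted.
- The counting distribution for record draws is Poisson; any distribution
  with the stated mean would honour the generator's contract, Poisson being
  the natural effort-count model.
- Problem sizes in the test suite (preset of 170 species × 198 years,
  10⁴-point grid oracles, 10³ random communities, 500-replicate effort
  scaling) were chosen as the smallest sizes at which the properties under
  test are non-trivial; the full suite runs in well under a minute.

## Known limitations

- PETS ignores record density between the first and last year; a species
  with one record in 1825 and one in 2020 scores almost 0.
- The community value is sensitive to the species-dropping convention under
  source exclusion (documented above; the dropped list is always reported).
- Grid occupancy with a derived (data-union) denominator is not comparable
  across datasets with different extents; supply a region mask for that.
- The UTM implementation targets in-zone use; cross-zone datasets should be
  projected upstream or gridded per zone.
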