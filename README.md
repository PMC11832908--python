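# pets — sightings-based local-extinction screening for occurrence records

Regional biodiversity databases are stitched together from very different
recording regimes: historical faunistic literature and museum collections,
opportunistic citizen-science portals, and structured expert sampling. For
many taxa (butterflies are the classic case) such a database is the only
evidence available to ask *which species may have quietly disappeared from a
region* — and how much the answer depends on which sources you trust.

This package implements that analysis end to end for conservation
ecologists and biodiversity informaticians:

- **ingestion & cleaning** of delimited occurrence tables from multiple
  source categories, with configurable column dialects, year-bounds
  validation, imputed-year flagging and a full accounting report;
- **the PETS index** (Potential Extinction upon Time Series) per species and
  for the whole community, with source-exclusion sensitivity analysis;
- **persistence/absence timelines** (species × year rasters, renderable as
  figures);
- **10 km grid occupancy** per source on a UTM plane, quantifying each
  regime's spatial coverage;
- **yearly trend tables** (records and species richness per year and
  source) ready for downstream smoothers — the model fitting itself is
  deliberately out of scope;
- a **synthetic multi-source generator** with known ground truth (true
  extinction years, effort regimes, detectabilities), so the whole pipeline
  is testable without any real dataset.

## The statistic

For a species with first record year *y*₍f₎, most recent record year *y*₍l₎
and a final survey year *Y*:

```
absence_fraction = (Y − y_l) / (Y − y_f)
```

the fraction of the species' known regional history during which it has gone
unobserved — 0 for a species seen in the final year, approaching 1 for one
unseen since shortly after its discovery (exactly 1 for a single historical
record). The community extinction potential pools the spans:

```
PETS_community = 100 × Σᵢ (Y − y_l,i) / Σᵢ (Y − y_f,i)   [%]
```

(a mean-of-ratios aggregation is also computed). Re-running with a recent
high-volume source excluded — typically citizen science — shows how strongly
that source's recent confirmations suppress apparent extinction. PETS flags
local-extinction candidates for targeted resurvey; it does not prove
extinction.

## Worked example

Simulate a two-century, 170-species community observed by three effort
regimes (oscillating-then-declining literature, post-2000 exponential
citizen science, post-2000 spatially restricted sampling, ten true
extinctions before 1996), then analyse it:

```sh
$ pets simulate --seed 7 --out sim
26955 records for 170 species

$ pets compute sim/records.csv --end-year 2022 --out out_all
community extinction potential: 2.77% (pooled_ratio, 170 species)

$ pets compute sim/records.csv --end-year 2022 \
      --exclude-source citizen_science --out out_nocs
community extinction potential: 5.21% (pooled_ratio, 170 species, excluding ['citizen_science'])

$ pets grid sim/records.csv --out out_grid
literature_collections: 65/65 cells (100.0%)
citizen_science: 65/65 cells (100.0%)
sampling: 24/65 cells (36.9%)

$ pets trends sim/records.csv --split-year 2005 --out out_trends
before 2005: 8031 (29.8%), after: 18924 (70.2%)
```

Reading the numbers: with all sources pooled, 2.77% of the community's
summed known history is unobserved time — a community whose species are
mostly reconfirmed recently. Dropping the citizen-science records nearly
doubles the apparent extinction potential (5.21%): recent opportunistic
records carry most of the power to reconfirm present-day persistence.
The grid report quantifies the complementary spatial story — structured
sampling touches ~37% of occupied cells versus 100% for the opportunistic
sources. Each command also writes machine-readable outputs
(`pets.json`, `species_table.csv`, `timeline_matrix.csv`, `cells.geojson`,
`yearly.csv`, …) into its `--out` directory; add `--plot` to `pets compute`
for the persistence/absence raster.

The same functions are importable directly (`pets.read_occurrences`,
`pets.clean_records`, `pets.build_timelines`, `pets.pets_community`,
`pets.occupancy_by_source`, `pets.yearly_table`, `pets.generate`, …); see
`docs/methods.md` for the model and design notes.

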