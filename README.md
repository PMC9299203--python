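# ventassess

Rapid IUCN Red List assessment for species endemic to insular habitat
patches — built for deep-sea hydrothermal vent faunas, where only geographic
range and regulatory context are knowable, and applicable to analogous
systems (karst towers, isolated springs) with the same key features: tiny
habitat patches, endemic species with limited inter-patch mobility, and a
threat that would eradicate all local habitat.

## The problem

Vent-endemic species are understudied: there are no population sizes or
trends, so the population-based Red List criteria (A, C, D1) and the
quantitative-analysis criterion (E) cannot be applied. What *is* known is
where a species occurs and who regulates the seabed there. That is exactly
what the geographic-range criteria need:

* **Criterion B** — a threatened tier requires a small extent of occurrence
  (B1: EOO < 100 / 5,000 / 20,000 km² for CR / EN / VU) or area of occupancy
  (B2: AOO < 10 / 500 / 2,000 km²), **plus** at least two of: (a) few
  locations (≤ 1 / 5 / 10), (b) continuing decline, (c) extreme
  fluctuations. Condition (c) is not relevant for vent species, so (a) and
  (b) are both required.
* **Criterion D2** — VU when the range is very restricted (AOO < 20 km² or
  ≤ 5 locations) and a plausible future threat could rapidly drive the
  species to CR or extinction.

The package operationalises the remaining judgement calls:

* A **location** is the set of vent fields inside one management area and
  chained within 80 km of each other — the precautionary bound on how far a
  mining event plus its sediment plume could reach. The threshold is
  configurable for regional sediment/depth/current conditions.
* **AOO** is the occupied-cell count of a 2 × 2 km grid times 4 km²; **EOO**
  is the minimum convex polygon area (equal-area projection), floored at
  the AOO.
* **Continuing decline** and **plausible threat** are read off the mining
  regulation of each location's management area: an exploration contract or
  active extraction implies a projected decline; anything short of an
  enacted mining prohibition leaves the threat plausible; active mining
  across the entire range means CR (possibly extinct).

Scenario analysis recomputes an assessment under hypothetical regulatory
changes (protection enacted, license granted, mining commencing), and the
**location-threat matrix** tabulates the category the engine assigns for
every combination of location-count band (1, 2–5, 6–10, >10) and regime —
a preliminary gauge of assessment outcomes for unassessed species.

## Worked example

Three Manus Basin vent fields within 80 km of each other, all inside one
management area under an exploration-phase mining contract:

```python
import ventassess as va

cs = va.case_study("B_manusensis")
a = va.assess_species(list(cs.fields), cs.regimes, species_id=cs.species_id)
print(a.to_text())
```

```
Category: EN
Criteria: B1ab(iii)+2ab(iii)
Range: 3 field(s), 1 location(s), AOO 12 km², EOO 178.723 km²
Rationale:
  - criterion B1 met at EN: a: n_locations=1 ≤ 5; b(iii): projected continuing decline in habitat extent/quality
  - criterion B2 met at EN: a: n_locations=1 ≤ 5; b(iii): projected continuing decline in habitat extent/quality
```

The three fields collapse into a single location (all within 80 km, one
jurisdiction) with an AOO of 12 km² (three occupied grid cells). Both range
metrics exceed the CR bounds (EOO > 100 km², AOO > 10 km²), so despite the
single threatened location the species is EN, not CR — small-range species
are not automatically pushed to the top category. To use a published EOO
verbatim instead of recomputing it from coordinates, build a
`RangeMetrics` and call `va.assess_from_metrics`.

The same pipeline is scriptable from the shell:

```sh
ventassess fixtures --out fixtures/
ventassess assess --occurrences fixtures/occurrences.csv \
                  --regimes fixtures/regimes.csv --out assessed/
ventassess matrix --out matrix/
```

`assess` writes one JSON report per species plus a `summary.csv`;
`matrix` writes the location-threat grid with provenance tags;
`scenario` and `simulate` cover regulatory what-ifs and synthetic
ridge-system generation.

## Layout

| module | contents |
| --- | --- |
| `ventassess.geo` | geodesic distance, location clustering, AOO, EOO |
| `ventassess.threats` | regulatory regimes → decline / plausible-threat flags |
| `ventassess.engine` | criteria B1/B2/D2, category assignment, criteria strings |
| `ventassess.assessment` | end-to-end pipeline, worst-case category |
| `ventassess.scenarios` | scenario transitions, location-threat matrix |
| `ventassess.synthetic` | ridge-system generator with constructive ground truth |
| `ventassess.fixtures` | curated case-study bundles |
| `ventassess.io`, `ventassess.cli` | CSV/GeoJSON/JSON formats and the CLI |

See `docs/methods.md` for the full account of the procedure, its
assumptions and its limitations.
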