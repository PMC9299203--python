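# Methods

## Scope and model of the assessment

The package assesses extinction risk for species whose entire known range
consists of small, discrete habitat patches (vent fields, each < 0.1 km²)
threatened by a single dominant process — seabed mineral extraction — whose
anticipated local impact is destruction of all habitat. Under these
conditions the assessment reduces to geographic range plus regulatory
context, and only the range-based criteria are evaluated:

* **B1** (extent of occurrence), **B2** (area of occupancy), each gated by
  condition (a) (number of locations) and condition (b(iii)) (continuing
  decline in habitat extent/quality). Condition (c), extreme fluctuations,
  does not apply to sessile or low-mobility patch endemics and is never
  used; a threatened tier under B therefore always requires (a) and (b)
  together.
* **D2**: VU for a very restricted range (AOO < 20 km² or ≤ 5 locations)
  with a plausible threat that would rapidly lead to CR or extinction.

Population-based criteria (A, C, D1) and quantitative extinction analysis
(E) are out of scope: no abundance or trend data exist for these faunas,
and mining timelines are too uncertain to model extinction probability.

## Locations

A location is a set of occurrence sites that one threatening event can
destroy at once. Operationally: sites in the same management area,
connected under single-linkage at a geodesic threshold of **80 km**
(default `GeoConfig.threshold_km`). The figure is precautionary — sediment
plumes from mining have been projected to reach ~70 km — and is exposed as
configuration because plume spread varies with sediment characteristics,
depth and current strength.

Design choices:

* **Single-linkage (chains allowed).** "Within 80 km of each other" could
  be read pairwise-complete or as chain connectivity. Chaining is the
  precautionary reading: an event plus plume can propagate along a ridge
  segment, producing fewer, larger locations, which raises assessed risk
  (fewer locations ⇒ stricter condition (a) tiers reached).
* **Boundary**: a gap of exactly the threshold separates; strictly smaller
  merges ("a minimum threshold to separate").
* **Ordering**: locations are sorted by smallest member site id and
  numbered `L001…`, so outputs are deterministic.
* Distances are haversine on a sphere of mean radius 6371.0088 km. At the
  80-km decision scale the maximal ellipsoidal correction (~0.5%) is far
  inside the threshold's own uncertainty.

## Area of occupancy

AOO = (number of occupied 2 × 2 km grid cells) × 4 km². Sites are projected
to a local spherical transverse-Mercator plane centred on the species
centroid and snapped to a `cell_km` grid. The grid is **anchored at the
point set's minimum projected coordinate**: the standard rule that several
sites inside one cell width count as a single 4 km² cell must hold
regardless of where the range sits, and a fixed-origin grid can split a
sub-cell-width pair across a boundary (any two sites closer than one cell
edge are guaranteed co-celled under minimum anchoring). Sites with
identical coordinates remain distinct occurrence records but occupy one
cell.

## Extent of occurrence

EOO is the area of the minimum convex polygon over all sites, computed in
a Lambert azimuthal equal-area projection about the site centroid (ranges
handled here span well under ~4,000 km, where the projection's area
distortion is negligible for hull purposes). Longitudes are re-centred on
the circular-mean longitude before projection, so antimeridian-spanning
ranges produce compact hulls. Degenerate hulls (one site, collinear sites)
have zero planar area; EOO is always **floored at the AOO**, following the
standard convention that the extent of occurrence cannot be smaller than
the occupied area — without the floor, single-patch species would have an
undefined B1 input.

## Threat derivation

Each management area carries one of four regimes, in increasing severity:

| regime | meaning |
| --- | --- |
| `PROTECTED_EFFECTIVE` | MPA with a specific mining prohibition, treaty protection, or an *enacted* moratorium |
| `UNPROTECTED_NO_LICENSE` | no moratorium, no license granted |
| `EXPLORATION_LICENSE` | exploratory contract signed (or exploitation licensed but not begun) |
| `ACTIVE_MINING` | commercial extraction under way |

Flags are derived per species: *continuing decline* iff any location is
licensed or mined (exploratory activity may already have had an effect);
*plausible future threat* iff any location lacks effective protection;
*all range destroyed* iff every location is under active extraction. A
proposed but unratified moratorium confers nothing — only enacted
regulation that specifically prevents seabed mining counts as effective,
and a generic MPA without a mining ban must be encoded as
`UNPROTECTED_NO_LICENSE`.

## Category assignment

The category is the highest tier reached by B1, B2 or D2. D2's "rapidly
lead to CR or EX" condition is operationalised through the **worst-case
category**: the category criterion B would assign were every location
licensed (decline everywhere). D2 fires only when that worst case is CR;
a worst case of EN is a near-miss expressed as NT.

When no criterion fires: **LC** iff every location is effectively
protected; **NT** otherwise — this covers mixed protected/unprotected
ranges, unprotected ranges too large or too multi-location for any bound,
and the worst-case-EN near-miss. Consequently no species with a licensed
or mined location is ever LC, and a fully protected species always is.

One rule sits above the criteria: `ACTIVE_MINING` at **every** location
yields **CR (possibly extinct)** regardless of the tier reached —
commercial extraction is anticipated to remove all local habitat, so a
species whose entire range is being mined is likely already extinct
pending confirmation. For ranges with more than 10 locations no B tier can
fire, so such a cell carries the possibly-extinct tag with an empty
criteria string; everywhere else the fired criteria are reported at their
own tiers. Criteria strings follow the published convention
(`B1ab(iii)+2ab(iii)`, `D2`; B before D, B1 before B2, identical condition
sets merged with `+`). Decline from mining is recorded as b(iii) — decline
in habitat extent/quality — since mining destroys habitat. An empty
occurrence set yields DD.

Default thresholds (`ThresholdTable`) are the IUCN v3.1 standard bounds:
B1 EOO 100 / 5,000 / 20,000 km²; B2 AOO 10 / 500 / 2,000 km²; locations
1 / 5 / 10 (CR / EN / VU); D2 AOO < 20 km² or ≤ 5 locations. All are
configuration, not constants in code.

## Scenarios and the location-threat matrix

`apply_scenario` recomputes an assessment under per-area regime overrides
and reports the transition. Downlistings are flagged as subject to the
five-year rule (no higher-category criterion met for five years); the
engine reports the freshly computed category and never suppresses it —
publication timing is assessor metadata.

`build_matrix` runs the full engine on a canonical synthetic species per
cell: location-count bands 1, 2–5, 6–10, >10 are represented by 1, 3, 8
and 12 single-field locations (interior points of the location-count
tiers) spaced 200 km apart along a ridge at 15°S; the `MIXED` row places
the rounded-up half of locations under license and the rest under
protection. Cells corroborated by published assessments (single licensed
location ⇒ CR; fully protected ⇒ LC; actively mined ⇒ CR possibly
extinct) are tagged `text-confirmed` and verified at build time; all other
cells are tagged `engine-derived`. The matrix is recomputed on demand and
is never consulted as a lookup table by the engine.

## Synthetic data

`generate_synthetic_ridge` emulates the geometry the procedure targets:
clusters of vent fields along a great-circle ridge segment, intra-cluster
spacing 10 km (default; real vent fields on fast-spreading ridges sit
kilometres to tens of kilometres apart), inter-cluster gaps 200 km
(default, 2.5× the location threshold), isotropic positional jitter with
σ = 0.5 km (survey-scale position uncertainty), and management areas cut
at fractional positions along the ridge. The intended location partition
is returned alongside, and the spec is rejected as infeasible unless a
12σ jitter margin keeps every realised gap on the intended side of the
threshold (draws are clipped at 4σ), making the ground truth provable
rather than probable — which is what lets the generator serve as an
independent oracle for the clustering code.

What the generator does not emulate: uneven field spacing, curved ridge
geometry, polygonal management boundaries, and positional error structure
of real surveys. None of these enter the clustering definition (pairwise
distance + shared area), so passing the recovery tests demonstrates
correctness of the partition logic, not realism of ridge geometry.

## Case-study fixtures

Four bundles encode published assessments: *Gigantopelta chessoia* (two
protected East Scotia Ridge fields, LC), *Dracogyra subfusca* (one
licensed Southwest Indian Ridge field, CR), *Alviniconcha boucheti* (four
fields across three western-Pacific EEZs, EN) and *Bathymodiolus
manusensis* (three Manus Basin fields in one licensed location, EN).
Coordinates are approximate published vent-field positions; fixture-based
tests therefore assert categories, location counts and AOO (which are
robust to coordinate error at this scale), never recomputed EOO values.
Where a published EOO exists (171.23 km² for *B. manusensis*) it is
carried in the fixture and supplied to the engine verbatim through
`assess_from_metrics`.

## Numerical notes and limitations

* Clustering, AOO and EOO are exact given the spherical model; the only
  tolerance in the package is the hull-area comparison in tests (0.1%).
* AOO depends (as any fixed grid does) on cell placement for sites near
  cell boundaries when more than two sites are involved; the minimum
  anchoring makes the choice deterministic and documented.
* Regimes are declared per management area; the package does not overlay
  license polygons on coordinates, so a user must pre-resolve which area a
  site falls in. Temporal regime histories are not modelled.
* Test and matrix problem sizes (≤ 50 sites per random instance, 1,000
  clustering trials, a 12-location maximum band representative) were
  chosen to cover the discrete decision structure exhaustively — vent
  species are rarely known from more than 10 fields, so larger instances
  add no new decision paths.
* The engine encodes one reading of ambiguous guidance in two places:
  single-linkage chaining for "within 80 km of each other", and NT for
  unprotected species that meet no bound. Both are deliberate,
  precautionary choices and are configurable or clearly separable in code.
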