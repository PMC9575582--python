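# Methods

This note documents the data model brickstore implements, the choices
made where the design was genuinely open, and what the bundled
synthetic instance does and does not demonstrate.

## The model

**Ontologies.** A vocabulary is a set of terms with CURIE identifiers
(`PREFIX:LOCALID`), display labels, synonyms, and `is_a` parents.
Multiple inheritance is allowed (real vocabularies such as ENVO and
ChEBI are DAGs, not trees); cycles, duplicate ids, and dangling parents
are rejected at load. Documents use a minimal OBO-like stanza dialect
(`[Term]`, `id:`, `name:`, `synonym: "…"`, `is_a:`) — a deliberately
small, bit-exact format rather than full OBO 1.4, which would pull in
semantics (obsoletion, xrefs, relationship types) the model does not
use. Label/synonym matching is case-insensitive and
whitespace-normalized; CURIE matching is exact. A label that matches
terms in more than one loaded ontology is an *ambiguity error* rather
than resolved by priority: silent priority rules are how synonym
collisions turn into silent data corruption, and a CURIE always
disambiguates.

**Microtypes** pair an ontological name with one scalar type, an
optional validator, and allowed units. Unit classes expand through the
hierarchy: listing "concentration unit" admits every descendant unit
term, and the class term itself. Numeric microtypes must either list
units or be explicitly dimensionless — an unlabeled axis is precisely
the failure mode the model exists to prevent. Validators are data, not
code: regular expressions, numeric ranges (closed bounds by default,
open flags available), term subtrees, and *named* predicates drawn from
a whitelist registered in code — validators are never evaluated from
uploaded definitions, which closes the code-execution path through
data files. `validate_value` is total: any input yields a
`ValidationResult` with reason codes (`scalar-type-mismatch`,
`validator-failure`, `missing-unit`, `unit-not-allowed`,
`unexpected-unit`, `unknown-term`); unit discipline is checked before
value checks, and the reason tuple preserves that order. A null value
is valid for every microtype and flagged `is_null` — missingness is a
property of data, not an error.

Four *system microtypes* — Data Category, Dimension Type, Values Type,
Unit Type — must be defined per instance before any brick exists; their
allowed term sets are the instance's language. "Data Type" is carried
as a synonym of Data Category.

**Contextons** are built by `make_contexton`, which validates every
entry and raises with the full per-value failure list. Nulls live in an
explicit boolean mask beside the value array: a sentinel (NaN, empty
string, −1) can always collide with real data in at least one scalar
type, a mask cannot. Modifiers (compound contextons) are scalar only
and nest exactly one level deep — one level is what the compound
concept ("concentration of nitrate at 25 °C") requires, and deeper
nesting has no use case yet. Modifier order is irrelevant for equality
but preserved in serialization. Modifier values are visible to search.

**Bricks.** Dimension order is significant; value arrays serialize in
row-major order. Each dimension needs at least one *informative*
variable — a dimension described only by free-text `comment` microtypes
documents nothing and is rejected. A brick may carry several value sets
(heterogeneous measurements on the same grid), each with its own
microtype and unit. Overall context is restricted to scalar contextons.
Brick ids (`Brick:NNNNNNN`) are assigned only at store registration;
unsaved bricks have none.

**Aggregation** (`mean`, `sum`, `min`, `max`) ignores nulls; a cell
whose every contributing value is null stays null. `mean` over an
integer value set is refused rather than silently retyped, since the
result would violate the value set's own microtype; `sum`/`min`/`max`
preserve the scalar type. Slicing resolves predicates to explicit index
lists *before* recording the session op, so replay never depends on a
predicate object.

**Session provenance and replay.** Every manipulation is pure and
appends exactly one `(op, params)` record; the first manipulation of a
stored brick roots the session at that brick's permanent id. Replay
fetches the origin and re-executes the ops through a registry
(`slice`, `aggregate`, `join`); since all ops are deterministic the
result equals the stored derived brick exactly, IEEE-754 floats
included. An empty session replays to the origin itself.

**The store.** One JSON document per object under a per-type directory,
an append-only edge log, and a counter file; writes are
write-then-rename (atomic on POSIX), with a single-writer /
multi-reader concurrency contract. Processes are stored as records with
explicit input/output id lists; the graph materializes them as
`input → process → output` edges, plus `reference` edges from
referenced core objects and `superseded_by` edges between versions.
Anchoring: a brick must either reference live core objects or arrive
with a process whose inputs already exist; core objects may be roots.
Supersession marks the old object and registers the replacement under a
fresh id — nothing is deleted, and every historical id stays
retrievable. Reference edges point at the object that was live at
registration time; lineage is resolved at read time
(`resolve_lineage`), so history remains truthful after corrections.

**Search** is a conjunction of predicates over live objects: data
category, core-type name, microtype presence, term values (optionally
hierarchy-expanded), scalar comparisons, and provenance predicates
(derived-from an id, person, process term). This fixed vocabulary
covers the query patterns the model is for without growing a general
graph-query language.

**Dynamic joins** align fields of referenced core objects by the
reference variable's values and attach them as new 1-D variables on
that dimension; a second hop is allowed only through an `object_ref`
field of the first target. If the same field carries different units
across the joined objects the join is refused — inventing a conversion
would silently change data.

## Serialization

The canonical on-disk form is a versioned JSON dialect
(`format_version: 1`) that round-trips every field losslessly: floats
survive via `repr`-based JSON encoding (exact for finite doubles),
masks via explicit nulls, modifiers and sessions structurally. NetCDF-4
is an export/import codec for bricks whose value sets are numeric:
files are written directly with h5py following the NetCDF-4 profile of
HDF5 (dimension-scale datasets, per-variable attributes carrying
microtype and unit CURIEs, JSON-encoded session and overall context,
companion `__mask` datasets for nulls). String- or term-valued value
sets do not map cleanly onto NetCDF variables, so JSON remains the
source of truth.

## Upload workflow

CSV (RFC 4180, UTF-8) replaces a spreadsheet wizard. A sheet embeds its
schema in `#`-prefixed metadata rows, then a labeled grid: 1-D schemas
are a plain table; ≥2-D schemas are stacked 2-D slabs (one per value
set per trailing coordinate) with axis-1 variable labels across the
top and axis-0 variables down the left; variables of axes ≥2 appear in
dedicated `#dim_values` sections. The labeled layout is contractual:
label cells that disagree with the schema are a hard error, which is
what makes `generate → parse` the identity on schemas. Blank data cells
become nulls with a warning. Upload templates attach per-microtype
invalid-data policies applied per cell: `error` (reject), `null`
(missing, warn), `clamp` (move to the nearest bound of the numeric
range validator, warn; clamped values are re-validated and the clamp is
refused where no numeric bounds exist). Policy precedence is
per-microtype template policy, then template default, then the instance
default (`error`). Registration is a separate, final step that requires
a process record (process term, person, date, inputs) — provenance is
never optional.

Use templates are structural interfaces: a conjunction of constraints
(dimension labeled with a given microtype, value-set scalar type or
microtype, dimension-count bounds) deciding which bricks an algorithm
accepts. Plot-eligibility rules are expressed as shipped use templates
(e.g. `line_graph_2d`).

## The synthetic instance

`brickstore.fixtures.generate_fixture(seed, sizes)` builds a complete
miniature deployment: two fictional vocabularies (`EX:` domain terms
including the carbohydrate ⟶ glucose branch and a biome subtree; `EXU:`
units), ~20 microtypes, Well/Sample/Gene core types, and three bricks —
gene fitness (4 conditions × 100 genes × 3 replicates, defaults chosen
to exercise a 3-D factorial layout), geochemistry (6 samples × 5
analytes, ~5 % of cells null to exercise sparsity), and growth curves
(8 time points × 4 strains, logistic with per-strain capacity and rate,
anchored purely through its process record). Values are drawn from
seeded uniform/normal generators within validator bounds; generation is
a pure function of `(seed, sizes)` and writes byte-identical
directories for identical arguments. CURIE prefixes are fictional so no
real ENVO/ChEBI identifiers are implied.

What passing tests on this instance do **not** show: performance or
concurrency at realistic scale (the store is scanned linearly; searches
are exact but O(objects × context)), robustness to genuinely messy
real-world uploads (hand-edited spreadsheets, encoding damage), or the
adequacy of any particular microtype vocabulary for a real domain — the
fixture's language is illustrative, and choosing static core types for
a real deployment remains a judgment call.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
the full suite completes in seconds on one CPU: 100 randomized bricks
for round-trip checks, 25 random factorial designs for representation
equivalence, 200 randomized queries against the linear-scan oracle on
an instance of ≈120 objects, 100 randomized
registrations/supersessions for graph-integrity checks, and 50 random
op sequences for replay.

## Known limitations

- Tree- and graph-structured dynamic types are out of scope; the brick
  is the only dynamic shape.
- No unit conversion arithmetic (mM → M) and no uncertainty on values.
- No access control or authentication; the store trusts its caller.
- Core-type schemas cannot be migrated in place; corrections go through
  supersession.
- NetCDF-4 export covers numeric value sets only (by design, above).
- The CLI exposes template editing only by editing the emitted schema
  JSON; there is no interactive wizard.
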