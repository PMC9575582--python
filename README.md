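# brickstore

Self-validating units of context, N-dimensional data bricks, and a
file-backed provenance store for FAIR scientific data management.

## The problem

Research organizations accumulate hundreds of heterogeneous dataset
types — field measurements, assay results, derived analyses — and most of
them are, mathematically, just labeled N-dimensional arrays. What makes
them hard to integrate and reuse is everything *around* the numbers:
units left implicit, synonymous names for the same concept, lost
provenance, and free-text metadata that no machine can check. This
package implements a data model in which that context is mandatory,
formally grounded, and carried through every analysis step:

- **Ontologies** (controlled vocabularies in a multi-parent hierarchy)
  ground every name, unit, and categorical value; synonyms collapse onto
  one term, and queries can expand over the hierarchy ("carbohydrate"
  finds "glucose").
- A **microtype** is an atomic concept definition: an ontological name,
  exactly one scalar type (`int`, `float`, `string`, `boolean`, an
  ontology-term reference, or an object reference), an optional
  validator (regular expression, numeric range, whitelisted predicate,
  or term subtree), and the allowed measurement units — either explicit
  unit terms or unit *classes* whose whole subtree is admitted.
- A **contexton** is an instantiated microtype: the trio
  (microtype, value-or-array, unit). Contextons are *self-validating* —
  validity is decidable from the contexton alone, independent of any
  enclosing structure — and may be *compound*: a primary contexton plus
  scalar modifiers (concentration, *of nitrate*, *at 25 °C*,
  *log₂-scaled*). Missing values are carried in an explicit null mask,
  never as a sentinel.
- Static **core types** (Well, Sample, Gene, …) are stable record
  schemas built from scalar contexton fields; their instances form the
  reference backbone everything else must link to.
- A **data brick** is an N-dimensional dataset whose every part is a
  contexton: per-dimension 1-D variables (with a *Dimension Type* term),
  one or more N-D value sets (each with its own microtype and unit),
  scalar overall context, and a mandatory *Data Category* and brick
  name. A 2-D brick with two paired variables per dimension flattens to
  exactly the same (context, value) multiset as the expanded 4-D
  factorial form — the representation is a modeling choice, not a
  semantic one.
- The **provenance store** assigns permanent ids, links objects through
  process records in a directed acyclic graph, rejects unanchored "data
  islands", supersedes (never deletes) old versions, answers
  ancestor/descendant queries, and serves term-expanded search and
  **dynamic joins** (merging fields of referenced core objects — across
  one or two reference hops — into a brick as new dimension variables).
- Every manipulation (slice, aggregate, join) is pure and records one
  **session provenance** op, so any derived brick can be replayed
  bit-for-bit from its origin.

Bricks serialize to a canonical JSON dialect and, for numeric value
sets, to NetCDF-4 (written via HDF5 dimension-scale conventions).

## A worked example

The package ships a deterministic miniature instance (three groundwater
wells, six samples, a gene catalog, fitness / geochemistry / growth
bricks, and the processes linking them). From
`examples/03_search_and_joins.py`:

```text
bricks whose context mentions any carbohydrate: ['Brick:0000001', 'Brick:0000002']
    Brick:0000001 = fitness assay GW101 pool
    Brick:0000002 = geochemistry panel 2021

geochemistry brick 'geochemistry panel 2021' joined to Sample and Well:
  sample-dimension variables: ['sample', 'depth (meter)', 'latitude (degree)', 'longitude (degree)']
  S001: depth=41.385 m, lat=35.925591 deg
```

The search asked for the *parent* term "carbohydrate" with hierarchy
expansion: it finds the fitness brick (glucose and sucrose media) and
the geochemistry brick (glucose among the analytes), neither of which
mentions "carbohydrate" literally. The join resolved each sample
reference on the brick's first dimension, pulled `depth` from the
Sample objects (one hop), then followed each sample's `well` reference
to merge well coordinates (two hops); the merged columns arrive as new
1-D contextons with their microtypes and units intact.

From `examples/02_bricks_and_replay.py`, on the 4×100×3 fitness brick:

```text
after slice+mean: shape [4, 100], session ops ['slice', 'aggregate']
stored as Brick:0000004; replay reproduces it exactly: True
```

The other examples show total validation with reason codes
(`01_validated_context.py`) and the CSV upload workflow — labeled
template sheet, per-cell invalid-data policies (error / null / clamp),
registration with a process record (`04_upload_workflow.py`).

There is also a thin CLI (`brickstore --help`) with verbs for instance
management (`init`, `load-ontology`, `define-microtype`,
`define-core-type`), data flow (`template`, `upload`, `upload-core`,
`validate`), and queries (`search`, `provenance`, `join`,
`export-netcdf`, `fixtures`).

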