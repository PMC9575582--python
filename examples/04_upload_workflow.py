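"""The CSV upload workflow: template sheet -> fill -> validate -> register.

A labeled template is generated from a declared schema; filling it (here
programmatically, with one deliberate blank and one out-of-range value)
and parsing it back applies the upload template's invalid-data policy
per cell and yields a registrable brick.
"""

import dataclasses

import numpy as np

import brickstore as bs
from brickstore.fixtures import generate_fixture
from brickstore.sheets import (
    SheetSchema, parse_filled_sheet, render_sheet, rows_to_csv,
)

inst = generate_fixture(seed=1)
growth = inst.store.get("Brick:0000003")
schema = SheetSchema.from_brick(growth)

print("template sheet (first 8 lines):")
for line in rows_to_csv(render_sheet(schema)).splitlines()[:8]:
    print("  ", line)

nt, ns = growth.shape
times = [round(1.5 * i, 2) for i in range(nt)]
strains = [f"demo-s{j}" for j in range(ns)]
od = np.round(np.random.default_rng(0).uniform(0.05, 1.2, (nt, ns)), 4).astype(object)
od[1, 1] = None      # missing reading -> null with a warning
od[0, 0] = -0.25     # invalid: growth template clamps OD to its range

brick, report = parse_filled_sheet(
    render_sheet(schema, [[times], [strains]], [od]),
    inst,
    upload_template=inst.upload_templates["growth"],
)
print(f"\nparse: ok={report.ok}, warnings={len(report.warnings)}")
for w in report.warnings:
    print("   warning:", w)

brick = dataclasses.replace(brick, name="growth curves upload demo")
bid = inst.store.register_object(
    brick,
    bs.ProcessSpec(
        process_term=inst.terms.resolve("growth assay"),
        person="carol",
        date="2021-10-01",
        input_ids=("Sample:0000001",),
    ),
)
print(f"registered as {bid}; OD[0,0] clamped to "
      f"{brick.value_sets[0].value_at((0, 0))}, "
      f"OD[1,1] is null: {brick.value_sets[0].mask[1, 1]}")
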