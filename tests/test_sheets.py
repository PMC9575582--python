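"""Template sheet generation, filling, and parse round trips."""

import numpy as np
import pytest

from brickstore.bricks import point_multiset
from brickstore.errors import SheetError
from brickstore.sheets import (
    SheetSchema,
    csv_to_rows,
    generate_template_sheet,
    parse_filled_sheet,
    render_sheet,
    rows_to_csv,
    _schema_from_rows,
)
from brickstore.store import ProcessSpec


def _growth_schema(inst):
    return SheetSchema.from_brick(inst.store.get("Brick:0000003"))


def _fill_from_brick(inst, brick):
    schema = SheetSchema.from_brick(brick)
    dim_values = [
        [[v.value_at((i,)) for i in range(d.size)] for v in d.variables]
        for d in brick.dims
    ]
    values = [np.array(vs.to_list(), dtype=object) for vs in brick.value_sets]
    return schema, render_sheet(schema, dim_values, values)


def test_template_encodes_schema_and_round_trips(inst):
    schema = _growth_schema(inst)
    rows = generate_template_sheet(schema)
    # labels present: time with unit across, strains; data region blank
    flat = rows_to_csv(rows)
    assert "time (hour)" in flat and "strain name" in flat
    recovered, _ = _schema_from_rows(csv_to_rows(flat), inst)
    assert recovered.to_doc() == schema.to_doc()


def test_one_dimensional_layout_is_a_plain_table(inst):
    geo = inst.store.get("Brick:0000002")
    import brickstore as bs

    one_d = bs.slice_brick(geo, 1, [0])
    one_d = bs.aggregate_dimension(one_d, 1, "mean")
    schema, rows = _fill_from_brick(inst, one_d)
    header = [r for r in rows if r and not r[0].startswith("#")][0]
    assert header == ["sample", "concentration (millimolar)"]
    brick, report = parse_filled_sheet(rows, inst)
    assert brick is not None


def test_filled_sheet_round_trips_every_cell(inst):
    growth = inst.store.get("Brick:0000003")
    schema, rows = _fill_from_brick(inst, growth)
    rows = csv_to_rows(rows_to_csv(rows))  # through the textual form
    brick, report = parse_filled_sheet(rows, inst, schema=schema)
    assert report.ok and brick is not None
    assert point_multiset(brick) == point_multiset(growth)


def test_three_dimensional_sheet_uses_stacked_slabs(inst):
    fit = inst.store.get("Brick:0000001")
    schema, rows = _fill_from_brick(inst, fit)
    slab_headers = [r for r in rows if r and r[0] == "#slab"]
    assert len(slab_headers) == fit.dims[2].size  # one 2-D slab per replicate
    brick, report = parse_filled_sheet(rows, inst, schema=schema)
    assert report.ok
    # sheets carry dims + value sets; overall context is added at upload
    import dataclasses

    assert point_multiset(brick) == point_multiset(
        dataclasses.replace(fit, overall_context=())
    )


def test_blank_cell_becomes_null_with_warning(inst):
    growth = inst.store.get("Brick:0000003")
    schema, rows = _fill_from_brick(inst, growth)
    # blank one data cell (first data row = after col-var rows + corner row)
    for i, r in enumerate(rows):
        if r and r[0] == "#slab":
            rows[i + len(growth.dims[1].variables) + 2][1] = ""
            break
    brick, report = parse_filled_sheet(rows, inst)
    assert brick is not None
    assert any("null" in w for w in report.warnings)
    assert brick.value_sets[0].mask.sum() == 1


def test_shuffled_header_is_a_layout_error(inst):
    growth = inst.store.get("Brick:0000003")
    schema, rows = _fill_from_brick(inst, growth)
    for r in rows:
        if r and r[0] == "strain name":  # corner label row
            r[0] = "renamed"
            break
    with pytest.raises(SheetError, match="label"):
        parse_filled_sheet(rows, inst)


def test_schema_mismatch_detected(inst):
    growth_schema, rows = _fill_from_brick(inst, inst.store.get("Brick:0000003"))
    other = SheetSchema.from_brick(inst.store.get("Brick:0000002"))
    with pytest.raises(SheetError, match="schema"):
        parse_filled_sheet(rows, inst, schema=other)


def test_upload_template_policy_applied_per_cell(inst):
    growth = inst.store.get("Brick:0000003")
    schema, rows = _fill_from_brick(inst, growth)
    # corrupt one OD cell to a negative value: growth template clamps
    for i, r in enumerate(rows):
        if r and r[0] == "#slab":
            rows[i + len(growth.dims[1].variables) + 2][1] = "-0.25"
            break
    brick, report = parse_filled_sheet(
        rows, inst, upload_template=inst.upload_templates["growth"]
    )
    assert brick is not None
    assert any("clamped" in w for w in report.warnings)
    assert brick.value_sets[0].value_at((0, 0)) == 0.0


def test_parsed_brick_registers_with_process(inst):
    growth = inst.store.get("Brick:0000003")
    schema, rows = _fill_from_brick(inst, growth)
    brick, report = parse_filled_sheet(rows, inst)
    import dataclasses

    brick = dataclasses.replace(brick, name="growth reupload")
    bid = inst.store.register_object(
        brick,
        ProcessSpec(
            process_term=inst.terms.resolve("growth assay"),
            person="carol",
            input_ids=("Sample:0000001",),
        ),
    )
    assert bid.startswith("Brick:")
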