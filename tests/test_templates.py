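"""Upload-template merging, invalid-data policies, and use-template matching."""

import numpy as np
import pytest

from brickstore.errors import PolicyViolation, TemplateError
from brickstore.microtypes import ValidatorSpec, validate_value
from brickstore.templates import (
    BrickDraft,
    DimDraft,
    UseConstraint,
    UseTemplate,
    apply_upload_template,
    enforce_policy,
    matches_use_template,
)

from conftest import random_brick


def test_template_fills_empty_draft(inst):
    tpl = inst.upload_templates["growth"]
    draft = apply_upload_template(tpl, BrickDraft())
    assert draft.data_category.label == "microbial growth data"
    assert [d.dim_type.label for d in draft.dims] == ["time series", "strain series"]
    assert draft.value_sets[0][0].name == "optical density"


def test_user_content_wins_over_defaults(inst):
    tpl = inst.upload_templates["growth"]
    # user chose a single strain dimension instead of the default two
    own_dim = [
        DimDraft(
            inst.terms.resolve("strain series"),
            [(inst.microtypes.get("strain name"), None)],
        )
    ]
    draft = apply_upload_template(
        tpl, BrickDraft(data_category=tpl.data_category, dims=own_dim)
    )
    assert len(draft.dims) == 1
    # but policies/validators are still attached
    assert draft.policy_for(inst.microtypes.get("optical density")) == "clamp"


def test_apply_is_idempotent(inst):
    tpl = inst.upload_templates["growth"]
    once = apply_upload_template(tpl, BrickDraft())
    twice = apply_upload_template(tpl, once)
    assert once.policies == twice.policies
    assert [d.dim_type.id for d in once.dims] == [d.dim_type.id for d in twice.dims]
    assert once.value_sets == twice.value_sets


def test_category_mismatch_rejected(inst):
    tpl = inst.upload_templates["growth"]
    with pytest.raises(TemplateError, match="category"):
        apply_upload_template(
            tpl, BrickDraft(data_category=inst.terms.resolve("fitness data"))
        )


def test_valid_value_passes_under_every_policy(inst):
    od = inst.microtypes.get("optical density")
    for policy in ("error", "null", "clamp"):
        v, warning = enforce_policy(od, 0.42, None, policy, inst.terms)
        assert v == 0.42 and warning is None


def test_error_policy_raises(inst):
    od = inst.microtypes.get("optical density")
    with pytest.raises(PolicyViolation):
        enforce_policy(od, -0.2, None, "error", inst.terms)


def test_null_policy_nulls_with_warning(inst):
    od = inst.microtypes.get("optical density")
    v, warning = enforce_policy(od, -0.2, None, "null", inst.terms)
    assert v is None and "missing" in warning


def test_clamp_policy_moves_to_nearest_bound_and_revalidates(inst):
    od = inst.microtypes.get("optical density")  # range [0, inf)
    v, warning = enforce_policy(od, -0.2, None, "clamp", inst.terms)
    assert v == 0.0 and "clamped" in warning
    assert validate_value(od, v, None, inst.terms).ok
    lat = inst.microtypes.get("latitude")  # range [-90, 90]
    deg = inst.terms.resolve("degree")
    v, _ = enforce_policy(lat, 123.0, deg, "clamp", inst.terms)
    assert v == 90.0 and validate_value(lat, v, deg, inst.terms).ok


def test_clamp_refused_without_numeric_bounds(inst):
    name = inst.microtypes.get("strain name")  # string, no range
    with pytest.raises(TemplateError):
        enforce_policy(name, 3, None, "clamp", inst.terms)


def test_template_validator_attached_and_used(inst):
    od = inst.microtypes.get("optical density")
    strict = ValidatorSpec(kind="numeric_range", minimum=0.0, maximum=2.0)
    v, warning = enforce_policy(
        od, 5.0, None, "clamp", inst.terms, extra_validator=strict
    )
    assert v == 2.0 and warning is not None


def test_time_series_use_template_matches_growth_brick(inst):
    growth = inst.store.get("Brick:0000003")
    fitness = inst.store.get("Brick:0000001")
    tpl = inst.use_templates["time_series_analysis"]
    ok, _ = matches_use_template(growth, tpl)
    assert ok
    ok, why = matches_use_template(fitness, tpl)
    assert not ok and "EX:0000204" in why


def test_unconstrained_template_matches_everything(inst):
    empty = UseTemplate(name="anything")
    for bid in ("Brick:0000001", "Brick:0000002", "Brick:0000003"):
        assert matches_use_template(inst.store.get(bid), empty)[0]


def _brute_force_match(brick, template):
    """Exhaustively test every (constraint, dimension/value-set) pairing."""
    for c in template.constraints:
        if c.requires_dimension_with_microtype is not None:
            hits = [
                v.microtype.id == c.requires_dimension_with_microtype
                for d in brick.dims
                for v in d.variables
            ]
            if not any(hits):
                return False
        if c.requires_value_set_scalar_type is not None:
            if not any(
                vs.microtype.scalar_type == c.requires_value_set_scalar_type
                for vs in brick.value_sets
            ):
                return False
        if c.requires_value_set_microtype is not None:
            if not any(
                vs.microtype.id == c.requires_value_set_microtype
                for vs in brick.value_sets
            ):
                return False
        if c.min_dims is not None and len(brick.dims) < c.min_dims:
            return False
        if c.max_dims is not None and len(brick.dims) > c.max_dims:
            return False
    return True


def test_matcher_agrees_with_exhaustive_pairing_oracle(inst):
    rng = np.random.default_rng(5)
    mt_pool = ["EX:0000204", "EX:0000201", "EX:0000110", "EX:0000109", "EX:0000111"]
    bricks = [random_brick(rng, inst, f"m-{i}") for i in range(8)]
    for _ in range(40):
        constraints = []
        for _ in range(int(rng.integers(0, 3))):
            kind = int(rng.integers(0, 5))
            c = {}
            if kind == 0:
                c["requires_dimension_with_microtype"] = mt_pool[int(rng.integers(0, 5))]
            elif kind == 1:
                c["requires_value_set_scalar_type"] = ["float", "int", "string"][int(rng.integers(0, 3))]
            elif kind == 2:
                c["requires_value_set_microtype"] = mt_pool[int(rng.integers(0, 5))]
            elif kind == 3:
                c["min_dims"] = int(rng.integers(1, 4))
            else:
                c["max_dims"] = int(rng.integers(1, 4))
            constraints.append(UseConstraint(**c))
        tpl = UseTemplate(name="rand", constraints=tuple(constraints))
        for b in bricks:
            assert matches_use_template(b, tpl)[0] == _brute_force_match(b, tpl)


def test_matching_is_monotone_in_constraints(inst):
    """Adding a constraint can only shrink the accepted set."""
    rng = np.random.default_rng(9)
    bricks = [random_brick(rng, inst, f"mono-{i}") for i in range(6)]
    base = UseTemplate(
        name="base",
        constraints=(UseConstraint(requires_value_set_scalar_type="float"),),
    )
    stricter = UseTemplate(
        name="strict",
        constraints=base.constraints + (UseConstraint(min_dims=2),),
    )
    accepted_base = {b.name for b in bricks if matches_use_template(b, base)[0]}
    accepted_strict = {b.name for b in bricks if matches_use_template(b, stricter)[0]}
    assert accepted_strict <= accepted_base
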