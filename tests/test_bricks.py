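"""Brick construction, flattening, manipulation, replay, serialization."""

import json
from collections import Counter

import numpy as np
import pytest

import brickstore as bs
from brickstore.bricks import (
    DataBrick,
    DimensionSpec,
    build_brick,
    enumerate_points,
    point_multiset,
    validate_brick,
)
from brickstore.contextons import make_contexton
from brickstore.errors import BrickError
from brickstore.netcdf import export_netcdf, import_netcdf

from conftest import nested_loop_points, random_brick


def _ctx(inst, name, values, unit=None):
    return make_contexton(
        inst.microtypes.get(name), values, unit=unit, ontologies=inst.terms
    )


def test_fixture_fitness_brick_is_valid(inst):
    fit = inst.store.get("Brick:0000001")
    assert fit.shape == [4, 30, 3]
    assert validate_brick(fit, inst.microtypes, store=inst.store).ok


def test_all_comment_dimension_rejected(inst):
    t = inst.terms.resolve
    with pytest.raises(BrickError, match="all-comment"):
        build_brick(
            "notes only",
            t("fitness data"),
            dims=(
                DimensionSpec(
                    t("condition series"), 2, (_ctx(inst, "comment", ["a", "b"]),)
                ),
            ),
            value_sets=(_ctx(inst, "fitness", [0.0, 1.0]),),
            system=inst.require_system(),
            registry=inst.microtypes,
        )


def test_disallowed_category_term_rejected(inst):
    t = inst.terms.resolve
    with pytest.raises(BrickError, match="Data Category"):
        build_brick(
            "bad category",
            t("glucose"),  # not under the data-category subtree
            dims=(
                DimensionSpec(
                    t("strain series"), 1, (_ctx(inst, "strain name", ["s"]),)
                ),
            ),
            value_sets=(_ctx(inst, "fitness", [0.0]),),
            system=inst.require_system(),
            registry=inst.microtypes,
        )


def test_minimal_brick_with_single_null_value(inst):
    t = inst.terms.resolve
    b = build_brick(
        "tiny",
        t("fitness data"),
        dims=(
            DimensionSpec(t("strain series"), 1, (_ctx(inst, "strain name", ["s1"]),)),
        ),
        value_sets=(_ctx(inst, "fitness", [None]),),
        system=inst.require_system(),
        registry=inst.microtypes,
    )
    pts = enumerate_points(b)
    assert len(pts) == 1 and pts[0].is_null


def test_shape_mismatch_reported_with_path(inst):
    fit = inst.store.get("Brick:0000001")
    broken = DataBrick(
        name=fit.name,
        data_category=fit.data_category,
        dims=fit.dims,
        value_sets=(_ctx(inst, "fitness", np.zeros((2, 2))),),
    )
    rep = validate_brick(broken, inst.microtypes)
    assert not rep.ok
    assert any(f.code == "shape-mismatch" and "value_sets[0]" in f.path for f in rep)


def test_dangling_gene_reference_located_by_coordinate(inst):
    t = inst.terms.resolve
    b = build_brick(
        "bad ref",
        t("fitness data"),
        dims=(
            DimensionSpec(
                t("gene axis"), 2, (_ctx(inst, "gene", ["G0001", "G9999"]),)
            ),
        ),
        value_sets=(_ctx(inst, "fitness", [0.1, 0.2]),),
        system=inst.require_system(),
        registry=inst.microtypes,
    )
    rep = validate_brick(b, inst.microtypes, store=inst.store)
    bad = [f for f in rep if f.code == "dangling-reference"]
    assert len(bad) == 1 and "[(1,)]" in bad[0].path


def test_enumerate_point_count_and_oracle(inst):
    fit = inst.store.get("Brick:0000001")
    pts = enumerate_points(fit)
    assert len(pts) == 4 * 30 * 3 * len(fit.value_sets)
    assert Counter(r.key() for r in pts) == Counter(
        (frozenset(ctx), mt, u, v, n) for ctx, mt, u, v, n in nested_loop_points(fit)
    )


def test_representation_equivalence_2d_vs_4d(inst):
    """A 2-D brick with paired dimension variables enumerates identically
    to the expanded factorial N-D brick."""
    rng = np.random.default_rng(0)
    t = inst.terms.resolve
    strains = ["sA", "sB", "sC"]
    media = ["EX:0000012", "EX:0000014"]
    vals4 = rng.normal(size=(3, 2)).round(6)
    # 2-D-combined: one dimension holding the (strain, media) product
    combined = build_brick(
        "combined",
        t("fitness data"),
        dims=(
            DimensionSpec(
                t("condition series"),
                6,
                (
                    _ctx(inst, "strain name", [s for s in strains for _ in media]),
                    _ctx(inst, "molecule", media * len(strains)),
                ),
            ),
            DimensionSpec(t("replicate series"), 1, (_ctx(inst, "replicate number", [1]),)),
        ),
        value_sets=(_ctx(inst, "fitness", vals4.reshape(6, 1)),),
        system=inst.require_system(),
        registry=inst.microtypes,
    )
    expanded = build_brick(
        "expanded",
        t("fitness data"),
        dims=(
            DimensionSpec(t("strain series"), 3, (_ctx(inst, "strain name", strains),)),
            DimensionSpec(t("analyte series"), 2, (_ctx(inst, "molecule", media),)),
            DimensionSpec(t("replicate series"), 1, (_ctx(inst, "replicate number", [1]),)),
        ),
        value_sets=(_ctx(inst, "fitness", vals4.reshape(3, 2, 1)),),
        system=inst.require_system(),
        registry=inst.microtypes,
    )
    assert point_multiset(combined) == point_multiset(expanded)


def test_identity_slice_changes_only_the_session(inst):
    fit = inst.store.get("Brick:0000001")
    s = bs.slice_brick(fit, 1, list(range(fit.dims[1].size)))
    assert s.shape == fit.shape
    assert s.value_sets == fit.value_sets
    assert s.session.ops[-1][0] == "slice"
    assert fit.session.ops == ()  # original untouched


def test_slice_matches_nested_loop_extraction(inst):
    fit = inst.store.get("Brick:0000001")
    s = bs.slice_brick(fit, 2, [1])
    assert s.shape == [4, 30, 1]
    vs, ovs = s.value_sets[0], fit.value_sets[0]
    for i in range(4):
        for j in range(30):
            assert vs.values[i, j, 0] == ovs.values[i, j, 1]


def test_slicing_commutes_with_enumeration(inst):
    geo = inst.store.get("Brick:0000002")
    keep = [0, 2, 4]
    sliced_pts = point_multiset(bs.slice_brick(geo, 0, keep))
    kept_names = {
        geo.dims[0].variables[0].value_at((i,)) for i in keep
    }
    key = (geo.dims[0].variables[0].microtype.id, None, ())
    filtered = Counter(
        r.key()
        for r in enumerate_points(geo)
        if dict(r.context)[key] in kept_names
    )
    assert sliced_pts == filtered


def test_empty_selection_and_bad_dim_rejected(inst):
    fit = inst.store.get("Brick:0000001")
    with pytest.raises(BrickError, match="empty selection"):
        bs.slice_brick(fit, 0, [])
    with pytest.raises(BrickError):
        bs.slice_brick(fit, 9, [0])


@pytest.mark.parametrize(
    "stat,vec,expected",
    [
        ("mean", [1.0, 2.0, 3.0], 2.0),
        ("mean", [1.0, None, 3.0], 2.0),  # null ignored
        ("sum", [1.0, None, 3.0], 4.0),
        ("min", [1.0, None, 3.0], 1.0),
        ("max", [1.0, None, 3.0], 3.0),
        ("mean", [None, None, None], None),  # all-null cell stays null
    ],
)
def test_aggregation_masked_reduction(inst, stat, vec, expected):
    t = inst.terms.resolve
    b = build_brick(
        "agg",
        t("fitness data"),
        dims=(
            DimensionSpec(t("strain series"), 1, (_ctx(inst, "strain name", ["s"]),)),
            DimensionSpec(
                t("replicate series"), 3, (_ctx(inst, "replicate number", [1, 2, 3]),)
            ),
        ),
        value_sets=(_ctx(inst, "fitness", [vec]),),
        system=inst.require_system(),
        registry=inst.microtypes,
    )
    out = bs.aggregate_dimension(b, 1, stat)
    assert out.ndim == 1
    assert out.value_sets[0].value_at((0,)) == expected
    assert out.session.ops[-1] == ("aggregate", {"dim": 1, "statistic": stat})


def test_aggregating_singleton_dimension_keeps_values(inst):
    fit = inst.store.get("Brick:0000001")
    s = bs.slice_brick(fit, 2, [0])
    a = bs.aggregate_dimension(s, 2, "mean")
    assert a.shape == [4, 30]
    assert np.array_equal(a.value_sets[0].values, s.value_sets[0].values[:, :, 0])


def test_replay_reproduces_derived_brick_bit_for_bit(inst):
    store = inst.store
    fit = store.get("Brick:0000001")
    derived = bs.aggregate_dimension(bs.slice_brick(fit, 2, [1, 2]), 2, "mean")
    t = inst.terms.resolve
    bid = store.register_object(
        derived,
        bs.ProcessSpec(
            process_term=t("computational analysis"),
            person="alice",
            input_ids=(fit.brick_id,),
        ),
    )
    stored = store.get(bid)
    replayed = bs.replay_session(store, stored.session)
    assert replayed == stored
    # replay is insensitive to session re-serialization
    from brickstore.bricks import SessionProvenance

    rt = SessionProvenance.from_doc(json.loads(json.dumps(stored.session.to_doc())))
    assert bs.replay_session(store, rt) == stored


def test_empty_session_replays_to_origin(inst):
    from brickstore.bricks import SessionProvenance

    fit = inst.store.get("Brick:0000001")
    out = bs.replay_session(
        inst.store, SessionProvenance(origin_brick_id=fit.brick_id)
    )
    assert out == fit


def test_json_round_trip_of_fixture_bricks(inst):
    for bid in ("Brick:0000001", "Brick:0000002", "Brick:0000003"):
        b = inst.store.get(bid)
        doc = json.loads(json.dumps(bs.serialize_brick(b)))
        assert bs.deserialize_brick(doc, inst.microtypes) == b


def test_document_missing_brick_name_rejected(inst):
    doc = bs.serialize_brick(inst.store.get("Brick:0000001"))
    doc["name"] = ""
    with pytest.raises(BrickError, match="Brick Name"):
        bs.deserialize_brick(doc, inst.microtypes)


def test_netcdf_and_json_exports_agree(inst, tmp_path):
    geo = inst.store.get("Brick:0000002")  # has nulls
    path = tmp_path / "geo.nc"
    export_netcdf(geo, path)
    from_nc = import_netcdf(path, inst.microtypes)
    from_json = bs.deserialize_brick(
        json.loads(json.dumps(bs.serialize_brick(geo))), inst.microtypes
    )
    assert point_multiset(from_nc) == point_multiset(from_json) == point_multiset(geo)


def test_random_bricks_round_trip_and_conserve_shape(inst):
    rng = np.random.default_rng(11)
    for i in range(10):
        b = random_brick(rng, inst, f"rand-{i}")
        doc = json.loads(json.dumps(bs.serialize_brick(b)))
        assert bs.deserialize_brick(doc, inst.microtypes) == b
        # shape conservation through a random op
        if b.ndim and b.dims[0].size > 1:
            s = bs.slice_brick(b, 0, [0])
            assert all(vs.shape == s.shape for vs in s.value_sets)
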