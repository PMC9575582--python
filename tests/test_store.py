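"""Provenance store: anchoring, versioning, graph queries, search, joins."""

import numpy as np
import pytest

import brickstore as bs
from brickstore.bricks import enumerate_points
from brickstore.core_types import build_core_object
from brickstore.errors import StoreError
from brickstore.store import ProcessSpec, create_core_object, dynamic_join

from conftest import bfs_reachable, random_brick


# -- raw edge table ----------------------------------------------------------


def raw_edges(store):
    """The store's append-only edge table as plain (src, dst) pairs; the
    oracles below traverse it with their own BFS, independently of the
    graph object.  Process in/out edges are cross-checked against the
    process documents."""
    edges = [(s, d) for s, d, _ in store.edge_log]
    for proc in store.processes():
        for i in proc.input_ids:
            assert (i, proc.id) in edges
        for o in proc.output_ids:
            assert (proc.id, o) in edges
    return edges


def assert_anchored(store):
    """Every live object is a core object or reaches one upstream."""
    edges = raw_edges(store)
    for obj in store.objects(live_only=True):
        oid = store._id_of(obj)
        if not isinstance(obj, bs.DataBrick):
            continue
        upstream = bfs_reachable(edges, oid, reverse=True) - {oid}
        assert any(
            not isinstance(store.get(a), bs.DataBrick)
            and not a.startswith("Process:")
            for a in upstream
        ), f"{oid} is not anchored"


def test_wells_are_backbone_roots(inst):
    """Core objects with no experimental inputs register without a process."""
    w = inst.store.get("Well:0000001")
    anc = inst.store.provenance_ancestors("Well:0000001")
    assert set(anc.nodes) == {"Well:0000001"}
    assert w.live


def test_isolated_brick_rejected_as_data_island(inst):
    rng = np.random.default_rng(3)
    b = random_brick(rng, inst, "island")  # no object refs by construction
    with pytest.raises(StoreError, match="island"):
        inst.store.register_object(b)


def test_brick_anchors_through_its_process_inputs(inst):
    rng = np.random.default_rng(4)
    b = random_brick(rng, inst, "anchored-by-process")
    bid = inst.store.register_object(
        b,
        ProcessSpec(
            process_term=inst.terms.resolve("assay"),
            person="carol",
            input_ids=("Sample:0000001",),
        ),
    )
    assert bid.startswith("Brick:")
    assert_anchored(inst.store)


def test_fixture_instance_is_fully_anchored_and_acyclic(inst):
    import networkx as nx

    assert_anchored(inst.store)
    assert nx.is_directed_acyclic_graph(inst.store._graph)


def test_supersession_keeps_history_retrievable(inst):
    store = inst.store
    old = store.get("Well:0000002")
    deg = inst.terms.resolve("degree")

    def corrected(lat):
        return build_core_object(
            inst.core_types.get("Well"),
            {
                "name": old.get("name"),
                "biome": old.field_values["biome"].scalar_value(),
                "latitude": (lat, deg),
                "longitude": (old.get("longitude"), deg),
            },
            inst.microtypes,
        )

    b_id = store.supersede("Well:0000002", corrected(36.0))
    c_id = store.supersede(b_id, corrected(36.5))
    # all three versions retrievable; only the last is live
    assert store.get("Well:0000002").superseded_by == b_id
    assert store.get(b_id).superseded_by == c_id
    assert store.get(c_id).superseded_by is None
    assert store.resolve_lineage("Well:0000002") == c_id
    live_names = [w.get("name") for w in store.objects("Well")]
    assert live_names.count(old.get("name")) == 1
    with pytest.raises(StoreError, match="already superseded"):
        store.supersede("Well:0000002", corrected(37.0))


def test_ancestors_match_bfs_oracle(inst):
    store = inst.store
    edges = raw_edges(store)
    for oid in ("Brick:0000001", "Brick:0000002", "Sample:0000003", "Well:0000001"):
        got = set(store.provenance_ancestors(oid).nodes)
        assert got == bfs_reachable(edges, oid, reverse=True)
    # derived brick: ancestors span origin brick, process, samples, wells
    fit = store.get("Brick:0000001")
    derived = bs.aggregate_dimension(fit, 2, "mean")
    did = store.register_object(
        derived,
        ProcessSpec(
            process_term=inst.terms.resolve("computational analysis"),
            person="alice",
            input_ids=(fit.brick_id,),
        ),
    )
    anc = set(store.provenance_ancestors(did).nodes)
    assert fit.brick_id in anc
    assert any(n.startswith("Sample:") for n in anc)
    assert any(n.startswith("Well:") for n in anc)
    assert anc == bfs_reachable(raw_edges(store), did, reverse=True)


def test_descendants_match_reverse_bfs_oracle(inst):
    store = inst.store
    edges = raw_edges(store)
    for oid in ("Well:0000001", "Sample:0000001"):
        got = set(store.provenance_descendants(oid).nodes)
        assert got == bfs_reachable(edges, oid, reverse=False)


def test_carbohydrate_search_finds_glucose_data(inst):
    """Ancestor expansion: searching the parent term finds child-term data."""
    hits = inst.store.search(
        [{"kind": "term_value", "term": "carbohydrate", "expand": True}]
    )
    # fitness (glucose/sucrose media) and geochemistry (glucose analyte)
    assert hits == ["Brick:0000001", "Brick:0000002"]
    # without expansion the exact parent term matches nothing
    assert (
        inst.store.search([{"kind": "term_value", "term": "carbohydrate"}]) == []
    )


def test_search_on_empty_store(inst):
    from brickstore.core_types import CoreTypeRegistry
    from brickstore.store import ProvenanceStore

    empty = ProvenanceStore(inst.core_types)
    assert empty.search([{"kind": "term_value", "term": "carbohydrate", "expand": True}]) == []


def test_person_and_derivation_predicates(inst):
    store = inst.store
    # everything downstream of bob's geochemical assay
    hits = store.search([{"kind": "person", "name": "bob"}])
    assert "Brick:0000002" in hits
    hits = store.search([{"kind": "derived_from", "id": "Well:0000001"}])
    assert "Sample:0000001" in hits
    hits = store.search(
        [{"kind": "process_term", "term": "assay", "expand": True},
         {"kind": "data_category", "term": "geochemistry data"}]
    )
    assert hits == ["Brick:0000002"]


# -- search vs linear-scan oracle -------------------------------------------


def _object_term_values(store, obj, mt_id=None):
    vals = set()
    for c, _ in store.iter_context(obj):
        if c.microtype.scalar_type != "oterm_ref":
            continue
        if mt_id is not None and c.microtype.id != mt_id:
            continue
        for _, v in c.iter_values():
            if v is not None:
                vals.add(v)
    return vals


def linear_scan(store, inst, query):
    edges = raw_edges(store)
    out = []
    for obj in store.objects(live_only=True):
        oid = store._id_of(obj)
        ok = True
        for p in query:
            kind = p["kind"]
            if kind == "term_value":
                ids = {
                    t.id
                    for t in (
                        inst.terms.expand(inst.terms.resolve(p["term"]))
                        if p.get("expand")
                        else [inst.terms.resolve(p["term"])]
                    )
                }
                mt_id = (
                    inst.microtypes.get(p["microtype"]).id
                    if p.get("microtype")
                    else None
                )
                ok = bool(_object_term_values(store, obj, mt_id) & ids)
            elif kind == "value_compare":
                import operator

                op = {
                    "==": operator.eq, "!=": operator.ne, "<": operator.lt,
                    "<=": operator.le, ">": operator.gt, ">=": operator.ge,
                }[p["op"]]
                mt_id = inst.microtypes.get(p["microtype"]).id
                vals = []
                for c, _ in store.iter_context(obj):
                    if c.microtype.id == mt_id:
                        vals += [v for _, v in c.iter_values() if v is not None]
                ok = any(op(v, p["value"]) for v in vals)
            elif kind == "data_category":
                ids = {
                    t.id
                    for t in (
                        inst.terms.expand(inst.terms.resolve(p["term"]))
                        if p.get("expand")
                        else [inst.terms.resolve(p["term"])]
                    )
                }
                ok = isinstance(obj, bs.DataBrick) and obj.data_category.id in ids
            elif kind == "type_name":
                ok = store._type_of(obj) == p["name"]
            elif kind == "has_microtype":
                mt_id = inst.microtypes.get(p["microtype"]).id
                ok = any(
                    c.microtype.id == mt_id for c, _ in store.iter_context(obj)
                )
            elif kind == "derived_from":
                ok = p["id"] != oid and p["id"] in bfs_reachable(
                    edges, oid, reverse=True
                )
            elif kind == "person":
                anc = bfs_reachable(edges, oid, reverse=True)
                ok = any(
                    pr.id in anc and pr.person == p["name"]
                    for pr in store.processes()
                )
            elif kind == "process_term":
                ids = {
                    t.id
                    for t in (
                        inst.terms.expand(inst.terms.resolve(p["term"]))
                        if p.get("expand")
                        else [inst.terms.resolve(p["term"])]
                    )
                }
                anc = bfs_reachable(edges, oid, reverse=True)
                ok = any(
                    pr.id in anc and pr.process_term.id in ids
                    for pr in store.processes()
                )
            if not ok:
                break
        if ok:
            out.append(oid)
    return sorted(out)


def random_query(rng, inst, store):
    terms = ["carbohydrate", "glucose", "nitrate", "chemical entity", "biome",
             "terrestrial biome", "EX:0000012"]
    people = ["alice", "bob", "carol", "nobody"]
    ids = [store._id_of(o) for o in store.objects(live_only=False)]

    def one():
        kind = int(rng.integers(0, 7))
        if kind == 0:
            return {
                "kind": "term_value",
                "term": terms[int(rng.integers(0, len(terms)))],
                "expand": bool(rng.integers(0, 2)),
            }
        if kind == 1:
            return {
                "kind": "value_compare",
                "microtype": ["fitness", "concentration", "latitude"][int(rng.integers(0, 3))],
                "op": ["<", "<=", ">", ">=", "==", "!="][int(rng.integers(0, 6))],
                "value": round(float(rng.uniform(-2, 4)), 3),
            }
        if kind == 2:
            return {
                "kind": "data_category",
                "term": ["data category", "fitness data", "geochemistry data"][int(rng.integers(0, 3))],
                "expand": bool(rng.integers(0, 2)),
            }
        if kind == 3:
            return {"kind": "type_name", "name": ["Well", "Sample", "Gene", "Brick"][int(rng.integers(0, 4))]}
        if kind == 4:
            return {"kind": "has_microtype", "microtype": ["gene", "sample", "EX:0000204", "depth"][int(rng.integers(0, 4))]}
        if kind == 5:
            return {"kind": "person", "name": people[int(rng.integers(0, 4))]}
        return {"kind": "derived_from", "id": ids[int(rng.integers(0, len(ids)))]}

    return [one() for _ in range(int(rng.integers(1, 3)))]


def test_search_matches_linear_scan_oracle(inst):
    rng = np.random.default_rng(21)
    store = inst.store
    for _ in range(40):
        q = random_query(rng, inst, store)
        assert store.search(q) == linear_scan(store, inst, q), q


# -- dynamic joins -----------------------------------------------------------


def test_one_hop_join_matches_lookup_oracle(inst):
    store = inst.store
    geo = store.get("Brick:0000002")
    joined = dynamic_join(store, geo, 0, 0, ["depth"])
    depth_var = joined.dims[0].variables[-1]
    assert depth_var.microtype.name == "depth"
    ref = geo.dims[0].variables[0]
    for i in range(geo.dims[0].size):
        sample = store.resolve_pk("Sample", ref.value_at((i,)))
        assert depth_var.value_at((i,)) == sample.get("depth")
    # shape preserved, only variables added
    assert joined.shape == geo.shape
    assert joined.session.ops[-1][0] == "join"


def test_two_hop_join_brings_in_well_coordinates(inst):
    store = inst.store
    geo = store.get("Brick:0000002")
    joined = dynamic_join(
        store, geo, 0, 0, ["depth"], then=("well", ["latitude", "longitude"])
    )
    labels = [v.microtype.name for v in joined.dims[0].variables]
    assert labels == ["sample", "depth", "latitude", "longitude"]
    ref = geo.dims[0].variables[0]
    lat_var = joined.dims[0].variables[2]
    for i in range(geo.dims[0].size):
        sample = store.resolve_pk("Sample", ref.value_at((i,)))
        well = store.resolve_pk("Well", sample.get("well"))
        assert lat_var.value_at((i,)) == well.get("latitude")


def test_zero_field_join_only_records_session(inst):
    store = inst.store
    geo = store.get("Brick:0000002")
    joined = dynamic_join(store, geo, 0, 0, [])
    assert joined.dims[0].variables == geo.dims[0].variables
    assert joined.value_sets == geo.value_sets
    assert joined.session.ops[-1][0] == "join"


def test_join_through_non_ref_variable_rejected(inst):
    store = inst.store
    geo = store.get("Brick:0000002")
    with pytest.raises(StoreError, match="not an object reference"):
        dynamic_join(store, geo, 1, 0, ["depth"])  # analyte axis: oterm var
    with pytest.raises(StoreError, match="no field"):
        dynamic_join(store, geo, 0, 0, ["no_such_field"])
    with pytest.raises(StoreError, match="object_ref field"):
        dynamic_join(store, geo, 0, 0, [], then=("depth", ["latitude"]))


def test_registration_sequence_preserves_invariants(inst):
    """Random registrations + supersessions keep the graph acyclic,
    anchored, and fully retrievable."""
    import networkx as nx

    rng = np.random.default_rng(33)
    store = inst.store
    all_ids = [store._id_of(o) for o in store.objects(live_only=False)]
    for i in range(20):
        move = rng.random()
        if move < 0.5:
            b = random_brick(rng, inst, f"seq-{i}")
            inputs = tuple(
                rng.choice(all_ids, size=min(2, len(all_ids)), replace=False)
            )
            bid = store.register_object(
                b,
                ProcessSpec(
                    process_term=inst.terms.resolve("assay"),
                    person="alice",
                    input_ids=inputs,
                ),
            )
            all_ids.append(bid)
        else:
            gene = create_core_object(
                store, inst.core_types.get("Gene"), {"name": f"G9{i:03d}"}
            )
            all_ids.append(gene.id)
    assert nx.is_directed_acyclic_graph(store._graph)
    assert_anchored(store)
    for oid in all_ids:
        store.get(oid)  # every historical id retrievable
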