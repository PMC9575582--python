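"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
hierarchy closure is a hand-rolled BFS over the parent table, brick
flattening is a nested loop over raw arrays, search is a linear scan over
flattened context, and provenance reachability is a BFS over the raw edge
list.
"""

from __future__ import annotations

import numpy as np
import pytest

import brickstore as bs
from brickstore.bricks import DataBrick, DimensionSpec, build_brick
from brickstore.contextons import make_contexton
from brickstore.fixtures import generate_fixture


@pytest.fixture()
def inst():
    """A fresh miniature instance (small gene catalog for speed)."""
    return generate_fixture(1, sizes={"genes": 30})


@pytest.fixture()
def store(inst):
    return inst.store


# ---------------------------------------------------------------------------
# independent oracles


def bfs_descendants(parent_pairs, root):
    """Closure of the child relation from explicit (child, parent) pairs."""
    children = {}
    for child, parent in parent_pairs:
        children.setdefault(parent, set()).add(child)
    seen = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for node in frontier:
            for c in children.get(node, ()):
                if c not in seen:
                    seen.add(c)
                    nxt.append(c)
        frontier = nxt
    return seen


def nested_loop_points(brick: DataBrick):
    """Flatten a brick by explicit nested loops over the raw arrays."""
    records = []
    shape = [d.size for d in brick.dims]

    def rec(coord):
        if len(coord) == len(shape):
            ctx = []
            for c in brick.overall_context:
                ctx.append((_okey(c), c.value_at(())))
            for axis, d in enumerate(brick.dims):
                for v in d.variables:
                    ctx.append((_okey(v), v.value_at((coord[axis],))))
            for vs in brick.value_sets:
                records.append(
                    (
                        frozenset(ctx),
                        vs.microtype.id,
                        vs.unit.id if vs.unit else None,
                        vs.value_at(tuple(coord)),
                        bool(vs.mask[tuple(coord)]),
                    )
                )
            return
        for i in range(shape[len(coord)]):
            rec(coord + [i])

    rec([])
    return records


def _okey(c):
    mods = tuple(
        sorted(
            (m.microtype.id, m.unit.id if m.unit else None, m.scalar_value())
            for m in c.modifiers
        )
    )
    return (c.microtype.id, c.unit.id if c.unit else None, mods)


def bfs_reachable(edges, target, reverse=True):
    """Node set reaching (reverse) or reachable from (forward) target,
    computed from a raw (src, dst) edge list."""
    adj = {}
    for src, dst in edges:
        if reverse:
            adj.setdefault(dst, set()).add(src)
        else:
            adj.setdefault(src, set()).add(dst)
    seen = {target}
    frontier = [target]
    while frontier:
        nxt = []
        for n in frontier:
            for m in adj.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    nxt.append(m)
        frontier = nxt
    return seen


# ---------------------------------------------------------------------------
# randomized brick construction (within the fixture instance's language)


def random_brick(rng: np.random.Generator, inst, name: str, max_dims=3, max_size=4):
    """A random valid brick built from the fixture instance's microtypes.

    Mixes float/int/string/oterm dimension variables, 1-2 float value
    sets with ~10% nulls, and an optional overall-context contexton.
    """
    t = inst.terms.resolve
    reg = inst.microtypes

    def ctx(mt_name, values, unit=None):
        return make_contexton(
            reg.get(mt_name), values, unit=unit, ontologies=inst.terms
        )

    ndim = int(rng.integers(1, max_dims + 1))
    sizes = [int(rng.integers(1, max_size + 1)) for _ in range(ndim)]
    dim_kinds = [
        ("strain series", "strain name", lambda n: [f"s{rng.integers(0, 50)}-{i}" for i in range(n)]),
        ("time series", "EX:0000204", lambda n: [round(float(x), 4) for x in sorted(rng.uniform(0, 24, n))]),
        ("replicate series", "replicate number", lambda n: list(range(1, n + 1))),
        ("analyte series", "molecule", lambda n: [
            ["EX:0000012", "EX:0000013", "EX:0000014", "EX:0000015"][int(rng.integers(0, 4))]
            for _ in range(n)
        ]),
    ]
    dims = []
    for ax, n in enumerate(sizes):
        kind = dim_kinds[int(rng.integers(0, len(dim_kinds)))]
        unit = t("EXU:0000011") if kind[1] == "EX:0000204" else None
        dims.append(
            DimensionSpec(t(kind[0]), n, (ctx(kind[1], kind[2](n), unit),))
        )
    nvs = int(rng.integers(1, 3))
    value_sets = []
    for _ in range(nvs):
        vals = rng.normal(0, 1, size=tuple(sizes)).round(6).astype(object)
        nulls = rng.random(tuple(sizes)) < 0.1
        vals[nulls] = None
        value_sets.append(ctx("EX:0000201", vals))
    overall = ()
    if rng.random() < 0.5:
        overall = (ctx("temperature", round(float(rng.uniform(4, 37)), 2), t("degree Celsius")),)
    return build_brick(
        name,
        t("fitness data"),
        dims,
        value_sets,
        overall,
        system=inst.require_system(),
        registry=reg,
    )
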