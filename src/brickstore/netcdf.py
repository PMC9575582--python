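"""NetCDF-4 export/import for numeric bricks.

NetCDF-4 is a constrained profile of HDF5 (named dimensions are HDF5
dimension scales; attributes are plain HDF5 attributes), so the codec is
written directly against :mod:`h5py` and produces files any NetCDF-4
reader can open.  The canonical on-disk form of a brick is the JSON
dialect (see :func:`brickstore.bricks.serialize_brick`); NetCDF-4 is an
interchange codec for bricks whose value sets are numeric — string or
term-valued value sets do not map cleanly onto NetCDF variables.

Layout: one file per brick.  Global attributes ``bs_brick_name``,
``bs_data_category`` (CURIE), ``bs_id``, ``bs_session`` and
``bs_overall_context`` (JSON).  Each dimension ``i`` is a scale dataset
``dim<i>`` with attribute ``bs_dim_type``; each dimension variable is a
1-D dataset ``dim<i>_var<j>`` and each value set an N-D dataset
``values<k>``, all carrying ``bs_microtype`` and ``bs_unit`` (CURIEs) and
``bs_modifiers`` (JSON).  Null masks are companion ``<name>__mask``
datasets (1 = missing).
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .bricks import DataBrick, DimensionSpec, SessionProvenance, validate_brick
from .contextons import Contexton, make_contexton
from .errors import BrickError
from .microtypes import MicrotypeRegistry, NUMERIC_KINDS, ScalarKind

__all__ = ["export_netcdf", "import_netcdf"]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_contexton(f: h5py.File, name: str, c: Contexton) -> h5py.Dataset:
    kind = c.microtype.scalar_type
    if kind == ScalarKind.FLOAT:
        data = np.where(c.mask, np.nan, c.values.astype(np.float64))
        ds = f.create_dataset(name, data=data)
    elif kind == ScalarKind.INT:
        ds = f.create_dataset(name, data=np.where(c.mask, 0, c.values))
    elif kind == ScalarKind.BOOLEAN:
        data = np.vectorize(lambda v: 1 if v else 0, otypes=[np.int8])(
            np.where(c.mask, False, c.values)
        )
        ds = f.create_dataset(name, data=data.astype(np.int8))
    else:  # string / oterm_ref / object_ref as vlen UTF-8
        flat = np.array(
            ["" if v is None else str(v) for _, v in c.iter_values()], dtype=object
        ).reshape(c.values.shape)
        ds = f.create_dataset(name, shape=c.values.shape, dtype=_STR)
        ds[...] = flat
    ds.attrs["bs_microtype"] = c.microtype.id
    ds.attrs["bs_unit"] = c.unit.id if c.unit else ""
    ds.attrs["bs_modifiers"] = json.dumps([m.to_doc() for m in c.modifiers])
    if c.mask.any():
        f.create_dataset(name + "__mask", data=c.mask.astype(np.int8))
    return ds


def _read_contexton(f: h5py.File, name: str, registry: MicrotypeRegistry) -> Contexton:
    ds = f[name]
    mt = registry.get(ds.attrs["bs_microtype"])
    unit_id = ds.attrs["bs_unit"]
    unit = registry.term_index.get(unit_id) if unit_id else None
    modifiers = tuple(
        Contexton.from_doc(m, registry)
        for m in json.loads(ds.attrs["bs_modifiers"])
    )
    raw = ds[...]
    mask = (
        f[name + "__mask"][...].astype(bool)
        if name + "__mask" in f
        else np.zeros(raw.shape, dtype=bool)
    )
    kind = mt.scalar_type
    values = np.empty(raw.shape, dtype=object)
    for idx in np.ndindex(raw.shape):
        if mask[idx]:
            values[idx] = None
            continue
        v = raw[idx]
        if kind == ScalarKind.FLOAT:
            values[idx] = float(v)
        elif kind == ScalarKind.INT:
            values[idx] = int(v)
        elif kind == ScalarKind.BOOLEAN:
            values[idx] = bool(v)
        else:
            values[idx] = v.decode("utf-8") if isinstance(v, bytes) else str(v)
    return make_contexton(
        mt, values, unit=unit, modifiers=modifiers, ontologies=registry.term_index
    )


def export_netcdf(brick: DataBrick, path) -> None:
    """Write a numeric brick as a NetCDF-4 (HDF5) file."""
    for vs in brick.value_sets:
        if vs.microtype.scalar_type not in NUMERIC_KINDS:
            raise BrickError(
                f"value set {vs.microtype.name!r} is not numeric; NetCDF-4 "
                "export handles numeric value sets only (use the JSON form)"
            )
    with h5py.File(path, "w") as f:
        f.attrs["bs_format_version"] = 1
        f.attrs["bs_brick_name"] = brick.name
        f.attrs["bs_data_category"] = brick.data_category.id
        f.attrs["bs_id"] = brick.brick_id or ""
        f.attrs["bs_session"] = json.dumps(brick.session.to_doc())
        f.attrs["bs_overall_context"] = json.dumps(
            [c.to_doc() for c in brick.overall_context]
        )
        f.attrs["bs_ndim"] = len(brick.dims)
        scales = []
        for i, d in enumerate(brick.dims):
            sd = f.create_dataset(f"dim{i}", data=np.arange(d.size, dtype=np.int64))
            sd.attrs["bs_dim_type"] = d.dim_type.id
            sd.attrs["bs_nvars"] = len(d.variables)
            sd.make_scale(f"dim{i}")
            scales.append(sd)
            for j, v in enumerate(d.variables):
                vd = _write_contexton(f, f"dim{i}_var{j}", v)
                vd.dims[0].attach_scale(sd)
        f.attrs["bs_nvalues"] = len(brick.value_sets)
        for k, vs in enumerate(brick.value_sets):
            vd = _write_contexton(f, f"values{k}", vs)
            for ax, sd in enumerate(scales):
                vd.dims[ax].attach_scale(sd)


def import_netcdf(path, registry: MicrotypeRegistry) -> DataBrick:
    """Load a brick previously written by :func:`export_netcdf`."""
    with h5py.File(path, "r") as f:
        name = f.attrs["bs_brick_name"]
        if not name:
            raise BrickError("file lacks the mandatory Brick Name")
        index = registry.term_index
        dims = []
        for i in range(int(f.attrs["bs_ndim"])):
            sd = f[f"dim{i}"]
            nvars = int(sd.attrs["bs_nvars"])
            variables = tuple(
                _read_contexton(f, f"dim{i}_var{j}", registry) for j in range(nvars)
            )
            dims.append(
                DimensionSpec(
                    dim_type=index.get(sd.attrs["bs_dim_type"]),
                    size=sd.shape[0],
                    variables=variables,
                )
            )
        value_sets = tuple(
            _read_contexton(f, f"values{k}", registry)
            for k in range(int(f.attrs["bs_nvalues"]))
        )
        brick = DataBrick(
            name=str(name),
            data_category=index.get(f.attrs["bs_data_category"]),
            dims=tuple(dims),
            value_sets=value_sets,
            overall_context=tuple(
                Contexton.from_doc(c, registry)
                for c in json.loads(f.attrs["bs_overall_context"])
            ),
            session=SessionProvenance.from_doc(json.loads(f.attrs["bs_session"])),
            brick_id=str(f.attrs["bs_id"]) or None,
        )
    rep = validate_brick(brick, registry)
    if not rep.ok:
        raise BrickError(f"imported brick {brick.name!r} is invalid: {rep!r}")
    return brick
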