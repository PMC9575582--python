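"""File-backed document store plus the directed provenance graph.

Every data object — core object or brick — gets a permanent identifier
(``<TypeName>:<zero-padded counter>``) when registered, and is never
deleted: corrections *supersede* the old version under a fresh id, and
every historical id stays retrievable.  Objects and process records form
a directed acyclic graph (inputs -> process -> outputs, plus reference
edges from referenced core objects), and every live object must be
*anchored*: reachable from the static backbone either through object
references or through a process whose inputs are already in the store.
Isolated "data islands" are rejected at registration.

The store also serves ancestor-expanded context search and dynamic joins
(merging fields of referenced core objects into a brick as new dimension
variables, optionally across a second reference hop).

On disk an instance is one JSON document per object under ``objects/``
and ``processes/``, an append-only edge log, and a counter file; writes
are write-then-rename, single-writer / multi-reader.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx

from . import bricks as _bricks
from .bricks import (
    DataBrick,
    DimensionSpec,
    SessionProvenance,
    deserialize_brick,
    serialize_brick,
    validate_brick,
)
from .contextons import Contexton, make_contexton
from .core_types import CoreObject, CoreTypeDef, CoreTypeRegistry, build_core_object
from .errors import DuplicateNameError, StoreError
from .microtypes import MicrotypeRegistry, ScalarKind
from .ontology import Term

__all__ = [
    "ProcessSpec",
    "ProcessRecord",
    "ProvenanceStore",
    "create_core_object",
    "dynamic_join",
]

BRICK_TYPE = "Brick"
PROCESS_TYPE = "Process"


@dataclass(frozen=True)
class ProcessSpec:
    """User-supplied description of the process that produced an object."""

    process_term: Term
    person: str
    campaign: str | None = None
    lab: str | None = None
    date: str | None = None  # ISO date
    input_ids: tuple[str, ...] = ()
    parameters: Mapping[str, Any] = field(default_factory=dict)


@dataclass
class ProcessRecord:
    """A stored process: the labeled edge bundle of the provenance graph."""

    id: str
    process_term: Term
    person: str
    input_ids: tuple[str, ...]
    output_ids: tuple[str, ...]
    campaign: str | None = None
    lab: str | None = None
    date: str | None = None
    parameters: Mapping[str, Any] = field(default_factory=dict)

    def to_doc(self) -> dict:
        return {
            "kind": "process",
            "id": self.id,
            "process_term": self.process_term.id,
            "person": self.person,
            "campaign": self.campaign,
            "lab": self.lab,
            "date": self.date,
            "input_ids": list(self.input_ids),
            "output_ids": list(self.output_ids),
            "parameters": dict(self.parameters),
        }


class ProvenanceStore:
    """See module docstring.  ``root=None`` keeps everything in memory."""

    def __init__(
        self,
        core_types: CoreTypeRegistry,
        root: str | Path | None = None,
    ):
        self.core_types = core_types
        self.registry: MicrotypeRegistry = core_types.microtypes
        self.root = Path(root) if root is not None else None
        self._objects: dict[str, Any] = {}
        self._processes: dict[str, ProcessRecord] = {}
        #: append-only raw edge table (src, dst, kind); the graph is built
        #: from it and it is what edges.jsonl persists
        self.edge_log: list[tuple[str, str, str]] = []
        self._graph = nx.DiGraph()
        self._counters: dict[str, int] = {}
        self._pk_index: dict[tuple[str, str], str] = {}  # (type, pk) -> live id
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)
            self._load()

    # -- identifiers -------------------------------------------------------
    def _next_id(self, prefix: str) -> str:
        n = self._counters.get(prefix, 0) + 1
        self._counters[prefix] = n
        return f"{prefix}:{n:07d}"

    # -- retrieval ---------------------------------------------------------
    def __contains__(self, obj_id: str) -> bool:
        return obj_id in self._objects or obj_id in self._processes

    def get(self, obj_id: str):
        """Any version of any object (or process record) by permanent id."""
        if obj_id in self._objects:
            return self._objects[obj_id]
        if obj_id in self._processes:
            return self._processes[obj_id]
        raise StoreError(f"unknown id {obj_id!r}")

    def objects(self, type_name: str | None = None, live_only: bool = True):
        for o in self._objects.values():
            if live_only and not self._is_live(o):
                continue
            if type_name is not None and self._type_of(o) != type_name:
                continue
            yield o

    def processes(self) -> Iterable[ProcessRecord]:
        return self._processes.values()

    @staticmethod
    def _type_of(obj) -> str:
        return BRICK_TYPE if isinstance(obj, DataBrick) else obj.type_name

    @staticmethod
    def _id_of(obj) -> str | None:
        return obj.brick_id if isinstance(obj, DataBrick) else obj.id

    def _is_live(self, obj) -> bool:
        if isinstance(obj, DataBrick):
            return obj.brick_id not in self._brick_superseded
        return obj.superseded_by is None

    def resolve_pk(self, type_name: str, pk: str):
        """Live object of a core type by its primary-key name, or None."""
        obj_id = self._pk_index.get((type_name, pk))
        return self._objects.get(obj_id) if obj_id else None

    def resolve_lineage(self, obj_id: str) -> str:
        """Follow superseded_by pointers to the live end of the lineage."""
        seen = set()
        current = obj_id
        while True:
            obj = self.get(current)
            if isinstance(obj, DataBrick):
                nxt = self._brick_superseded.get(current)
            else:
                nxt = getattr(obj, "superseded_by", None)
            if nxt is None:
                return current
            if nxt in seen:
                raise StoreError(f"supersession cycle at {nxt!r}")
            seen.add(nxt)
            current = nxt

    # -- reference extraction ----------------------------------------------
    def _iter_contextons(self, obj) -> Iterable[Contexton]:
        if isinstance(obj, DataBrick):
            for d in obj.dims:
                yield from d.variables
            yield from obj.value_sets
            yield from obj.overall_context
        else:
            yield from obj.field_values.values()

    def iter_context(self, obj, include_modifiers: bool = True):
        """All contextons of an object; modifiers flagged with their primary."""
        for c in self._iter_contextons(obj):
            yield c, None
            if include_modifiers:
                for m in c.modifiers:
                    yield m, c

    def _referenced_ids(self, obj) -> set[str]:
        out: set[str] = set()
        for c, _ in self.iter_context(obj):
            if c.microtype.scalar_type != ScalarKind.OBJECT_REF:
                continue
            target = c.microtype.ref_target
            for _, v in c.iter_values():
                if v is None:
                    continue
                hit = self.resolve_pk(target, v)
                if hit is None:
                    raise StoreError(
                        f"dangling reference: no live {target} named {v!r}"
                    )
                out.add(self._id_of(hit))
        return out

    # -- registration ------------------------------------------------------
    def register_object(
        self,
        obj: "CoreObject | DataBrick",
        process: ProcessSpec | None = None,
    ) -> str:
        """Validate, anchor, assign a permanent id, and record provenance.

        Bricks must reference the backbone or arrive with a process whose
        inputs are existing objects; core objects without inputs are
        accepted as backbone roots.
        """
        is_brick = isinstance(obj, DataBrick)
        if is_brick:
            if obj.brick_id is not None:
                raise StoreError(f"brick already registered as {obj.brick_id}")
            report = validate_brick(obj, self.registry, store=self)
            if not report.ok:
                raise StoreError(f"brick {obj.name!r} failed validation: {report!r}")
            refs = self._referenced_ids(obj)
        else:
            if obj.id is not None:
                raise StoreError(f"object already registered as {obj.id}")
            typedef = self.core_types.get(obj.type_name)
            self._validate_core(obj, typedef)
            refs = self._referenced_ids(obj)

        if process is not None:
            for iid in process.input_ids:
                if iid not in self._objects:
                    raise StoreError(f"process input {iid!r} not in store")

        if is_brick and not refs and not (process and process.input_ids):
            raise StoreError(
                f"brick {obj.name!r} is an isolated data island: it neither "
                "references core objects nor derives from existing objects"
            )

        type_name = self._type_of(obj)
        obj_id = self._next_id(type_name)
        if is_brick:
            obj = replace(obj, brick_id=obj_id)
        else:
            obj.id = obj_id
            typedef = self.core_types.get(obj.type_name)
            self._pk_index[(obj.type_name, obj.pk(typedef))] = obj_id
        self._objects[obj_id] = obj
        self._graph.add_node(obj_id, kind="object", type=type_name)

        edges = [(r, obj_id, "reference") for r in sorted(refs)]
        proc_rec = None
        if process is not None:
            pid = self._next_id(PROCESS_TYPE)
            proc_rec = ProcessRecord(
                id=pid,
                process_term=process.process_term,
                person=process.person,
                campaign=process.campaign,
                lab=process.lab,
                date=process.date,
                input_ids=tuple(process.input_ids),
                output_ids=(obj_id,),
                parameters=dict(process.parameters),
            )
            self._processes[pid] = proc_rec
            self._graph.add_node(pid, kind="process")
            edges += [(iid, pid, "input") for iid in process.input_ids]
            edges.append((pid, obj_id, "output"))
        for src, dst, kind in edges:
            self._graph.add_edge(src, dst, kind=kind)
        self.edge_log.extend(edges)

        if not nx.is_directed_acyclic_graph(self._graph):
            raise StoreError("registration would create a provenance cycle")

        self._persist(obj, proc_rec, edges)
        return obj_id

    def _validate_core(self, obj: CoreObject, typedef: CoreTypeDef) -> None:
        for f in typedef.required_fields():
            if f.name not in obj.field_values:
                raise StoreError(f"missing required field {f.name!r}")
        for name, c in obj.field_values.items():
            if not c.is_scalar:
                raise StoreError(f"field {name!r} is not a scalar contexton")
            bad = c.revalidate(self.registry.term_index)
            if bad:
                raise StoreError(
                    f"field {name!r} fails self-validation: "
                    + "; ".join(",".join(r.reasons) for _, r in bad)
                )
        pk = obj.pk(typedef)
        if (obj.type_name, pk) in self._pk_index:
            raise DuplicateNameError(
                f"a live {obj.type_name} named {pk!r} already exists"
            )

    def supersede(
        self,
        old_id: str,
        new_object: "CoreObject | DataBrick",
        process: ProcessSpec | None = None,
    ) -> str:
        """Replace a live object with a corrected version under a new id.

        The old object stays retrievable by its id, flagged with
        ``superseded_by``.
        """
        old = self.get(old_id)
        if isinstance(old, ProcessRecord):
            raise StoreError("processes cannot be superseded")
        if getattr(old, "superseded_by", None) is not None:
            raise StoreError(f"{old_id} is already superseded")
        if isinstance(old, CoreObject):
            typedef = self.core_types.get(old.type_name)
            # free the pk slot so the replacement (often same pk) can register
            self._pk_index.pop((old.type_name, old.pk(typedef)), None)
        try:
            new_id = self.register_object(new_object, process)
        except Exception:
            if isinstance(old, CoreObject):
                typedef = self.core_types.get(old.type_name)
                self._pk_index[(old.type_name, old.pk(typedef))] = old_id
            raise
        if isinstance(old, DataBrick):
            # DataBrick is frozen and has no superseded_by field; brick
            # lineage lives in a side table rebuilt from the edge log
            self._brick_superseded[old_id] = new_id
        else:
            old.superseded_by = new_id
            self._persist(old, None, [])
        self._graph.add_edge(old_id, new_id, kind="superseded_by")
        self.edge_log.append((old_id, new_id, "superseded_by"))
        self._append_edges([(old_id, new_id, "superseded_by")])
        return new_id

    # bricks are frozen dataclasses without superseded_by; lineage for
    # bricks lives in this side table (persisted with the edge log)
    @property
    def _brick_superseded(self) -> dict[str, str]:
        if not hasattr(self, "_brick_superseded_tbl"):
            self._brick_superseded_tbl: dict[str, str] = {}
        return self._brick_superseded_tbl

    # -- provenance queries --------------------------------------------------
    def provenance_ancestors(self, obj_id: str) -> nx.DiGraph:
        """Subgraph of everything on directed paths *into* the object."""
        if obj_id not in self._graph:
            raise StoreError(f"unknown id {obj_id!r}")
        nodes = nx.ancestors(self._graph, obj_id) | {obj_id}
        return self._graph.subgraph(nodes).copy()

    def provenance_descendants(self, obj_id: str) -> nx.DiGraph:
        if obj_id not in self._graph:
            raise StoreError(f"unknown id {obj_id!r}")
        nodes = nx.descendants(self._graph, obj_id) | {obj_id}
        return self._graph.subgraph(nodes).copy()

    def to_dot(self, graph: nx.DiGraph | None = None) -> str:
        """DOT export of the provenance graph (for graph overviews)."""
        g = graph if graph is not None else self._graph
        lines = ["digraph provenance {"]
        for n, data in g.nodes(data=True):
            shape = "box" if data.get("kind") == "process" else "ellipse"
            lines.append(f'  "{n}" [shape={shape}];')
        for u, v, data in g.edges(data=True):
            lines.append(f'  "{u}" -> "{v}" [label="{data.get("kind","")}"];')
        lines.append("}")
        return "\n".join(lines)

    # -- search --------------------------------------------------------------
    def search(self, query: Sequence[Mapping[str, Any]]) -> list[str]:
        """Conjunction of predicates over live objects; returns sorted ids.

        Predicate dictionaries (``kind`` selects the predicate):

        - ``data_category``: ``term`` (+ ``expand``) — bricks whose category
          matches the term or, expanded, any descendant.
        - ``type_name``: ``name`` — core objects of that type (or "Brick").
        - ``has_microtype``: ``microtype`` — some contexton (modifiers
          included) uses the microtype.
        - ``term_value``: ``term`` (+ ``expand``, optional ``microtype``) —
          some term-valued contexton value matches.
        - ``value_compare``: ``microtype``, ``op`` in ==,!=,<,<=,>,>=,
          ``value`` — some non-null value of that microtype compares true.
        - ``derived_from``: ``id`` — the object has that id among its
          provenance ancestors.
        - ``person``: ``name`` — some ancestor process was performed by them.
        - ``process_term``: ``term`` (+ ``expand``) — some ancestor process
          has a matching process type term.
        """
        preds = [self._compile_predicate(p) for p in query]
        out = []
        for obj in self.objects(live_only=True):
            obj_id = self._id_of(obj)
            if all(p(obj, obj_id) for p in preds):
                out.append(obj_id)
        return sorted(out)

    def _term_ids(self, term_query: str, expand: bool) -> set[str]:
        term = self.registry.term_index.resolve(term_query)
        if not expand:
            return {term.id}
        return {t.id for t in self.registry.term_index.expand(term)}

    def _compile_predicate(self, p: Mapping[str, Any]):
        kind = p.get("kind")
        index = self.registry.term_index

        if kind == "data_category":
            ids = self._term_ids(p["term"], bool(p.get("expand", False)))
            return lambda obj, oid: (
                isinstance(obj, DataBrick) and obj.data_category.id in ids
            )

        if kind == "type_name":
            name = p["name"]
            return lambda obj, oid: self._type_of(obj) == name

        if kind == "has_microtype":
            mt_id = self.registry.get(p["microtype"]).id
            return lambda obj, oid: any(
                c.microtype.id == mt_id for c, _ in self.iter_context(obj)
            )

        if kind == "term_value":
            ids = self._term_ids(p["term"], bool(p.get("expand", False)))
            mt_id = (
                self.registry.get(p["microtype"]).id if p.get("microtype") else None
            )

            def pred(obj, oid):
                for c, _ in self.iter_context(obj):
                    if c.microtype.scalar_type != ScalarKind.OTERM_REF:
                        continue
                    if mt_id is not None and c.microtype.id != mt_id:
                        continue
                    for _, v in c.iter_values():
                        if v is not None and v in ids:
                            return True
                return False

            return pred

        if kind == "value_compare":
            import operator

            ops = {
                "==": operator.eq,
                "!=": operator.ne,
                "<": operator.lt,
                "<=": operator.le,
                ">": operator.gt,
                ">=": operator.ge,
            }
            if p["op"] not in ops:
                raise StoreError(f"unknown comparison operator {p['op']!r}")
            op = ops[p["op"]]
            ref = p["value"]
            mt_id = self.registry.get(p["microtype"]).id

            def pred(obj, oid):
                for c, _ in self.iter_context(obj):
                    if c.microtype.id != mt_id:
                        continue
                    for _, v in c.iter_values():
                        if v is None:
                            continue
                        try:
                            if op(v, ref):
                                return True
                        except TypeError:
                            continue
                return False

            return pred

        if kind == "derived_from":
            src = p["id"]

            def pred(obj, oid):
                return src != oid and src in nx.ancestors(self._graph, oid)

            return pred

        if kind == "person":
            name = p["name"]

            def pred(obj, oid):
                anc = nx.ancestors(self._graph, oid) | {oid}
                return any(
                    pid in anc and proc.person == name
                    for pid, proc in self._processes.items()
                )

            return pred

        if kind == "process_term":
            ids = self._term_ids(p["term"], bool(p.get("expand", False)))

            def pred(obj, oid):
                anc = nx.ancestors(self._graph, oid) | {oid}
                return any(
                    pid in anc and proc.process_term.id in ids
                    for pid, proc in self._processes.items()
                )

            return pred

        raise StoreError(f"malformed predicate: {dict(p)!r}")

    # -- persistence ---------------------------------------------------------
    def _doc_path(self, obj_id: str) -> Path:
        type_name, local = obj_id.split(":", 1)
        sub = "processes" if type_name == PROCESS_TYPE else f"objects/{type_name}"
        return self.root / sub / f"{local}.json"

    @staticmethod
    def _atomic_write(path: Path, text: str) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(text, encoding="utf-8")
        os.replace(tmp, path)

    def _persist(self, obj, proc_rec: ProcessRecord | None, edges) -> None:
        if self.root is None:
            return
        doc = serialize_brick(obj) if isinstance(obj, DataBrick) else obj.to_doc()
        obj_id = self._id_of(obj)
        self._atomic_write(
            self._doc_path(obj_id),
            json.dumps(doc, sort_keys=True, separators=(",", ":")),
        )
        if proc_rec is not None:
            self._atomic_write(
                self._doc_path(proc_rec.id),
                json.dumps(proc_rec.to_doc(), sort_keys=True, separators=(",", ":")),
            )
        self._append_edges(edges)
        self._atomic_write(
            self.root / "counters.json", json.dumps(self._counters, sort_keys=True)
        )

    def _append_edges(self, edges) -> None:
        if self.root is None or not edges:
            return
        with open(self.root / "edges.jsonl", "a", encoding="utf-8") as fh:
            for src, dst, kind in edges:
                fh.write(json.dumps({"src": src, "dst": dst, "kind": kind}) + "\n")

    def _load(self) -> None:
        counters = self.root / "counters.json"
        if counters.exists():
            self._counters = json.loads(counters.read_text())
        objdir = self.root / "objects"
        if objdir.exists():
            for type_dir in sorted(objdir.iterdir()):
                for path in sorted(type_dir.glob("*.json")):
                    doc = json.loads(path.read_text())
                    if doc.get("kind") == "brick":
                        obj = deserialize_brick(doc, self.registry)
                        obj_id = obj.brick_id
                    else:
                        obj = CoreObject.from_doc(doc, self.registry)
                        obj_id = obj.id
                    self._objects[obj_id] = obj
                    self._graph.add_node(
                        obj_id, kind="object", type=self._type_of(obj)
                    )
                    if isinstance(obj, CoreObject) and obj.superseded_by is None:
                        typedef = self.core_types.get(obj.type_name)
                        self._pk_index[(obj.type_name, obj.pk(typedef))] = obj_id
        procdir = self.root / "processes"
        if procdir.exists():
            for path in sorted(procdir.glob("*.json")):
                doc = json.loads(path.read_text())
                rec = ProcessRecord(
                    id=doc["id"],
                    process_term=self.registry.term_index.get(doc["process_term"]),
                    person=doc["person"],
                    campaign=doc.get("campaign"),
                    lab=doc.get("lab"),
                    date=doc.get("date"),
                    input_ids=tuple(doc["input_ids"]),
                    output_ids=tuple(doc["output_ids"]),
                    parameters=doc.get("parameters", {}),
                )
                self._processes[rec.id] = rec
                self._graph.add_node(rec.id, kind="process")
        edge_log = self.root / "edges.jsonl"
        if edge_log.exists():
            for line in edge_log.read_text().splitlines():
                if not line.strip():
                    continue
                e = json.loads(line)
                self._graph.add_edge(e["src"], e["dst"], kind=e["kind"])
                self.edge_log.append((e["src"], e["dst"], e["kind"]))
                if e["kind"] == "superseded_by" and e["src"].startswith(
                    BRICK_TYPE + ":"
                ):
                    self._brick_superseded[e["src"]] = e["dst"]


def create_core_object(
    store: ProvenanceStore,
    typedef: CoreTypeDef,
    values: Mapping[str, Any],
    process: ProcessSpec | None = None,
) -> CoreObject:
    """Build, validate, and register a core object; returns it with its
    permanent id assigned."""
    obj = build_core_object(typedef, values, store.registry)
    store.register_object(obj, process)
    return obj


# ---------------------------------------------------------------------------
# dynamic joins


def _field_column(store, typedef, targets, field_name):
    """Values + shared unit of one core field across resolved targets."""
    f = typedef.field(field_name)
    if f is None:
        raise StoreError(f"{typedef.name} has no field {field_name!r}")
    vals, units = [], set()
    for t in targets:
        if t is None:
            vals.append(None)
            continue
        c = t.field_values.get(field_name)
        if c is None:
            vals.append(None)
        else:
            vals.append(c.value_at(()))
            if c.unit is not None:
                units.add(c.unit.id)
    if len(units) > 1:
        raise StoreError(
            f"field {field_name!r} has inconsistent units across joined "
            f"objects: {sorted(units)}"
        )
    unit = store.registry.term_index.get(next(iter(units))) if units else None
    if unit is None and f.microtype.unitful:
        unit = sorted(
            store.registry.valid_units(f.microtype), key=lambda t: t.id
        )[0]
    return make_contexton(
        f.microtype, vals, unit=unit, ontologies=store.registry.term_index
    )


def dynamic_join(
    store: ProvenanceStore,
    brick: DataBrick,
    dim: int,
    var: int,
    fields: Sequence[str],
    then: tuple[str, Sequence[str]] | None = None,
) -> DataBrick:
    """Merge core-object fields into a brick as new dimension variables.

    ``dims[dim].variables[var]`` must be an object_ref contexton; each
    requested field of the referenced core type becomes an additional 1-D
    variable on that dimension, aligned by reference.  ``then=(ref_field,
    fields2)`` performs a second hop through an object_ref field of the
    first target (e.g. brick -> Sample -> Well for latitude/longitude).
    Pure; records one session op.
    """
    if not (0 <= dim < brick.ndim):
        raise StoreError(f"no dimension {dim}")
    d = brick.dims[dim]
    if not (0 <= var < len(d.variables)):
        raise StoreError(f"no variable {var} on dimension {dim}")
    ref = d.variables[var]
    if ref.microtype.scalar_type != ScalarKind.OBJECT_REF:
        raise StoreError(
            f"variable {ref.microtype.name!r} is not an object reference"
        )
    target_type = store.core_types.get(ref.microtype.ref_target)
    targets = []
    for i in range(d.size):
        pk = ref.value_at((i,))
        if pk is None:
            targets.append(None)
            continue
        hit = store.resolve_pk(target_type.name, pk)
        if hit is None:
            raise StoreError(f"dangling reference: no live {target_type.name} {pk!r}")
        targets.append(hit)

    new_vars = [_field_column(store, target_type, targets, f) for f in fields]

    if then is not None:
        via, fields2 = then
        vf = target_type.field(via)
        if vf is None:
            raise StoreError(f"{target_type.name} has no field {via!r}")
        if vf.microtype.scalar_type != ScalarKind.OBJECT_REF:
            raise StoreError(
                f"second hop must go through an object_ref field; "
                f"{via!r} is {vf.microtype.scalar_type}"
            )
        second_type = store.core_types.get(vf.microtype.ref_target)
        second_targets = []
        for t in targets:
            pk = None if t is None else t.get(via)
            if pk is None:
                second_targets.append(None)
                continue
            hit = store.resolve_pk(second_type.name, pk)
            if hit is None:
                raise StoreError(
                    f"dangling reference: no live {second_type.name} {pk!r}"
                )
            second_targets.append(hit)
        new_vars += [
            _field_column(store, second_type, second_targets, f) for f in fields2
        ]

    new_dim = DimensionSpec(
        dim_type=d.dim_type,
        size=d.size,
        variables=d.variables + tuple(new_vars),
    )
    params = {"dim": dim, "var": var, "fields": list(fields)}
    if then is not None:
        params["then"] = {"via": then[0], "fields": list(then[1])}
    return DataBrick(
        name=brick.name,
        data_category=brick.data_category,
        dims=brick.dims[:dim] + (new_dim,) + brick.dims[dim + 1 :],
        value_sets=brick.value_sets,
        overall_context=brick.overall_context,
        session=brick.with_session("join", params),
    )


def _replay_join(store, brick, params):
    then = None
    if params.get("then"):
        then = (params["then"]["via"], params["then"]["fields"])
    return dynamic_join(
        store, brick, params["dim"], params["var"], params["fields"], then
    )


_bricks.OPS["join"] = _replay_join
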