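"""An *instance*: one deployment's language plus its data.

Bundles the loaded ontologies (term index), the microtype registry with
its four system microtypes, the static core-type registry, and the
provenance store.  On disk an instance is a directory::

    instance/
      config.toml          # names the definition files below
      ontologies/*.obo     # OBO-subset vocabularies
      microtypes.json      # list of microtype records (JSON dialect)
      core_types.json      # list of core type schemas
      store/               # objects, processes, edge log, counters

Definition order matters (ontologies -> microtypes -> core types); the
config records it explicitly.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Iterable, Mapping

from .core_types import CoreTypeDef, CoreTypeRegistry
from .errors import BrickstoreError, MicrotypeError
from .microtypes import (
    Microtype,
    MicrotypeRegistry,
    SystemMicrotypes,
    microtype_from_doc,
)
from .ontology import Ontology, TermIndex, load_ontology
from .store import ProvenanceStore

__all__ = ["Instance"]

_SYSTEM_KEYS = ("data_category", "dimension_type", "values_type", "unit_type")


class Instance:
    """See module docstring."""

    def __init__(self, root: str | Path | None = None):
        self.root = Path(root) if root is not None else None
        self.terms = TermIndex()
        self.microtypes = MicrotypeRegistry(self.terms)
        self.core_types = CoreTypeRegistry(self.microtypes)
        self.system: SystemMicrotypes | None = None
        self.upload_templates: dict[str, "UploadTemplate"] = {}
        self.use_templates: dict[str, "UseTemplate"] = {}
        self._ontology_files: list[str] = []
        self.store = ProvenanceStore(
            self.core_types,
            None if self.root is None else self.root / "store",
        )

    # -- building the language ---------------------------------------------
    def load_ontology(self, source, ontology_id: str | None = None) -> Ontology:
        onto = load_ontology(source, ontology_id)
        self.terms.add(onto)
        if self.root is not None and not hasattr(source, "read"):
            src = Path(source)
            dest = self.root / "ontologies" / f"{onto.id}.obo"
            dest.parent.mkdir(parents=True, exist_ok=True)
            if src.resolve() != dest.resolve():
                dest.write_text(src.read_text(encoding="utf-8"), encoding="utf-8")
            self._ontology_files.append(dest.name)
            self._save_config()
        return onto

    def register_microtype(self, spec: Microtype) -> Microtype:
        mt = self.microtypes.register(spec)
        self._save_definitions()
        return mt

    def load_microtypes(self, docs: Iterable[Mapping]) -> list[Microtype]:
        out = [
            self.microtypes.register(microtype_from_doc(d, self.terms))
            for d in docs
        ]
        self._save_definitions()
        return out

    def set_system_microtypes(self, mapping: Mapping[str, str]) -> SystemMicrotypes:
        """``mapping`` names the microtype (CURIE or label) for each of the
        four system roles."""
        missing = [k for k in _SYSTEM_KEYS if k not in mapping]
        if missing:
            raise MicrotypeError(f"system microtypes missing: {missing}")
        self.system = SystemMicrotypes(
            **{k: self.microtypes.get(mapping[k]) for k in _SYSTEM_KEYS}
        )
        self._save_definitions()
        return self.system

    def define_core_type(self, typedef: CoreTypeDef) -> CoreTypeDef:
        td = self.core_types.define(typedef)
        self._save_definitions()
        return td

    def add_upload_template(self, template) -> None:
        self.upload_templates[template.name] = template
        self._save_definitions()

    def add_use_template(self, template) -> None:
        self.use_templates[template.name] = template
        self._save_definitions()

    def require_system(self) -> SystemMicrotypes:
        if self.system is None:
            raise MicrotypeError(
                "the four system microtypes must be defined before bricks"
            )
        return self.system

    # -- persistence ---------------------------------------------------------
    def _save_config(self) -> None:
        if self.root is None:
            return
        self.root.mkdir(parents=True, exist_ok=True)
        lines = ["# brickstore instance configuration"]
        files = ", ".join(f'"{f}"' for f in self._ontology_files)
        lines.append(f"ontologies = [{files}]")
        lines.append('microtypes = "microtypes.json"')
        lines.append('core_types = "core_types.json"')
        lines.append('store = "store"')
        (self.root / "config.toml").write_text("\n".join(lines) + "\n", "utf-8")

    def _save_definitions(self) -> None:
        if self.root is None:
            return
        self.root.mkdir(parents=True, exist_ok=True)
        doc = {
            "microtypes": [m.to_doc() for m in self.microtypes],
            "system": {
                k: getattr(self.system, k).name_term.id for k in _SYSTEM_KEYS
            }
            if self.system is not None
            else None,
        }
        (self.root / "microtypes.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True), "utf-8"
        )
        (self.root / "core_types.json").write_text(
            json.dumps(
                [t.to_doc() for t in self.core_types], indent=1, sort_keys=True
            ),
            "utf-8",
        )
        (self.root / "templates.json").write_text(
            json.dumps(
                {
                    "upload": [t.to_doc() for t in self.upload_templates.values()],
                    "use": [t.to_doc() for t in self.use_templates.values()],
                },
                indent=1,
                sort_keys=True,
            ),
            "utf-8",
        )
        self._save_config()

    @classmethod
    def open(cls, root: str | Path) -> "Instance":
        """Load a saved instance directory."""
        root = Path(root)
        cfg_path = root / "config.toml"
        if not cfg_path.exists():
            raise BrickstoreError(f"{root} is not an instance (no config.toml)")
        cfg = tomllib.loads(cfg_path.read_text("utf-8"))

        inst = cls.__new__(cls)
        inst.root = root
        inst.terms = TermIndex()
        inst.microtypes = MicrotypeRegistry(inst.terms)
        inst.core_types = CoreTypeRegistry(inst.microtypes)
        inst.system = None
        inst.upload_templates = {}
        inst.use_templates = {}
        inst._ontology_files = list(cfg.get("ontologies", ()))
        for fname in inst._ontology_files:
            inst.terms.add(load_ontology(root / "ontologies" / fname))
        mt_path = root / cfg.get("microtypes", "microtypes.json")
        if mt_path.exists():
            doc = json.loads(mt_path.read_text("utf-8"))
            for d in doc["microtypes"]:
                inst.microtypes.register(microtype_from_doc(d, inst.terms))
            if doc.get("system"):
                inst.system = SystemMicrotypes(
                    **{
                        k: inst.microtypes.get(v)
                        for k, v in doc["system"].items()
                    }
                )
        ct_path = root / cfg.get("core_types", "core_types.json")
        if ct_path.exists():
            for d in json.loads(ct_path.read_text("utf-8")):
                inst.core_types.define(CoreTypeDef.from_doc(d, inst.microtypes))
        tpl_path = root / "templates.json"
        if tpl_path.exists():
            from .templates import UploadTemplate, UseTemplate

            doc = json.loads(tpl_path.read_text("utf-8"))
            for d in doc.get("upload", ()):
                t = UploadTemplate.from_doc(d, inst.microtypes)
                inst.upload_templates[t.name] = t
            for d in doc.get("use", ()):
                t = UseTemplate.from_doc(d)
                inst.use_templates[t.name] = t
        inst.store = ProvenanceStore(
            inst.core_types, root / cfg.get("store", "store")
        )
        return inst
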