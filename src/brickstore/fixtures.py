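"""Deterministic miniature instance for testing and demonstration.

Emulates a small environmental-microbiology deployment: groundwater
*Wells* in which *Samples* are taken, a *Gene* catalog, a gene-fitness
brick (conditions x genes x replicates), a geochemistry brick
(samples x analytes, with missing cells), and a growth-curve brick
(time x strain).  Ontology CURIE prefixes are fictional (``EX:`` domain
terms, ``EXU:`` units) so no real ENVO/ChEBI identifiers are implied.

``generate_fixture`` is a pure function of ``(seed, sizes)``: the same
arguments produce a byte-identical instance directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .bricks import DataBrick, DimensionSpec, build_brick
from .contextons import make_contexton
from .core_types import CoreField, CoreTypeDef
from .instance import Instance
from .microtypes import Microtype, ValidatorSpec
from .store import ProcessSpec, create_core_object
from .templates import DimDraft, UploadTemplate, UseConstraint, UseTemplate

__all__ = ["DEFAULT_SIZES", "generate_fixture", "domain_obo", "units_obo"]

DEFAULT_SIZES = {
    "wells": 3,
    "samples": 6,
    "genes": 100,
    "conditions": 4,
    "replicates": 3,
    "analytes": 5,
    "times": 8,
    "strains": 4,
}

PEOPLE = ("alice", "bob", "carol")
LABS = ("field lab", "assay lab")


def units_obo() -> str:
    """The units vocabulary (modeled on unit-ontology practice)."""
    terms = [
        ("EXU:0000001", "unit", [], []),
        ("EXU:0000002", "length unit", ["EXU:0000001"], []),
        ("EXU:0000003", "meter", ["EXU:0000002"], ["m"]),
        ("EXU:0000004", "centimeter", ["EXU:0000002"], ["cm"]),
        ("EXU:0000005", "angular unit", ["EXU:0000001"], []),
        ("EXU:0000006", "degree", ["EXU:0000005"], []),
        ("EXU:0000007", "concentration unit", ["EXU:0000001"], []),
        ("EXU:0000008", "millimolar", ["EXU:0000007"], ["mM"]),
        ("EXU:0000009", "milligram per milliliter", ["EXU:0000007"], ["mg/mL"]),
        ("EXU:0000010", "time unit", ["EXU:0000001"], []),
        ("EXU:0000011", "hour", ["EXU:0000010"], ["h"]),
        ("EXU:0000012", "temperature unit", ["EXU:0000001"], []),
        ("EXU:0000013", "degree Celsius", ["EXU:0000012"], []),
    ]
    return _render_obo(terms)


def domain_obo() -> str:
    """Domain vocabulary: chemistry, biomes, data/dimension/measurement
    categories, and process types."""
    terms = [
        ("EX:0000001", "entity", [], []),
        # chemistry (carbohydrate > glucose is the canonical ancestor-search case)
        ("EX:0000010", "chemical entity", ["EX:0000001"], []),
        ("EX:0000011", "carbohydrate", ["EX:0000010"], ["saccharide"]),
        ("EX:0000012", "glucose", ["EX:0000011"], ["dextrose"]),
        ("EX:0000013", "sucrose", ["EX:0000011"], []),
        ("EX:0000014", "nitrate", ["EX:0000010"], []),
        ("EX:0000015", "acetate", ["EX:0000010"], []),
        ("EX:0000016", "sulfate", ["EX:0000010"], []),
        # biomes
        ("EX:0000020", "biome", ["EX:0000001"], []),
        ("EX:0000021", "terrestrial biome", ["EX:0000020"], []),
        ("EX:0000022", "freshwater biome", ["EX:0000020"], []),
        # amplicon synonym cluster (synonym-resolution fixture)
        ("EX:0000030", "amplicon sequence variant", ["EX:0000001"],
         ["ASV", "ESV", "Exact Sequence Variant", "sub-OTU"]),
        # microtype name terms
        ("EX:0000100", "latitude", ["EX:0000001"], []),
        ("EX:0000101", "longitude", ["EX:0000001"], []),
        ("EX:0000102", "well name", ["EX:0000001"], []),
        ("EX:0000103", "sample name", ["EX:0000001"], []),
        ("EX:0000104", "depth", ["EX:0000001"], []),
        ("EX:0000105", "gene name", ["EX:0000001"], []),
        ("EX:0000106", "gene", ["EX:0000001"], []),
        ("EX:0000107", "well", ["EX:0000001"], []),
        ("EX:0000108", "sample", ["EX:0000001"], []),
        ("EX:0000109", "molecule", ["EX:0000001"], []),
        ("EX:0000110", "strain name", ["EX:0000001"], []),
        ("EX:0000111", "replicate number", ["EX:0000001"], []),
        ("EX:0000112", "comment", ["EX:0000001"], []),
        ("EX:0000113", "temperature", ["EX:0000001"], []),
        ("EX:0000114", "scaling", ["EX:0000001"], []),
        ("EX:0000115", "brick name", ["EX:0000001"], []),
        # measurements (Values Type vocabulary)
        ("EX:0000200", "measurement", ["EX:0000001"], []),
        ("EX:0000201", "fitness", ["EX:0000200"], []),
        ("EX:0000202", "concentration", ["EX:0000200"], []),
        ("EX:0000203", "optical density", ["EX:0000200"], ["OD"]),
        ("EX:0000204", "time", ["EX:0000200"], []),
        # data categories
        ("EX:0000300", "data category", ["EX:0000001"], ["data type"]),
        ("EX:0000301", "fitness data", ["EX:0000300"], []),
        ("EX:0000302", "geochemistry data", ["EX:0000300"], []),
        ("EX:0000303", "microbial growth data", ["EX:0000300"], []),
        # dimension types
        ("EX:0000400", "dimension type", ["EX:0000001"], []),
        ("EX:0000401", "condition series", ["EX:0000400"], []),
        ("EX:0000402", "gene axis", ["EX:0000400"], []),
        ("EX:0000403", "replicate series", ["EX:0000400"], []),
        ("EX:0000404", "sample series", ["EX:0000400"], []),
        ("EX:0000405", "analyte series", ["EX:0000400"], []),
        ("EX:0000406", "time series", ["EX:0000400"], []),
        ("EX:0000407", "strain series", ["EX:0000400"], []),
        # system microtype names
        ("EX:0000500", "values type", ["EX:0000001"], []),
        ("EX:0000501", "unit type", ["EX:0000001"], []),
        # processes
        ("EX:0000600", "process", ["EX:0000001"], []),
        ("EX:0000601", "field sampling", ["EX:0000600"], []),
        ("EX:0000602", "assay", ["EX:0000600"], []),
        ("EX:0000603", "fitness assay", ["EX:0000602"], []),
        ("EX:0000604", "geochemical assay", ["EX:0000602"], []),
        ("EX:0000605", "growth assay", ["EX:0000602"], []),
        ("EX:0000606", "computational analysis", ["EX:0000600"], []),
    ]
    return _render_obo(terms)


def _render_obo(terms) -> str:
    chunks = ["format-version: 1.2", ""]
    for tid, name, parents, synonyms in terms:
        chunk = ["[Term]", f"id: {tid}", f"name: {name}"]
        chunk += [f'synonym: "{s}"' for s in synonyms]
        chunk += [f"is_a: {p}" for p in parents]
        chunks.append("\n".join(chunk))
        chunks.append("")
    return "\n".join(chunks)


def _subtree(*roots: str) -> ValidatorSpec:
    return ValidatorSpec(kind="oterm_subtree", roots=roots)


def _range(lo=None, hi=None) -> ValidatorSpec:
    return ValidatorSpec(kind="numeric_range", minimum=lo, maximum=hi)


def _build_language(inst: Instance) -> None:
    from .ontology import parse_ontology_text

    inst.terms.add(parse_ontology_text(domain_obo(), "domain"))
    inst.terms.add(parse_ontology_text(units_obo(), "units"))

    t = inst.terms.resolve
    reg = inst.microtypes
    degree = t("EXU:0000006")

    def mt(name, scalar, **kw):
        return reg.register(Microtype(name_term=t(name), scalar_type=scalar, **kw))

    mt("latitude", "float", allowed_units=(degree,), validator=_range(-90, 90),
       description="north-south position of a well, in degrees")
    mt("longitude", "float", allowed_units=(degree,), validator=_range(-180, 180),
       description="east-west position of a well, in degrees")
    mt("EX:0000020", "oterm_ref", validator=_subtree("EX:0000020"),
       description="biome classification of a sampling location")
    mt("well name", "string")
    mt("sample name", "string")
    mt("depth", "float", allowed_units=(t("EXU:0000002"),), validator=_range(lo=0),
       description="depth below ground, nonnegative")
    mt("gene name", "string", validator=ValidatorSpec(kind="regex", pattern=r"G\d{4}"))
    mt("gene", "object_ref", ref_target="Gene")
    mt("well", "object_ref", ref_target="Well")
    mt("sample", "object_ref", ref_target="Sample")
    mt("molecule", "oterm_ref", validator=_subtree("EX:0000010"),
       description="chemical identity of a measured or supplied compound")
    mt("strain name", "string")
    mt("replicate number", "int", dimensionless=True, validator=_range(lo=1))
    mt("comment", "string", non_informative=True,
       description="free-text note; not informative as a dimension label")
    mt("temperature", "float", allowed_units=(t("EXU:0000012"),))
    mt("scaling", "string")
    mt("EX:0000201", "float", dimensionless=True,
       description="relative fitness score of a mutant strain")
    mt("EX:0000202", "float", allowed_units=(t("EXU:0000007"),),
       validator=_range(lo=0), description="amount of analyte per volume")
    mt("EX:0000203", "float", dimensionless=True, validator=_range(lo=0),
       description="optical density at 600 nm, dimensionless")
    mt("EX:0000204", "float", allowed_units=(t("EXU:0000010"),))
    # the four system microtypes ("data type" is a synonym of data category)
    mt("EX:0000300", "oterm_ref", validator=_subtree("EX:0000300"))
    mt("EX:0000400", "oterm_ref", validator=_subtree("EX:0000400"))
    mt("values type", "oterm_ref", validator=_subtree("EX:0000200"))
    mt("unit type", "oterm_ref", validator=_subtree("EXU:0000001"))
    inst.set_system_microtypes(
        {
            "data_category": "EX:0000300",
            "dimension_type": "EX:0000400",
            "values_type": "values type",
            "unit_type": "unit type",
        }
    )

    def f(name, mt_name, required=False):
        return CoreField(name, reg.get(mt_name), required)

    inst.define_core_type(
        CoreTypeDef(
            name="Well",
            fields=(
                f("name", "well name", True),
                f("biome", "EX:0000020", True),
                f("latitude", "latitude", True),
                f("longitude", "longitude", True),
            ),
            pk_field="name",
        )
    )
    inst.define_core_type(
        CoreTypeDef(
            name="Sample",
            fields=(
                f("name", "sample name", True),
                f("well", "well", True),
                f("depth", "depth", False),
            ),
            pk_field="name",
        )
    )
    inst.define_core_type(
        CoreTypeDef(
            name="Gene",
            fields=(f("name", "gene name", True),),
            pk_field="name",
        )
    )

    growth_template = UploadTemplate(
        name="growth",
        data_category=t("EX:0000303"),
        default_dims=(
            DimDraft(t("time series"), [(reg.get("EX:0000204"), t("EXU:0000011"))]),
            DimDraft(t("strain series"), [(reg.get("strain name"), None)]),
        ),
        default_value_sets=((reg.get("EX:0000203"), None),),
        policies={reg.get("EX:0000203").id: "clamp"},
    )
    inst.add_upload_template(growth_template)
    inst.add_use_template(
        UseTemplate(
            name="time_series_analysis",
            constraints=(
                UseConstraint(requires_dimension_with_microtype="EX:0000204"),
            ),
        )
    )
    inst.add_use_template(
        UseTemplate(
            name="line_graph_2d",
            constraints=(
                UseConstraint(
                    requires_value_set_scalar_type="float", min_dims=1
                ),
            ),
        )
    )


def generate_fixture(
    seed: int,
    sizes: dict | None = None,
    root: str | Path | None = None,
) -> Instance:
    """Build (and optionally persist) the complete miniature instance.

    Identical ``(seed, sizes)`` produce identical content; with ``root``
    the instance directory is written and reloadable via
    :meth:`Instance.open`.
    """
    sz = dict(DEFAULT_SIZES)
    if sizes:
        sz.update(sizes)
    rng = np.random.default_rng(seed)

    inst = Instance(root)
    if inst.root is not None:
        (inst.root / "ontologies").mkdir(parents=True, exist_ok=True)
        (inst.root / "ontologies" / "domain.obo").write_text(domain_obo(), "utf-8")
        (inst.root / "ontologies" / "units.obo").write_text(units_obo(), "utf-8")
        inst._ontology_files = ["domain.obo", "units.obo"]
    _build_language(inst)
    if inst.root is not None:
        inst._save_definitions()
    t = inst.terms.resolve
    reg = inst.microtypes
    store = inst.store
    degree = t("EXU:0000006")
    meter = t("EXU:0000003")
    mM = t("mM")
    hour = t("EXU:0000011")

    biomes = [t("terrestrial biome"), t("freshwater biome")]
    wells = []
    for i in range(sz["wells"]):
        wells.append(
            create_core_object(
                store,
                inst.core_types.get("Well"),
                {
                    "name": f"GW{101 + i}",
                    "biome": biomes[i % 2].id,
                    "latitude": (round(35.9 + 0.05 * rng.random(), 6), degree),
                    "longitude": (round(-84.3 + 0.05 * rng.random(), 6), degree),
                },
            )
        )

    sampling = t("field sampling")
    samples = []
    for i in range(sz["samples"]):
        well = wells[i % len(wells)]
        samples.append(
            create_core_object(
                store,
                inst.core_types.get("Sample"),
                {
                    "name": f"S{i + 1:03d}",
                    "well": well.get("name"),
                    "depth": (round(float(rng.uniform(0, 50)), 3), meter),
                },
                process=ProcessSpec(
                    process_term=sampling,
                    person=PEOPLE[i % len(PEOPLE)],
                    lab=LABS[0],
                    date="2021-06-15",
                    input_ids=(well.id,),
                ),
            )
        )

    genes = [
        create_core_object(
            store, inst.core_types.get("Gene"), {"name": f"G{i + 1:04d}"}
        )
        for i in range(sz["genes"])
    ]

    media_pool = [t("glucose"), t("sucrose"), t("nitrate"), t("acetate")]
    strains = [f"strain-{chr(65 + i)}" for i in range(max(sz["strains"], sz["conditions"]))]

    def ctx(mt_name, values, unit=None, modifiers=()):
        return make_contexton(
            reg.get(mt_name), values, unit=unit, modifiers=modifiers,
            ontologies=inst.terms,
        )

    # fitness brick: conditions x genes x replicates
    nc, ng, nr = sz["conditions"], sz["genes"], sz["replicates"]
    fitness_values = rng.normal(0.0, 1.0, size=(nc, ng, nr)).round(6)
    fitness = build_brick(
        "fitness assay GW101 pool",
        t("fitness data"),
        dims=(
            DimensionSpec(
                t("condition series"),
                nc,
                (
                    ctx("strain name", [strains[i] for i in range(nc)]),
                    ctx("molecule", [media_pool[i % len(media_pool)].id for i in range(nc)]),
                ),
            ),
            DimensionSpec(
                t("gene axis"), ng, (ctx("gene", [g.get("name") for g in genes]),)
            ),
            DimensionSpec(
                t("replicate series"),
                nr,
                (ctx("replicate number", list(range(1, nr + 1))),),
            ),
        ),
        value_sets=(ctx("EX:0000201", fitness_values),),
        overall_context=(ctx("temperature", 25.0, unit=t("degree Celsius")),),
        system=inst.require_system(),
        registry=reg,
    )
    store.register_object(
        fitness,
        ProcessSpec(
            process_term=t("fitness assay"),
            person=PEOPLE[0],
            lab=LABS[1],
            date="2021-07-01",
            input_ids=tuple(s.id for s in samples[:2]),
        ),
    )

    # geochemistry brick: samples x analytes, ~5% nulls
    ns, na = sz["samples"], sz["analytes"]
    analytes = [media_pool[i % len(media_pool)] if i < len(media_pool) else t("sulfate")
                for i in range(na)]
    conc = rng.uniform(0.01, 5.0, size=(ns, na)).round(6).astype(object)
    null_mask = rng.random((ns, na)) < 0.05
    conc[null_mask] = None
    geochem = build_brick(
        "geochemistry panel 2021",
        t("geochemistry data"),
        dims=(
            DimensionSpec(
                t("sample series"),
                ns,
                (ctx("sample", [s.get("name") for s in samples]),),
            ),
            DimensionSpec(
                t("analyte series"), na, (ctx("molecule", [a.id for a in analytes]),)
            ),
        ),
        value_sets=(ctx("EX:0000202", conc, unit=mM),),
        system=inst.require_system(),
        registry=reg,
    )
    store.register_object(
        geochem,
        ProcessSpec(
            process_term=t("geochemical assay"),
            person=PEOPLE[1],
            lab=LABS[1],
            date="2021-08-10",
            input_ids=tuple(s.id for s in samples),
        ),
    )

    # growth brick: time x strain (anchored purely through its process)
    nt, nst = sz["times"], sz["strains"]
    times = [round(2.0 * i, 1) for i in range(nt)]
    od = np.empty((nt, nst), dtype=object)
    for j in range(nst):
        cap = rng.uniform(0.8, 1.4)
        rate = rng.uniform(0.3, 0.7)
        for i in range(nt):
            od[i, j] = round(
                float(cap / (1 + np.exp(-rate * (times[i] - 7.0)))), 6
            )
    growth = build_brick(
        "growth curves batch 3",
        t("microbial growth data"),
        dims=(
            DimensionSpec(t("time series"), nt, (ctx("EX:0000204", times, unit=hour),)),
            DimensionSpec(
                t("strain series"), nst, (ctx("strain name", strains[:nst]),)
            ),
        ),
        value_sets=(ctx("EX:0000203", od),),
        system=inst.require_system(),
        registry=reg,
    )
    store.register_object(
        growth,
        ProcessSpec(
            process_term=t("growth assay"),
            person=PEOPLE[2],
            lab=LABS[1],
            date="2021-09-05",
            input_ids=tuple(s.id for s in samples[:3]),
        ),
    )

    return inst
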