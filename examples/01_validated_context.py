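"""Defining a language and self-validating values.

Loads the bundled demonstration vocabularies, then shows how microtypes
validate values totally: every (value, unit) pair gets an answer with
machine-readable reason codes instead of an exception.
"""

from brickstore.fixtures import generate_fixture
from brickstore.microtypes import validate_value, valid_units

inst = generate_fixture(seed=1)
t = inst.terms.resolve

lat = inst.microtypes.get("latitude")
conc = inst.microtypes.get("concentration")

print("valid units for 'concentration' (a unit class expands to its subtree):")
for u in sorted(valid_units(inst.microtypes, conc, inst.terms), key=lambda x: x.id):
    print("  ", u.id, u.label)

cases = [
    (lat, 35.97, t("degree")),
    (lat, 120.0, t("degree")),   # outside [-90, 90]
    (lat, 35.97, None),          # unit is mandatory for unitful microtypes
    (conc, -1.0, t("mM")),       # concentrations are nonnegative
    (conc, None, t("mM")),       # null = missing data, always allowed
]
print("\nvalidation results (ok / reason codes / null flag):")
for mt, value, unit in cases:
    res = validate_value(mt, value, unit, inst.terms)
    unit_label = unit.label if unit else "-"
    print(f"  {mt.name}={value!r} [{unit_label}] -> ok={res.ok} "
          f"reasons={list(res.reasons)} null={res.is_null}")

# synonyms collapse onto one concept
asv = inst.terms.resolve("ESV")
print(f"\n'ESV' resolves to {asv.id} ({asv.label}); "
      f"'sub-OTU' -> {inst.terms.resolve('sub-OTU').id}")
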