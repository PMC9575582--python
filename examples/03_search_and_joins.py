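"""Ancestor-expanded search, provenance queries, and dynamic joins.

A search for the general term "carbohydrate" also finds data that refer
to its descendant "glucose".  A dynamic join pulls fields of referenced
core objects into a brick as new dimension variables — here sample depth
(one hop) and well latitude/longitude (two hops).
"""

import brickstore as bs
from brickstore.fixtures import generate_fixture
from brickstore.store import dynamic_join

inst = generate_fixture(seed=1)
store = inst.store

hits = store.search([{"kind": "term_value", "term": "carbohydrate", "expand": True}])
print("bricks whose context mentions any carbohydrate:", hits)
for h in hits:
    print("   ", h, "=", store.get(h).name)

print("\nobjects derived from well GW101 (Well:0000001):")
print("  ", store.search([{"kind": "derived_from", "id": "Well:0000001"}]))

geo = store.get("Brick:0000002")
joined = dynamic_join(
    store, geo, dim=0, var=0, fields=["depth"],
    then=("well", ["latitude", "longitude"]),
)
print(f"\ngeochemistry brick {geo.name!r} joined to Sample and Well:")
print("  sample-dimension variables:",
      [v.label for v in joined.dims[0].variables])
ref = geo.dims[0].variables[0]
depth = joined.dims[0].variables[1]
lat = joined.dims[0].variables[2]
for i in range(3):
    print(f"  {ref.value_at((i,))}: depth={depth.value_at((i,))} m, "
          f"lat={lat.value_at((i,))} deg")
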