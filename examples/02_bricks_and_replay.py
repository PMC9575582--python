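"""Slicing and aggregating a data brick, then replaying its provenance.

The fixture instance ships a 4x100x3 gene-fitness brick (conditions x
genes x replicates).  Every manipulation is pure and appends one session
record; a derived brick stored in the provenance store can be
reconstructed bit-for-bit from its origin.
"""

import brickstore as bs
from brickstore.fixtures import generate_fixture

inst = generate_fixture(seed=1)
store = inst.store

fitness = store.get("Brick:0000001")
print(f"origin brick: {fitness.name!r}, shape {fitness.shape}, "
      f"category {fitness.data_category.label!r}")

# keep replicates 2-3, then average them away
sliced = bs.slice_brick(fitness, 2, [1, 2])
mean = bs.aggregate_dimension(sliced, 2, "mean")
print(f"after slice+mean: shape {mean.shape}, "
      f"session ops {[op for op, _ in mean.session.ops]}")
print("mean fitness of gene G0001 across conditions:",
      [round(float(mean.value_sets[0].values[i, 0]), 4) for i in range(4)])

derived_id = store.register_object(
    mean,
    bs.ProcessSpec(
        process_term=inst.terms.resolve("computational analysis"),
        person="alice",
        input_ids=(fitness.brick_id,),
    ),
)
replayed = bs.replay_session(store, store.get(derived_id).session)
print(f"stored as {derived_id}; replay reproduces it exactly:",
      replayed == store.get(derived_id))
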