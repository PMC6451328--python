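"""Assign budding-yeast buds to their mother cells and compute size ratios.

Renders ellipse-shaped mothers with attached circular buds (shared wall at
the neck), segments with the budding-yeast profile (TV denoising; green and
blue channel markers OR-merged), splits buds from mothers by area, assigns
each bud its nearest mother by boundary distance, and prints the
daughter/parent equivalent-diameter ratios.
"""

from brightmorph import (
    BUDDING_YEAST,
    assign_parents,
    generate_budding_scene,
    measure_regions,
    run_pipeline,
    select_channel,
    size_ratios,
    split_buds,
)

scene = generate_budding_scene(6, bud_fraction=0.8, seed=7)
labels = run_pipeline(scene.raw, BUDDING_YEAST, pixel_size_um=0.1)
records = measure_regions(labels, select_channel(scene.raw, "blue", 0.1))

buds, mothers = split_buds(records)
print(f"{labels.n_objects} objects -> {len(buds)} buds, {len(mothers)} mothers\n")

assignments = assign_parents(buds, mothers, labels)
table = size_ratios(assignments, records)
print(table.round(3).to_string(index=False))

print(
    "\ndiameter_ratio is bud/mother equivalent-circle diameter (commanded"
    "\n0.35-0.55); buds have visibly lower eccentricity than the elongated"
    "\nmothers; ambiguous=True would flag a bud touching several mothers."
)
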