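"""Simulate a dual-date paddy scene and write it to ENVI rasters.

Builds the default synthetic field — 52 one-metre observation plots on a
150x240 px mosaic, 304 bands (399–1005 nm), moderate infestation dominant —
and saves both reflectance cubes plus the plot/count table.
"""

from collections import Counter
from pathlib import Path

from paddyspec import SynthConfig, simulate_scene, write_cube, write_plot_table

out = Path("scene_output")
out.mkdir(exist_ok=True)

scene = simulate_scene(SynthConfig(seed=1))
write_cube(scene.cube_t1, out / "t1.dat")
write_cube(scene.cube_t2, out / "t2.dat")
write_plot_table(
    scene.footprints,
    [scene.truth.counts_t1[fp.plot_id] for fp in scene.footprints],
    [scene.truth.counts_t2[fp.plot_id] for fp in scene.footprints],
    out / "plots.csv",
)

print(f"cube dims: {scene.cube_t1.values.shape} (rows x cols x bands)")
print(f"plots: {len(scene.footprints)} of side {scene.config.plot_side} px")
print("severity mix:", dict(Counter(scene.truth.plot_severity.values())))
# The mix mirrors an early-infestation field: the moderate class dominates,
# which is why the modelling stage balances classes before training.
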