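"""Score DSDI bands jointly (LDA + SHAP + ANOVA) and pick representatives.

The joint indicator is the average of the three min-max-normalized scores;
one band is picked per short-wave subinterval (violet ... red-edge) and
four in the NIR region, parameterizing the 24 DSDI-SL candidates.
"""

import numpy as np

from paddyspec import SynthConfig, dsdi, extract_plot_pixels, simulate_scene
from paddyspec.band_select import (
    DEFAULT_SCHEME,
    pick_representatives,
    score_dsdi_bands,
    score_table,
)

scene = simulate_scene(SynthConfig(seed=1))
pairs = extract_plot_pixels(scene.cube_t1, scene.cube_t2, scene.footprints)
labels = np.array([scene.truth.plot_severity[p] for p in pairs.plot_id])

rng = np.random.default_rng(0)
sample = rng.choice(len(pairs), size=3000, replace=False)
vals = dsdi(pairs.r_early, pairs.r_late)
score = score_dsdi_bands(vals[sample], labels[sample], pairs.grid, seed=0)
short, long = pick_representatives(score, n_long=4)

print("short-wave picks (nm):", [int(w) for w in short])
print("long-wave picks  (nm):", [int(w) for w in long])
table = score_table(score, DEFAULT_SCHEME, (short, long))
table.to_csv("band_scores.csv", index=False)
print("per-band scores written to band_scores.csv")
print(f"-> {len(short)}x{len(long)} = {len(short) * len(long)} DSDI-SL candidates")
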