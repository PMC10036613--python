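"""Render one trial as a scanpath image and decode what the pixels encode.

The raster shows only the 18 AOI circles on black, straight saccade lines
colour-coded dark blue (early) to light green (late), one aggregated
fixation marker per AOI (triangle = own payoff, diamond = counterpart)
coloured by fixation count on the sequential ramp, and fuchsia dots for
fixations outside every AOI.
"""

from pathlib import Path

import numpy as np

from gazestrat import (
    GeneratorConfig,
    build_layout,
    generate_battery,
    render_scanpath,
    simulate_trial,
)
from gazestrat.games import StrategyLabel
from gazestrat.render import assign_aoi, fixation_color

rng = np.random.default_rng(2)
layout = build_layout()
game = generate_battery(rng, n_do=1, n_ue=0)[0]
record = simulate_trial(game, StrategyLabel.EQUILIBRIUM, layout, GeneratorConfig(), rng)

img = render_scanpath(record, layout)
out = Path("scratch") / "scanpath_example.png"
out.parent.mkdir(exist_ok=True)
img.save(out)

counts: dict[str, int] = {}
for f in record.fixations:
    aid = assign_aoi(f.x, f.y, layout)
    counts[aid] = counts.get(aid, 0) + 1
busiest = max((k for k in counts if k != "OUT"), key=counts.get)
print(f"trial: {len(record.fixations)} fixations, {len(record.saccades)} saccades, rt {record.rt:.0f} ms")
print(f"busiest AOI: {busiest} with {counts[busiest]} fixations -> marker RGB {fixation_color(counts[busiest])}")
print(f"image written to {out} ({img.size[0]}x{img.size[1]} px); re-rendering is byte-identical")
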