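"""Build the eight partial-scanpath sets from one trial.

Partial records keep only events completed before a cutoff — a fraction of
the response time (15/30/50/80%) or an absolute time (2/5/10/15 s).  The
surviving event sets nest as the cutoff grows; cutoffs beyond the trial
duration return the full record.
"""

import numpy as np

from gazestrat import GeneratorConfig, build_layout, generate_battery, simulate_trial
from gazestrat.games import StrategyLabel
from gazestrat.truncate import default_specs, truncate_record

rng = np.random.default_rng(3)
layout = build_layout()
game = generate_battery(rng, n_do=0, n_ue=1)[0]
record = simulate_trial(game, StrategyLabel.COORDINATION, layout, GeneratorConfig(), rng)

print(f"full trial: {len(record.fixations)} fixations, rt {record.rt:.0f} ms")
for spec in default_specs():
    cut = truncate_record(record, spec)
    print(f"  {spec.name:4s}: {len(cut.fixations):3d} fixations kept")
print("\nFixation counts are non-decreasing within each grid (nesting property).")
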