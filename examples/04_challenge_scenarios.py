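"""Reproduce the challenge-specimen failure modes pixel by pixel.

Paucicellular (few malignant thyrocytes) and colloid-rich (mostly
background) malignant aspirates depress the pixel-mode third quartile
relative to an adequate malignant specimen: exactly the mechanism behind
first-screening misclassifications of difficult real-world aspirates.
Also writes the green-to-red probability maps as PNG + CSV.
"""

from dataclasses import replace

import numpy as np

from msicyto import (
    PipelineConfig,
    classify_pixelwise,
    render_probability_map,
    run_training,
    simulate_cohort,
)
from msicyto.synthetic import Scenario, make_challenge_specimen, simulate_specimen

config = PipelineConfig(seed=1)
config.synthetic.seed = 1
datasets, rois, truth = simulate_cohort(config.synthetic)
result = run_training(config, datasets, rois, truth.specimen_class)

rng = np.random.default_rng(777)
standard, _, _ = simulate_specimen(
    config.synthetic, rng, "standard", "standard", malignant=True
)
specimens = [("standard malignant", standard)]
for scenario in (Scenario.PAUCICELLULAR, Scenario.HETEROGENEOUS_MIXTURE,
                 Scenario.COLLOID_RICH):
    ch_config = replace(config.synthetic, scenario=scenario, seed=778)
    ds, _, _ = make_challenge_specimen(ch_config)
    specimens.append((scenario.value, ds))

q3_standard = None
print(f"{'specimen':>24} {'pixels':>7} {'pixel q3':>9} {'drop vs standard':>17}")
for name, ds in specimens:
    pmap, summary = classify_pixelwise(result.model, ds, config.preprocessing)
    render_probability_map(pmap, f"map_{ds.specimen_id}.png", scale=4)
    if q3_standard is None:
        q3_standard = summary.q3
        drop = ""
    else:
        drop = f"-{(q3_standard - summary.q3) * 100:.0f} pct points"
    print(f"{name:>24} {summary.n:>7} {summary.q3:>9.4f} {drop:>17}")
print(
    "\nchallenge aspirates depress the pixel-mode q3 toward the 28% decision"
    "\nline; with even less tumor signal they cross it and read benign at the"
    "\nfirst screening. Maps written as map_<specimen>.png (+ .csv sidecars):"
    "\ngreen = low malignancy probability, red = high."
)
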