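"""Bin-wise vertical-displacement comparison between two groups.

At every cycle bin an unpaired t-test compares the two groups' vertical
displacement; the share of significant bins is the 'percent of the step
cycle changed'.  Here a known 35-bin lesion effect is injected and
recovered.
"""

import numpy as np

from gaitdf import (
    CohortConfig, LesionEffect, binwise_compare, extract_step,
    generate_cohort, normalize_step,
)

sigma = 0.3
effect = LesionEffect(bin_start=33, bin_end=67, delta=10 * sigma, taper=0.0)
cfg = CohortConfig(
    groups=[("rat", "M", "control"), ("rat", "M", "lesioned")],
    animals_per_group=5, steps_per_animal=6,
    noise_sd_step=sigma, noise_sd_animal=0.0,
    lesion_effects={"rat:M:metatarsus:left": effect},
    seed=2,
)
cohort = generate_cohort(cfg)

groups = {"control": [], "lesioned": []}
for traj in cohort.trajectories:
    if traj.joint != "metatarsus" or traj.side != "left":
        continue
    for k, ann in enumerate(cohort.steps_for(traj)):
        groups[traj.condition].append(
            normalize_step(extract_step(traj, ann, f"s{k + 1}"))
        )

comp = binwise_compare(
    groups["control"], groups["lesioned"],
    axis="y", alpha=0.05, tail="two_sided", correction="bh",
)
print(f"{comp.group_a} vs {comp.group_b}, {comp.joint} {comp.side}, "
      f"{comp.n_a}+{comp.n_b} step curves")
print(f"percent of step cycle changed: {comp.percent_changed}% "
      f"(injected effect spans 35 bins)")
sig = np.arange(1, 101)[comp.significant]
print(f"significant bins: {sig.min()}..{sig.max()}")
print("-> the flagged bins localize where in the stride the lesioned "
      "group's joint height deviates.")
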