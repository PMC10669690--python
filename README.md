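# gaitdf

Hindlimb locomotion kinematics for rodent tunnel-walk recordings:
step-cycle time normalization, bin-wise waveform comparison, and the
dissimilarity factor (DF), with a synthetic gait generator for
validation.

## The problem

High-speed video of a rat or mouse walking through a transparent tunnel
yields per-frame positions of hindlimb joint landmarks (metatarsus,
ankle, knee) for the left and right limbs. After removing lens
distortion with a four-point homography, each manually annotated step
is resampled onto a common *percent-of-step-cycle* axis — 100 bins from
step start to step end — by cubic-spline interpolation, so steps of
different durations become comparable. Groups (species × sex ×
control/lesioned, labelled `CMR`, `LFM`, …) are then compared two ways:

**Bin-wise vertical displacement.** At every cycle bin `i`, an unpaired
Student's t-test compares the groups' vertical displacement
`y(i)`. The *percent of the step cycle changed* is the count of
significant bins out of 100 — a localization of *where* in the stride
the groups differ.

**Dissimilarity factor.** For two normalized curves `a`, `b`,

```
DF(a,b) = (1/200) [ Σ_{i=1..100} (x_a(i) − x_b(i))² + Σ_{i=1..100} (y_a(i) − y_b(i))² ]
```

the mean of the 200 squared coordinate differences. Per group, DF is
computed for every *cross-animal* pair of step curves (never two steps
of the same animal), and the resulting distributions are compared with
Kruskal–Wallis plus Dunn's post hoc (Lilliefors-corrected
Kolmogorov–Smirnov normality reported per group).

Because such video datasets are rarely shareable, `gaitdf` ships a
synthetic cohort generator with species-specific joint waveform shapes
(single-excursion vs. pendular), step-to-step and animal-to-animal
noise, and localized ground-truth lesion effects, so the whole pipeline
is testable end to end.

## Worked example

```python
from gaitdf import CohortConfig, RunConfig, run_pipeline

config = RunConfig(synthetic=CohortConfig(), tail="two_sided", seed=0)
report = run_pipeline(config, outdir="scratch/example_run")
for side in ("left", "right"):
    print(side, report.percent_changed("ankle", side, "CMR:LMR"))
```

Running `python examples/05_full_pipeline.py` (this configuration)
prints:

```
percent of step cycle changed (control vs lesioned male rats):
  metatarsus  left    37%
  metatarsus  right   10%
  ankle       left    66%
  ankle       right   62%
  knee        left    10%
  knee        right    4%

left metatarsus DF: Kruskal-Wallis H = 295.7, p = 5.03e-60 across 8 groups
```

The default synthetic cohort injects lesion effects spanning 35 bins in
the left metatarsus and 63/62 bins in the ankles of male rats, so the
recovered percentages sit a few bins above those spans (the uncorrected
per-bin test adds ≈ alpha·100 falsely significant bins; see
`docs/methods.md`). The Kruskal–Wallis H says the eight groups' DF
distributions differ strongly — expected, since species and sex use
different waveform templates.

Each `examples/*.py` script demonstrates one capability (simulation,
homography calibration, normalization + DF, bin-wise comparison, full
pipeline). The same stages are available from the shell:

```sh
gaitdf simulate --out sim --seed 0
gaitdf normalize --in sim/trajectories.tsv --ann sim/steps.tsv --out curves.tsv
gaitdf df --curves curves.tsv --out df.tsv
gaitdf binwise --curves curves.tsv --contrast CMR:LMR --joint ankle --side left --out binwise.tsv
gaitdf dfstats --df df.tsv --groups CMR,LMR,CFR,LFR --joint ankle --side left --out dfstats.json
```

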