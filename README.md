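# pcimove

Movement and immobility dynamics after post-contact immobility (PCI).

Many animals respond to being seized by a predator with a prolonged bout of
stillness — thanatosis, death-feigning, tonic immobility.  `pcimove` asks
what happens *next*: once the animal stirs again, how do its alternating
immobility and movement bouts evolve, and how fast does it disperse from
the spot where the predator dropped it?  The package implements the full
analysis chain for centroid-tracking experiments of this kind (the
motivating system is antlion larvae dropped onto paper and onto shallow or
deep sand in a 225 × 225 mm arena), together with a synthetic
intermittent-locomotion generator so every stage can be exercised and
validated without any raw video data.

It is written for behavioural ecologists and movement-ecology
statisticians working with per-individual track files (`time,x,y` CSV at a
fixed frame rate) and/or manually timed bout tables.

## What it computes

**Trajectory preparation.** Raw 10 fps tracks are recursively
coarse-grained — every two successive samples of time, x and y replaced by
their average, halving the series per level (level 4 gives 1.6 s
intervals) — and optionally smoothed with a centred running average.

**Bout segmentation.** A frame is *moving* when its step displacement
exceeds a per-track camera-noise threshold; a movement bout ends only
after ≥ 3.2 s of continuous stillness.  The first immobility bout is the
PCI itself; up to 16 immobility/movement pairs are extracted, truncating
at arrival at the arena wall.

**Duration trends.** For bout kind *k* with duration *t* and sequential
number *n*, the package fits the linear mixed model

    log10 t = (α_s + a_i) + (β_s + b_i) · log10 n + ε

with substrate-specific fixed intercepts α_s and slopes β_s and random
individual effects (a_i, b_i) — a straight line on log-log axes, i.e. a
power-law change of bout duration with event number.  Slope t-tests use
Satterthwaite degrees of freedom; the three pairwise slope contrasts are
adjusted with the single-step max-|Z| joint-normal method.

**Heavy-tail comparison.** Continuous exponential, power-law and
log-normal models are fitted to pooled bout durations above a lower bound
x_min (maximum tail likelihood; x_min chosen to minimise the
Kolmogorov–Smirnov distance between fitted and empirical tail ccdf), and
compared pairwise with Vuong's normalised log-likelihood-ratio test at the
Bonferroni level α′ = 0.05/3.

**Dispersal.** Mean squared displacement (MSD, mm²) and mean instantaneous
speed (MIS, mm/s) from each individual's PCI end, averaged across
individuals inside 14 logarithmically spaced time bins (geometric-mean
midpoints) over the 90-minute window.  A one-breakpoint segmented
regression (Davies-type breakpoint-existence test, Muggeo iterative
estimation) is fitted on log-log axes; the slope of the segment covering
most bins classifies dispersal as sub-diffusive (95% CI below 1),
diffusive (CI straddles 1) or super-diffusive (CI above 1), the Brownian
reference being MSD = 4Dt.  Start-to-finish displacements are compared
across substrates with a mixed model on log10 distance.

**Synthetic cohorts.** `pcimove.synth` generates bout sequences whose
log-durations trend linearly in log event index with per-individual random
intercepts/slopes (or i.i.d. draws from exponential/log-normal/power-law
laws), and renders them as 2-D tracks: Gaussian centroid jitter during
stillness, a correlated random walk with per-event speed trends during
movement, reflective walls, and tracking stopped at wall arrival.  Three
built-in scenarios encode the study conditions on paper (22 individuals),
shallow sand (8) and deep sand (8).

## Worked example

```
$ pcimove simulate --scenario paper --seed 1 --out demo
$ pcimove trends --bouts demo/bout_table.csv --response immobility
LMM for log10 immobility duration ~ log10 sequential number x treatment (random: intercept_and_slope)
  Paper         slope =  -1.188  t_23.4 = -14.23  P = 5.23e-13
$ pcimove tails --bouts demo/bout_table.csv --response immobility
Vuong comparisons for immobility duration (alpha' = 0.017)
  Substrate, N                 EXP vs LN       EXP vs PL        LN vs PL
  Paper, N = 259          -5.098, 0.000*  -3.067, 0.002*   1.802, 0.072
$ pcimove dispersal demo/track_*.csv --kind msd
MSD profile (mm^2), 12 usable bins
  simple fit: slope 1.29 [1.06, 1.52], breakpoint P = 0.269, R2adj = 93.5%
  diffusion regime: super_diffusive
```

Reading the numbers: immobility bouts on the hard substrate shrink
steeply with event number (slope −1.19: the tenth immobility is roughly
15× shorter than the PCI), their pooled distribution is fitted
significantly better by a log-normal than by an exponential (Vuong
−5.10, p < 0.017), and the cohort disperses super-diffusively (log-log
MSD slope 1.29, CI above 1) — the signature of an animal fleeing a surface
it cannot dig into.

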