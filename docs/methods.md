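# Methods

This note documents the models behind `pcimove`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical decisions a user re-deriving results should know about.
Times are seconds, positions millimetres throughout; the arena is a
225 × 225 mm square with the release point at its centre (112.5, 112.5),
so 159 mm (half the diagonal) bounds the start-to-finish displacement.

## Trajectory preparation

Coarse-graining replaces every two successive samples of time, x and y by
their average, recursively; each level halves the series and doubles the
sampling interval, so level 4 turns a 10 fps track into 1.6 s samples.  A
trailing unpaired sample is dropped rather than padded — halving is then
exact, application is associative (level *a* then *b* equals *a+b*), and
the per-coordinate mean is preserved up to the dropped sample.  The
downstream analyses run at level 4 by default: fine enough to time bouts
against 1 s manual records, coarse enough to suppress fictive
sub-resolution movement.

Smoothing is a centred running average of x and y with an odd window,
shrinking symmetrically at the edges.  The window length is a free
parameter (config `smooth_window`, default 3, the minimal centred window);
it is applied by convention only to sand-substrate tracks, where the
centroid estimate is noisiest.

## Bout segmentation

A frame is *moving* iff its step displacement from the previous frame
exceeds a threshold; a movement bout terminates only after at least
`still_gap` seconds of consecutive still frames (default 3.2 s = two
coarse frames, operationalising "more than a couple of seconds"), with the
terminal gap assigned to the following immobility bout.  Shorter pauses
are absorbed into the movement bout.  The bout list starts with the
immobility containing the first timestamp — the PCI — and bout durations
partition the track's time span exactly.

The automatic movement threshold treats still-frame step lengths as
Rayleigh-distributed (isotropic Gaussian centroid noise).  Because the
animal is still for most frames, the 25th percentile of all step lengths
estimates the noise scale `s = q25 / sqrt(-2 ln 0.75)`; the threshold is
placed at the whole-track α = 0.05 exceedance level,
`s · sqrt(2 ln(n/α))` for *n* steps.  A plain in-window percentile (e.g. a
95th percentile over a 10 s calibration window) was rejected: by
construction it leaves 5% of still frames above threshold, which shatters
a several-hundred-second immobility bout into spurious one-frame
movements.  The exceedance-level form makes a noise-only false movement
frame an ≈ 5%-per-track event instead.  The threshold is configurable for
cameras whose noise is not step-independent.

Sequence extraction truncates at 16 immobility/movement pairs and,
optionally, at wall arrival (first frame within 5 mm — about one body
length — of an arena edge), clipping the bout in progress at the arrival
time, as in the observation protocol on the hard substrate.  Wall
detection should use the raw track: coarse-grained positions near the wall
are averages and can sit outside the margin.

## Duration-trend mixed models

For each bout kind, `log10 duration` is regressed on
`log10 sequential number` with a separate intercept and slope per
substrate and a random individual effect — random intercept *and* slope
for immobility, random intercept for movement (the structures preferred by
AIC in the motivating experiments; both overridable).  REML fitting is
delegated to statsmodels `MixedLM`; a singular random-slope fit falls back
to intercept-only with a logged warning.

Two inferential pieces are computed in-package:

* **Satterthwaite degrees of freedom** for per-treatment slope t-tests:
  `dof = 2 f² / (∇f' A ∇f)` with `f(θ) = c' Cov(β̂; θ) c`, the gradient
  taken by central differences in the variance parameters
  θ = (σ², vech G), and `A` the inverse negative Hessian of the profiled
  REML log-likelihood, also by central differences (relative step 1e-4,
  one-sided at a variance boundary).  The dof is clamped to
  [1, n − p]; on numerical failure the residual dof is used with a
  warning.  For a random-slope model this yields dof on the order of the
  number of individuals, not observations — slope tests are governed by
  between-animal information.
* **Single-step max-|Z| adjustment** for the three pairwise slope
  contrasts: `p_j = P(max_k |Z_k| ≥ |z_j|)` under the joint normal with
  the contrasts' estimated correlation.  Three contrasts of three slopes
  span a rank-2 space, so the rectangle probability is evaluated by 2-D
  Gauss quadrature over the eigen-factor (801² grid over ±8 SD; error
  ≲ 1e-3, ample for p-values); full-rank cases use the scipy rectangle
  CDF.  Bonferroni and unadjusted variants are available.  The reported
  difference for pair (A, B) is slope(A) − slope(B); reversing a pair
  flips the sign, not the p-value.

The start-to-finish displacement model mirrors this with
`log10 displacement` and treatment means only, flooring zero displacement
at the 0.1 mm measurement resolution before the log (logged when it
happens).  Body weight is excluded by default (not significant in the
motivating data) and can be added via the configuration.

## Tail models and Vuong comparisons

All three duration models are continuous, tail-conditional densities on
x ≥ x_min:

* power law `p(x) = (α−1)/x_min (x/x_min)^−α`, with the closed-form MLE
  `α̂ = 1 + n / Σ ln(x_i/x_min)`;
* exponential `λ e^{−λ(x−x_min)}`, `λ̂ = 1/(mean − x_min)`;
* log-normal truncated at x_min, maximised numerically (L-BFGS-B on
  (μ, ln σ) with analytic gradient, tolerance 1e-8 on the log-likelihood;
  multi-start from the method of moments of the log data plus three
  dispersed starts, because truncation can push μ̂ far below ln x_min).

Estimating x_min minimises the two-sided KS distance between the fitted
and empirical tail ccdf over the grid of unique observed values, excluding
the largest two (at least two tail points are required); ties break toward
the smaller candidate, which keeps more data.  During the grid scan the
log-normal fit warm-starts from the previous candidate's solution; the
winning candidate is refitted at full tolerance.

Vuong's statistic is `Σ d_i / (sd(d) √n)` for pointwise log-density
differences d above a shared x_min, referred to a standard normal
(two-sided, no small-sample correction), with sample (n−1) standard
deviation; identical models give statistic 0, p 1.  The three-way
comparison follows the convention of the motivating analysis:
exponential-vs-log-normal above the log-normal's estimated x_min, both
power-law comparisons above the power law's, flagged at α′ = 0.05/3.

A caution established during validation: above the power law's *own*
KS-chosen x_min, data that are truly exponential are locally
power-law-mimicking — the selection picks exactly the tail region where
the power law fits best — so the Vuong sign there is close to noise
(wrong-sign runs occur in ~¼ of simulated samples, always with |V| < 1
and p ≫ 0.05).  The comparison reliably *rejects* a wrong model
(power-law or log-normal truth against the exponential) but should not be
read as positive evidence for the exponential from the sign alone.

## Dispersal profiles and segmented regression

The 90-minute window is divided into 14 geometric intervals; the default
lower edge is 1.6 s (the first coarse step; the original description
leaves it open, and it is configurable).  Each interval is represented by
the geometric mean of its edges.  Bins are left-open/right-closed with the
first bin closed on the left; samples before the first edge are excluded.
Per individual and bin, the squared displacement from the position at that
individual's PCI end (time re-zeroed there) is averaged over the bin's
samples; across individuals, the plain mean and the upper limit of its
t-based 95% CI are reported.  "Individuals that moved within the bin" is
read literally: a contributor must have at least one sample in the bin
and, when first-movement times are supplied, must have started moving by
the bin's upper edge.  Bins with fewer than two contributors carry no CI
and are dropped from regression, as are bins whose mean is non-positive.
Instantaneous speed is step displacement over the sampling interval,
assigned to the step's later timestamp; the MIS profile is otherwise
identical.

The one-breakpoint segmented regression tests breakpoint existence first:
a Davies-type supremum test over the interior unique x values, taking for
each candidate the t-statistic of the hinge term `(x − ψ)+` and bounding
the supremum's p-value with Davies' total-variation bound (two-sided).  If
H₀ is retained at α = 0.05 the simple line is returned.  Otherwise the
breakpoint is estimated by iterative linearisation (Muggeo's working
model with hinge and indicator terms, ψ updated by γ̂/β̂₂), with residual
step-halving and a stall detector: the RSS profile in ψ is piecewise
quadratic, so the update can cycle around a kink — the incumbent minimiser
is then taken and polished by bounded scalar minimisation in the
bracketing interval.  Slope CIs come from the final hinge OLS with n − 4
residual dof (ψ counts as a parameter); the breakpoint SE is
SE(γ̂)/|β̂₂|.  A forced ψ outside the data range reproduces the simple
regression exactly.

Diffusion classification takes the slope of the segment covering the most
bins and compares its 95% CI with 1 (sub / diffusive / super).  A known
limitation: the bin means of an *ensemble* MSD share the same individuals,
so their errors are strongly correlated and the residual-based OLS slope
CI is roughly 2–3× too narrow.  On clean simulated Brownian cohorts the
slope estimate is accurate (within [0.85, 1.15] in every validation run)
but the CI-based label can flip between classes; with real, heterogeneous
cohorts the residual scatter is much larger and the labels are stable.
Classifications near the boundary should be read together with the slope
CI itself.  Additionally, at the 1.6 s level the first bin contains a
single sample located at its left edge, slightly below the bin midpoint;
this produces a small systematic dip of the first MSD point.

## Synthetic generator

The generator emulates: per-individual alternating bout sequences with
log-linear duration trends and normal random intercepts/slopes
(`duration_k = 10^(a_i + b_i log10 k + ε)`, ε ~ N(0, σ_resid), truncated
at the 5400 s window and 16 pairs, right-censoring later bouts exactly as
the observation window does); i.i.d. exponential / log-normal / power-law
duration marginals by inverse-CDF; and tracks at 10 samples/s with
isotropic Gaussian centroid jitter during stillness (SD 0.05 mm,
exercising the threshold logic), correlated-random-walk movement (wrapped
normal turning angles, per-event multiplicative speed trend), reflective
walls, and tracking stopped at wall arrival with the stored bout sequence
truncated to match.  A single root seed spawns per-individual streams, so
cohorts are bit-reproducible and individuals independently re-drawable.

Scenario defaults encode the three study conditions: paper — 22
individuals, immobility slope −1.18, movement slope +1.16, base speed
1.5 mm/s growing 15% per event, mild turning (SD 0.3 rad/frame); shallow
sand — 8 individuals, −1.00 / +0.38, 0.8 mm/s decaying 5% per event,
turning SD 0.8; deep sand — 8 individuals, −0.36 / +0.01, 0.6 mm/s
decaying 8% per event, turning SD 0.8.  Shared: intercepts 2.3 (immobility,
≈ 200 s PCI) and 0.2–0.4 (movement) in log10 s, random-effect SDs 0.30
(intercept) and 0.35 (slope), residual SD 0.30, weights log-normal around
0.036 g.  Speed decays on sand are kept above the camera-noise floor so
that late movement remains physically detectable at 1.6 s sampling; on
real deep sand movement can drop below that floor, which the generator
reproduces if pushed (and which segmentation then rightly cannot recover).
Durations are floored at the 1 s manual-timing resolution.  For
segmentation-validation purposes a "resolvable" configuration
(min_immobility 6.4 s, min_movement 1.6 s, jitter off) guarantees every
bout is recoverable at the analysis scale; with it, segmentation inverts
the generator within ±(still_gap + one coarse step).

What the generator does *not* emulate: burial and sand-throwing (movement
without net displacement), postural changes, heterogeneous per-frame
noise, camera jitter between clips, or any interaction between substrate
and turning behaviour beyond the scenario parameters.  Passing tests
therefore demonstrate correctness of the estimators under the stated
stochastic model, not robustness to those real-data artefacts.

## Problem sizes

The validation suite runs desk-scale: tail recovery at n = 5000, Vuong
sign calibration at 100 replicates of n = 2000, trend-slope recovery at
200 replicate cohorts (22/8/8 individuals), dispersal validation on 50
Brownian walkers, and full-pipeline runs on the three scenario cohorts.
The acceptance script regenerates all three cohorts and completes in a few
minutes on one CPU.
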