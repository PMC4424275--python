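# Methods

## Problem

National forest-monitoring (MRV) systems for REDD+ must estimate the
*change* in aboveground biomass (AGB) between inventory occasions. Three
design families exist for sampling on successive occasions:

* **temporary plots** — independent samples at each occasion;
* **continuous forest inventory (CFI)** — the same permanent plots
  remeasured at every occasion;
* **sampling with partial replacement (SPR)** — a mixture: `n12`
  remeasured plots, `n1-` plots measured only at occasion 1, `n-2` new
  plots measured only at occasion 2.

Permanent plots are precise for change (the between-occasion
correlation cancels most population variability) but are exposed to
*treatment bias*: once plot locations are known they may be exempted
from logging or degradation and stop representing the landscape.
Temporary plots are immune to treatment bias but imprecise. SPR sits in
between and, because its new plots see the true landscape, also
provides an internal check for treatment bias. This package implements
the three estimators, a synthetic two-occasion tropical-forest
population, six disturbance scenarios, and the Monte Carlo experiment
that compares the designs with and without treatment bias.

## Estimators

All estimators consume plot-level AGB values in t/ha and omit
finite-population corrections. With `Xbar`/`Ybar` the occasion means,
change is always `C = Ybar - Xbar`.

* Temporary: `V_t(C) = V(Ybar) + V(Xbar)` with `V(mean) =
  sum((v - mean)^2) / (n(n-1))`.
* CFI: `V_cfi(C) = V(Ybar) + V(Xbar) - 2 r sqrt(V(Ybar) V(Xbar))`, `r`
  the paired Pearson correlation. Negative values from rounding are
  clamped to 0. If either occasion has zero spread, `r` is undefined
  and the temporary-form variance is returned with a warning flag.
* SPR: on the remeasured plots, regress Y on X (slope `beta = s_XY /
  s2_X12`) and update the full occasion-1 mean:
  `Y_I = Ybar12 + beta (Xbar1 - Xbar12)` with
  `V(Y_I) = s2_YX (1/n12 + (Xbar1 - Xbar12)^2 / SSX12) +
  (s2_Y12 - s2_YX)/n1`. The new-plot mean `Y_II` has variance
  `s2_Ynew / n-2`. The combined current mean weights both by inverse
  variance; its variance is `[1 + 4 wI wII (1/(n12-1) + 1/(n-2-1)) /
  w^2] / w` (implemented verbatim, including the small-sample inflation
  term). Change subtracts `Xbar1`; its variance is
  `1/w + s2_X1/n1 - 2 (wI/w) beta s2_X1 / n1`.

Two deliberate repairs of the published formula set, both exposed for
inspection:

1. The covariance `s_XY` is computed with deviations of `X12` from
   `Xbar12` (the printed form subtracts `Ybar12` from the X
   deviations, which breaks `|r| <= 1`).
2. The change-variance's final term is divided by `n1` in the default
   `corrected` mode; the printed form omits the division, making the
   term O(s^2) against the other terms' O(s^2/n) and driving the
   variance far negative on realistic inputs (e.g. -105 on the
   package's own worked example whose corrected value is 13.76).
   `mode="as_printed"` reproduces the printed form verbatim, unclamped,
   flagged when negative.

Degenerate designs (`n12 < 3`, `n-2 < 2`, constant `x12`) are rejected
rather than silently reduced to another design. Estimators never see
plot roles or bias flags; the separation keeps the estimation layer
testable against brute-force oracles (explicit-sum recomputation to
1e-10 relative, plus location/scale-equivariance property tests).

## Synthetic population

The study population is 750 subplots of 400 m2 (30 one-ha experimental
plots x 25 subplots) in Suriname-type moist tropical forest, measured
at two occasions 13 years apart. The generator emulates its published
summary statistics:

| quantity | target | generator mechanism |
|---|---|---|
| stems (occ. 1 -> 2) | 8650 -> 8191 | Poisson(11.53)/plot; Bernoulli mortality 0.0531 |
| dbh distribution | min 15 cm, mean 29.3, inverse-J | 15 + Exponential(scale 15.15 cm) |
| tree AGB | mean 417.4 kg | ln(AGB) = -1.562 + 2.148 ln(dbh) |
| plot AGB means | 120.3 -> 132.5 t/ha | dbh growth, mean 2.31 cm/period |
| plot correlation | 0.804 | plot-level growth effect, SD 2.25 |

Units: kg per tree, t/ha per plot; on a 400 m2 plot the conversion is
a division by 40. Dead trees contribute zero at occasion 2; the count
drop is modelled as mortality only (no ingrowth — the source statistics
give no decomposition, and the caliper limit makes ingrowth
unidentifiable from them).

**Plot growth effect.** Surviving trees grow by a nonnegative gamma
increment (tree-level SD 1.5 cm) whose plot-level mean is
`growth_mean * g_p`. Without a plot effect the surviving trees alone
leave the two occasions correlated at ~0.97; `g_p` (mean 1, SD
`plot_growth_sd`) is the single knob that brings the correlation down
to the observed 0.804, and the correlation decreases monotonically in
it (property-tested). Because a diameter increment of ~2.3 cm moves
plot AGB by only ~17%, a plot-effect SD above 2 is required, which
forces a strongly bimodal effect: `g_p` is a scaled Beta on
`[0, plot_growth_max = 8]`, so most plots barely grow while a minority
grow hard. Two consequences are intentional:

* the bounded support keeps the plot-difference distribution's tails
  light, so the design-based variance estimators are well calibrated at
  the study's sample sizes (empirical SD / mean estimated SE = 1.02-1.04
  for CFI and SPR over 2000 iid replicates); an unbounded (gamma)
  effect at the same SD produces kurtosis ~60 and a spurious ~14% gap
  through E[sqrt] concavity alone;
* the bimodal growth pattern loosely mirrors the original experiment's
  structure of released (silviculturally treated, fast-growing) versus
  untreated stands.

**What the generator does not reproduce.** A mean-1 multiplicative
growth effect that is independent of occasion-1 biomass cannot match
the published occasion-2 SD (65.5 t/ha) at correlation 0.804: with
multiplier mean m ~ 1.10, `SD(Y) ~ m SD(X)/r ~ 83` t/ha. The real data
imply mean reversion (regression slope ~0.87 < growth factor), i.e.
high-biomass plots grew proportionally less. Calibration therefore
targets the occasion *means*, *correlation* and *tree counts* only; the
generated occasion-2 SD (~80 t/ha) overshoots the published 65.5.
Passing tests show the design comparison behaves as published on a
population with the right means, correlation and diameter structure —
not that the generator is a faithful model of the Suriname stands.
Spatial structure, species composition, multi-predictor allometry and
ingrowth are out of scope.

**Calibration** (`population.calibrate`) is coordinate moment-matching:
tree counts and the occasion-1 mean have closed-form/quadrature
solutions (`trees_per_plot_mean`, `mortality_prob`, `dbh_scale`); the
occasion-2 mean and the correlation are matched by a damped
two-dimensional fixed-point iteration on `growth_mean` and
`plot_growth_sd`, averaging simulated moments over >= 20 seeds.
Defaults: 5% relative tolerance on means, +-0.05 on the correlation;
the shipped `data/default_params.yaml` was produced at 1%. Failure to
converge raises an error carrying the best residuals. Infinite
tolerances return the inputs unchanged.

## Scenarios and treatment bias

Six scenarios: no intervention; degradation removing trees with
dbh < 35 cm (fuelwood) or dbh > 45 cm (timber) on 10% or 20% of plots;
and deforestation (all trees) on 5% of plots. Affected plots are drawn
by SRSWOR over the full 750-plot population — `floor(fraction * n)`
plots, hence exactly 37/75/150 — and redrawn every Monte Carlo
iteration. Threshold comparisons are strict, against the occasion-2
diameter (removal happens at occasion 2; an occasion-1 basis is
available behind a flag). Occasion-1 values are never modified, and
truth is always the population mean change over all 750 plots using
disturbed occasion-2 values.

Treatment bias is simulated at its conceivable endpoint: *every*
sampled permanent plot observes the undisturbed occasion-2 value, while
temporary occasion-2 plots always observe the disturbed landscape.

## Monte Carlo experiment

Per (scenario x design x bias) cell and iteration: redraw affected
plots, draw the design's sample (CFI: one SRSWOR draw; temporary: two
independent draws, chance overlap left unmatched; SPR: 375 occasion-1
plots of which 250 are designated permanent, plus 125 new plots drawn
from the unsampled remainder — new plots are genuinely new), observe,
estimate. Child seeds derive from the master seed via `SeedSequence`
spawn keys: the affected-plot stream depends only on (scenario,
iteration) and the sample stream only on (scenario, design, iteration),
so truth is identical across designs and bias variants within an
iteration and every cell is independently reproducible.

Summaries per cell: mean estimated change, mean signed and absolute
error, estimate in percent of truth, percent SE, mean SE, empirical SD.
Percent quantities are ratios of cell means (`100 * mean(SE) / |mean
change|`), not means of per-iteration ratios: a per-iteration ratio has
no finite moments when the change estimate has density near zero, as in
the heavy-degradation scenario whose true change is ~-3 t/ha. When
comparing the *precision* of two biased estimators (CFI vs SPR under
treatment bias) the mean SEs are compared directly, because bias moves
the two self-referencing denominators apart by construction.

The reference experiment uses 1000 iterations (`analysis/03`, ~10 s);
tests and the acceptance script use 200 with correspondingly widened
Monte Carlo tolerances, and variance-validity checks use 1500-2000
freshly generated iid replicates at the study sample sizes — iid
generation rather than SRSWOR from the fixed 750 plots, because the
estimators carry no finite-population correction and sampling half of a
finite population would leave a sqrt(1 - n/N) ~ 29% gap for any correct
estimator. The single-population true change of the 20%-degradation
dbh > 45 cm scenario is negative in expectation (~-3 t/ha) but its sign
varies across population realizations (growth SD ~2 t/ha between
750-plot realizations), so scenario-sign statements are evaluated on
the expectation over >= 12 realizations.

## Bias diagnostic

`compare_permanent_temporary` compares current-occasion biomass on
permanent versus temporary plots with a Welch (unequal-variance) t-test
and a TOST equivalence companion. The source framing names no test,
level or margin; the defaults — alpha 0.05, margin 10% of the
temporary-plot mean — are this package's choices and are all
configurable. Verdicts: `evidence_of_bias` when the difference test
rejects, `no_evidence_of_bias` when TOST passes (or the two samples are
literally identical), otherwise `inconclusive`. Type-I error and
monotone power are property-tested; at the study's n = 125 new plots
the power against realistic degradation is modest (~0.4 for the
heaviest scenario), which is itself a finding about the design's
detection capability at these sample sizes.

## Numerical and interface choices

* CSV (UTF-8, header, 12 significant digits) for tables; YAML for
  configurations; JSON for single results and run manifests (config
  SHA-256, master seed, package version, per-cell counts).
* A dead tree's occasion-2 dbh is an empty CSV field, never 0; readers
  reject negative diameters, shrinkage, duplicate tree keys and dead
  trees carrying an occasion-2 diameter, naming the offending row.
* All randomness flows from integer seeds through named
  `SeedSequence` spawn keys; equal seeds give bit-identical outputs.
* The CLI (`sprforest gen-pop | calibrate | apply-scenario | estimate |
  run-mc | bias-check`) is a thin layer over the library; the numbered
  scripts under `analysis/` are the reference walk-through of the full
  study and write their tables under `results/`.

## Known limitations

* Occasion-2 plot SD overshoots the published value (see above).
* Two occasions only; the multi-occasion SPR plot-type system,
  stratified SPR and sample-size optimization are out of scope, as are
  spatial allocation, clustered disturbance and biomass-to-carbon
  conversion.
* The as-printed SPR change variance is retained only for fidelity
  inspection; it is not a usable variance estimator.
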