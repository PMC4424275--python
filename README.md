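# sprforest

Design-based comparison of forest-inventory sampling designs for
estimating aboveground-biomass (AGB) change on two successive
occasions, aimed at REDD+ measurement-reporting-verification (MRV)
settings where *treatment bias* — permanent plots being quietly spared
from logging or degradation once their locations are known — can
corrupt change estimates.

The package implements three estimators of the biomass change
`C = Ybar - Xbar` (t/ha) and its variance:

* **temporary plots** — independent samples per occasion,
  `V_t(C) = V(Ybar) + V(Xbar)`;
* **CFI** (continuous forest inventory, permanent plots) —
  `V_cfi(C) = V(Ybar) + V(Xbar) - 2 r sqrt(V(Ybar) V(Xbar))` with `r`
  the paired correlation;
* **SPR** (sampling with partial replacement) — `n12` remeasured plots
  update the occasion-1 mean through the regression `Y ~ X`
  (`Y_I = Ybar12 + beta (Xbar1 - Xbar12)`), the `n-2` new plots give a
  second mean `Y_II`, and the current estimate combines both by
  inverse-variance weighting; change subtracts the full occasion-1
  mean `Xbar1`.

Around the estimators sit a calibrated synthetic two-occasion tropical
forest population (750 plots of 400 m2, inverse-J diameter
distribution, allometric AGB `ln(AGB) = -1.562 + 2.148 ln(dbh)`), six
deforestation/degradation scenarios, a Monte Carlo experiment that
crosses scenario x design x treatment-bias variant, and a
permanent-vs-temporary Welch/TOST diagnostic for treatment bias.
`docs/methods.md` describes the models and the design choices.

## Worked example

```python
import sprforest as sf

# the hand-checkable SPR chain: 3 remeasured plots, one occasion-1-only
# plot, two new occasion-2 plots
comps = sf.spr_fit(x1_all=[10, 20, 30, 40],
                   x12=[10, 20, 30], y12=[12, 24, 30],
                   y_new=[20, 30])
print(comps.beta_yx, comps.yI, comps.vI)   # 0.9  26.5  22.25
cur = sf.spr_current(comps)
print(round(cur.mean, 3), round(cur.variance, 2))   # 25.794  29.37
est = sf.spr_change(comps)
print(round(est.change, 3), round(est.variance, 2))  # 0.794  13.76
```

The regression slope 0.9 updates the occasion-1 mean (25) onto the
occasion-2 scale (`Y_I = 26.5`); weighting against the new-plot mean
(25, variance 25) gives the combined current state 25.794 t/ha, and
subtracting the occasion-1 mean leaves a change of +0.794 t/ha with
variance 13.76.

The full study pipeline lives in `analysis/` (each script prints its
findings and writes tables under `results/`):

```sh
python analysis/01_calibrate_population.py   # moment-match the generator
python analysis/02_scenario_true_changes.py  # true change per scenario
python analysis/03_monte_carlo_experiment.py # the design comparison
python analysis/04_bias_diagnostics.py       # bias-detection rates
```

`analysis/03` at its default 1000 iterations prints, for example, the
percent standard errors without treatment bias (CFI < SPR < temporary
in every scenario):

```
design            cfi    spr  temporary
defor5           79.7  100.7      145.1
deg10_above45    84.6  113.5      171.9
deg10_below35    37.9   49.6       81.5
deg20_above45    78.3   85.5      132.5
deg20_below35    88.4  123.3      175.3
no_intervention  23.2   30.6       51.2
```

and the mean overestimation under treatment bias (t/ha), showing CFI
fully blind to disturbance, SPR partially protected by its new plots,
and temporary plots unbiased:

```
design             cfi   spr  temporary
defor5            6.34  4.43       0.03
deg10_above45     6.84  4.53      -0.19
deg20_above45    13.69  9.30      -0.06
```

A `sprforest` command-line interface wraps the same functionality
(`gen-pop`, `calibrate`, `apply-scenario`, `estimate`, `run-mc`,
`bias-check`); `sprforest --help` lists the options.

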