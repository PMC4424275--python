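"""Monte Carlo comparison of the three inventory designs.

Each iteration of a (scenario, design, bias) cell:

1. redraws the disturbance-affected plots and applies the scenario,
   giving the disturbed panel and the population truth;
2. draws the design's sample plots by SRSWOR;
3. observes occasion-2 values — disturbed everywhere, except that under
   *treatment bias* every sampled permanent plot reports its
   undisturbed value (the plots are exempted from disturbance once
   their location is known), while temporary occasion-2 plots always
   see the disturbed landscape;
4. runs the design's estimator.

Truth is shared across designs and bias variants within one
(scenario, iteration) because the affected-plot draw depends only on
the scenario and iteration child seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .estimators import (
    ChangeEstimate,
    estimate_cfi,
    estimate_temporary,
    spr_change,
    spr_fit,
)
from .population import (
    PopulationParams,
    TreePopulation,
    generate_population,
    plot_biomass,
    _generate_arrays,
)
from .allometry import LN_INTERCEPT, LN_SLOPE
from .scenarios import (
    DEFAULT_SCENARIOS,
    ScenarioSpec,
    TrueChange,
    disturbed_plot_biomass,
    select_affected_plots,
)

logger = logging.getLogger(__name__)

DESIGN_NAMES = ("temporary", "cfi", "spr")


@dataclass(frozen=True)
class DesignSpec:
    """Plot-type counts for one design: n1- (occasion-1 only), n12
    (permanent) and n-2 (occasion-2 only)."""

    design: str
    n_t1_only: int
    n_permanent: int
    n_t2_only: int

    def validate(self) -> None:
        if self.design not in DESIGN_NAMES:
            raise ConfigError(f"unknown design {self.design!r}")
        if min(self.n_t1_only, self.n_permanent, self.n_t2_only) < 0:
            raise ConfigError("plot-type counts must be >= 0")
        if self.design == "temporary" and self.n_permanent != 0:
            raise ConfigError("temporary design cannot have permanent plots")
        if self.design == "cfi" and (self.n_t1_only or self.n_t2_only):
            raise ConfigError("CFI uses permanent plots only")
        if self.design == "spr" and (self.n_permanent < 3 or self.n_t2_only < 2):
            raise ConfigError("SPR needs n12 >= 3 and n-2 >= 2")

    @property
    def n_occ1(self) -> int:
        return self.n_t1_only + self.n_permanent

    @property
    def n_occ2(self) -> int:
        return self.n_permanent + self.n_t2_only


#: study sample sizes: 375 plots assessed per occasion for every design
DEFAULT_DESIGNS: tuple[DesignSpec, ...] = (
    DesignSpec("temporary", 375, 0, 375),
    DesignSpec("cfi", 0, 375, 0),
    DesignSpec("spr", 125, 250, 125),
)


@dataclass(frozen=True)
class SampleRoles:
    """Plot ids (1-based) by role for one realised sample."""

    t1_only: np.ndarray
    permanent: np.ndarray
    t2_only: np.ndarray


def draw_samples(n_plots: int, d: DesignSpec, rng) -> SampleRoles:
    """SRSWOR role assignment for one iteration.

    CFI draws its permanent plots once; the temporary design draws the
    two occasions independently (chance overlap stays unmatched); SPR
    draws the occasion-1 plots, designates the permanent subset at
    random, and draws the new occasion-2 plots from the plots *not*
    sampled at occasion 1.
    """
    d.validate()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ids = np.arange(1, n_plots + 1)
    empty = np.array([], dtype=int)
    if d.design == "cfi":
        if d.n_permanent > n_plots:
            raise DesignError("permanent sample exceeds population")
        perm = gen.choice(ids, size=d.n_permanent, replace=False)
        return SampleRoles(empty, perm, empty)
    if d.design == "temporary":
        if max(d.n_t1_only, d.n_t2_only) > n_plots:
            raise DesignError("sample exceeds population")
        t1 = gen.choice(ids, size=d.n_t1_only, replace=False)
        t2 = gen.choice(ids, size=d.n_t2_only, replace=False)
        return SampleRoles(t1, empty, t2)
    # spr
    if d.n_occ1 > n_plots or d.n_t2_only > n_plots - d.n_occ1:
        raise DesignError("SPR plot types exceed population")
    occ1 = gen.choice(ids, size=d.n_occ1, replace=False)
    perm_pick = gen.choice(d.n_occ1, size=d.n_permanent, replace=False)
    perm_mask = np.zeros(d.n_occ1, dtype=bool)
    perm_mask[perm_pick] = True
    rest = np.setdiff1d(ids, occ1, assume_unique=False)
    t2 = gen.choice(rest, size=d.n_t2_only, replace=False)
    return SampleRoles(occ1[~perm_mask], occ1[perm_mask], t2)


class PanelSource:
    """Per-plot biomass columns of one fixed population, with the fully
    disturbed occasion-2 column cached per scenario rule."""

    def __init__(self, pop: TreePopulation):
        self.pop = pop
        self.n_plots = pop.n_plots
        self.x = plot_biomass(pop, 1).to_numpy()
        self.y_undist = plot_biomass(pop, 2).to_numpy()
        self._cols: dict[tuple, np.ndarray] = {}

    @classmethod
    def from_params(cls, params: PopulationParams) -> "PanelSource":
        return cls(generate_population(params))

    def disturbed_column(self, spec: ScenarioSpec) -> np.ndarray:
        key = (spec.rule, spec.threshold)
        if key not in self._cols:
            self._cols[key] = disturbed_plot_biomass(self.pop, spec).to_numpy()
        return self._cols[key]


@dataclass(frozen=True)
class IterationResult:
    scenario: str
    design: str
    bias: bool
    iteration: int
    estimate: ChangeEstimate
    truth: TrueChange


def _disturb(source: PanelSource, spec: ScenarioSpec, affected: np.ndarray) -> np.ndarray:
    y = source.y_undist.copy()
    if affected.size and spec.rule != "none":
        col = source.disturbed_column(spec)
        y[affected - 1] = col[affected - 1]
    return y


def run_iteration(source: PanelSource, scenario: ScenarioSpec, design: DesignSpec,
                  bias: bool, scenario_rng, sample_rng,
                  spr_variance_mode: str = "corrected",
                  affected: np.ndarray | None = None) -> IterationResult:
    """One Monte Carlo iteration; see the module docstring for the steps.

    ``affected`` can be supplied to share one disturbance draw across
    designs; otherwise it is drawn from ``scenario_rng``.
    """
    if affected is None:
        affected = select_affected_plots(source.n_plots, scenario.fraction, scenario_rng)
    y_dist = _disturb(source, scenario, affected)
    truth = TrueChange(
        change=float(y_dist.mean() - source.x.mean()),
        mean_t1=float(source.x.mean()),
        mean_t2=float(y_dist.mean()),
    )
    roles = draw_samples(source.n_plots, design, sample_rng)
    x = source.x
    y_perm_obs = source.y_undist if bias else y_dist  # bias exempts permanent plots

    if design.design == "temporary":
        est = estimate_temporary(x[roles.t1_only - 1], y_dist[roles.t2_only - 1])
    elif design.design == "cfi":
        est = estimate_cfi(x[roles.permanent - 1], y_perm_obs[roles.permanent - 1])
    else:
        occ1 = np.concatenate([roles.permanent, roles.t1_only])
        comps = spr_fit(
            x[occ1 - 1],
            x[roles.permanent - 1],
            y_perm_obs[roles.permanent - 1],
            y_dist[roles.t2_only - 1],
        )
        est = spr_change(comps, mode=spr_variance_mode)
    return IterationResult(scenario.name, design.design, bias, -1, est, truth)


@dataclass
class ExperimentConfig:
    """Configuration of the full scenario x design x bias experiment."""

    population: PopulationParams = field(default_factory=PopulationParams)
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS
    designs: tuple[DesignSpec, ...] = DEFAULT_DESIGNS
    bias_variants: tuple[bool, ...] = (False, True)
    iterations: int = 1000
    master_seed: int = 1
    spr_variance_mode: str = "corrected"
    #: redraw the affected plots every iteration (study protocol); when
    #: False a single disturbance realisation is reused throughout
    redraw_scenarios: bool = True

    def validate(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        self.population.validate()
        for s in self.scenarios:
            s.validate()
        for d in self.designs:
            d.validate()


def _cell_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Run every (scenario, design, bias, iteration) cell.

    Deterministic for a fixed master seed.  The affected-plot child seed
    depends only on (scenario, iteration), the sample child seed only on
    (scenario, design, iteration): truth is therefore identical across
    designs and bias variants within an iteration, and bias variants
    share the same realised samples.

    Returns a tidy DataFrame with one row per iteration result.
    """
    cfg.validate()
    source = PanelSource.from_params(cfg.population)
    rows = []
    for si, scenario in enumerate(cfg.scenarios):
        for it in range(cfg.iterations):
            if cfg.redraw_scenarios or it == 0:
                affected = select_affected_plots(
                    source.n_plots, scenario.fraction,
                    _cell_rng(cfg.master_seed, 1, si, it))
            for di, design in enumerate(cfg.designs):
                for bias in cfg.bias_variants:
                    # fresh generator from the same child seed: both bias
                    # variants see the identical sample draw
                    rng = _cell_rng(cfg.master_seed, 2, si, di, it)
                    res = run_iteration(
                        source, scenario, design, bias,
                        scenario_rng=None, sample_rng=rng,
                        spr_variance_mode=cfg.spr_variance_mode,
                        affected=affected,
                    )
                    rows.append(
                        {
                            "scenario": scenario.name,
                            "design": design.design,
                            "bias": bias,
                            "iteration": it,
                            "change": res.estimate.change,
                            "variance": res.estimate.variance,
                            "se": res.estimate.se,
                            "truth_change": res.truth.change,
                            "truth_mean_t1": res.truth.mean_t1,
                            "truth_mean_t2": res.truth.mean_t2,
                            "n_t1": res.estimate.n_t1,
                            "n_t2": res.estimate.n_t2,
                        }
                    )
        if progress:
            logger.info("scenario %s done (%d iterations)", scenario.name, cfg.iterations)
    return pd.DataFrame(rows)


def expected_true_change(source: PanelSource, spec: ScenarioSpec) -> float:
    """Exact expectation of the true change over the affected-plot draw.

    SRSWOR of k = floor(fraction * n) plots makes every plot affected
    with probability k/n, so the expected population change is the
    undisturbed growth minus k/n times the mean per-plot disturbance
    loss.  Useful for characterising a scenario without Monte Carlo
    noise from the disturbance draw.
    """
    spec.validate()
    growth = float(source.y_undist.mean() - source.x.mean())
    k = int(np.floor(spec.fraction * source.n_plots))
    if spec.rule == "none" or k == 0:
        return growth
    col = source.disturbed_column(spec)
    loss = float(source.y_undist.mean() - col.mean())
    return growth - k / source.n_plots * loss


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per (scenario, design, bias) cell.

    Columns: mean estimated change, mean signed and mean absolute error
    against truth, the estimate in percent of true change (ratio of
    means; NaN-flagged when the mean truth is ~0), the percent standard
    error (100 * mean SE / |mean estimate|), the mean SE, the empirical
    SD of the estimates and the iteration count.

    Percent quantities use ratios of cell means rather than means of
    per-iteration ratios: a per-iteration ratio has no finite moments
    when the denominator can approach zero.
    """
    if results.empty:
        raise ConfigError("no results to summarise")
    out = []
    for (scn, des, bias), g in results.groupby(["scenario", "design", "bias"], sort=False):
        if len(g) < 2:
            raise ConfigError("summary needs >= 2 iterations per cell")
        mean_change = g["change"].mean()
        mean_truth = g["truth_change"].mean()
        pct_true = 100.0 * mean_change / mean_truth if abs(mean_truth) > 1e-9 else math.nan
        mean_se = g["se"].mean()
        pct_se = 100.0 * mean_se / abs(mean_change) if mean_change != 0 else math.nan
        out.append(
            {
                "scenario": scn,
                "design": des,
                "bias": bias,
                "mean_change": mean_change,
                "mean_truth": mean_truth,
                "mean_error": (g["change"] - g["truth_change"]).mean(),
                "mean_abs_error": (g["change"] - g["truth_change"]).abs().mean(),
                "pct_of_true": pct_true,
                "mean_se": mean_se,
                "pct_se": pct_se,
                "empirical_sd": g["change"].std(ddof=1),
                "iterations": len(g),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# sampling-distribution validation (infinite-population replicates)

def simulate_sampling_distribution(params: PopulationParams, design: DesignSpec,
                                   n_reps: int, seed: int,
                                   spr_variance_mode: str = "corrected") -> pd.DataFrame:
    """Undisturbed change estimates on freshly generated plots.

    Each replicate generates exactly the plots the design needs from the
    superpopulation defined by ``params`` — an iid setting matching the
    estimators' no-finite-population-correction assumption — and records
    the change estimate and its estimated SE.  The empirical SD of the
    change column against the mean SE checks variance-estimator
    validity.
    """
    design.validate()
    rows = []
    per_ha = params.plot_area_m2 / 10_000.0
    for rep in range(n_reps):
        n_need = design.n_occ1 + design.n_t2_only
        p = PopulationParams(**{**params.__dict__, "n_plots": n_need, "seed": 0})
        plot_idx, d1, alive, d2 = _generate_arrays(p, seed + rep)
        a1 = np.exp(LN_INTERCEPT + LN_SLOPE * np.log(d1))
        a2 = np.where(alive, np.exp(LN_INTERCEPT + LN_SLOPE * np.log(d2)), 0.0)
        x = np.bincount(plot_idx, a1, n_need) / 1000.0 / per_ha
        y = np.bincount(plot_idx, a2, n_need) / 1000.0 / per_ha
        if design.design == "temporary":
            est = estimate_temporary(x[: design.n_t1_only], y[design.n_t1_only:])
        elif design.design == "cfi":
            est = estimate_cfi(x[: design.n_permanent], y[: design.n_permanent])
        else:
            n1 = design.n_occ1
            est = spr_change(
                spr_fit(x[:n1], x[: design.n_permanent], y[: design.n_permanent],
                        y[n1:]),
                mode=spr_variance_mode,
            )
        rows.append({"rep": rep, "change": est.change, "se": est.se})
    return pd.DataFrame(rows)
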