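"""Deforestation and degradation scenarios applied to a plot population.

A scenario removes biomass on a randomly chosen fraction of plots at the
second occasion: either every tree (deforestation) or the trees below /
above a dbh threshold (degradation by fuelwood or timber harvesting).
Occasion-1 values are never touched, and the "true" population change is
always computed over all plots of the population, not over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import LN_INTERCEPT, LN_SLOPE
from .errors import ConfigError
from .population import TreePopulation, plot_biomass, M2_PER_HA

RULES = ("none", "remove_below", "remove_above", "remove_all")


@dataclass(frozen=True)
class ScenarioSpec:
    """One disturbance scenario.

    ``fraction`` of plots is affected; on affected plots trees matching
    ``rule`` (strictly below / strictly above ``threshold`` cm, or all
    trees) contribute zero biomass at occasion 2.
    """

    name: str
    fraction: float
    rule: str
    threshold: float | None = None

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"scenario {self.name!r}: fraction must be in [0, 1]")
        if self.rule not in RULES:
            raise ConfigError(f"scenario {self.name!r}: unknown rule {self.rule!r}")
        if self.rule in ("remove_below", "remove_above"):
            if self.threshold is None or self.threshold <= 0:
                raise ConfigError(
                    f"scenario {self.name!r}: rule {self.rule!r} needs a positive threshold"
                )


#: the six study scenarios: no intervention, 10%/20% degradation of
#: small (dbh < 35 cm) or large (dbh > 45 cm) trees, and 5% deforestation
DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("no_intervention", 0.0, "none"),
    ScenarioSpec("deg10_below35", 0.10, "remove_below", 35.0),
    ScenarioSpec("deg10_above45", 0.10, "remove_above", 45.0),
    ScenarioSpec("deg20_below35", 0.20, "remove_below", 35.0),
    ScenarioSpec("deg20_above45", 0.20, "remove_above", 45.0),
    ScenarioSpec("defor5", 0.05, "remove_all"),
)


@dataclass(frozen=True)
class TrueChange:
    """Population-level mean change and occasion means, t/ha."""

    change: float
    mean_t1: float
    mean_t2: float


def select_affected_plots(n_plots: int, fraction: float, rng) -> np.ndarray:
    """Draw floor(fraction * n_plots) distinct plot ids (SRSWOR from 1..n).

    ``rng`` is a numpy Generator or an integer seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    if n_plots < 0:
        raise ConfigError("n_plots must be >= 0")
    k = int(np.floor(fraction * n_plots))
    if k == 0:
        return np.array([], dtype=int)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return np.sort(gen.choice(np.arange(1, n_plots + 1), size=k, replace=False))


def _removal_mask(trees: pd.DataFrame, spec: ScenarioSpec, dbh_basis: str) -> np.ndarray:
    """Boolean mask over tree rows: True where the rule removes the tree."""
    if dbh_basis not in ("t1", "t2"):
        raise ConfigError("dbh_basis must be 't1' or 't2'")
    if spec.rule == "none":
        return np.zeros(len(trees), dtype=bool)
    if spec.rule == "remove_all":
        return np.ones(len(trees), dtype=bool)
    d = trees[f"dbh_{dbh_basis}"].to_numpy(float)
    d = np.where(np.isnan(d), -np.inf, d)  # dead trees contribute 0 anyway
    if spec.rule == "remove_below":
        return d < spec.threshold
    return d > spec.threshold


def disturbed_plot_biomass(pop: TreePopulation, spec: ScenarioSpec,
                           dbh_basis: str = "t2") -> pd.Series:
    """Occasion-2 plot biomass (t/ha) as if every plot were affected."""
    spec.validate()
    y = plot_biomass(pop, 2)
    if spec.rule == "none" or len(pop.trees) == 0:
        return y if spec.rule != "remove_all" else y * 0.0
    remove = _removal_mask(pop.trees, spec, dbh_basis)
    alive = pop.trees["alive_t2"].to_numpy()
    keep = alive & ~remove
    d2 = pop.trees["dbh_t2"].to_numpy(float)
    agb = np.where(keep, np.exp(LN_INTERCEPT + LN_SLOPE * np.log(np.where(keep, d2, 1.0))), 0.0)
    per_ha = pop.plot_area_m2 / M2_PER_HA
    vals = np.bincount(pop.trees["plot_id"].to_numpy() - 1, weights=agb,
                       minlength=pop.n_plots) / 1000.0 / per_ha
    return pd.Series(vals, index=y.index, name="y_t2_disturbed")


def apply_scenario(pop: TreePopulation, spec: ScenarioSpec,
                   affected, dbh_basis: str = "t2") -> pd.DataFrame:
    """Build the plot panel with ``spec`` applied on the ``affected`` plots.

    The dbh tested against the threshold is the occasion-2 diameter by
    default (removal happens at occasion 2); ``dbh_basis='t1'`` switches
    to the occasion-1 diameter.
    """
    spec.validate()
    affected = np.asarray(list(affected), dtype=int)
    if affected.size and (affected.min() < 1 or affected.max() > pop.n_plots):
        raise ConfigError("affected plot ids outside the population")
    x = plot_biomass(pop, 1)
    y = plot_biomass(pop, 2)
    mask = np.zeros(pop.n_plots, dtype=bool)
    if affected.size:
        mask[affected - 1] = True
    y_dist = y.to_numpy().copy()
    if affected.size and spec.rule != "none":
        y_all = disturbed_plot_biomass(pop, spec, dbh_basis).to_numpy()
        y_dist[mask] = y_all[mask]
    return pd.DataFrame(
        {
            "plot_id": x.index,
            "x_t1": x.to_numpy(),
            "y_t2_undisturbed": y.to_numpy(),
            "y_t2_disturbed": y_dist,
            "affected": mask,
            "scenario": spec.name,
        }
    )


def true_change(panel: pd.DataFrame) -> TrueChange:
    """Population mean change (disturbed occasion 2 minus occasion 1)."""
    m1 = float(panel["x_t1"].mean())
    m2 = float(panel["y_t2_disturbed"].mean())
    return TrueChange(change=m2 - m1, mean_t1=m1, mean_t2=m2)
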