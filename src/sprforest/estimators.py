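"""Design-based estimators of current biomass and biomass change.

Three designs for sampling on two successive occasions:

* **temporary plots** — independent samples at each occasion; the change
  variance is the sum of the two mean variances,
  ``V_t(C) = V(Ybar) + V(Xbar)``.
* **CFI (continuous forest inventory)** — the same (permanent) plots at
  both occasions; the paired correlation r reduces the change variance,
  ``V_cfi(C) = V(Ybar) + V(Xbar) - 2 r sqrt(V(Ybar)) sqrt(V(Xbar))``.
* **SPR (sampling with partial replacement)** — a mix of remeasured
  plots (n12), plots measured only at occasion 1 (n1-) and new plots
  measured only at occasion 2 (n-2).  The current mean combines a
  regression-updated mean (slope of Y on X on the remeasured plots,
  applied to the full occasion-1 mean) with the new-plot mean by
  inverse-variance weighting; change subtracts the full occasion-1
  mean.

All estimators take plain value arrays in t/ha and know nothing about
plot roles, scenarios or bias flags.  Formulas omit finite-population
corrections throughout.

The SPR change variance is offered in two modes.  The published
approximation writes its covariance term as ``2 (wI/w) beta * SSX1 /
(n1 - 1)`` — i.e. beta times the occasion-1 sample *variance* rather
than the variance of the occasion-1 *mean* — which is dimensionally
inconsistent with the other two terms (both O(s^2/n)) and goes far
negative on realistic inputs.  The default ``corrected`` mode divides
that term by n1; ``as_printed`` reproduces the published form verbatim
(unclamped, flagged when negative) for fidelity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

from .errors import (
    DegenerateRegressionError,
    DesignError,
    InsufficientDataError,
    PairingError,
)


@dataclass(frozen=True)
class ChangeEstimate:
    """An estimated biomass change with its variance."""

    design: str
    change: float
    variance: float
    se: float
    n_t1: int
    n_t2: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CurrentEstimate:
    """Combined SPR current-state estimate."""

    mean: float
    variance: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SPRComponents:
    """Every intermediate quantity of the SPR estimation chain."""

    n1: int
    n12: int
    n_minus2: int
    xbar1: float
    xbar12: float
    ybar12: float
    ybar_minus2: float
    s_xy: float
    s2_x12: float
    s2_y12: float
    s2_yx: float
    r: float
    beta_yx: float
    s2_x1: float
    yI: float
    yII: float
    vI: float
    vII: float
    wI: float = field(init=False)
    wII: float = field(init=False)
    w: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "wI", 1.0 / self.vI if self.vI > 0 else math.inf)
        object.__setattr__(self, "wII", 1.0 / self.vII if self.vII > 0 else math.inf)
        object.__setattr__(self, "w", self.wI + self.wII)


def _as_array(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _mean_variance(v: np.ndarray) -> float:
    """Variance of the sample mean: sum of squared deviations / (n(n-1))."""
    n = v.size
    return float(np.sum((v - v.mean()) ** 2) / (n * (n - 1)))


def estimate_temporary(x, y) -> ChangeEstimate:
    """Change estimate from two independent (unmatched) samples."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("temporary design needs >= 2 plots per occasion")
    var = _mean_variance(x) + _mean_variance(y)
    return ChangeEstimate(
        design="temporary", change=float(y.mean() - x.mean()),
        variance=var, se=math.sqrt(var), n_t1=x.size, n_t2=y.size,
    )


def estimate_cfi(x, y) -> ChangeEstimate:
    """Change estimate from paired permanent plots.

    Falls back to the unmatched variance (with a flag) when either
    occasion has zero spread, where r is undefined.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if x.size != y.size:
        raise PairingError(f"paired samples of unequal length ({x.size} vs {y.size})")
    if x.size < 3:
        raise InsufficientDataError("CFI needs >= 3 paired plots")
    vx = _mean_variance(x)
    vy = _mean_variance(y)
    flags: tuple[str, ...] = ()
    if vx == 0.0 or vy == 0.0:
        warnings.warn("zero variance in a paired sample: correlation undefined, "
                      "using the unmatched variance", stacklevel=2)
        var = vx + vy
        flags = ("r_undefined",)
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        var = max(vy + vx - 2.0 * r * math.sqrt(vy) * math.sqrt(vx), 0.0)
    return ChangeEstimate(
        design="cfi", change=float(y.mean() - x.mean()),
        variance=var, se=math.sqrt(var), n_t1=x.size, n_t2=y.size, flags=flags,
    )


def spr_fit(x1_all, x12, y12, y_new) -> SPRComponents:
    """Compute every SPR component from the three plot groups.

    ``x1_all`` holds all n1 occasion-1 measurements (remeasured plots
    plus occasion-1-only plots); ``x12``/``y12`` the paired values on
    the n12 remeasured plots; ``y_new`` the n-2 new-plot values.
    """
    x1_all = _as_array(x1_all, "x1_all")
    x12 = _as_array(x12, "x12")
    y12 = _as_array(y12, "y12")
    y_new = _as_array(y_new, "y_new")
    n1, n12, n_minus2 = x1_all.size, x12.size, y_new.size
    if x12.size != y12.size:
        raise PairingError("x12 and y12 must have equal length")
    if n12 < 3:
        raise DesignError("SPR regression needs at least 3 remeasured plots")
    if n_minus2 < 2:
        raise DesignError("SPR needs at least 2 new occasion-2 plots")
    if n1 < n12:
        raise DesignError("x1_all must contain all occasion-1 plots (n1 >= n12)")

    xbar1 = float(x1_all.mean())
    xbar12 = float(x12.mean())
    ybar12 = float(y12.mean())
    ybar_m2 = float(y_new.mean())

    dx = x12 - xbar12
    dy = y12 - ybar12
    ssx = float(np.sum(dx**2))
    ssy = float(np.sum(dy**2))
    if ssx == 0.0:
        raise DegenerateRegressionError("constant occasion-1 values on remeasured plots")
    s_xy = float(np.sum(dy * dx)) / (n12 - 1)
    s2_x12 = ssx / (n12 - 1)
    s2_y12 = ssy / (n12 - 1)
    beta = s_xy / s2_x12
    r = s_xy / math.sqrt(s2_x12 * s2_y12) if s2_y12 > 0 else 0.0
    s2_yx = (1.0 - r * r) * ssy / (n12 - 2)

    yI = ybar12 + beta * (xbar1 - xbar12)
    vI = s2_yx * (1.0 / n12 + (xbar1 - xbar12) ** 2 / ssx) + (s2_y12 - s2_yx) / n1
    vII = _mean_variance(y_new)
    s2_x1 = float(np.sum((x1_all - xbar1) ** 2)) / (n1 - 1)

    return SPRComponents(
        n1=n1, n12=n12, n_minus2=n_minus2,
        xbar1=xbar1, xbar12=xbar12, ybar12=ybar12, ybar_minus2=ybar_m2,
        s_xy=s_xy, s2_x12=s2_x12, s2_y12=s2_y12, s2_yx=max(s2_yx, 0.0),
        r=r, beta_yx=beta, s2_x1=s2_x1,
        yI=yI, yII=ybar_m2, vI=max(vI, 0.0), vII=vII,
    )


def spr_current(c: SPRComponents) -> CurrentEstimate:
    """Inverse-variance combination of the two SPR current-state means.

    The combined variance carries the small-sample inflation factor
    ``1 + 4 wI wII (1/(n12-1) + 1/(n-2-1)) / w^2`` on top of ``1/w``.
    """
    if c.vI <= 0.0 or c.vII <= 0.0:
        mean = c.yI if c.vI <= 0.0 else c.yII
        warnings.warn("zero component variance: degenerate SPR weights",
                      stacklevel=2)
        return CurrentEstimate(mean=mean, variance=0.0, flags=("degenerate_weights",))
    mean = (c.wI * c.yI + c.wII * c.yII) / c.w
    inflation = 4.0 * c.wI * c.wII * (1.0 / (c.n12 - 1) + 1.0 / (c.n_minus2 - 1)) / c.w**2
    variance = (1.0 + inflation) / c.w
    return CurrentEstimate(mean=mean, variance=variance)


def spr_change(c: SPRComponents, mode: str = "corrected") -> ChangeEstimate:
    """SPR change estimate: combined current mean minus the full
    occasion-1 mean, with the approximate change variance.

    ``mode='corrected'`` (default) divides the covariance term by n1 so
    all three terms are variances of means; negative results are clamped
    to 0 with a flag.  ``mode='as_printed'`` keeps the published form and
    reports negative variances unclamped with a flag.
    """
    if mode not in ("corrected", "as_printed"):
        raise ValueError("mode must be 'corrected' or 'as_printed'")
    cur = spr_current(c)
    change = cur.mean - c.xbar1
    flags = list(cur.flags)
    cov_term = 2.0 * (c.wI / c.w if c.w > 0 and math.isfinite(c.w) else 1.0) \
        * c.beta_yx * c.s2_x1
    if mode == "corrected":
        cov_term /= c.n1
    base = (1.0 / c.w if math.isfinite(c.w) and c.w > 0 else 0.0) + c.s2_x1 / c.n1
    variance = base - cov_term
    if variance < 0.0:
        if mode == "corrected":
            warnings.warn("negative corrected SPR change variance clamped to 0",
                          stacklevel=2)
            variance = 0.0
            flags.append("variance_clamped")
        else:
            flags.append("negative_variance")
    se = math.sqrt(variance) if variance >= 0.0 else math.nan
    return ChangeEstimate(
        design="spr", change=change, variance=variance, se=se,
        n_t1=c.n1, n_t2=c.n12 + c.n_minus2, flags=tuple(flags),
    )


def percent_standard_error(e: ChangeEstimate, denominator: str = "abs_change",
                           ref: float | None = None) -> float:
    """Percent standard error, 100 * se / |ref|.

    ``ref`` defaults to the estimate's own change when ``denominator``
    is ``abs_change``; for ``current_mean`` it must be supplied.  A zero
    reference yields NaN.
    """
    if denominator not in ("abs_change", "current_mean"):
        raise ValueError("denominator must be 'abs_change' or 'current_mean'")
    if ref is None:
        if denominator == "current_mean":
            raise ValueError("denominator='current_mean' requires ref")
        ref = e.change
    if ref == 0.0:
        return math.nan
    return 100.0 * e.se / abs(ref)
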