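"""Treatment-bias diagnostic: permanent vs temporary plots.

If permanent plots are quietly exempted from logging or degradation,
their current-occasion biomass drifts above that of freshly placed
temporary plots, whose locations nobody could have known in advance.
Comparing the two samples at the current occasion therefore probes for
treatment bias: a significant difference is evidence of bias, while a
passed equivalence test (TOST within a margin) supports its absence.
Both tests use unequal-variance (Welch) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from statsmodels.stats import weightstats

from .errors import InsufficientDataError

VERDICTS = ("no_evidence_of_bias", "evidence_of_bias", "inconclusive")


@dataclass(frozen=True)
class BiasCheckResult:
    mean_difference: float  # permanent - temporary, t/ha
    se_difference: float
    t_statistic: float
    p_value: float  # two-sided Welch difference test
    p_equivalence: float  # TOST p-value
    alpha: float
    margin: float  # equivalence margin, t/ha
    verdict: str


def compare_permanent_temporary(y_perm, y_temp, alpha: float = 0.05,
                                margin: float | None = None) -> BiasCheckResult:
    """Welch difference test plus TOST equivalence of the two means.

    ``margin`` defaults to 10% of the temporary-plot mean.  Verdict:
    ``evidence_of_bias`` when the difference test rejects at ``alpha``;
    otherwise ``no_evidence_of_bias`` when TOST passes at ``alpha``;
    otherwise ``inconclusive``.
    """
    y_perm = np.asarray(y_perm, dtype=float).ravel()
    y_temp = np.asarray(y_temp, dtype=float).ravel()
    if y_perm.size < 2 or y_temp.size < 2:
        raise InsufficientDataError("both samples need at least 2 plots")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if margin is None:
        margin = 0.1 * abs(float(y_temp.mean()))
    if margin <= 0.0:
        raise ValueError("equivalence margin must be positive")

    diff = float(y_perm.mean() - y_temp.mean())
    se = math.sqrt(y_perm.var(ddof=1) / y_perm.size + y_temp.var(ddof=1) / y_temp.size)

    if y_perm.size == y_temp.size and np.array_equal(np.sort(y_perm), np.sort(y_temp)):
        # literally the same measurements: equivalent by definition
        return BiasCheckResult(0.0, se, 0.0, 1.0, 0.0, alpha, margin,
                               "no_evidence_of_bias")

    if se == 0.0:
        # degenerate spread: the raw difference decides; any nonzero
        # difference with zero sampling noise is evidence of bias
        if diff == 0.0:
            return BiasCheckResult(diff, se, 0.0, 1.0, 0.0, alpha, margin,
                                   "no_evidence_of_bias")
        return BiasCheckResult(diff, se, math.inf, 0.0, 1.0, alpha, margin,
                               "evidence_of_bias")

    t, p, _ = weightstats.ttest_ind(y_perm, y_temp, usevar="unequal")
    p_tost, _, _ = weightstats.ttost_ind(y_perm, y_temp, -margin, margin,
                                         usevar="unequal")
    if p < alpha:
        verdict = "evidence_of_bias"
    elif p_tost < alpha:
        verdict = "no_evidence_of_bias"
    else:
        verdict = "inconclusive"
    return BiasCheckResult(diff, se, float(t), float(p), float(p_tost),
                           alpha, margin, verdict)
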