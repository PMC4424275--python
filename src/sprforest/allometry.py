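"""Allometric conversion of tree diameter to aboveground biomass.

The model is a single-predictor log-log regression for moist tropical
forest, ln(AGB) = a + b * ln(dbh) with AGB in kg and dbh in cm, which is
the standard form for pan-tropical biomass allometry.  The coefficients
shipped here (a = -1.562, b = 2.148) are those selected for Guiana-Shield
forest and are used for every biomass figure in this package.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

#: intercept of the log-log allometric model (ln kg)
LN_INTERCEPT: float = -1.562
#: slope of the log-log allometric model (dimensionless)
LN_SLOPE: float = 2.148


def agb_from_dbh(dbh):
    """Aboveground biomass (kg) of a tree from its dbh (cm).

    Parameters
    ----------
    dbh : float or array-like
        Diameter at breast height in cm; must be strictly positive.

    Returns
    -------
    float or ndarray
        exp(-1.562 + 2.148 * ln(dbh)), strictly increasing in dbh.

    Raises
    ------
    DomainError
        If any diameter is not strictly positive.
    """
    arr = np.asarray(dbh, dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr <= 0.0)):
        raise DomainError("dbh must be a finite positive diameter in cm")
    out = np.exp(LN_INTERCEPT + LN_SLOPE * np.log(arr))
    if np.isscalar(dbh) or arr.ndim == 0:
        return float(out)
    return out
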