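"""Independent brute-force recomputation of the change estimators.

Pure-Python explicit sums, sharing no code with the package: the oracle
against which the vectorised estimators are checked.
"""

import math


def _mean(v):
    return sum(v) / len(v)


def mean_variance(v):
    m = _mean(v)
    n = len(v)
    return sum((x - m) ** 2 for x in v) / (n * (n - 1))


def temporary_oracle(x, y):
    return {
        "change": _mean(y) - _mean(x),
        "variance": mean_variance(x) + mean_variance(y),
    }


def cfi_oracle(x, y):
    n = len(x)
    mx, my = _mean(x), _mean(y)
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    r = sxy / math.sqrt(sxx * syy)
    vx = sxx / (n * (n - 1))
    vy = syy / (n * (n - 1))
    return {
        "change": my - mx,
        "variance": max(vy + vx - 2.0 * r * math.sqrt(vy) * math.sqrt(vx), 0.0),
        "r": r,
    }


def spr_oracle(x1_all, x12, y12, y_new, mode="corrected"):
    """Every SPR component, the combined current estimate, and the change
    estimate, from first principles."""
    n1, n12, nm2 = len(x1_all), len(x12), len(y_new)
    xbar1 = _mean(x1_all)
    xbar12 = _mean(x12)
    ybar12 = _mean(y12)
    ybar_m2 = _mean(y_new)
    ssx = sum((a - xbar12) ** 2 for a in x12)
    ssy = sum((b - ybar12) ** 2 for b in y12)
    s_xy = sum((b - ybar12) * (a - xbar12) for a, b in zip(x12, y12)) / (n12 - 1)
    s2_x12 = ssx / (n12 - 1)
    s2_y12 = ssy / (n12 - 1)
    beta = s_xy / s2_x12
    r = s_xy / math.sqrt(s2_x12 * s2_y12)
    s2_yx = (1.0 - r * r) * ssy / (n12 - 2)
    yI = ybar12 + beta * (xbar1 - xbar12)
    vI = s2_yx * (1.0 / n12 + (xbar1 - xbar12) ** 2 / ssx) + (s2_y12 - s2_yx) / n1
    vII = mean_variance(y_new)
    s2_x1 = sum((a - xbar1) ** 2 for a in x1_all) / (n1 - 1)
    wI, wII = 1.0 / vI, 1.0 / vII
    w = wI + wII
    ybar = (wI * yI + wII * ybar_m2) / w
    v_ybar = (1.0 + 4.0 * wI * wII * (1.0 / (n12 - 1) + 1.0 / (nm2 - 1)) / w**2) / w
    change = ybar - xbar1
    cov = 2.0 * (wI / w) * beta * s2_x1
    if mode == "corrected":
        cov /= n1
    variance = 1.0 / w + s2_x1 / n1 - cov
    if mode == "corrected":
        variance = max(variance, 0.0)
    return {
        "n1": n1, "n12": n12, "n_minus2": nm2,
        "xbar1": xbar1, "xbar12": xbar12, "ybar12": ybar12,
        "ybar_minus2": ybar_m2,
        "s_xy": s_xy, "s2_x12": s2_x12, "s2_y12": s2_y12, "s2_yx": s2_yx,
        "r": r, "beta_yx": beta, "s2_x1": s2_x1,
        "yI": yI, "yII": ybar_m2, "vI": vI, "vII": vII,
        "wI": wI, "wII": wII, "w": w,
        "current_mean": ybar, "current_variance": v_ybar,
        "change": change, "change_variance": variance,
    }
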