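"""Non-phylogenetic era-split regressions of log wingspan on geological age.

Ages are in Ma before present, so a body-size *increase* toward the present
appears as a negative slope against age; reversing the age axis flips the
sign exactly. Both ordinary least squares (t-based confidence interval) and
major-axis regression (bootstrap confidence interval) are provided because
the two are standard alternatives when neither variable is error-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .seeding import rng_for


@dataclass
class TrendFit:
    """A fitted size-versus-age line for one time interval."""

    interval: str
    n: int
    slope: float
    slope_ci: tuple[float, float]  # 95%
    intercept: float
    intercept_m: float  # back-transform of the intercept to metres
    p_value: float
    method: str  # ols | major_axis


def split_by_interval(
    ages: Sequence[float], values: Sequence[float], boundary_ma: float
):
    """Partition (age, value) pairs at a boundary age (Ma before present).

    A taxon whose age equals the boundary goes to the *older* subset.
    Returns ``((ages_old, values_old), (ages_young, values_young))``.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    old = ages >= boundary_ma
    if not old.any():
        raise ValidationError(f"no taxa older than {boundary_ma} Ma")
    if old.all():
        raise ValidationError(f"no taxa younger than {boundary_ma} Ma")
    return (ages[old], values[old]), (ages[~old], values[~old])


def _check_xy(age, y):
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(age) < 3:
        raise ValidationError("trend regression needs n >= 3")
    if np.var(age) == 0:
        raise ValidationError("zero age variance")
    return age, y


def ols_fit(age, log_size, interval: str = "") -> TrendFit:
    """Ordinary least squares of log10 size on age, with t-based 95% CI."""
    age, y = _check_xy(age, log_size)
    n = len(age)
    res = stats.linregress(age, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    half = tcrit * res.stderr
    return TrendFit(
        interval=interval,
        n=n,
        slope=float(res.slope),
        slope_ci=(float(res.slope - half), float(res.slope + half)),
        intercept=float(res.intercept),
        intercept_m=float(10.0 ** res.intercept),
        p_value=float(res.pvalue),
        method="ols",
    )


def _ma_slope(age, y) -> float:
    """Major-axis slope: leading eigenvector of the 2x2 covariance matrix."""
    C = np.cov(np.vstack([age, y]))
    evals, evecs = np.linalg.eigh(C)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValidationError("major-axis slope undefined (vertical axis)")
    return float(v[1] / v[0])


def major_axis_fit(
    age, log_size, interval: str = "", n_boot: int = 2000, seed: int = 0
) -> TrendFit:
    """Major-axis regression with a seeded nonparametric bootstrap CI.

    The slope is the direction of the leading principal axis of (age, size);
    the p-value is taken from the correlation test (the major-axis slope is
    zero-consistent exactly when the correlation is)."""
    age, y = _check_xy(age, log_size)
    n = len(age)
    slope = _ma_slope(age, y)
    intercept = float(np.mean(y) - slope * np.mean(age))
    rng = rng_for(seed, "ma_bootstrap", interval)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.var(age[idx]) == 0:
            boot[b] = np.nan
            continue
        boot[b] = _ma_slope(age[idx], y[idx])
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    if np.std(y) == 0 or np.std(age) == 0:
        p = 1.0
    else:
        p = float(stats.pearsonr(age, y).pvalue)
    return TrendFit(
        interval=interval,
        n=n,
        slope=slope,
        slope_ci=(float(lo), float(hi)),
        intercept=intercept,
        intercept_m=float(10.0 ** intercept),
        p_value=p,
        method="major_axis",
    )


def era_split_trends(
    ages, values, boundary_ma: float, seed: int = 0,
    labels: tuple[str, str] = ("pre_boundary", "post_boundary"),
) -> dict[str, dict[str, TrendFit]]:
    """OLS and major-axis fits on both sides of a boundary age."""
    (a_old, v_old), (a_young, v_young) = split_by_interval(ages, values, boundary_ma)
    out = {}
    for lab, (a, v) in zip(labels, [(a_old, v_old), (a_young, v_young)]):
        out[lab] = {
            "ols": ols_fit(a, v, interval=lab),
            "major_axis": major_axis_fit(a, v, interval=lab, seed=seed),
        }
    return out
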