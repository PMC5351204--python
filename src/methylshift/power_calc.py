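"""Two-sample t-test power for unequal group sizes (noncentral t)."""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def t2n_power(n1: int, n2: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at effect size d (Cohen's d).

    power = P(|T'| > t_crit) with T' noncentral t, df = n1 + n2 - 2 and
    noncentrality d * sqrt(n1 n2 / (n1 + n2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def solve_d(n1: int, n2: int, alpha: float = 0.05, power: float = 0.8) -> float:
    """Effect size d achieving the target power, by root bracketing to 1e-6."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if power <= t2n_power(n1, n2, 0.0, alpha):
        raise ValueError("target power not above the null rejection rate")
    hi = 0.5
    while t2n_power(n1, n2, hi, alpha) < power:
        hi *= 2
        if hi > 1e3:
            raise ValueError("cannot bracket the target power")
    return float(
        optimize.brentq(
            lambda d: t2n_power(n1, n2, d, alpha) - power, 0.0, hi, xtol=1e-9
        )
    )


def min_detectable_diff(
    n1: int, n2: int, alpha: float, power: float, sd: float
) -> float:
    """Smallest mean methylation difference (percentage points) detectable.

    Solves the power equation for Cohen's d and scales by the per-group
    SD of methylation percentages (a user input; not derivable from
    group sizes alone).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return solve_d(n1, n2, alpha, power) * sd


def power_table(
    n1: int, n2: int, alpha: float = 0.05, d_grid: np.ndarray | None = None
):
    """Power over a grid of effect sizes, as a DataFrame."""
    import pandas as pd

    if d_grid is None:
        d_grid = np.round(np.arange(0.1, 1.55, 0.1), 2)
    return pd.DataFrame(
        {"d": d_grid, "power": [t2n_power(n1, n2, d, alpha) for d in d_grid]}
    )
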