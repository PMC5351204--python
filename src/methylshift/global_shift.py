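"""Global hypermethylation-proportion test against the bootstrap null.

Among sites nominally significant at a p-value cutoff, the fraction
with a positive diagnosis coefficient is compared to the same fraction
recomputed in each residual bootstrap; the empirical p is one-sided
toward hypermethylation with add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylshift.site_diffmeth import BootstrapNull

DEFAULT_CUTOFFS = (0.05, 5e-3, 5e-4)


@dataclass
class GlobalShiftResult:
    context: str
    cutoff: float
    n_nominal: int
    prop_hyper: float  # NaN when no nominal sites
    boot_props: np.ndarray
    empirical_p: float
    unstable: bool = False


def _prop_hyper(p: np.ndarray, beta: np.ndarray, cutoff: float) -> tuple[int, float]:
    sel = p < cutoff
    n_nominal = int(np.sum(sel))
    nz = sel & (beta != 0)
    if nz.sum() == 0:
        return n_nominal, np.nan
    return n_nominal, float(np.mean(beta[nz] > 0))


def hyper_proportion(fits: pd.DataFrame, cutoff: float) -> tuple[int, float]:
    """(number of nominal sites, fraction hypermethylated among them).

    Sites with a diagnosis coefficient of exactly zero are excluded from
    both numerator and denominator; with no nominal sites the proportion
    is NaN.
    """
    if len(fits) == 0:
        raise ValueError("no site fits")
    return _prop_hyper(fits["p"].to_numpy(), fits["beta_diag"].to_numpy(), cutoff)


def global_shift_test(
    fits: pd.DataFrame,
    null: BootstrapNull,
    cutoffs: tuple = DEFAULT_CUTOFFS,
    context: str = "all",
) -> list[GlobalShiftResult]:
    """Test the observed hyper-proportion against the bootstrap null.

    empirical_p = (1 + #{b : prop_hyper_b >= observed}) / (B + 1),
    one-sided toward hypermethylation. A cutoff is flagged unstable when
    more than half the bootstraps have no nominal site.
    """
    p_obs = fits["p"].to_numpy()
    beta_obs = fits["beta_diag"].to_numpy()
    results = []
    for cutoff in cutoffs:
        n_nominal, prop = _prop_hyper(p_obs, beta_obs, cutoff)
        boot_props = np.full(null.B, np.nan)
        for b in range(null.B):
            _, boot_props[b] = _prop_hyper(null.p_null[b], null.beta_null[b], cutoff)
        n_empty = int(np.isnan(boot_props).sum())
        if np.isnan(prop):
            emp_p = np.nan
        else:
            emp_p = (1.0 + np.nansum(boot_props >= prop)) / (null.B + 1.0)
        results.append(
            GlobalShiftResult(
                context=context,
                cutoff=cutoff,
                n_nominal=n_nominal,
                prop_hyper=prop,
                boot_props=boot_props,
                empirical_p=emp_p,
                unstable=n_empty > null.B / 2,
            )
        )
    return results


def shift_vs_effect_size(
    fits: pd.DataFrame, min_abs_beta: np.ndarray, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Hyper-proportion among nominal sites passing increasing |beta| floors."""
    if len(fits) == 0:
        raise ValueError("no site fits")
    p = fits["p"].to_numpy()
    beta = fits["beta_diag"].to_numpy()
    rows = []
    for thr in np.asarray(min_abs_beta, dtype=float):
        sel = (p < p_cutoff) & (np.abs(beta) >= thr) & (beta != 0)
        n = int(sel.sum())
        prop = float(np.mean(beta[sel] > 0)) if n else np.nan
        rows.append({"min_abs_beta": thr, "n_sites": n, "prop_hyper": prop})
    return pd.DataFrame(rows)


def results_table(results: list[GlobalShiftResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "context": r.context,
                "cutoff": r.cutoff,
                "n_nominal": r.n_nominal,
                "prop_hyper": r.prop_hyper,
                "empirical_p": r.empirical_p,
                "unstable": r.unstable,
            }
            for r in results
        ]
    )
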