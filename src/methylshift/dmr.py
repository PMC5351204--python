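"""Bump-hunting DMR detection with bootstrap family-wise error rates.

Sites are clustered by genomic gap, per-site diagnosis coefficients are
smoothed within large clusters by a running weighted mean, a data-driven
cutoff is taken as a high quantile of |smoothed values|, and maximal
runs beyond the cutoff become candidate regions. The FWER of a region is
the fraction of residual bootstraps containing a null candidate that is
strictly longer and has a strictly higher |average coefficient|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylshift.preprocess import MethylationMatrix
from methylshift.site_diffmeth import (
    BootstrapNull,
    DesignMatrix,
    fit_site_models,
    residual_bootstrap,
)

REGION_COLUMNS = ["chrom", "start", "end", "n_sites", "value", "length_bp", "direction", "fwer"]


def cluster_sites(chroms: np.ndarray, positions: np.ndarray, maxgap: int = 300) -> np.ndarray:
    """Label sites so that same-chromosome neighbors within maxgap share a cluster.

    Positions must be sorted within each chromosome (genomic order).
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    n = len(positions)
    labels = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if chroms[i] != chroms[i - 1]:
            labels[i] = labels[i - 1] + 1
        elif positions[i] < positions[i - 1]:
            raise ValueError("positions not sorted within chromosome")
        elif positions[i] - positions[i - 1] > maxgap:
            labels[i] = labels[i - 1] + 1
        else:
            labels[i] = labels[i - 1]
    return labels


def smooth_coefficients(
    positions: np.ndarray,
    values: np.ndarray,
    clusters: np.ndarray,
    window: int = 5,
    min_sites: int = 7,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Running weighted mean over a centered window, within large clusters.

    Clusters with fewer than ``min_sites`` members pass through
    unsmoothed; at cluster edges the window truncates to available sites.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    out = values.copy()
    half = window // 2
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        m = len(idx)
        if m < min_sites:
            continue
        v = values[idx]
        w = weights[idx]
        sm = np.empty(m)
        for i in range(m):
            lo, hi = max(0, i - half), min(m, i + half + 1)
            ww = w[lo:hi]
            sm[i] = np.average(v[lo:hi], weights=ww) if ww.sum() > 0 else v[i]
        out[idx] = sm
    return out


def pick_cutoff(smoothed: np.ndarray, quantile: float = 0.99) -> float:
    """Data-driven cutoff: the ``quantile`` of |smoothed| over all sites."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    return float(np.quantile(np.abs(np.asarray(smoothed, dtype=float)), quantile))


def find_candidate_regions(
    chroms: np.ndarray,
    positions: np.ndarray,
    smoothed: np.ndarray,
    raw_values: np.ndarray,
    clusters: np.ndarray,
    cutoff: float,
) -> pd.DataFrame:
    """Maximal same-direction runs beyond the cutoff, within clusters.

    ``value`` is the mean of the member sites' raw coefficients; start
    and end are the 1-based positions of the first and last member site.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    state = np.where(smoothed > cutoff, 1, np.where(smoothed < -cutoff, -1, 0))
    rows = []
    n = len(positions)
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and state[j + 1] == state[i]
            and clusters[j + 1] == clusters[i]
        ):
            j += 1
        members = slice(i, j + 1)
        rows.append(
            {
                "chrom": chroms[i],
                "start": int(positions[i]),
                "end": int(positions[j]),
                "n_sites": j - i + 1,
                "value": float(np.mean(raw_values[members])),
                "length_bp": int(positions[j] - positions[i] + 1),
                "direction": int(state[i]),
                "fwer": np.nan,
            }
        )
        i = j + 1
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def compute_fwer(
    observed: pd.DataFrame, bootstrap_regions: list[pd.DataFrame], B: int | None = None
) -> pd.DataFrame:
    """FWER per observed region from per-bootstrap null candidate regions.

    fwer(r) = fraction of bootstraps containing a null region q with
    length_bp(q) > length_bp(r) and |value(q)| > |value(r)| (strict on both).
    """
    if B is None:
        B = len(bootstrap_regions)
    if B == 0:
        raise ValueError("B must be > 0")
    out = observed.copy()
    lengths = out["length_bp"].to_numpy()
    values = np.abs(out["value"].to_numpy())
    counts = np.zeros(len(out))
    for boot in bootstrap_regions:
        if len(boot) == 0:
            continue
        bl = boot["length_bp"].to_numpy()
        bv = np.abs(boot["value"].to_numpy())
        dominated = (
            (bl[None, :] > lengths[:, None]) & (bv[None, :] > values[:, None])
        ).any(axis=1)
        counts += dominated
    out["fwer"] = counts / B
    return out


def dmr_significance(
    regions: pd.DataFrame, n_tests: int = 24, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag regions with fwer strictly below the Bonferroni threshold alpha/n_tests."""
    threshold = significance_threshold(n_tests, alpha)
    out = regions.copy()
    out["significant"] = out["fwer"] < threshold
    return out


def significance_threshold(n_tests: int = 24, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def dmr_analysis(
    meth: MethylationMatrix,
    full_design: DesignMatrix,
    null_design: DesignMatrix,
    maxgap: int = 300,
    quantile: float = 0.99,
    window: int = 5,
    min_sites: int = 7,
    B: int = 1000,
    seed: int = 0,
    n_tests: int = 24,
    alpha: float = 0.05,
    null: BootstrapNull | None = None,
) -> pd.DataFrame:
    """End-to-end DMR scan: fit, cluster, smooth, cut, bootstrap FWER.

    Null candidate regions use the same pipeline and the observed cutoff
    on each bootstrap's refitted coefficients. Pass ``null`` to reuse an
    existing bootstrap (must match the site set).
    """
    fits = fit_site_models(meth, full_design)
    chroms = meth.sites["chrom"].to_numpy()
    positions = meth.sites["pos"].to_numpy()
    beta = fits["beta_diag"].to_numpy()
    clusters = cluster_sites(chroms, positions, maxgap)
    smoothed = smooth_coefficients(positions, beta, clusters, window, min_sites)
    cutoff = pick_cutoff(smoothed, quantile)
    observed = find_candidate_regions(chroms, positions, smoothed, beta, clusters, cutoff)

    if null is None:
        null = residual_bootstrap(meth, full_design, null_design, B=B, seed=seed)
    boot_regions = []
    for b in range(null.B):
        bb = null.beta_null[b]
        sm = smooth_coefficients(positions, bb, clusters, window, min_sites)
        boot_regions.append(
            find_candidate_regions(chroms, positions, sm, bb, clusters, cutoff)
        )
    observed = compute_fwer(observed, boot_regions)
    return dmr_significance(observed, n_tests=n_tests, alpha=alpha)
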