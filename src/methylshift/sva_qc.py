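"""Surrogate-variable estimation, iterative sample-outlier removal, and QC.

Surrogate variables are estimated with a simplified iteratively
reweighted SVA: the methylation matrix is residualized against the
protected design (diagnosis retained), per-site weights favoring sites
associated with the current SVs but not the protected variable are
computed from nested-model F tests, and the SVD is recomputed on the
reweighted residual matrix for a fixed number of rounds.

Sample outliers are any sample beyond ``z`` SDs from an SV column mean,
removed iteratively; each removal round can be validated externally by
known-meQTL recovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methylshift.preprocess import CountMatrix, MethylationMatrix
from methylshift.site_diffmeth import DesignMatrix, build_design

logger = logging.getLogger(__name__)


@dataclass
class SurrogateVariableSet:
    samples: list[str]
    sv: np.ndarray  # n_samples x k, orthonormal columns
    method: str = "irw"

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        if self.sv.shape[0] != len(self.samples):
            raise ValueError("sv rows must match samples")

    @property
    def k(self) -> int:
        return self.sv.shape[1]


def _projection(X: np.ndarray) -> np.ndarray:
    """Hat matrix X (X'X)^-1 X'."""
    return X @ np.linalg.solve(X.T @ X, X.T)


def _nested_f_pvalues(M: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Row-wise F-test p-values comparing nested designs X0 subset of X1."""
    n = M.shape[1]
    p0, p1 = X0.shape[1], X1.shape[1]
    R0 = M - M @ _projection(X0)
    R1 = M - M @ _projection(X1)
    rss0 = (R0**2).sum(axis=1)
    rss1 = (R1**2).sum(axis=1)
    df1 = n - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / (p1 - p0)) / (rss1 / df1)
    pv = np.ones(len(f))
    valid = np.isfinite(f) & (f > 0)
    pv[valid] = stats.f.sf(f[valid], p1 - p0, df1)
    return pv


def estimate_svs(
    meth: MethylationMatrix,
    design: DesignMatrix,
    k: int = 10,
    n_iter: int = 5,
) -> SurrogateVariableSet:
    """Estimate k orthonormal surrogate variables, protecting the design.

    Requires complete cases (sites with data across all samples); rows
    with any masked entry are dropped with a warning. k is truncated to
    the residual rank when necessary.
    """
    if not meth.mask.all():
        n_bad = int((~meth.mask.all(axis=1)).sum())
        warnings.warn(f"dropping {n_bad} incomplete sites for SV estimation")
        meth = meth.complete_cases()
    if k < 1:
        raise ValueError("k must be >= 1")
    M = meth.meth_pct
    X = design.matrix
    n = X.shape[0]
    max_k = n - np.linalg.matrix_rank(X)
    if k > max_k:
        warnings.warn(f"k truncated from {k} to {max_k} (residual rank)")
        k = max_k
    resid_proj = np.eye(n) - _projection(X)
    R = M @ resid_proj

    if design.diag_index is not None:
        X_null = design.drop_diagnosis().matrix
    else:
        X_null = X
    weights = np.ones(M.shape[0])
    sv = None
    for _ in range(max(n_iter, 1)):
        _, _, vt = np.linalg.svd(R * weights[:, None], full_matrices=False)
        sv = vt[:k].T  # n x k, orthonormal
        # weight up sites tracking the SVs but not the protected variable
        p_sv = _nested_f_pvalues(M, X_null, np.column_stack([X_null, sv]))
        if design.diag_index is not None:
            p_prot = _nested_f_pvalues(M, X_null, X)
        else:
            p_prot = np.ones(M.shape[0])
        weights = (1.0 - p_sv) * p_prot
        if weights.sum() <= 0:
            weights = np.ones(M.shape[0])
    return SurrogateVariableSet(list(meth.samples), sv, "irw")


def detect_sv_outliers(
    meth: MethylationMatrix,
    sample_sheet: pd.DataFrame,
    z_thresh: float = 4.0,
    k: int = 10,
    max_iter: int = 10,
    n_iter_sva: int = 5,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove samples extreme in any surrogate variable.

    Each round re-estimates SVs on the remaining samples (complete-case
    sites recomputed) and flags samples beyond ``z_thresh`` sample SDs
    from any SV column mean (SD includes the candidate). Stops when no
    sample is flagged or ``max_iter`` rounds elapse. Returns the kept
    sample ids and a per-round removal log.
    """
    current = meth
    sheet = sample_sheet.set_index("sample_id")
    log: list[dict] = []
    for round_no in range(1, max_iter + 1):
        sub_sheet = sheet.loc[current.samples].reset_index()
        design = build_design(sub_sheet)
        svset = estimate_svs(current.complete_cases(), design, k=k, n_iter=n_iter_sva)
        sv = svset.sv
        mean = sv.mean(axis=0)
        sd = sv.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(sv - mean) / np.where(sd > 0, sd, np.inf)
        flagged_idx = np.flatnonzero((z > z_thresh).any(axis=1))
        flagged = [current.samples[i] for i in flagged_idx]
        log.append({"round": round_no, "flagged": flagged, "n_samples": current.n_samples})
        if not flagged:
            break
        if len(flagged) == current.n_samples:
            raise ValueError("all samples flagged as SV outliers; degenerate data")
        keep = [s for s in current.samples if s not in flagged]
        current = current.subset_samples(keep)
    return list(current.samples), log


def detect_meqtls(
    meth: MethylationMatrix,
    dosages: pd.DataFrame,
    snps: pd.DataFrame,
    covariates: np.ndarray | None = None,
    cis_window: int = 1_000_000,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """cis meQTL scan: OLS of methylation on additive dosage + covariates.

    Tests every SNP-site pair with |SNP pos - site pos| <= cis_window on
    the same chromosome (inclusive window). Monomorphic SNPs are skipped.
    Returns pairs with p < alpha.
    """
    shared = [s for s in meth.samples if s in dosages.index]
    if not shared:
        raise ValueError("no shared samples between methylation and genotypes")
    sub = meth.subset_samples(shared)
    D = dosages.loc[shared]
    n = len(shared)
    if covariates is None:
        base = np.ones((n, 1))
    else:
        base = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])

    site_chrom = sub.sites["chrom"].to_numpy()
    site_pos = sub.sites["pos"].to_numpy()
    site_ids = sub.sites["site_id"].to_numpy()
    Y = np.where(sub.mask, sub.meth_pct, np.nan)

    records = []
    for _, snp in snps.iterrows():
        snp_id = snp["snp_id"]
        if snp_id not in D.columns:
            continue
        g = D[snp_id].to_numpy(dtype=float)
        if np.all(g == g[0]):
            logger.info("skipping monomorphic SNP %s", snp_id)
            continue
        near = (site_chrom == snp["chrom"]) & (np.abs(site_pos - snp["pos"]) <= cis_window)
        rows = np.flatnonzero(near)
        if len(rows) == 0:
            continue
        X = np.column_stack([base, g])
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        p_cols = X.shape[1]
        for r in rows:
            y = Y[r]
            ok = ~np.isnan(y)
            if ok.sum() <= p_cols:
                continue
            if ok.all():
                bhat = H @ y
                resid = y - X @ bhat
                var_g = XtX_inv[-1, -1]
                df = n - p_cols
            else:
                Xs = X[ok]
                try:
                    XtX_inv_s = np.linalg.inv(Xs.T @ Xs)
                except np.linalg.LinAlgError:
                    continue
                bhat = XtX_inv_s @ Xs.T @ y[ok]
                resid = y[ok] - Xs @ bhat
                var_g = XtX_inv_s[-1, -1]
                df = int(ok.sum()) - p_cols
            sigma2 = resid @ resid / df
            se = np.sqrt(sigma2 * var_g)
            if se == 0:
                continue
            t = bhat[-1] / se
            p = 2.0 * stats.t.sf(abs(t), df)
            if p < alpha:
                records.append(
                    {
                        "snp_id": snp_id,
                        "site_id": site_ids[r],
                        "distance": int(abs(site_pos[r] - snp["pos"])),
                        "beta": float(bhat[-1]),
                        "p": float(p),
                    }
                )
    return pd.DataFrame(records, columns=["snp_id", "site_id", "distance", "beta", "p"])


def known_meqtl_recovery(
    detected: pd.DataFrame,
    known: pd.DataFrame,
    snp_ids: set | None = None,
    site_ids: set | None = None,
) -> float:
    """Fraction of assayable known meQTL pairs present among detected pairs.

    Assayable = known pairs whose SNP and site both appear in the data
    (pass ``snp_ids``/``site_ids``; omit to treat all known pairs as
    assayable).
    """
    assayable = known
    if snp_ids is not None:
        assayable = assayable[assayable["snp_id"].isin(snp_ids)]
    if site_ids is not None:
        assayable = assayable[assayable["site_id"].isin(site_ids)]
    if len(assayable) == 0:
        raise ValueError("no assayable known meQTL pairs")
    det = set(zip(detected["snp_id"], detected["site_id"])) if len(detected) else set()
    hits = sum((s, c) in det for s, c in zip(assayable["snp_id"], assayable["site_id"]))
    return hits / len(assayable)


def sample_qc(
    counts: CountMatrix,
    hyper_thresh: float = 0.99,
    midrange_thresh: float = 0.5,
    ks_thresh: float = 0.3,
) -> pd.DataFrame:
    """Per-sample library-failure diagnostics.

    Reports, per sample: (a) fraction of covered cytosines with
    methylation > 50% (flag hypermethylated library if > ``hyper_thresh``),
    (b) fraction of covered CpG sites with methylation in (20%, 80%)
    (flag non-bimodal if > ``midrange_thresh``), and (c) the
    Kolmogorov-Smirnov distance between the sample's log-coverage ECDF
    and the pooled ECDF across all samples (flag aberrant coverage if
    > ``ks_thresh``).
    """
    is_cpg = (counts.sites["context"] == "CpG").to_numpy()
    covered = counts.mask & (counts.coverage > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(covered, counts.methylated / np.maximum(counts.coverage, 1), np.nan)

    pooled_logcov = np.log10(counts.coverage[covered].astype(float) + 1.0)
    rows = []
    for j, sample in enumerate(counts.samples):
        cj = covered[:, j]
        fj = frac[cj, j]
        frac_hyper = float(np.mean(fj > 0.5)) if len(fj) else np.nan
        cpg_f = frac[cj & is_cpg, j]
        frac_mid = float(np.mean((cpg_f > 0.2) & (cpg_f < 0.8))) if len(cpg_f) else np.nan
        logcov = np.log10(counts.coverage[cj, j].astype(float) + 1.0)
        if len(logcov):
            ks = float(stats.ks_2samp(logcov, pooled_logcov, method="asymp").statistic)
        else:
            ks = np.nan
        rows.append(
            {
                "sample_id": sample,
                "frac_methylated_gt50": frac_hyper,
                "frac_cpg_midrange": frac_mid,
                "coverage_ks": ks,
                "flag_hypermethylated": bool(frac_hyper > hyper_thresh),
                "flag_non_bimodal": bool(frac_mid > midrange_thresh),
                "flag_coverage": bool(ks > ks_thresh),
            }
        )
    df = pd.DataFrame(rows)
    df["flag_any"] = df[["flag_hypermethylated", "flag_non_bimodal", "flag_coverage"]].any(axis=1)
    return df
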