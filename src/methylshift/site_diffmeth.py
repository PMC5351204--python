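"""Per-site weighted linear models and the residual-bootstrap empirical null.

Each site is fit by weighted least squares of percent methylation on the
design (diagnosis + covariates + surrogate variables), with per-entry
weights log10(coverage). The empirical null resamples full-model
residuals with replacement — one index vector shared across all sites
per bootstrap, preserving cross-site dependence — adds them to the
null-model fitted values, and refits the full model, yielding null
p-values and diagnosis coefficients per bootstrap.

Fits are batched across sites with stacked normal equations, so a
bootstrap round over thousands of sites costs a few matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methylshift.preprocess import MethylationMatrix

logger = logging.getLogger(__name__)

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class DesignMatrix:
    """Fixed design shared by all sites; diagnosis coded case=1."""

    samples: list[str]
    matrix: np.ndarray  # n x p
    columns: list[str]
    diag_index: int | None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.samples), len(self.columns)):
            raise ValueError("design shape mismatch")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def drop_diagnosis(self) -> "DesignMatrix":
        if self.diag_index is None:
            raise ValueError("design has no diagnosis column")
        keep = [i for i in range(self.p) if i != self.diag_index]
        return DesignMatrix(
            self.samples,
            self.matrix[:, keep],
            [self.columns[i] for i in keep],
            None,
        )


def build_design(
    sample_sheet: pd.DataFrame,
    svs: np.ndarray | None = None,
    include_diagnosis: bool = True,
    include_covariates: bool = True,
) -> DesignMatrix:
    """Assemble intercept, diagnosis, age, sex, bank dummies, and SV columns."""
    n = len(sample_sheet)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    diag_index = None
    if include_diagnosis:
        cols.append((sample_sheet["diagnosis"] == "case").to_numpy(dtype=float))
        names.append("diagnosis")
        diag_index = 1
    if include_covariates:
        cols.append(sample_sheet["age"].to_numpy(dtype=float))
        names.append("age")
        cols.append((sample_sheet["sex"] == "F").to_numpy(dtype=float))
        names.append("sexF")
        banks = sorted(sample_sheet["bank"].unique())
        for b in banks[1:]:
            cols.append((sample_sheet["bank"] == b).to_numpy(dtype=float))
            names.append(f"bank_{b}")
    if svs is not None:
        svs = np.asarray(svs, dtype=float)
        for k in range(svs.shape[1]):
            cols.append(svs[:, k])
            names.append(f"SV{k + 1}")
    return DesignMatrix(
        list(sample_sheet["sample_id"]), np.column_stack(cols), names, diag_index
    )


def default_weights(meth: MethylationMatrix) -> np.ndarray:
    """log10(coverage) weights; masked entries get weight zero."""
    w = np.log10(np.maximum(meth.coverage.astype(float), 1.0))
    return np.where(meth.mask, w, 0.0)


@dataclass
class WLSFit:
    """Batched weighted-least-squares fit of one design to all sites."""

    beta: np.ndarray       # S x p
    fitted: np.ndarray     # S x n
    resid: np.ndarray      # S x n (zeroed where masked)
    rss: np.ndarray        # S
    xtwx_inv: np.ndarray   # S x p x p
    n_used: np.ndarray     # S
    ok: np.ndarray         # S bool; False where normal equations were singular


def _batched_wls(Y: np.ndarray, W: np.ndarray, X: np.ndarray) -> WLSFit:
    S, n = Y.shape
    p = X.shape[1]
    XtWX = np.einsum("np,sn,nq->spq", X, W, X, optimize=True)
    XtWy = np.einsum("np,sn->sp", X, W * Y, optimize=True)
    ok = np.ones(S, dtype=bool)
    try:
        xtwx_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        xtwx_inv = np.empty_like(XtWX)
        for s in range(S):
            try:
                xtwx_inv[s] = np.linalg.inv(XtWX[s])
            except np.linalg.LinAlgError:
                xtwx_inv[s] = np.nan
                ok[s] = False
    beta = np.einsum("spq,sq->sp", xtwx_inv, XtWy, optimize=True)
    fitted = beta @ X.T
    resid = np.where(W > 0, Y - fitted, 0.0)
    rss = (W * resid**2).sum(axis=1)
    n_used = (W > 0).sum(axis=1)
    return WLSFit(beta, fitted, resid, rss, xtwx_inv, n_used, ok)


def wls_fit(
    meth: MethylationMatrix, design: DesignMatrix, weights: np.ndarray | None = None
) -> WLSFit:
    """Fit the design to every site; masked entries drop out via zero weight."""
    if weights is None:
        weights = default_weights(meth)
    if design.samples != meth.samples:
        raise ValueError("design and matrix sample order differ")
    return _batched_wls(meth.meth_pct, weights, design.matrix)


def _diag_stats(fit: WLSFit, design: DesignMatrix):
    """t statistics and two-sided p for the diagnosis coefficient."""
    d = design.diag_index
    if d is None:
        raise ValueError("design has no diagnosis column")
    df = fit.n_used - design.p
    sigma2 = np.where(df > 0, fit.rss / np.maximum(df, 1), np.nan)
    var = sigma2 * fit.xtwx_inv[:, d, d]
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.beta[:, d] / se
    p = np.full(len(t), np.nan)
    valid = np.isfinite(t) & (df > 0)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    degenerate = (fit.rss <= 1e-10) & (df > 0) & fit.ok
    p[degenerate] = _TINY_P
    t[degenerate] = np.where(fit.beta[degenerate, d] >= 0, np.inf, -np.inf)
    p = np.clip(p, _TINY_P, 1.0)
    return fit.beta[:, d], se, t, p, df, degenerate


def fit_site_models(
    meth: MethylationMatrix,
    design: DesignMatrix,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site diagnosis effect estimates, t statistics and two-sided p-values.

    Sites whose normal equations are singular after masking are skipped
    (returned with NaN statistics) and logged.
    """
    fit = wls_fit(meth, design, weights)
    beta, se, t, p, df, degenerate = _diag_stats(fit, design)
    n_skipped = int((~fit.ok).sum())
    if n_skipped:
        logger.warning("%d sites skipped: singular design after masking", n_skipped)
    out = pd.DataFrame(
        {
            "site_id": meth.sites["site_id"].to_numpy(),
            "chrom": meth.sites["chrom"].to_numpy(),
            "pos": meth.sites["pos"].to_numpy(),
            "context": meth.sites["context"].to_numpy(),
            "beta_diag": beta,
            "se": se,
            "t": t,
            "p": p,
            "direction": np.sign(beta).astype(int),
            "n_used": fit.n_used,
            "degenerate": degenerate,
        }
    )
    out.loc[~fit.ok, ["beta_diag", "se", "t", "p"]] = np.nan
    return out


@dataclass
class BootstrapNull:
    """Null diagnosis p-values and coefficients from B residual bootstraps."""

    B: int
    seed: int
    site_ids: np.ndarray
    p_null: np.ndarray     # B x S
    beta_null: np.ndarray  # B x S

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def min_p(self) -> np.ndarray:
        """Per-bootstrap minimum null p across sites."""
        return np.nanmin(self.p_null, axis=1)


def residual_bootstrap(
    meth: MethylationMatrix,
    full_design: DesignMatrix,
    null_design: DesignMatrix,
    weights: np.ndarray | None = None,
    B: int = 1000,
    seed: int = 0,
    _index_vectors: np.ndarray | None = None,
) -> BootstrapNull:
    """Residual-bootstrap null for the diagnosis coefficient.

    Pseudonull data = null-model fitted values + full-model residuals
    re-indexed by a with-replacement draw of sample indices (one vector
    per bootstrap, shared across sites); the full model is refit on each
    pseudonull matrix. Weights are reused from the observed fit.
    ``_index_vectors`` overrides the random draws (testing hook).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if null_design.diag_index is not None:
        raise ValueError("null design must not contain the diagnosis column")
    if weights is None:
        weights = default_weights(meth)
    full_fit = wls_fit(meth, full_design, weights)
    null_fit = wls_fit(meth, null_design, weights)

    X = full_design.matrix
    W = weights
    n = full_design.n
    d = full_design.diag_index
    p_cols = full_design.p
    df = full_fit.n_used - p_cols
    A = full_fit.xtwx_inv  # XtWX depends only on W, X: reusable across bootstraps
    Add = A[:, d, d]

    rng = np.random.default_rng(seed)
    S = meth.n_sites
    beta_null = np.empty((B, S))
    t_null = np.empty((B, S))
    degen = np.zeros((B, S), dtype=bool)
    for b in range(B):
        if _index_vectors is not None:
            idx = np.asarray(_index_vectors[b])
        else:
            idx = rng.integers(0, n, n)
        Yb = null_fit.fitted + full_fit.resid[:, idx]
        XtWy = np.einsum("np,sn->sp", X, W * Yb, optimize=True)
        beta = np.einsum("spq,sq->sp", A, XtWy, optimize=True)
        fitted = beta @ X.T
        rss = (W * np.where(W > 0, Yb - fitted, 0.0) ** 2).sum(axis=1)
        sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
        se = np.sqrt(np.maximum(sigma2 * Add, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null[b] = beta[:, d] / se
        beta_null[b] = beta[:, d]
        # perfect pseudonull fits get the same 0-adjacent p as observed fits
        degen[b] = (rss <= 1e-10) & (df > 0) & full_fit.ok
    p_null = np.full((B, S), np.nan)
    finite = np.isfinite(t_null)
    df_b = np.broadcast_to(df, (B, S))
    p_null[finite] = 2.0 * stats.t.sf(np.abs(t_null[finite]), df_b[finite])
    p_null[degen] = _TINY_P
    p_null = np.clip(p_null, _TINY_P, 1.0)
    return BootstrapNull(B, seed, meth.sites["site_id"].to_numpy(), p_null, beta_null)


def empirical_significance(
    fits: pd.DataFrame, null: BootstrapNull, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Study-wide verdicts from the bootstrap min-p distribution.

    The study-wide threshold is the alpha-quantile of per-bootstrap
    minimum null p-values; a site is significant iff its observed p is
    below it. Per-site empirical p = (1 + #{min-p_b <= p_site}) / (B + 1).
    """
    min_p = null.min_p()
    threshold = float(np.quantile(min_p, alpha))
    out = fits.copy()
    p_obs = out["p"].to_numpy()
    out["study_wide_significant"] = p_obs < threshold
    counts = np.searchsorted(np.sort(min_p), p_obs, side="right")
    out["empirical_p"] = (1.0 + counts) / (null.B + 1.0)
    return out, threshold
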