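"""Coverage filtering, normalization, and methylation-percentage matrices.

The raw substrate is a :class:`CountMatrix`: per-(site, sample) read
coverage and methylated-read counts plus a validity mask. Filters mask
entries rather than delete them; site-level operations drop rows.
Percentages live in a :class:`MethylationMatrix`, which keeps coverage
alongside for use as model weights downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["site_id", "chrom", "pos", "strand", "context"]


def make_site_table(
    chrom: np.ndarray,
    pos: np.ndarray,
    strand: np.ndarray | str = "+",
    context: np.ndarray | str = "CpG",
) -> pd.DataFrame:
    """Build a site table with canonical columns and ``chrom:pos:strand`` ids."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if np.isscalar(strand) or isinstance(strand, str):
        strand = np.full(len(pos), strand, dtype=object)
    if np.isscalar(context) or isinstance(context, str):
        context = np.full(len(pos), context, dtype=object)
    site_id = np.array(
        [f"{c}:{p}:{s}" for c, p, s in zip(chrom, pos, strand)], dtype=object
    )
    return pd.DataFrame(
        {"site_id": site_id, "chrom": chrom, "pos": pos, "strand": strand, "context": context}
    )


def genomic_order(sites: pd.DataFrame) -> np.ndarray:
    """Indices that sort a site table by (chrom, pos, strand)."""
    return np.lexsort(
        (sites["strand"].to_numpy(), sites["pos"].to_numpy(), sites["chrom"].to_numpy())
    )


@dataclass
class CountMatrix:
    """Per-site, per-sample coverage and methylated-read counts.

    ``mask[i, j]`` is True where the entry is valid; filters clear it.
    Invariant: 0 <= methylated <= coverage wherever unmasked.
    """

    sites: pd.DataFrame
    samples: list[str]
    coverage: np.ndarray
    methylated: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage)
        self.methylated = np.asarray(self.methylated)
        if self.mask is None:
            self.mask = np.ones(self.coverage.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.coverage.shape == self.methylated.shape == self.mask.shape):
            raise ValueError("coverage, methylated and mask shapes differ")
        if self.coverage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites x samples")
        self.validate()

    def validate(self) -> None:
        m = self.mask
        if np.any(self.coverage[m] < 0):
            raise ValueError("negative coverage")
        if np.any(self.methylated[m] < 0):
            raise ValueError("negative methylated count")
        if np.any(self.methylated[m] > self.coverage[m]):
            raise ValueError("methylated count exceeds coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.sites.copy(),
            list(self.samples),
            self.coverage.copy(),
            self.methylated.copy(),
            self.mask.copy(),
        )

    def subset_sites(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.coverage[idx],
            self.methylated[idx],
            self.mask[idx],
        )

    def subset_samples(self, keep: list[str]) -> "CountMatrix":
        pos = [self.samples.index(s) for s in keep]
        return CountMatrix(
            self.sites.copy(),
            list(keep),
            self.coverage[:, pos],
            self.methylated[:, pos],
            self.mask[:, pos],
        )


@dataclass
class MethylationMatrix:
    """Percent methylation in [0, 100] with coverage retained for weights."""

    sites: pd.DataFrame
    samples: list[str]
    meth_pct: np.ndarray
    coverage: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.meth_pct = np.asarray(self.meth_pct, dtype=float)
        self.coverage = np.asarray(self.coverage)
        self.mask = np.asarray(self.mask, dtype=bool)
        m = self.mask
        if m.any() and (np.any(self.meth_pct[m] < 0) or np.any(self.meth_pct[m] > 100)):
            raise ValueError("meth_pct outside [0, 100]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.sites.copy(),
            list(self.samples),
            self.meth_pct.copy(),
            self.coverage.copy(),
            self.mask.copy(),
        )

    def subset_sites(self, idx: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.samples),
            self.meth_pct[idx],
            self.coverage[idx],
            self.mask[idx],
        )

    def subset_samples(self, keep: list[str]) -> "MethylationMatrix":
        pos = [self.samples.index(s) for s in keep]
        return MethylationMatrix(
            self.sites.copy(),
            list(keep),
            self.meth_pct[:, pos],
            self.coverage[:, pos],
            self.mask[:, pos],
        )

    def complete_cases(self) -> "MethylationMatrix":
        """Restrict to sites with unmasked data in every sample."""
        keep = np.flatnonzero(self.mask.all(axis=1))
        return self.subset_sites(keep)


def filter_coverage(
    counts: CountMatrix, min_cov: int = 10, upper_pctile: float = 99.9
) -> CountMatrix:
    """Mask low-coverage entries and per-sample extreme-coverage entries.

    Entries with coverage < ``min_cov`` are masked first; then, per sample,
    entries above that sample's ``upper_pctile`` coverage quantile (linear
    interpolation, computed over the entries surviving the lower filter)
    are masked to guard against PCR duplicates.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if not 0 < upper_pctile <= 100:
        raise ValueError("upper_pctile must be in (0, 100]")
    out = counts.copy()
    out.mask &= out.coverage >= min_cov
    for j, sample in enumerate(out.samples):
        valid = out.mask[:, j]
        if not valid.any():
            logger.warning("sample %s fully masked after coverage filter", sample)
            continue
        thr = np.quantile(out.coverage[valid, j], upper_pctile / 100.0)
        out.mask[:, j] &= out.coverage[:, j] <= thr
    return out


def normalize_coverage(counts: CountMatrix) -> CountMatrix:
    """Scale each sample's counts so median coverages match across samples.

    The reference is the median of per-sample median coverages; each
    sample's coverage and methylated counts are multiplied by
    reference / sample-median and rounded, with methylated clipped to
    coverage.
    """
    out = counts.copy()
    medians = np.empty(out.n_samples)
    for j, sample in enumerate(out.samples):
        valid = out.mask[:, j]
        if not valid.any():
            raise ValueError(f"sample {sample} has no unmasked entries")
        medians[j] = np.median(out.coverage[valid, j])
    if np.any(medians == 0):
        raise ValueError("zero median coverage")
    reference = np.median(medians)
    factors = reference / medians
    cov = np.rint(out.coverage * factors[np.newaxis, :])
    meth = np.rint(out.methylated * factors[np.newaxis, :])
    # keep unmasked entries usable: never round a covered site to zero reads
    cov = np.where(out.mask, np.maximum(cov, 1), cov)
    meth = np.minimum(meth, cov)
    out.coverage = cov.astype(np.int64)
    out.methylated = meth.astype(np.int64)
    out.validate()
    return out


def unite_sites(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    min_cases: int = 20,
    min_controls: int = 20,
) -> CountMatrix:
    """Keep sites with unmasked data in enough cases and controls, in genomic order."""
    diag = sample_sheet.set_index("sample_id").loc[counts.samples, "diagnosis"].to_numpy()
    is_case = diag == "case"
    is_ctrl = diag == "control"
    if min_cases > is_case.sum() or min_controls > is_ctrl.sum():
        raise ValueError("min thresholds exceed group sizes")
    n_case = counts.mask[:, is_case].sum(axis=1)
    n_ctrl = counts.mask[:, is_ctrl].sum(axis=1)
    keep = (n_case >= min_cases) & (n_ctrl >= min_controls)
    out = counts.subset_sites(np.flatnonzero(keep))
    return out.subset_sites(genomic_order(out.sites))


def percent_methylation(counts: CountMatrix) -> MethylationMatrix:
    """Convert counts to percent methylation; masks carry over."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            counts.coverage > 0, 100.0 * counts.methylated / counts.coverage, 0.0
        )
    pct = np.where(counts.mask, pct, 0.0)
    return MethylationMatrix(
        counts.sites.copy(), list(counts.samples), pct, counts.coverage.copy(), counts.mask.copy()
    )


def site_sd(meth: MethylationMatrix) -> np.ndarray:
    """Per-site sample SD (ddof=1) of meth_pct over unmasked samples."""
    m = meth.mask
    n = m.sum(axis=1)
    x = np.where(m, meth.meth_pct, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x.sum(axis=1) / n
        ss = (np.where(m, (meth.meth_pct - mean[:, None]) ** 2, 0.0)).sum(axis=1)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    sd[n < 2] = 0.0
    return sd


def drop_invariant_sites(
    meth: MethylationMatrix, drop_fraction: float = 0.25
) -> MethylationMatrix:
    """Remove the least-variable fraction of sites by percent-methylation SD.

    Ties are broken by genomic order: the lower-coordinate site drops first.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    if drop_fraction == 0:
        return meth.copy()
    sd = site_sd(meth)
    # stable sort on SD keeps genomic input order among ties
    order = np.argsort(sd, kind="stable")
    n_drop = int(np.floor(drop_fraction * meth.n_sites))
    keep = np.sort(order[n_drop:])
    return meth.subset_sites(keep)


def mask_site_outliers(meth: MethylationMatrix, z_thresh: float = 3.0) -> MethylationMatrix:
    """Mask per-site sample outliers beyond ``z_thresh`` site SDs from the site mean.

    Single pass; the mean and SD (ddof=1) are computed once from all
    unmasked values including the candidate. Sites with zero SD mask nothing.
    """
    out = meth.copy()
    m = out.mask
    n = m.sum(axis=1)
    x = np.where(m, out.meth_pct, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x.sum(axis=1) / n
        ss = (np.where(m, (out.meth_pct - mean[:, None]) ** 2, 0.0)).sum(axis=1)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
    ok = (sd > 0) & (n >= 2)
    dev = np.abs(out.meth_pct - mean[:, None])
    outlier = m & ok[:, None] & (dev > z_thresh * sd[:, None])
    out.mask = m & ~outlier
    return out
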