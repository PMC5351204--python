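"""Fisher-exact enrichment of hypermethylated sites in genomic categories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methylshift.io_formats import AnnotationCategory


@dataclass
class EnrichmentResult:
    category: str
    cutoff: float
    a: int  # hyper, in category
    b: int  # hyper, outside
    c: int  # non-hyper, in category
    d: int  # non-hyper, outside
    odds_ratio: float
    p: float
    degenerate: bool = False


def flank_beacons(
    positions: np.ndarray,
    chroms: np.ndarray,
    flank: int = 200,
    per_side: bool = False,
    name: str = "beacons",
) -> AnnotationCategory:
    """Window around each CpG dinucleotide: ``flank`` bp total (default) or per side.

    A CpG at 1-based position p becomes the half-open interval
    (p - 1 - half, p + 1 + half) where half = flank (per side) or
    flank // 2 (total), clipped at 0.
    """
    half = flank if per_side else flank // 2
    positions = np.asarray(positions, dtype=np.int64)
    starts = np.maximum(positions - 1 - half, 0)
    ends = positions + 1 + half
    return AnnotationCategory(
        name, pd.DataFrame({"chrom": np.asarray(chroms), "start": starts, "end": ends})
    )


def _merge(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals as maximal disjoint intervals, per chromosome."""
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _intersect_two(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    rows = []
    b_by_chrom = dict(tuple(b.groupby("chrom", sort=False)))
    for chrom, grp in a.groupby("chrom", sort=True):
        if chrom not in b_by_chrom:
            continue
        other = b_by_chrom[chrom]
        ai = list(zip(grp["start"], grp["end"]))
        bi = list(zip(other["start"], other["end"]))
        i = j = 0
        while i < len(ai) and j < len(bi):
            s = max(ai[i][0], bi[j][0])
            e = min(ai[i][1], bi[j][1])
            if s < e:
                rows.append((chrom, s, e))
            if ai[i][1] <= bi[j][1]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def intersect_replicates(categories: list[AnnotationCategory], name: str | None = None) -> AnnotationCategory:
    """Positions covered by every input set, as maximal disjoint intervals."""
    if not categories:
        raise ValueError("need at least one category")
    result = _merge(categories[0].intervals)
    for cat in categories[1:]:
        result = _intersect_two(result, _merge(cat.intervals))
        if len(result) == 0:
            break
    if name is None:
        name = "+".join(c.name for c in categories)
    return AnnotationCategory(name, result)


def annotate_sites(sites: pd.DataFrame, category: AnnotationCategory) -> np.ndarray:
    """Boolean in-category flag per site: pos p is inside (s, e) iff s <= p-1 < e."""
    import warnings

    merged = _merge(category.intervals)
    flags = np.zeros(len(sites), dtype=bool)
    cat_chroms = set(merged["chrom"])
    site_chroms = set(sites["chrom"])
    unmatched = sorted(cat_chroms - site_chroms)
    if unmatched and len(merged):
        warnings.warn(f"category chromosomes absent from sites: {unmatched}")
    for chrom, grp in merged.groupby("chrom", sort=False):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        p0 = sites.loc[sel, "pos"].to_numpy() - 1  # 0-based
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # merged intervals are disjoint & sorted: containing interval candidate
        k = np.searchsorted(starts, p0, side="right") - 1
        inside = (k >= 0) & (p0 < ends[np.clip(k, 0, len(ends) - 1)])
        flags[np.flatnonzero(sel)] = inside
    return flags


def fisher_enrichment(
    fits: pd.DataFrame,
    membership: np.ndarray,
    cutoff: float,
    category_name: str = "category",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of hypermethylation vs category membership.

    Hyper = p < cutoff and beta_diag > 0, over all tested sites. With an
    empty table margin the odds ratio is undefined and p = 1 (flagged).
    """
    if len(fits) != len(membership):
        raise ValueError("fits and membership are not aligned")
    membership = np.asarray(membership, dtype=bool)
    hyper = (fits["p"].to_numpy() < cutoff) & (fits["beta_diag"].to_numpy() > 0)
    a = int(np.sum(hyper & membership))
    b = int(np.sum(hyper & ~membership))
    c = int(np.sum(~hyper & membership))
    d = int(np.sum(~hyper & ~membership))
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return EnrichmentResult(category_name, cutoff, a, b, c, d, np.nan, 1.0, True)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(category_name, cutoff, a, b, c, d, float(odds), float(p))


def enrichment_scan(
    fits: pd.DataFrame,
    categories: list[AnnotationCategory],
    cutoffs: tuple = (0.05, 5e-3, 5e-4),
) -> pd.DataFrame:
    """Fisher enrichment for every category x cutoff combination."""
    sites = fits[["site_id", "chrom", "pos"]]
    rows = []
    for cat in categories:
        member = annotate_sites(sites, cat)
        for cutoff in cutoffs:
            r = fisher_enrichment(fits, member, cutoff, cat.name)
            rows.append(
                {
                    "category": r.category,
                    "cutoff": r.cutoff,
                    "a": r.a,
                    "b": r.b,
                    "c": r.c,
                    "d": r.d,
                    "odds_ratio": r.odds_ratio,
                    "p": r.p,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)
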