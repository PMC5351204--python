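"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions: cytosine positions are 1-based; BED intervals are
0-based half-open. A site at position ``p`` overlaps interval ``(s, e)``
iff ``s <= p - 1 < e``. All readers and writers are gzip-transparent
(paths ending in ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methylshift.preprocess import CountMatrix, make_site_table

logger = logging.getLogger(__name__)

CYTOSINE_REPORT_COLUMNS = ["chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT"]
BISMARK_COV_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_meth", "count_unmeth"]


@dataclass
class AnnotationCategory:
    """A named set of genomic intervals, 0-based half-open."""

    name: str
    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        self.intervals = self.intervals[["chrom", "start", "end"]].reset_index(drop=True)
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} intervals with start >= end in {self.name}")

    def __len__(self) -> int:
        return len(self.intervals)


def _open(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(path, dialect: str = "cytosine_report"):
    """Read one sample's per-cytosine counts.

    ``cytosine_report`` dialect: header + columns chrBase, chr, base,
    strand, coverage, freqC, freqT; methylated count is recovered as
    round(coverage * freqC / 100). ``bismark_coverage`` dialect: headerless
    chrom, start, end, methylation%, count-methylated, count-unmethylated.

    Returns (site table, coverage array, methylated array).
    """
    if dialect == "cytosine_report":
        return _read_cytosine_report_dialect(path)
    if dialect == "bismark_coverage":
        return _read_bismark_coverage(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_cytosine_report_dialect(path):
    chroms, poss, strands, covs, meths = [], [], [], [], []
    with _open(path) as fh:
        header = fh.readline()
        if not header:
            logger.warning("empty cytosine report: %s", path)
            return make_site_table([], []), np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}: malformed line {lineno}: expected 7 fields")
            try:
                cov = int(fields[4])
                freq_c = float(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            meth = int(round(cov * freq_c / 100.0))
            if cov < 0 or meth < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            if meth > cov:
                raise ValueError(f"{path}: methylated > coverage at line {lineno}")
            chroms.append(fields[1])
            poss.append(int(fields[2]))
            strands.append(fields[3])
            covs.append(cov)
            meths.append(meth)
    sites = make_site_table(np.array(chroms, dtype=object), np.array(poss), np.array(strands, dtype=object))
    return sites, np.array(covs, dtype=np.int64), np.array(meths, dtype=np.int64)


def _read_bismark_coverage(path):
    chroms, poss, covs, meths = [], [], [], []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: malformed line {lineno}: expected 6 fields")
            try:
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            covs.append(meth + unmeth)
            meths.append(meth)
    if not chroms:
        logger.warning("empty coverage file: %s", path)
    sites = make_site_table(np.array(chroms, dtype=object), np.array(poss))
    return sites, np.array(covs, dtype=np.int64), np.array(meths, dtype=np.int64)


def write_cytosine_report(
    path, sites: pd.DataFrame, coverage: np.ndarray, methylated: np.ndarray,
    dialect: str = "cytosine_report",
) -> None:
    """Write one sample's counts in the requested dialect."""
    with _open(path, "wt") as fh:
        if dialect == "cytosine_report":
            fh.write("\t".join(CYTOSINE_REPORT_COLUMNS) + "\n")
            for (chrom, pos, strand), cov, meth in zip(
                sites[["chrom", "pos", "strand"]].itertuples(index=False), coverage, methylated
            ):
                freq_c = 100.0 * meth / cov if cov > 0 else 0.0
                fh.write(
                    f"{chrom}.{pos}\t{chrom}\t{pos}\t{strand}\t{cov}\t{freq_c:.6f}\t{100.0 - freq_c:.6f}\n"
                )
        elif dialect == "bismark_coverage":
            for (chrom, pos), cov, meth in zip(
                sites[["chrom", "pos"]].itertuples(index=False), coverage, methylated
            ):
                pct = 100.0 * meth / cov if cov > 0 else 0.0
                fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6f}\t{meth}\t{cov - meth}\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")


def read_bed(path, name: str | None = None) -> AnnotationCategory:
    """Read a BED3+ file; extra columns are ignored."""
    chroms, starts, ends = [], [], []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if name is None:
        name = str(path).rsplit("/", 1)[-1].split(".")[0]
    return AnnotationCategory(name, df)


def write_bed(path, category: AnnotationCategory, extra: pd.DataFrame | None = None) -> None:
    """Write BED3, optionally with extra columns appended after the first three."""
    df = category.intervals.copy()
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet CSV (sample_id, diagnosis, age, sex, bank)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "diagnosis": str, "sex": str, "bank": str})
    required = {"sample_id", "diagnosis", "age", "sex", "bank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        raise ValueError("sample sheet has missing values")
    bad = set(df["diagnosis"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    return df


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, index=False)


def write_count_matrix(out_dir, counts: CountMatrix, dialect: str = "cytosine_report") -> list[str]:
    """Write one cytosine report per sample; masked entries are omitted."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for j, sample in enumerate(counts.samples):
        keep = counts.mask[:, j]
        path = os.path.join(out_dir, f"{sample}.cytosine_report.txt")
        write_cytosine_report(
            path, counts.sites.loc[keep], counts.coverage[keep, j], counts.methylated[keep, j],
            dialect=dialect,
        )
        paths.append(path)
    return paths


def read_genotypes(dosage_path, snp_bed_path):
    """Read a samples x SNPs dosage TSV and SNP coordinates from BED.

    The dosage table has sample ids in the first column and one column
    per SNP id. Returns (dosage DataFrame indexed by sample, snp table).
    """
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dosages.index = dosages.index.astype(str)
    bed = read_bed(snp_bed_path, name="snps")
    snps = bed.intervals.copy()
    snps["pos"] = snps["end"]  # 1-based SNP position
    return dosages, snps


def write_site_results(path, fits: pd.DataFrame) -> None:
    fits.to_csv(path, sep="\t", index=False)


def read_site_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dmr_results(bed_path, tsv_path, regions: pd.DataFrame) -> None:
    """DMRs as BED3 (0-based half-open) plus a TSV sidecar with statistics."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int) - 1,
            "end": regions["end"].astype(int),
        }
    )
    with _open(bed_path, "wt") as fh:
        bed.to_csv(fh, sep="\t", header=False, index=False)
    regions.to_csv(tsv_path, sep="\t", index=False)


def read_dmr_results(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")


def write_enrichment_results(path, results: pd.DataFrame) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_enrichment_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results(tables: dict, out_dir) -> dict:
    """Write the standard result bundle; returns {kind: path}.

    Recognized keys: ``site_fits`` (TSV), ``dmrs`` (BED + TSV sidecar),
    ``enrichment`` (TSV), ``global_shift`` (TSV).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict = {}
    if "site_fits" in tables:
        p = os.path.join(out_dir, "site_results.tsv")
        write_site_results(p, tables["site_fits"])
        paths["site_fits"] = p
    if "dmrs" in tables:
        bed = os.path.join(out_dir, "dmrs.bed")
        tsv = os.path.join(out_dir, "dmrs.tsv")
        write_dmr_results(bed, tsv, tables["dmrs"])
        paths["dmrs"] = tsv
        paths["dmrs_bed"] = bed
    if "enrichment" in tables:
        p = os.path.join(out_dir, "enrichment.tsv")
        write_enrichment_results(p, tables["enrichment"])
        paths["enrichment"] = p
    if "global_shift" in tables:
        p = os.path.join(out_dir, "global_shift.tsv")
        tables["global_shift"].to_csv(p, sep="\t", index=False)
        paths["global_shift"] = p
    return paths
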