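"""End-to-end orchestration: simulate/ingest -> QC -> fit -> bootstrap ->
global test -> DMR -> enrichment, with one seed and a run log."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from methylshift import io_formats, preprocess, sva_qc
from methylshift.dmr import dmr_analysis
from methylshift.global_shift import DEFAULT_CUTOFFS, global_shift_test, results_table
from methylshift.site_diffmeth import (
    build_design,
    empirical_significance,
    fit_site_models,
    residual_bootstrap,
)
from methylshift.synthetic_data import QCFailureSpec, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold the workflow uses, with the standard defaults."""

    simulation: SimulationConfig | None = None
    data_dir: str | None = None  # per-sample cytosine reports + sample_sheet.csv
    min_cov: int = 10
    upper_pctile: float = 99.9
    min_cases: int = 20
    min_controls: int = 20
    dmr_min_cov: int = 5
    drop_fraction: float = 0.25
    site_z: float = 3.0
    sv_z: float = 4.0
    k_svs: int = 10
    B: int = 1000
    cutoffs: tuple = DEFAULT_CUTOFFS
    maxgap: int = 300
    dmr_quantile: float = 0.99
    smooth_window: int = 5
    smooth_min_sites: int = 7
    n_tests: int = 24
    alpha: float = 0.05
    category_beds: dict = field(default_factory=dict)  # name -> BED path
    seed: int = 0
    out_dir: str = "methylshift_out"

    def validate(self) -> None:
        if self.simulation is None and self.data_dir is None:
            raise ValueError("config needs a simulation block or a data_dir")
        for name in ("min_cov", "dmr_min_cov", "B", "maxgap", "n_tests", "k_svs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.upper_pctile <= 100:
            raise ValueError("upper_pctile must be in (0, 100]")
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            modes = [QCFailureSpec(**m) for m in sim.pop("qc_failure_modes", [])]
            sim = SimulationConfig(**sim, qc_failure_modes=modes)
        cfg = cls(simulation=sim, **raw)
        if isinstance(cfg.cutoffs, list):
            cfg.cutoffs = tuple(cfg.cutoffs)
        return cfg


def _load_counts(config: PipelineConfig):
    """Counts + sample sheet, from the simulator or a directory of reports."""
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        return ds.counts, ds.sample_sheet, ds.truth
    sheet = io_formats.read_sample_sheet(os.path.join(config.data_dir, "sample_sheet.csv"))
    per_sample = {}
    ref_sites = None
    for sid in sheet["sample_id"]:
        path = os.path.join(config.data_dir, f"{sid}.cytosine_report.txt")
        sites, cov, meth = io_formats.read_cytosine_report(path)
        per_sample[sid] = (sites, cov, meth)
        if ref_sites is None or len(sites) > len(ref_sites):
            ref_sites = sites
    # align all samples on the union of sites; absent entries masked
    frames = [s.assign(_order=np.arange(len(s))) for s, _, _ in per_sample.values()]
    union = (
        pd.concat([f[["site_id", "chrom", "pos", "strand", "context"]] for f in frames])
        .drop_duplicates("site_id")
        .reset_index(drop=True)
    )
    union = union.iloc[preprocess.genomic_order(union)].reset_index(drop=True)
    idx = {sid: i for i, sid in enumerate(union["site_id"])}
    n_sites, n_samples = len(union), len(sheet)
    coverage = np.zeros((n_sites, n_samples), dtype=np.int64)
    methylated = np.zeros((n_sites, n_samples), dtype=np.int64)
    mask = np.zeros((n_sites, n_samples), dtype=bool)
    for j, sid in enumerate(sheet["sample_id"]):
        sites, cov, meth = per_sample[sid]
        rows = np.array([idx[s] for s in sites["site_id"]])
        coverage[rows, j] = cov
        methylated[rows, j] = meth
        mask[rows, j] = True
    counts = preprocess.CountMatrix(union, list(sheet["sample_id"]), coverage, methylated, mask)
    return counts, sheet, None


@dataclass
class PipelineResult:
    sample_sheet: pd.DataFrame
    qc: pd.DataFrame
    kept_samples: list[str]
    removal_log: list
    site_fits: dict           # context -> DataFrame
    thresholds: dict          # context -> study-wide p threshold
    global_shift: pd.DataFrame
    dmrs: pd.DataFrame
    enrichment: pd.DataFrame | None
    truth: object | None
    log: list


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; deterministic for a given config + seed."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    run_log: list = []

    def note(stage, **info):
        entry = {"stage": stage, **info}
        run_log.append(entry)
        logger.info("%s: %s", stage, info)

    counts, sheet, truth = _load_counts(config)
    note("input", n_sites=counts.n_sites, n_samples=counts.n_samples)

    # library-failure QC on raw counts
    qc = sva_qc.sample_qc(counts)
    failed = list(qc.loc[qc["flag_any"], "sample_id"])
    note("sample_qc", failed=failed)
    keep = [s for s in counts.samples if s not in failed]
    counts = counts.subset_samples(keep)
    sheet_kept = sheet[sheet["sample_id"].isin(keep)].reset_index(drop=True)

    # coverage filters, normalization, site union
    counts = preprocess.filter_coverage(counts, config.min_cov, config.upper_pctile)
    counts = preprocess.normalize_coverage(counts)
    min_cases = min(config.min_cases, int((sheet_kept["diagnosis"] == "case").sum()))
    min_controls = min(config.min_controls, int((sheet_kept["diagnosis"] == "control").sum()))
    united = preprocess.unite_sites(counts, sheet_kept, min_cases, min_controls)
    note("unite", n_sites=united.n_sites, min_cases=min_cases, min_controls=min_controls)

    meth_all = preprocess.percent_methylation(united)

    # SV-based iterative sample outlier removal on CpG complete cases
    is_cpg = (meth_all.sites["context"] == "CpG").to_numpy()
    cpg_for_sva = meth_all.subset_sites(np.flatnonzero(is_cpg)).complete_cases()
    k_qc = min(config.k_svs, max(1, cpg_for_sva.n_samples - 6))
    if cpg_for_sva.n_sites >= 10:
        kept_samples, removal_log = sva_qc.detect_sv_outliers(
            cpg_for_sva, sheet_kept, z_thresh=config.sv_z, k=k_qc
        )
    else:
        kept_samples, removal_log = list(meth_all.samples), []
    note("sv_outliers", removed=[s for s in meth_all.samples if s not in kept_samples])
    meth_all = meth_all.subset_samples(kept_samples)
    sheet_final = sheet_kept[sheet_kept["sample_id"].isin(kept_samples)].reset_index(drop=True)

    site_fits: dict = {}
    thresholds: dict = {}
    shift_rows = []
    nulls: dict = {}
    rng = np.random.default_rng(config.seed)
    for context in ("CpG", "CpH"):
        sel = (meth_all.sites["context"] == context).to_numpy()
        if sel.sum() < 10:
            continue
        meth = meth_all.subset_sites(np.flatnonzero(sel))
        meth = preprocess.mask_site_outliers(meth, config.site_z)
        meth = preprocess.drop_invariant_sites(meth, config.drop_fraction)

        complete = meth.complete_cases()
        k = min(config.k_svs, max(1, meth.n_samples - 6))
        protected = build_design(sheet_final)
        svs = None
        if complete.n_sites >= 10:
            svs = sva_qc.estimate_svs(complete, protected, k=k).sv
        full = build_design(sheet_final, svs=svs)
        null_design = full.drop_diagnosis()

        fits = fit_site_models(meth, full)
        boot = residual_bootstrap(
            meth, full, null_design, B=config.B, seed=int(rng.integers(2**31))
        )
        fits, thr = empirical_significance(fits, boot, config.alpha)
        site_fits[context] = fits
        thresholds[context] = thr
        nulls[context] = (meth, full, null_design, boot)
        note(
            "site_fit", context=context, n_sites=meth.n_sites,
            n_study_wide=int(fits["study_wide_significant"].sum()),
        )
        for r in global_shift_test(fits, boot, config.cutoffs, context=context):
            shift_rows.append(r)

    global_df = results_table(shift_rows)

    # DMR scan on the relaxed-coverage site set
    counts_dmr = preprocess.filter_coverage(
        _load_counts(config)[0].subset_samples(kept_samples),
        config.dmr_min_cov,
        config.upper_pctile,
    )
    counts_dmr = preprocess.normalize_coverage(counts_dmr)
    united_dmr = preprocess.unite_sites(counts_dmr, sheet_final, min_cases, min_controls)
    meth_dmr = preprocess.percent_methylation(united_dmr)
    protected = build_design(sheet_final)
    complete_dmr = meth_dmr.complete_cases()
    svs_dmr = None
    if complete_dmr.n_sites >= 10:
        k = min(config.k_svs, max(1, meth_dmr.n_samples - 6))
        svs_dmr = sva_qc.estimate_svs(complete_dmr, protected, k=k).sv
    full_dmr = build_design(sheet_final, svs=svs_dmr)
    dmrs = dmr_analysis(
        meth_dmr,
        full_dmr,
        full_dmr.drop_diagnosis(),
        maxgap=config.maxgap,
        quantile=config.dmr_quantile,
        window=config.smooth_window,
        min_sites=config.smooth_min_sites,
        B=config.B,
        seed=int(rng.integers(2**31)),
        n_tests=config.n_tests,
        alpha=config.alpha,
    )
    note("dmr", n_candidates=len(dmrs), n_significant=int(dmrs["significant"].sum()))

    enrich = None
    if config.category_beds and "CpH" in site_fits:
        from methylshift.enrichment import enrichment_scan

        categories = [
            io_formats.read_bed(path, name=name)
            for name, path in sorted(config.category_beds.items())
        ]
        enrich = enrichment_scan(site_fits["CpH"], categories, config.cutoffs)
        note("enrichment", n_tests=len(enrich))

    tables = {"global_shift": global_df, "dmrs": dmrs}
    for context, fits in site_fits.items():
        io_formats.write_site_results(
            os.path.join(config.out_dir, f"site_results_{context}.tsv"), fits
        )
    if enrich is not None:
        tables["enrichment"] = enrich
    io_formats.write_results(tables, config.out_dir)
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=1, default=str)

    return PipelineResult(
        sample_sheet=sheet,
        qc=qc,
        kept_samples=kept_samples,
        removal_log=removal_log,
        site_fits=site_fits,
        thresholds=thresholds,
        global_shift=global_df,
        dmrs=dmrs,
        enrichment=enrich,
        truth=truth,
        log=run_log,
    )


def config_to_yaml(config: PipelineConfig, path) -> None:
    raw = dataclasses.asdict(config)
    if raw.get("simulation"):
        sim = raw["simulation"]
        sim["qc_failure_modes"] = [dict(m) for m in sim.get("qc_failure_modes", [])]
        sim["chrom_layout"] = dict(sim["chrom_layout"])
    raw["cutoffs"] = list(raw["cutoffs"])
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
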