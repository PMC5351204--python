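"""Synthetic RRBS case-control data with known ground truth.

Generates per-site baseline methylation (bimodal beta mixture for CpG,
low-mean beta for CpH), negative-binomial read coverage, and binomial
methylated counts whose success probability is shifted on the logit
scale by planted case effects, covariate effects, and latent
confounders. Every planted signal is indexed in a :class:`GroundTruth`
so downstream stages can be tested for recovery and calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from methylshift.preprocess import CountMatrix, make_site_table, genomic_order

_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class QCFailureSpec:
    """One QC-failure mode applied to ``n_samples`` randomly chosen samples."""

    mode: str  # hypermethylated | non_bimodal | coverage_aberrant
    n_samples: int = 1


@dataclass
class SimulationConfig:
    n_cases: int = 29
    n_controls: int = 34
    n_cpg_sites: int = 1000
    n_cph_sites: int = 2000
    coverage_mean: float = 30.0
    # NB size parameter; default mean/2 gives variance ~ 3x mean
    coverage_dispersion: float = 15.0
    # ((a_low, b_low), (a_high, b_high), weight_low); marginal mean ~ 0.212
    cpg_bimodal_params: tuple = ((1.0, 32.333), (7.0, 4.0), 0.7)
    cph_baseline_params: tuple = (0.85, 49.15)
    effect_fraction: float = 0.0
    effect_median_shift: float = 1.8  # percentage points, case-minus-control
    n_confounders: int = 0
    confounder_sd: float = 1.0
    confounder_site_fraction: float = 0.4
    # per-sample logit offset shared by all sites: sample-level technical
    # variation, the cross-site dependence real libraries carry
    sample_noise_sd: float = 0.0
    covariate_effect_sd: float = 0.05  # per-site logit-scale age/sex coefficients
    n_dmrs: int = 0
    dmr_n_sites: int = 10
    dmr_span_bp: int = 1000
    dmr_shift: float = 10.0  # percentage points
    # sites clump inside size-selected fragments, as in RRBS libraries
    sites_per_fragment: float = 8.0
    fragment_span: int = 150
    qc_failure_modes: list = field(default_factory=list)
    chrom_layout: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_cpg_sites", "n_cph_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if self.effect_median_shift < 0:
            raise ValueError("effect_median_shift must be >= 0")
        for pair in (*self.cpg_bimodal_params[:2], self.cph_baseline_params):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("beta parameters must be > 0")
        if not 0 <= self.cpg_bimodal_params[2] <= 1:
            raise ValueError("mixture weight must be in [0, 1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be > 0")
        if (
            self.effect_fraction > 0
            and self.effect_median_shift > 0
            and self.effect_fraction * self.n_cph_sites < 1
        ):
            raise ValueError("effect sites cannot fit: effect_fraction * n_cph_sites < 1")
        for spec in self.qc_failure_modes:
            if spec.mode not in ("hypermethylated", "non_bimodal", "coverage_aberrant"):
                raise ValueError(f"unknown qc failure mode: {spec.mode!r}")


@dataclass
class GroundTruth:
    """Index of every planted signal in a simulated dataset."""

    effect_sites: dict = field(default_factory=dict)  # site_id -> true shift (pp)
    planted_dmrs: list = field(default_factory=list)  # dicts: chrom,start,end,shift,site_ids
    confounder_values: list = field(default_factory=list)  # per-sample values, k lists
    confounder_loadings: dict = field(default_factory=dict)  # site_id -> [loadings]
    outlier_samples: dict = field(default_factory=dict)  # sample_id -> failure mode
    meqtl_pairs: list = field(default_factory=list)  # dicts: snp_id, site_id, shift

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    sites: pd.DataFrame
    counts: CountMatrix
    sample_sheet: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _make_sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_cases + config.n_controls
    ids = [f"S{i:03d}" for i in range(n)]
    diagnosis = ["case"] * config.n_cases + ["control"] * config.n_controls
    age = np.round(np.clip(rng.normal(30, 12, n), 2, 85), 1)
    sex = rng.choice(["M", "F"], n)
    bank = rng.choice(["bankA", "bankB"], n)
    return pd.DataFrame(
        {"sample_id": ids, "diagnosis": diagnosis, "age": age, "sex": sex, "bank": bank}
    )


def _make_sites(config: SimulationConfig, rng: np.random.Generator):
    """Lay out CpG/CpH sites across chromosomes; reserve tight runs for DMRs."""
    total = config.n_cpg_sites + config.n_cph_sites
    chroms = list(config.chrom_layout)
    lengths = np.array([config.chrom_layout[c] for c in chroms], dtype=float)
    n_per = np.maximum(1, np.round(total * lengths / lengths.sum()).astype(int))
    # adjust rounding drift on the largest chromosome
    n_per[np.argmax(lengths)] += total - n_per.sum()

    chrom_col, pos_col = [], []
    for chrom, length, n_c in zip(chroms, lengths, n_per):
        # clump sites into fragment-sized windows so neighbors sit within
        # tens of bp, mimicking the enzyme-digested, size-selected library
        n_frag = max(1, int(np.ceil(n_c / config.sites_per_fragment)))
        frag_starts = np.sort(
            rng.choice(
                np.arange(100, max(int(length) - config.fragment_span, 200)),
                size=n_frag, replace=False,
            )
        )
        positions: list[int] = []
        f = 0
        while len(positions) < n_c:
            start = frag_starts[f % n_frag]
            k = max(1, rng.poisson(config.sites_per_fragment))
            k = min(k, config.fragment_span, n_c - len(positions))
            offsets = rng.choice(config.fragment_span, size=k, replace=False)
            positions.extend(int(start + o) for o in offsets)
            f += 1
        pos = np.unique(np.asarray(positions[:n_c], dtype=np.int64))
        chrom_col.append(np.full(len(pos), chrom, dtype=object))
        pos_col.append(pos)
    chrom_col = np.concatenate(chrom_col)
    pos_col = np.concatenate(pos_col)

    n_actual = len(pos_col)  # fragment overlap may deduplicate a few sites
    context = np.full(n_actual, "CpH", dtype=object)
    n_cpg = min(config.n_cpg_sites, n_actual)
    cpg_idx = rng.choice(n_actual, size=n_cpg, replace=False)
    context[cpg_idx] = "CpG"

    dmr_specs = []
    if config.n_dmrs > 0:
        # plant dedicated evenly spaced CpH runs, replacing existing rows
        spacing = max(1, config.dmr_span_bp // max(config.dmr_n_sites - 1, 1))
        chrom0 = chroms[int(np.argmax(lengths))]
        length0 = int(lengths[np.argmax(lengths)])
        anchor_gap = length0 // (config.n_dmrs + 1)
        for d in range(config.n_dmrs):
            start = anchor_gap * (d + 1)
            dmr_pos = start + spacing * np.arange(config.dmr_n_sites)
            dmr_specs.append((chrom0, dmr_pos))

    if dmr_specs:
        extra_chrom = np.concatenate([np.full(len(p), c, dtype=object) for c, p in dmr_specs])
        extra_pos = np.concatenate([p for _, p in dmr_specs])
        extra_ctx = np.full(len(extra_pos), "CpH", dtype=object)
        chrom_col = np.concatenate([chrom_col, extra_chrom])
        pos_col = np.concatenate([pos_col, extra_pos])
        context = np.concatenate([context, extra_ctx])

    sites = make_site_table(chrom_col, pos_col, "+", context)
    sites = sites.drop_duplicates(subset=["chrom", "pos", "strand"], keep="last")
    sites = sites.iloc[genomic_order(sites)].reset_index(drop=True)
    dmr_site_ids = []
    for chrom, dmr_pos in dmr_specs:
        ids = [f"{chrom}:{p}:+" for p in dmr_pos]
        dmr_site_ids.append((chrom, int(dmr_pos[0]), int(dmr_pos[-1]), ids))
    return sites, dmr_site_ids


def _shift_to_logit_delta(baseline: np.ndarray, shift_pp: np.ndarray) -> np.ndarray:
    """Logit-scale offset that moves baseline pi by shift_pp percentage points."""
    target = np.clip(baseline + shift_pp / 100.0, _EPS, 1 - _EPS)
    return _logit(target) - _logit(baseline)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset: site table, counts, sample sheet, ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_sites, s_samples, s_base, s_effects, s_conf, s_cov, s_counts, s_qc) = [
        np.random.default_rng(c) for c in ss.spawn(8)
    ]

    sample_sheet = _make_sample_sheet(config, s_samples)
    sites, dmr_layout = _make_sites(config, s_sites)
    n_sites = len(sites)
    n = len(sample_sheet)
    is_cpg = (sites["context"] == "CpG").to_numpy()
    is_cph = ~is_cpg

    # baseline methylation probability per site
    (a1, b1), (a2, b2), w_low = config.cpg_bimodal_params
    low = s_base.beta(a1, b1, n_sites)
    high = s_base.beta(a2, b2, n_sites)
    pick_low = s_base.random(n_sites) < w_low
    baseline = np.where(pick_low, low, high)
    a_cph, b_cph = config.cph_baseline_params
    baseline[is_cph] = s_base.beta(a_cph, b_cph, is_cph.sum())

    truth = GroundTruth()
    site_ids = sites["site_id"].to_numpy()
    is_case = (sample_sheet["diagnosis"] == "case").to_numpy().astype(float)

    # case effects on a fraction of CpH sites; per-site shift has median
    # effect_median_shift (lognormal multiplier with median 1)
    delta = np.zeros(n_sites)
    n_eff = int(round(config.effect_fraction * is_cph.sum()))
    if n_eff > 0 and config.effect_median_shift > 0:
        cph_idx = np.flatnonzero(is_cph)
        eff_idx = s_effects.choice(cph_idx, size=n_eff, replace=False)
        shifts = config.effect_median_shift * s_effects.lognormal(0.0, 0.5, n_eff)
        delta[eff_idx] = _shift_to_logit_delta(baseline[eff_idx], shifts)
        truth.effect_sites = {site_ids[i]: float(s) for i, s in zip(eff_idx, shifts)}

    # planted DMRs: contiguous CpH runs with a shared case-hyper shift
    id_to_row = {sid: i for i, sid in enumerate(site_ids)}
    for chrom, start, end, ids in dmr_layout:
        rows = np.array([id_to_row[i] for i in ids])
        delta[rows] = _shift_to_logit_delta(baseline[rows], np.full(len(rows), config.dmr_shift))
        truth.planted_dmrs.append(
            {"chrom": chrom, "start": start, "end": end, "shift": config.dmr_shift,
             "site_ids": list(ids)}
        )
        for i, sid in zip(rows, ids):
            truth.effect_sites.setdefault(sid, config.dmr_shift)

    # latent confounders: per-sample values, loadings on a site subset
    logit_pi = _logit(baseline)[:, None] + delta[:, None] * is_case[None, :]
    if config.sample_noise_sd > 0:
        logit_pi = logit_pi + s_conf.normal(0, config.sample_noise_sd, n)[None, :]
    if config.n_confounders > 0:
        conf_vals = s_conf.normal(0, 1, (n, config.n_confounders))
        loadings = np.zeros((n_sites, config.n_confounders))
        for k in range(config.n_confounders):
            loaded = s_conf.random(n_sites) < config.confounder_site_fraction
            loadings[loaded, k] = s_conf.normal(0, config.confounder_sd, loaded.sum())
        logit_pi = logit_pi + loadings @ conf_vals.T
        truth.confounder_values = conf_vals.T.tolist()
        loaded_any = np.abs(loadings).sum(axis=1) > 0
        truth.confounder_loadings = {
            site_ids[i]: loadings[i].tolist() for i in np.flatnonzero(loaded_any)
        }

    # small per-site covariate effects (age standardized, sex indicator)
    if config.covariate_effect_sd > 0:
        age = sample_sheet["age"].to_numpy(dtype=float)
        age_z = (age - age.mean()) / max(age.std(), 1e-9)
        sex_f = (sample_sheet["sex"] == "F").to_numpy().astype(float)
        beta_age = s_cov.normal(0, config.covariate_effect_sd, n_sites)
        beta_sex = s_cov.normal(0, config.covariate_effect_sd, n_sites)
        logit_pi = logit_pi + beta_age[:, None] * age_z[None, :] + beta_sex[:, None] * sex_f[None, :]

    pi = _expit(logit_pi)

    # negative-binomial coverage, binomial methylated reads
    r = config.coverage_dispersion
    p_nb = r / (r + config.coverage_mean)
    coverage = s_counts.negative_binomial(r, p_nb, (n_sites, n)).astype(np.int64)
    methylated = s_counts.binomial(coverage, pi).astype(np.int64)

    counts = CountMatrix(sites, list(sample_sheet["sample_id"]), coverage, methylated)

    if config.qc_failure_modes:
        healthy = list(sample_sheet["sample_id"])
        assignments = []
        for spec in config.qc_failure_modes:
            chosen = s_qc.choice(len(healthy), size=spec.n_samples, replace=False)
            for c in sorted(chosen, reverse=True):
                assignments.append((healthy.pop(c), spec.mode))
        counts = inject_qc_failures(counts, assignments, seed=int(s_qc.integers(2**31)))
        truth.outlier_samples = {sid: mode for sid, mode in assignments}

    return SimulatedDataset(sites, counts, sample_sheet, truth, config)


def inject_qc_failures(
    counts: CountMatrix, assignments: list[tuple[str, str]], seed: int = 0
) -> CountMatrix:
    """Corrupt named samples with library-failure signatures.

    ``hypermethylated``: >99% of the sample's cytosines become fully
    methylated. ``non_bimodal``: CpG methylation redrawn from a unimodal
    mid-range distribution. ``coverage_aberrant``: coverage rescaled by a
    heavy-tailed lognormal factor. Other samples are untouched.
    """
    out = counts.copy()
    rng = np.random.default_rng(seed)
    is_cpg = (out.sites["context"] == "CpG").to_numpy()
    for sample_id, mode in assignments:
        if sample_id not in out.samples:
            raise ValueError(f"unknown sample: {sample_id}")
        j = out.samples.index(sample_id)
        if mode == "hypermethylated":
            hit = rng.random(out.n_sites) < 0.995
            out.methylated[hit, j] = out.coverage[hit, j]
        elif mode == "non_bimodal":
            idx = np.flatnonzero(is_cpg)
            mid = rng.beta(20, 20, len(idx))
            out.methylated[idx, j] = rng.binomial(out.coverage[idx, j], mid)
        elif mode == "coverage_aberrant":
            factor = rng.lognormal(0.0, 1.5, out.n_sites)
            old_cov = out.coverage[:, j].astype(float)
            frac = np.where(old_cov > 0, out.methylated[:, j] / np.maximum(old_cov, 1), 0.0)
            new_cov = np.rint(old_cov * factor).astype(np.int64)
            out.coverage[:, j] = new_cov
            out.methylated[:, j] = rng.binomial(new_cov, np.clip(frac, 0, 1))
        else:
            raise ValueError(f"unknown qc failure mode: {mode!r}")
    out.validate()
    return out


def simulate_genotypes(
    site_table: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    n_snps: int,
    meqtl_pairs: int,
    seed: int = 0,
    counts: CountMatrix | None = None,
    per_allele_shift: float = 10.0,
    max_distance: int = 100_000,
):
    """Simulate Hardy-Weinberg dosages and plant cis meQTLs.

    Each SNP gets an allele frequency in [0.05, 0.5] (planted meQTL SNPs
    draw from [0.2, 0.5] so their signal is assayable) and a position within
    ``max_distance`` of a randomly linked site. For the first
    ``meqtl_pairs`` SNPs the linked site's methylation is shifted by
    ``per_allele_shift`` percentage points per alternate allele — applied
    in place to ``counts`` when given (the generator owns the counts; the
    caller passes them so genotype effects land in the same matrix).

    Returns (dosage DataFrame samples x SNPs, snp table, known-pair DataFrame).
    """
    if n_snps < meqtl_pairs:
        raise ValueError("n_snps must be >= meqtl_pairs")
    rng = np.random.default_rng(seed)
    n = len(sample_sheet)
    snp_ids = [f"rs{k:05d}" for k in range(n_snps)]
    target_rows = rng.choice(len(site_table), size=n_snps, replace=False)
    offsets = rng.integers(-max_distance, max_distance + 1, n_snps)
    snp_pos = np.maximum(1, site_table["pos"].to_numpy()[target_rows] + offsets)
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": site_table["chrom"].to_numpy()[target_rows],
            "pos": snp_pos,
        }
    )
    af = rng.uniform(0.05, 0.5, n_snps)
    # planted pairs need enough carriers for their signal to be assayable
    if meqtl_pairs:
        af[:meqtl_pairs] = rng.uniform(0.2, 0.5, meqtl_pairs)
    dosage = rng.binomial(2, af[None, :].repeat(n, axis=0))
    dosages = pd.DataFrame(dosage, index=list(sample_sheet["sample_id"]), columns=snp_ids)

    known = []
    for k in range(meqtl_pairs):
        row = int(target_rows[k])
        site_id = site_table["site_id"].iloc[row]
        known.append({"snp_id": snp_ids[k], "site_id": site_id, "shift": per_allele_shift})
        if counts is not None:
            cov = counts.coverage[row].astype(float)
            with np.errstate(invalid="ignore"):
                frac = np.where(cov > 0, counts.methylated[row] / np.maximum(cov, 1), 0.0)
            frac = np.clip(frac + per_allele_shift / 100.0 * dosage[:, k], 0, 1)
            counts.methylated[row] = np.rint(frac * cov).astype(np.int64)
    if counts is not None:
        counts.validate()
    return dosages, snps, pd.DataFrame(known, columns=["snp_id", "site_id", "shift"])
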