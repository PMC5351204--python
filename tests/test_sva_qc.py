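import numpy as np
import pandas as pd
import pytest

from methylshift import preprocess, sva_qc
from methylshift.site_diffmeth import build_design
from methylshift.synthetic_data import (
    QCFailureSpec,
    SimulationConfig,
    inject_qc_failures,
    simulate_dataset,
    simulate_genotypes,
)


def _confounded(seed=0, n_conf=1, n_sites=3000):
    cfg = SimulationConfig(
        n_cases=30, n_controls=30, n_cpg_sites=n_sites, n_cph_sites=50,
        n_confounders=n_conf, confounder_sd=1.0, covariate_effect_sd=0.0, seed=seed,
    )
    ds = simulate_dataset(cfg)
    meth = preprocess.percent_methylation(preprocess.filter_coverage(ds.counts))
    cpg = meth.subset_sites(
        np.flatnonzero((meth.sites["context"] == "CpG").to_numpy())
    ).complete_cases()
    return ds, cpg


class TestEstimateSvs:
    def test_orthonormal_and_protected(self, null_dataset):
        meth = preprocess.percent_methylation(
            preprocess.filter_coverage(null_dataset.counts)
        ).complete_cases()
        design = build_design(null_dataset.sample_sheet)
        svset = sva_qc.estimate_svs(meth, design, k=5)
        gram = svset.sv.T @ svset.sv
        assert np.allclose(gram, np.eye(svset.k), atol=1e-8)
        diag = (null_dataset.sample_sheet["diagnosis"] == "case").to_numpy(float)
        for k in range(svset.k):
            r = np.corrcoef(svset.sv[:, k], diag)[0, 1]
            assert abs(r) < 0.3

    def test_planted_confounder_recovered_by_sv1(self):
        ds, cpg = _confounded(seed=0)
        design = build_design(ds.sample_sheet, include_covariates=False)
        svset = sva_qc.estimate_svs(cpg, design, k=5)
        conf = np.asarray(ds.truth.confounder_values[0])
        assert abs(np.corrcoef(svset.sv[:, 0], conf)[0, 1]) >= 0.9

    def test_two_confounders_spanned_by_sv12(self):
        ds, cpg = _confounded(seed=1, n_conf=2)
        design = build_design(ds.sample_sheet, include_covariates=False)
        svset = sva_qc.estimate_svs(cpg, design, k=5)
        C = np.asarray(ds.truth.confounder_values).T  # n x 2
        V = svset.sv[:, :2]
        # canonical correlations via SVD of the cross-correlation of whitened blocks
        qc_, _ = np.linalg.qr(C - C.mean(0))
        qv, _ = np.linalg.qr(V - V.mean(0))
        cancor = np.linalg.svd(qc_.T @ qv, compute_uv=False)
        assert cancor.min() >= 0.9

    def test_k_truncated_with_warning(self):
        rng = np.random.default_rng(2)
        from tests.conftest import meth_from_values

        meth = meth_from_values(np.clip(50 + rng.normal(0, 5, (200, 8)), 0, 100))
        sheet = pd.DataFrame(
            {
                "sample_id": [f"S{j}" for j in range(8)],
                "diagnosis": ["case", "control"] * 4,
                "age": 30.0, "sex": "M", "bank": "bankA",
            }
        )
        design = build_design(sheet, include_covariates=False)
        with pytest.warns(UserWarning, match="truncated"):
            svset = sva_qc.estimate_svs(meth, design, k=10)
        assert svset.k == 6


class TestDetectSvOutliers:
    def test_clean_data_zero_removals(self, null_dataset):
        meth = preprocess.percent_methylation(
            preprocess.filter_coverage(null_dataset.counts)
        )
        cpg = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpG").to_numpy()))
        kept, log = sva_qc.detect_sv_outliers(cpg, null_dataset.sample_sheet, k=5)
        assert kept == list(cpg.samples)
        assert log[-1]["flagged"] == []

    def test_hypermethylated_sample_flagged_round_one(self, null_dataset):
        counts = inject_qc_failures(
            null_dataset.counts, [("S010", "hypermethylated")], seed=3
        )
        meth = preprocess.percent_methylation(preprocess.filter_coverage(counts))
        cpg = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpG").to_numpy()))
        kept, log = sva_qc.detect_sv_outliers(cpg, null_dataset.sample_sheet, k=5)
        assert "S010" in log[0]["flagged"]
        assert "S010" not in kept

    def test_deterministic(self, null_dataset):
        meth = preprocess.percent_methylation(preprocess.filter_coverage(null_dataset.counts))
        cpg = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpG").to_numpy()))
        a = sva_qc.detect_sv_outliers(cpg, null_dataset.sample_sheet, k=5)
        b = sva_qc.detect_sv_outliers(cpg, null_dataset.sample_sheet, k=5)
        assert a == b

    def test_sample_count_strictly_decreases(self, null_dataset):
        counts = inject_qc_failures(
            null_dataset.counts,
            [("S001", "hypermethylated"), ("S002", "hypermethylated")],
            seed=4,
        )
        meth = preprocess.percent_methylation(preprocess.filter_coverage(counts))
        cpg = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpG").to_numpy()))
        _, log = sva_qc.detect_sv_outliers(cpg, null_dataset.sample_sheet, k=5)
        sizes = [entry["n_samples"] for entry in log]
        assert all(b < a for a, b in zip(sizes, sizes[1:]))


class TestDetectMeqtls:
    def _toy(self):
        from tests.conftest import meth_from_values

        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, 30).astype(float)
        y = np.clip(40 + 6 * g + rng.normal(0, 3, 30), 0, 100)
        meth = meth_from_values(y[None, :], positions=[5000])
        dosages = pd.DataFrame({"rs1": g}, index=meth.samples)
        snps = pd.DataFrame({"snp_id": ["rs1"], "chrom": ["chr1"], "pos": [6000]})
        return meth, dosages, snps, g, y

    def test_coefficients_match_normal_equations_oracle(self):
        meth, dosages, snps, g, y = self._toy()
        det = sva_qc.detect_meqtls(meth, dosages, snps, alpha=1.0)
        X = np.column_stack([np.ones(30), g])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        assert det["beta"].iloc[0] == pytest.approx(expected[1], abs=1e-8)

    def test_cis_window_boundary(self):
        meth, dosages, snps, _, _ = self._toy()
        inside = snps.assign(pos=[5000 + 1_000_000])
        outside = snps.assign(pos=[5000 + 1_000_001])
        assert len(sva_qc.detect_meqtls(meth, dosages, inside, alpha=1.0)) == 1
        assert len(sva_qc.detect_meqtls(meth, dosages, outside, alpha=1.0)) == 0

    def test_monomorphic_skipped(self):
        meth, dosages, snps, _, _ = self._toy()
        dosages["rs1"] = 1.0
        assert len(sva_qc.detect_meqtls(meth, dosages, snps, alpha=1.0)) == 0

    def test_null_detection_rate_near_alpha(self):
        from tests.conftest import meth_from_values

        rng = np.random.default_rng(6)
        n, S = 60, 400
        y = np.clip(50 + rng.normal(0, 10, (S, n)), 0, 100)
        meth = meth_from_values(y, positions=1000 * (np.arange(S) + 1))
        g = rng.binomial(2, 0.3, n).astype(float)
        dosages = pd.DataFrame({"rs1": g}, index=meth.samples)
        snps = pd.DataFrame({"snp_id": ["rs1"], "chrom": ["chr1"], "pos": [200_000]})
        det = sva_qc.detect_meqtls(meth, dosages, snps, alpha=0.05)
        rate = len(det) / S
        assert 0.01 < rate < 0.10


class TestKnownMeqtlRecovery:
    def test_two_of_three(self):
        known = pd.DataFrame({"snp_id": ["a", "b", "c"], "site_id": ["x", "y", "z"]})
        det = pd.DataFrame({"snp_id": ["a", "b"], "site_id": ["x", "y"]})
        assert sva_qc.known_meqtl_recovery(det, known) == pytest.approx(2 / 3)

    def test_superset_gives_one(self):
        known = pd.DataFrame({"snp_id": ["a"], "site_id": ["x"]})
        det = pd.DataFrame({"snp_id": ["a", "q"], "site_id": ["x", "w"]})
        assert sva_qc.known_meqtl_recovery(det, known) == 1.0

    def test_zero_assayable_errors(self):
        known = pd.DataFrame({"snp_id": ["a"], "site_id": ["x"]})
        with pytest.raises(ValueError):
            sva_qc.known_meqtl_recovery(pd.DataFrame(columns=["snp_id", "site_id"]),
                                        known, snp_ids={"other"})

    def test_recovery_not_hurt_by_removing_bad_sample(self):
        cfg = SimulationConfig(
            n_cases=30, n_controls=30, n_cpg_sites=400, n_cph_sites=50, seed=11,
        )
        ds = simulate_dataset(cfg)
        dosages, snps, known = simulate_genotypes(
            ds.sites, ds.sample_sheet, 8, 4, seed=12, counts=ds.counts, per_allele_shift=10.0
        )
        corrupted = inject_qc_failures(ds.counts, [("S005", "hypermethylated")], seed=13)

        def recovery(counts, samples):
            meth = preprocess.percent_methylation(preprocess.filter_coverage(counts))
            meth = meth.subset_samples(samples)
            det = sva_qc.detect_meqtls(meth, dosages, snps, alpha=1e-3)
            return sva_qc.known_meqtl_recovery(
                det, known, set(dosages.columns), set(meth.sites["site_id"])
            )

        all_samples = list(ds.counts.samples)
        cleaned = [s for s in all_samples if s != "S005"]
        assert recovery(corrupted, cleaned) >= recovery(corrupted, all_samples)


class TestSampleQC:
    def test_clean_samples_unflagged(self, null_dataset):
        qc = sva_qc.sample_qc(null_dataset.counts)
        assert not qc["flag_any"].any()

    def test_hypermethylated_flagged(self, null_dataset):
        counts = inject_qc_failures(null_dataset.counts, [("S003", "hypermethylated")], seed=14)
        qc = sva_qc.sample_qc(counts).set_index("sample_id")
        assert qc.loc["S003", "flag_hypermethylated"]

    def test_non_bimodal_flagged(self, null_dataset):
        counts = inject_qc_failures(null_dataset.counts, [("S004", "non_bimodal")], seed=15)
        qc = sva_qc.sample_qc(counts).set_index("sample_id")
        assert qc.loc["S004", "flag_non_bimodal"]

    def test_coverage_aberrant_flagged(self, null_dataset):
        counts = inject_qc_failures(null_dataset.counts, [("S006", "coverage_aberrant")], seed=16)
        qc = sva_qc.sample_qc(counts).set_index("sample_id")
        assert qc.loc["S006", "flag_coverage"]
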