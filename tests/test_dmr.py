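import numpy as np
import pandas as pd
import pytest

from methylshift import preprocess
from methylshift.dmr import (
    cluster_sites,
    compute_fwer,
    dmr_analysis,
    dmr_significance,
    find_candidate_regions,
    pick_cutoff,
    significance_threshold,
    smooth_coefficients,
)
from methylshift.site_diffmeth import build_design
from methylshift.synthetic_data import SimulationConfig, simulate_dataset


class TestClusterSites:
    def test_gap_example(self):
        labels = cluster_sites(np.array(["chr1"] * 3), np.array([100, 200, 600]), maxgap=300)
        assert labels[0] == labels[1]
        assert labels[2] != labels[1]

    def test_maxgap_zero_degenerate(self):
        labels = cluster_sites(np.array(["chr1"] * 4), np.array([10, 20, 30, 40]), maxgap=0)
        assert len(set(labels)) == 4

    def test_chromosome_break(self):
        labels = cluster_sites(np.array(["chr1", "chr2"]), np.array([100, 100]), maxgap=300)
        assert labels[0] != labels[1]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(100_000, 500, replace=False))
        chroms = np.array(["chr1"] * 500)
        labels = cluster_sites(chroms, pos, maxgap=300)

        # brute-force union-find over all pairs within maxgap
        parent = list(range(500))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(500):
            for j in range(i + 1, 500):
                if pos[j] - pos[i] <= 300:
                    parent[find(j)] = find(i)
        oracle = np.array([find(i) for i in range(500)])
        # same partition: label equality patterns agree
        assert np.array_equal(
            labels[:, None] == labels[None, :], oracle[:, None] == oracle[None, :]
        )

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            cluster_sites(np.array(["chr1", "chr1"]), np.array([200, 100]))


class TestSmoothCoefficients:
    def test_constant_identity(self):
        pos = np.arange(10) * 10
        clusters = np.zeros(10, int)
        vals = np.full(10, 3.5)
        out = smooth_coefficients(pos, vals, clusters, window=5, min_sites=7)
        assert np.allclose(out, 3.5)

    def test_small_cluster_passthrough(self):
        pos = np.array([10, 20, 30])
        out = smooth_coefficients(pos, np.array([1.0, 5.0, 9.0]), np.zeros(3, int),
                                  window=3, min_sites=7)
        assert np.allclose(out, [1.0, 5.0, 9.0])

    def test_nine_site_running_mean_hand_computed(self):
        vals = np.arange(9, dtype=float)  # 0..8
        pos = np.arange(9) * 10
        out = smooth_coefficients(pos, vals, np.zeros(9, int), window=3, min_sites=7)
        expected = np.array([0.5, 1, 2, 3, 4, 5, 6, 7, 7.5])
        assert np.allclose(out, expected)

    def test_weighted_running_mean(self):
        vals = np.array([0.0, 10.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        w = np.array([1.0, 3.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        pos = np.arange(7) * 10
        out = smooth_coefficients(pos, vals, np.zeros(7, int), window=3, min_sites=7, weights=w)
        assert out[0] == pytest.approx(30 / 4)
        assert out[1] == pytest.approx(30 / 5)


class TestPickCutoff:
    def test_linear_interpolation_1_to_100(self):
        vals = np.arange(1.0, 101.0)
        assert pick_cutoff(vals, 0.99) == pytest.approx(99.01)

    def test_constant_values(self):
        assert pick_cutoff(np.full(200, 2.5), 0.99) == 2.5

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=500)
        cuts = [pick_cutoff(vals, q) for q in (0.9, 0.95, 0.99)]
        assert cuts[0] <= cuts[1] <= cuts[2]

    def test_uses_absolute_values(self):
        vals = np.concatenate([np.full(99, 0.1), [-50.0]])
        assert pick_cutoff(vals, 0.99) > 0.1


class TestFindCandidateRegions:
    def _frame(self, smoothed, raw=None, positions=None, cutoff=1.0):
        n = len(smoothed)
        if positions is None:
            positions = 100 * (np.arange(n) + 1)
        chroms = np.array(["chr1"] * n)
        clusters = np.zeros(n, int)
        if raw is None:
            raw = smoothed
        return find_candidate_regions(
            chroms, np.asarray(positions), np.asarray(smoothed, float),
            np.asarray(raw, float), clusters, cutoff,
        )

    def test_nothing_above_cutoff(self):
        out = self._frame([0.5, 0.2, -0.4])
        assert len(out) == 0

    def test_five_site_run(self):
        smoothed = [0.1, 2.0, 2.5, 3.0, 2.2, 1.8, 0.3]
        raw = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 0.0]
        out = self._frame(smoothed, raw)
        assert len(out) == 1
        r = out.iloc[0]
        assert r["n_sites"] == 5
        assert r["value"] == pytest.approx(np.mean([1, 2, 3, 4, 5]))
        assert r["length_bp"] == r["end"] - r["start"] + 1

    def test_regions_never_span_clusters(self):
        n = 6
        chroms = np.array(["chr1"] * n)
        positions = np.array([100, 200, 300, 5000, 5100, 5200])
        clusters = cluster_sites(chroms, positions, maxgap=300)
        smoothed = np.full(n, 5.0)
        out = find_candidate_regions(chroms, positions, smoothed, smoothed, clusters, 1.0)
        assert len(out) == 2

    def test_direction_split(self):
        out = self._frame([3.0, 3.0, -3.0, -3.0])
        assert len(out) == 2
        assert set(out["direction"]) == {1, -1}

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValueError):
            self._frame([1.0], cutoff=0.0)


class TestComputeFwer:
    def _region(self, length, value):
        return pd.DataFrame(
            {
                "chrom": ["chr1"], "start": [100], "end": [100 + length - 1],
                "n_sites": [5], "value": [value], "length_bp": [length],
                "direction": [1], "fwer": [np.nan],
            }
        )

    def test_dominating_observed_gets_zero(self):
        obs = self._region(1000, 10.0)
        boots = [self._region(100, 1.0)] * 4
        out = compute_fwer(obs, boots)
        assert out["fwer"].iloc[0] == 0.0

    def test_one_in_four_dominated(self):
        obs = self._region(500, 5.0)
        boots = [self._region(100, 1.0)] * 3 + [self._region(600, 6.0)]
        out = compute_fwer(obs, boots)
        assert out["fwer"].iloc[0] == pytest.approx(0.25)

    def test_strict_dominance_on_both(self):
        obs = self._region(500, 5.0)
        # longer but not higher; higher but not longer: neither dominates
        boots = [self._region(600, 5.0), self._region(500, 6.0)]
        out = compute_fwer(obs, boots)
        assert out["fwer"].iloc[0] == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        obs = pd.concat(
            [self._region(int(l), v) for l, v in zip(rng.integers(50, 2000, 8), rng.uniform(0.5, 8, 8))],
            ignore_index=True,
        )
        boots = []
        for _ in range(20):
            k = rng.integers(0, 4)
            boots.append(
                pd.concat(
                    [self._region(int(l), v) for l, v in
                     zip(rng.integers(50, 2000, k), rng.uniform(0.5, 8, k))],
                    ignore_index=True,
                ) if k else self._region(1, 1).iloc[:0]
            )
        out = compute_fwer(obs, boots)
        for i in range(len(obs)):
            count = 0
            for boot in boots:
                hit = any(
                    (q.length_bp > obs["length_bp"].iloc[i]) and (abs(q.value) > abs(obs["value"].iloc[i]))
                    for q in boot.itertuples()
                )
                count += hit
            assert out["fwer"].iloc[i] == pytest.approx(count / 20)

    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            compute_fwer(self._region(10, 1.0), [])


class TestDmrSignificance:
    def test_threshold_value(self):
        assert significance_threshold(24, 0.05) == pytest.approx(0.05 / 24)
        assert float(f"{significance_threshold(24, 0.05):.1g}") == 0.002

    def test_strict_boundary(self):
        # threshold is exactly alpha/n_tests with strict <; a region whose
        # fwer equals the threshold is not significant
        regions = pd.DataFrame({"fwer": [0.001, 0.05 / 24, 0.5]})
        out = dmr_significance(regions, n_tests=24, alpha=0.05)
        assert list(out["significant"]) == [True, False, False]

    def test_single_test_threshold_is_alpha(self):
        regions = pd.DataFrame({"fwer": [0.04]})
        out = dmr_significance(regions, n_tests=1, alpha=0.05)
        assert bool(out["significant"].iloc[0])


class TestDmrAnalysis:
    def test_planted_dmr_recovered(self):
        cfg = SimulationConfig(
            n_cases=30, n_controls=30, n_cpg_sites=50, n_cph_sites=1500,
            n_dmrs=1, dmr_n_sites=10, dmr_span_bp=1000, dmr_shift=10.0, seed=21,
        )
        ds = simulate_dataset(cfg)
        meth = preprocess.percent_methylation(preprocess.filter_coverage(ds.counts, min_cov=5))
        cph = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpH").to_numpy()))
        design = build_design(ds.sample_sheet)
        regions = dmr_analysis(cph, design, design.drop_diagnosis(), B=30, seed=5)
        truth = ds.truth.planted_dmrs[0]
        overlaps = regions[
            (regions["chrom"] == truth["chrom"])
            & (regions["end"] >= truth["start"])
            & (regions["start"] <= truth["end"])
        ]
        assert len(overlaps) >= 1
        assert overlaps["fwer"].min() <= regions["fwer"].min()

    def test_null_simulation_fwer_not_confident(self):
        # needs enough site density for multi-site noise regions to exist
        cfg = SimulationConfig(
            n_cases=29, n_controls=34, n_cpg_sites=300, n_cph_sites=2500,
            sites_per_fragment=16.0, seed=102,
        )
        ds = simulate_dataset(cfg)
        meth = preprocess.percent_methylation(
            preprocess.filter_coverage(ds.counts, min_cov=5)
        )
        cph = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpH").to_numpy()))
        design = build_design(ds.sample_sheet)
        regions = dmr_analysis(cph, design, design.drop_diagnosis(), B=50, seed=6)
        assert len(regions) > 0
        assert regions["fwer"].median() > 0.5

    def test_deterministic(self, null_dataset):
        meth = preprocess.percent_methylation(
            preprocess.filter_coverage(null_dataset.counts, min_cov=5)
        )
        cph = meth.subset_sites(np.flatnonzero((meth.sites["context"] == "CpH").to_numpy()))
        design = build_design(null_dataset.sample_sheet)
        a = dmr_analysis(cph, design, design.drop_diagnosis(), B=10, seed=7)
        b = dmr_analysis(cph, design, design.drop_diagnosis(), B=10, seed=7)
        pd.testing.assert_frame_equal(a, b)
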