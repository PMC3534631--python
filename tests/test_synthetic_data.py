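import numpy as np
import pandas as pd
import pytest

from gflseg import (
    CNVSpec,
    NoiseSpec,
    StateModel,
    TumorCNVSpec,
    generate_cohort,
    generate_pedigree_cohort,
    generate_tumor_dilution,
    score_detection,
)

TINY = NoiseSpec(lrr_sd=1e-9, baf_sd_boundary=1e-9, baf_sd_interior=1e-9, outlier_frac=1e-12)


class TestGenerateCohort:
    def test_null_cohort_is_diploid(self):
        lrr, baf, truth = generate_cohort(4, 400, [], seed=0)
        assert np.all(truth.cn == 2)
        sd = NoiseSpec().lrr_sd
        assert np.all(np.abs(lrr.values.mean(axis=1)) < 3 * sd / np.sqrt(400))

    def test_noiseless_limit_is_piecewise_constant(self):
        spec = [CNVSpec(10, 20, 1, (0,))]
        lrr, _, _ = generate_cohort(2, 50, spec, noise=TINY, seed=1)
        model = StateModel()
        assert np.allclose(lrr.values[0, 10:30], model.lrr_means[1], atol=1e-6)
        assert np.allclose(lrr.values[0, :10], 0.0, atol=1e-6)
        assert np.allclose(lrr.values[1], 0.0, atol=1e-6)

    def test_truth_area_bookkeeping(self):
        specs = [
            CNVSpec(10, 5, 1, (0, 2)),
            CNVSpec(50, 8, 3, (1,)),
        ]
        _, _, truth = generate_cohort(3, 100, specs, seed=2)
        assert int((truth.cn != 2).sum()) == 5 * 2 + 8 * 1
        assert len(truth.regions) == 3

    def test_fixed_seed_reproducible(self):
        a = generate_cohort(3, 200, [CNVSpec(50, 10, 3, (1,))], seed=7)
        b = generate_cohort(3, 200, [CNVSpec(50, 10, 3, (1,))], seed=7)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_overlapping_specs_rejected(self):
        specs = [CNVSpec(10, 10, 1, (0,)), CNVSpec(15, 10, 3, (0,))]
        with pytest.raises(ValueError, match="overlap"):
            generate_cohort(1, 100, specs)

    def test_baf_clusters_match_state(self):
        lrr, baf, _ = generate_cohort(1, 4000, [CNVSpec(0, 4000, 3, (0,))], noise=TINY, seed=3)
        uniq = np.unique(np.round(baf.values[0], 3))
        assert set(uniq) <= {0.0, round(1 / 3, 3), round(2 / 3, 3), 1.0}


class TestTumorDilution:
    def test_pure_normal_is_flat(self):
        specs = [TumorCNVSpec(100, 200, 1, 0)]
        lrr, baf, _ = generate_tumor_dilution(500, specs, alpha=1.0, noise=TINY, seed=0)
        assert np.allclose(lrr.values, 0.0, atol=1e-6)
        het = np.abs(baf.values[0] - 0.5) < 0.01
        assert het.sum() > 100  # Hardy-Weinberg heterozygotes stay at 1/2

    def test_pure_tumor_deletion_level(self):
        specs = [TumorCNVSpec(0, 500, 1, 0)]
        lrr, _, _ = generate_tumor_dilution(500, specs, alpha=0.0, noise=TINY, seed=0)
        assert np.allclose(lrr.values[0], -1.0, atol=1e-6)  # log2(1/2)

    def test_half_mix_trisomy_baf_levels(self):
        # alpha=0.5, tumor (2,1): n_eff=2.5; genotype-level BAF means are
        # 0 (AA), (0.5+1)/2.5=0.6 or (0.5+2)/2.5=1.0... het depends on phase:
        # b_t in {1, 2} -> 0.4 or 0.6; BB -> (1+1.5)/2.5 = 1.0
        specs = [TumorCNVSpec(0, 4000, 2, 1)]
        _, baf, _ = generate_tumor_dilution(4000, specs, alpha=0.5, noise=TINY, seed=1)
        uniq = set(np.unique(np.round(baf.values[0], 6)))
        assert uniq == {0.0, 0.4, 0.6, 1.0}

    def test_lrr_mean_continuous_in_alpha(self):
        specs = [TumorCNVSpec(0, 100, 1, 0)]
        means = []
        for alpha in (0.48, 0.5, 0.52):
            lrr, _, _ = generate_tumor_dilution(100, specs, alpha=alpha, noise=TINY, seed=2)
            means.append(lrr.values.mean())
        assert abs(means[0] - means[1]) < 0.05 and abs(means[2] - means[1]) < 0.05

    def test_cnloh_is_lrr_invisible_baf_visible(self):
        specs = [TumorCNVSpec(0, 2000, 2, 0)]
        lrr, baf, truth = generate_tumor_dilution(2000, specs, alpha=0.0, noise=TINY, seed=3)
        assert np.allclose(lrr.values, 0.0, atol=1e-6)
        assert truth.cnloh is not None and truth.cnloh.all()
        interior = (baf.values[0] > 0.01) & (baf.values[0] < 0.99)
        assert interior.sum() == 0  # heterozygosity is gone

    def test_homozygous_deletion_floored(self):
        specs = [TumorCNVSpec(0, 50, 0, 0)]
        lrr, _, _ = generate_tumor_dilution(50, specs, alpha=0.0, noise=TINY, seed=4)
        assert np.allclose(lrr.values[0], -5.0, atol=1e-6)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_tumor_dilution(50, [], alpha=1.5)


class TestPedigreeCohort:
    def test_full_sharing(self):
        spec = [CNVSpec(10, 10, 1, (0,))]
        _, _, truth = generate_pedigree_cohort(6, 100, 1.0, spec, seed=0)
        assert np.all(truth.cn[:, 10:20] == 1)

    def test_minimum_one_carrier(self):
        spec = [CNVSpec(10, 10, 1, (0,))]
        _, _, truth = generate_pedigree_cohort(5, 100, 1e-9, spec, seed=1)
        assert (truth.cn != 2).any()

    def test_carrier_fraction_matches_p_share(self):
        p = 0.4
        M, draws = 10, 300
        total = 0
        for s in range(draws):
            _, _, truth = generate_pedigree_cohort(
                M, 40, p, [CNVSpec(0, 40, 1, (0,))], noise=TINY, seed=s
            )
            total += int((truth.cn[:, 0] == 1).sum())
        frac = total / (M * draws)
        se = np.sqrt(p * (1 - p) / (M * draws))
        assert abs(frac - p) < 4 * se + 1 / M  # +1/M for the forced-carrier floor


class TestScoreDetection:
    def make_truth(self, M=2, N=100):
        specs = [CNVSpec(20, 10, 1, (0,)), CNVSpec(60, 10, 3, (1,))]
        _, _, truth = generate_cohort(M, N, specs, seed=0)
        return truth

    def test_perfect_calls(self):
        truth = self.make_truth()
        calls = truth.regions.copy()
        table = score_detection(truth, calls, labels=["sample0", "sample1"])
        overall = table[(table.type == "any") & (table.length_class == "all")].iloc[0]
        assert overall.tpr == 100.0 and overall.fdr == 0.0

    def test_no_calls_flagged(self):
        truth = self.make_truth()
        empty = pd.DataFrame(columns=["sample", "start_probe", "end_probe", "state"])
        table = score_detection(truth, empty, labels=["sample0", "sample1"])
        overall = table.iloc[0]
        assert overall.tpr == 0.0 and overall.fdr == 0.0 and not overall.fdr_defined

    def test_random_calls_high_fdr(self, rng):
        _, _, truth = generate_cohort(1, 1000, [CNVSpec(0, 100, 1, (0,))], seed=1)
        # call a random 10% of the grid as deletions
        starts = rng.choice(900, 10, replace=False)
        calls = pd.DataFrame(
            {
                "sample": "sample0",
                "start_probe": starts + 1,
                "end_probe": starts + 10,
                "state": 1,
            }
        )
        table = score_detection(truth, calls, labels=["sample0"])
        fdr = table.iloc[0].fdr
        assert 80.0 < fdr < 98.0
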