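"""Generator correctness: HWE genotypes, r2 calibration, LOD censoring,
proportional-hazards event times, and full-study determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipomr import (
    SimConfig,
    exclude_low_detect,
    make_study,
    simulate_exposure,
    simulate_genotypes,
    simulate_proteins,
    simulate_survival,
)


class TestGenotypes:
    def test_dosages_mean_and_range(self):
        g = simulate_genotypes(100_000, [0.3], seed=1)
        assert set(np.unique(g)) <= {0, 1, 2}
        assert abs(g.mean() - 0.6) < 0.01  # binomial expectation 2*maf

    def test_hardy_weinberg_proportions(self):
        mafs = np.linspace(0.05, 0.5, 50)
        g = simulate_genotypes(20_000, mafs, seed=2)
        n = g.shape[0]
        n_pass = 0
        for j, p in enumerate(mafs):
            counts = np.bincount(g[:, j], minlength=3)
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            if stats.chi2.sf(chi2, 2) > 0.001:
                n_pass += 1
        assert n_pass >= 49  # >= 98% of variants consistent with HWE

    def test_tiny_maf_gives_mostly_zero_column(self):
        g = simulate_genotypes(1000, [1e-6], seed=3)
        assert g.sum() == 0

    def test_determinism(self):
        a = simulate_genotypes(500, [0.1, 0.4], seed=7)
        b = simulate_genotypes(500, [0.1, 0.4], seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("n,mafs", [(0, [0.1]), (10, [0.0]), (10, [0.6]), (-3, [0.2])])
    def test_rejects_bad_inputs(self, n, mafs):
        with pytest.raises(ValueError):
            simulate_genotypes(n, mafs, seed=0)


class TestExposure:
    def _r2(self, g, w, exposure):
        score = g @ w
        return float(np.corrcoef(score, exposure)[0, 1] ** 2)

    def test_target_r2_calibration(self):
        """Realized score-on-exposure r2 within +-25% of target at n >= 50k."""
        mafs = np.random.default_rng(0).uniform(0.05, 0.5, 40)
        w = np.abs(np.random.default_rng(1).standard_normal(40))
        r2s = []
        for seed in range(5):
            g = simulate_genotypes(50_000, mafs, seed=seed)
            u = np.random.default_rng(seed + 100).standard_normal(50_000)
            x = simulate_exposure(g, w, 0.02, u, 0.4, mean=23.9, sd=3.4, seed=seed)
            r2s.append(self._r2(g, w, x))
        assert 0.015 <= np.mean(r2s) <= 0.025

    def test_perfect_r2_is_rank_correlated_with_score(self):
        g = simulate_genotypes(2000, [0.2, 0.3, 0.4], seed=4)
        w = np.array([0.5, 1.0, 0.2])
        x = simulate_exposure(g, w, 1.0, seed=4)
        rho = stats.spearmanr(g @ w, x).statistic
        assert rho > 0.999999

    def test_zero_weights_give_null_r2(self):
        g = simulate_genotypes(5000, [0.3, 0.3], seed=5)
        x = simulate_exposure(g, [0.0, 0.0], 0.02, seed=5)
        score = g @ np.array([1.0, 1.0])  # any score is uninformative
        assert np.corrcoef(score, x)[0, 1] ** 2 < 1e-3

    def test_exposure_scale(self):
        g = simulate_genotypes(20_000, [0.3], seed=6)
        x = simulate_exposure(g, [1.0], 0.02, mean=23.9, sd=3.4, seed=6)
        assert abs(x.mean() - 23.9) < 0.1
        assert abs(x.std() - 3.4) < 0.1

    @pytest.mark.parametrize("r2", [0.0, -0.1, 1.2])
    def test_rejects_bad_r2(self, r2):
        g = simulate_genotypes(50, [0.3], seed=0)
        with pytest.raises(ValueError):
            simulate_exposure(g, [1.0], r2, seed=0)


class TestProteins:
    def test_null_protein_uncorrelated_with_exposure(self):
        rng = np.random.default_rng(8)
        expo = rng.standard_normal(10_000)
        conf = rng.standard_normal(10_000)
        g = simulate_genotypes(10_000, [0.3], seed=8)
        panel, _ = simulate_proteins(expo, conf, g, [0.0], [0.0], seed=8)
        assert abs(np.corrcoef(expo, panel.iloc[:, 0])[0, 1]) < 0.05

    def test_lod_censoring_fraction_and_downstream_exclusion(self):
        rng = np.random.default_rng(9)
        expo, conf = rng.standard_normal((2, 2000))
        g = simulate_genotypes(2000, [0.3], seed=9)
        panel, flags = simulate_proteins(
            expo, conf, g, [0.1, 0.0], [0.1, 0.0], lod_quantile=[0.995, 0.0],
            names=["mostly_lod", "clean"], seed=9
        )
        assert flags["mostly_lod"].mean() > 0.99
        assert flags["clean"].sum() == 0
        retained, log = exclude_low_detect(panel, flags)
        assert retained == ["clean"]
        assert list(log["protein"]) == ["mostly_lod"]

    def test_effect_recovered_by_ols(self):
        rng = np.random.default_rng(10)
        expo = rng.standard_normal(20_000)
        conf = np.zeros(20_000)
        g = simulate_genotypes(20_000, [0.3], seed=10)
        panel, _ = simulate_proteins(expo, conf, g, [0.35], [0.0], seed=10)
        slope = np.polyfit(expo, panel.iloc[:, 0], 1)[0]
        assert abs(slope - 0.35) < 0.02

    def test_unit_variance_before_censoring(self):
        rng = np.random.default_rng(11)
        expo, conf = rng.standard_normal((2, 20_000))
        g = simulate_genotypes(20_000, [0.3], seed=11)
        panel, _ = simulate_proteins(expo, conf, g, [0.4, 0.0], [0.3, 0.1], seed=11)
        assert np.allclose(panel.std(), 1.0, atol=0.03)

    def test_rejects_bad_lod(self):
        with pytest.raises(ValueError):
            simulate_proteins(np.zeros(10), np.zeros(10), np.zeros((10, 1)),
                              [0.1], [0.1], lod_quantile=[1.0], seed=0)


class TestSurvival:
    def test_null_groups_have_equal_event_rates(self):
        group = np.repeat([0.0, 1.0], 5000)
        rec = simulate_survival(group[:, None], [0.0], 10.0, 0.1, seed=12)
        r0 = rec["event"][group == 0].mean()
        r1 = rec["event"][group == 1].mean()
        assert abs(r0 - r1) < 0.02

    def test_loghr_recovered_by_cox(self):
        from adipomr import fit_cox

        x = np.random.default_rng(13).standard_normal(20_000)
        rec = simulate_survival(x[:, None], [0.2], 10.0, 0.1, seed=13)
        df = rec.copy()
        df["x"] = x
        fit = fit_cox(df)
        assert abs(fit.loc["x", "log_hr"] - 0.2) < 2 * fit.loc["x", "se"]

    def test_full_censoring_gives_zero_events(self):
        rec = simulate_survival(np.zeros((200, 1)), [0.0], 10.0, 1.0, seed=14)
        assert rec["event"].sum() == 0
        assert (rec["time_years"] > 0).all() and (rec["time_years"] <= 10).all()

    def test_times_within_followup(self):
        x = np.random.default_rng(15).standard_normal(3000)
        rec = simulate_survival(x[:, None], [0.3], 8.0, 0.2, seed=15)
        assert (rec["time_years"] > 0).all() and (rec["time_years"] <= 8.0).all()

    def test_rejects_negative_followup(self):
        with pytest.raises(ValueError):
            simulate_survival(np.zeros((5, 1)), [0.0], -1.0, 0.1, seed=0)


class TestMakeStudy:
    def test_shapes_match_config(self, small_config, small_study):
        cohort, truth = small_study
        assert cohort.genotypes.shape == (small_config.n_gwas, small_config.n_variants)
        assert cohort.proteins.shape == (small_config.n_subcohort, 92)
        assert len(cohort.survival) == small_config.n_subcohort
        assert len(truth.protein) == 92
        assert len(truth.variant) == small_config.n_variants
        assert truth.confounder.shape == (small_config.n_gwas,)

    def test_subcohort_is_subset_of_genotyped(self, small_cohort):
        assert set(small_cohort.subcohort_ids) <= set(small_cohort.covariates.index)
        assert len(np.unique(small_cohort.subcohort_ids)) == len(small_cohort.subcohort_ids)

    def test_same_seed_byte_identical_outputs(self, small_config, tmp_path):
        for d in ("a", "b"):
            cohort, truth = make_study(small_config)
            cohort.write(tmp_path / d, include_genotypes=True)
            truth.write(tmp_path / d / "truth")
        for f in sorted((tmp_path / "a").rglob("*.tsv")):
            other = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == other.read_bytes(), f.name

    def test_rare_variant_count(self, small_config, small_cohort):
        maf = np.minimum(small_cohort.variants["EAF"], 1 - small_cohort.variants["EAF"])
        assert (maf < 0.01).sum() == small_config.n_variants_rare

    def test_vcf_export_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "geno.vcf"
        small_cohort.export_vcf(path)
        lines = path.read_text().splitlines()
        records = [ln for ln in lines if not ln.startswith("#")]
        assert len(records) == len(small_cohort.variants)
        first = records[0].split("\t")
        gt_map = {"0/0": 0, "0/1": 1, "1/1": 2}
        dosages = [gt_map[x] for x in first[9:]]
        assert np.array_equal(dosages, small_cohort.genotypes[:, 0])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_gwas=100, n_subcohort=200)
        with pytest.raises(ValueError):
            SimConfig(variance_explained_exposure=1.5)
        with pytest.raises(ValueError):
            SimConfig(censor_rate=1.2)
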