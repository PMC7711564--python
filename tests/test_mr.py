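"""MR estimators: 2SLS, Wald ratio, IVW, Egger, weighted median, Steiger,
Cochran Q and the cis-window exclusion filter."""

import numpy as np
import pandas as pd
import pytest

from adipomr import (
    SummaryAssoc,
    cochran_q_two_estimates,
    exclude_nearby_variants,
    harmonize_summary,
    ivw,
    mr_egger,
    rescale_per_exposure_sd,
    steiger_direction,
    two_stage_least_squares,
    wald_ratio,
    weighted_median,
)
from adipomr.mr import tsls_panel

from conftest import make_summary_stats


def sa(bx, by, sx=0.01, sy=0.01, id="v"):
    return SummaryAssoc(id=id, beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy)


class TestWaldRatio:
    def test_simple_ratio(self):
        assert wald_ratio(sa(0.1, 0.2)).estimate == pytest.approx(2.0)

    def test_zero_outcome_beta(self):
        assert wald_ratio(sa(0.1, 0.0)).estimate == 0.0

    def test_delta_method_se(self):
        assert wald_ratio(sa(0.5, 0.1, sy=0.05)).se == pytest.approx(0.1)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(sa(0.0, 0.1))


class TestIvw:
    def test_single_variant_equals_wald(self):
        a = sa(0.12, 0.3, sy=0.04)
        w, i = wald_ratio(a), ivw([a])
        assert i.estimate == pytest.approx(w.estimate, abs=1e-12)
        assert i.se == pytest.approx(w.se, abs=1e-12)

    def test_identical_ratios_pool_exactly(self):
        assocs = [sa(0.1, 0.05, sy=0.01, id=f"v{i}") for i in range(4)]
        res = ivw(assocs)
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(wald_ratio(assocs[0]).se / 2.0)

    def test_unbiased_without_pleiotropy(self):
        ests = [ivw(make_summary_stats(50, 0.3, seed=s)).estimate for s in range(100)]
        assert abs(np.mean(ests) - 0.3) < 0.02

    def test_random_effects_widens_under_heterogeneity(self):
        assocs = [sa(0.1, 0.01 * (i + 1) ** 2, sy=0.001, id=f"v{i}") for i in range(6)]
        assert ivw(assocs, random_effects=True).se > ivw(assocs).se


class TestEgger:
    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            mr_egger([sa(0.1, 0.2, id="a"), sa(0.2, 0.3, id="b")])

    def test_no_pleiotropy_recovers_slope_and_null_intercept(self):
        icpts, slopes = [], []
        for s in range(150):
            res = mr_egger(make_summary_stats(50, 0.3, seed=s))
            icpts.append(res.egger_intercept)
            slopes.append(res.estimate)
        assert abs(np.mean(icpts)) < 0.005
        assert abs(np.mean(slopes) - 0.3) < 0.05

    def test_constant_pleiotropy_lands_in_intercept(self):
        """Directional pleiotropy shifts the intercept, not the slope (InSIDE)."""
        icpts, slopes = [], []
        for s in range(150):
            stats = make_summary_stats(50, 0.3, seed=s, pleiotropy=np.full(50, 0.05))
            res = mr_egger(stats)
            icpts.append(res.egger_intercept)
            slopes.append(res.estimate)
        assert np.mean(icpts) == pytest.approx(0.05, abs=0.01)
        assert abs(np.mean(slopes) - 0.3) < 0.05


class TestWeightedMedian:
    def test_equal_ratios_exact(self):
        assocs = [sa(0.1 * (i + 1), 0.05 * (i + 1), id=f"v{i}") for i in range(5)]
        assert weighted_median(assocs, n_boot=10).estimate == pytest.approx(0.5)

    def test_equal_weights_is_plain_median(self):
        assocs = [sa(0.1, r * 0.1, id=f"v{i}") for i, r in enumerate([1.0, 2.0, 9.0])]
        assert weighted_median(assocs, n_boot=10).estimate == pytest.approx(2.0)

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            weighted_median([sa(0.1, 0.2, id="a"), sa(0.1, 0.2, id="b")])

    def test_breakdown_resistance(self):
        """40% invalid weight: median stays near truth while IVW drifts."""
        wm_est, ivw_est = [], []
        for s in range(60):
            delta = np.zeros(50)
            delta[:20] = 0.15  # 40 % of variants invalid
            stats = make_summary_stats(50, 0.3, seed=s, se_outcome=0.002, pleiotropy=delta)
            wm_est.append(weighted_median(stats, n_boot=50, seed=s).estimate)
            ivw_est.append(ivw(stats).estimate)
        assert abs(np.mean(wm_est) - 0.3) < 0.05
        assert np.mean(ivw_est) - 0.3 > 0.1

    def test_bootstrap_se_deterministic_given_seed(self):
        stats = make_summary_stats(10, 0.2, seed=1)
        a = weighted_median(stats, n_boot=100, seed=5)
        b = weighted_median(stats, n_boot=100, seed=5)
        assert a.se == b.se


class TestSteiger:
    def test_fisher_z_formula(self):
        res = steiger_direction(0.02, 10_000, 0.002, 10_000)
        z_expected = (np.arctanh(np.sqrt(0.02)) - np.arctanh(np.sqrt(0.002))) / np.sqrt(
            2.0 / 9997.0
        )
        assert res["z"] == pytest.approx(z_expected)
        assert res["orientation"] == "exposure->outcome"
        assert res["p"] < 0.001

    def test_equal_r2_gives_zero_z(self):
        res = steiger_direction(0.01, 5000, 0.01, 5000)
        assert res["z"] == pytest.approx(0.0)

    def test_reversed_orientation(self):
        assert steiger_direction(0.001, 5000, 0.02, 5000)["orientation"] == "outcome->exposure"

    def test_rejects_bad_r2(self):
        with pytest.raises(ValueError):
            steiger_direction(1.0, 100, 0.1, 100)


class TestCochranQ:
    def test_equal_estimates_give_zero_q(self):
        res = cochran_q_two_estimates(0.2, 0.05, 0.2, 0.08)
        assert res.q_statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_discordant_published_style_estimates(self):
        """Opposite-sign estimates with CI-derived SEs: Q ~= 20.2, p << 0.05."""
        se1 = (0.21 - 0.05) / 3.92
        se2 = (-0.09 + 0.35) / 3.92
        res = cochran_q_two_estimates(0.13, se1, -0.22, se2)
        assert res.q_statistic == pytest.approx(20.197, abs=0.01)
        assert res.p < 0.05

    def test_doubling_ses_quarters_q(self):
        a = cochran_q_two_estimates(0.1, 0.02, 0.3, 0.05)
        b = cochran_q_two_estimates(0.1, 0.04, 0.3, 0.10)
        assert b.q_statistic == pytest.approx(a.q_statistic / 4.0)


class TestExcludeNearby:
    def regions(self):
        return pd.DataFrame(
            {"chrom": [1], "start": [5_000_000], "end": [5_010_000], "name": ["GENE1"]}
        )

    def variants(self, pos, chrom=1):
        return pd.DataFrame(
            {"SNP": [f"s{i}" for i in range(len(pos))], "CHR": chrom, "POS": pos}
        )

    def test_variant_inside_span_excluded(self):
        kept, log = exclude_nearby_variants(self.variants([5_005_000]), self.regions(), 1e6)
        assert len(kept) == 0 and len(log) == 1

    def test_strict_boundary(self):
        # gene span ends at 5,010,000 (1-based); 1,000,000 bp away is dropped,
        # 1,000,001 bp away is retained
        kept, _ = exclude_nearby_variants(
            self.variants([6_010_000, 6_010_001]), self.regions(), 1_000_000
        )
        assert list(kept["SNP"]) == ["s1"]

    def test_empty_gene_list_is_identity(self):
        v = self.variants([1, 2, 3])
        kept, log = exclude_nearby_variants(v, self.regions().iloc[:0], 1e6)
        pd.testing.assert_frame_equal(kept, v)

    def test_other_chromosome_retained(self):
        kept, _ = exclude_nearby_variants(self.variants([5_005_000], chrom=2), self.regions(), 1e6)
        assert len(kept) == 1

    def test_chromosome_naming_mismatch_rejected(self):
        v = self.variants([5_005_000]).assign(CHR="chr1")
        with pytest.raises(ValueError, match="naming mismatch"):
            exclude_nearby_variants(v, self.regions(), 1e6)


class TestHarmonizeSummary:
    def stats(self, ea, oa, beta):
        return pd.DataFrame(
            {"SNP": ["v1"], "EA": [ea], "OA": [oa], "EAF": [0.3], "BETA": [beta], "SE": [0.01]}
        )

    def test_allele_swap_flips_outcome_sign(self):
        pairs = harmonize_summary(self.stats("A", "G", 0.1), self.stats("G", "A", 0.2))
        assert pairs[0].beta_outcome == pytest.approx(-0.2)

    def test_palindromic_near_half_dropped(self):
        exp = self.stats("A", "T", 0.1).assign(EAF=0.5)
        assert harmonize_summary(exp, self.stats("A", "T", 0.2)) == []

    def test_mismatched_alleles_dropped(self):
        assert harmonize_summary(self.stats("A", "G", 0.1), self.stats("A", "C", 0.2)) == []


class TestTwoStageLeastSquares:
    def _cohort(self, n1=4000, n2=800, beta=0.35, conf=0.5, seed=0):
        """Confounded exposure-outcome pair with a valid genetic score."""
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=(n1, 20)).astype(float)
        w = np.abs(rng.standard_normal(20))
        score = g @ w
        u = rng.standard_normal(n1)
        sz = (score - score.mean()) / score.std()
        x = np.sqrt(0.05) * sz + conf * u + np.sqrt(1 - 0.05 - conf**2) * rng.standard_normal(n1)
        y = beta * x + conf * u + rng.standard_normal(n1)
        d1 = pd.DataFrame({"score": score, "x": x, "y": y})
        return d1, d1.iloc[:n2]

    def test_outcome_identical_to_exposure_gives_unity(self):
        d1, d2 = self._cohort(beta=1.0)
        d1 = d1.assign(y=d1["x"])
        res = two_stage_least_squares(d1, "score", "x", d1, "y")
        assert res.estimate == pytest.approx(1.0, abs=1e-10)

    def test_just_identified_equals_wald_ratio(self):
        """With a single-variant score, 2SLS reduces to the Wald ratio."""
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 3000).astype(float)
        x = 0.3 * g + rng.standard_normal(3000)
        y = 0.5 * x + rng.standard_normal(3000)
        df = pd.DataFrame({"score": g, "x": x, "y": y})
        res = two_stage_least_squares(df, "score", "x", df, "y")
        bx = np.polyfit(g, x, 1)[0]
        by = np.polyfit(g, y, 1)[0]
        assert res.estimate == pytest.approx(by / bx, abs=1e-8)

    def test_confounding_immunity_vs_ols(self):
        """2SLS tracks the causal effect where OLS absorbs the confounder."""
        tsls_ests, ols_ests = [], []
        for s in range(40):
            d1, d2 = self._cohort(n2=2000, seed=s)
            res = two_stage_least_squares(d1, "score", "x", d2, "y")
            tsls_ests.append(res.estimate)
            ols_ests.append(np.polyfit(d2["x"], d2["y"], 1)[0])
        assert abs(np.mean(tsls_ests) - 0.35) < 0.05
        assert np.mean(ols_ests) - 0.35 > 0.15

    def test_panel_matches_per_protein_calls(self):
        d1, d2 = self._cohort()
        d2 = d2.assign(y2=d2["y"] * 0.5)
        panel = d2[["y", "y2"]]
        batch = tsls_panel(d1, "score", "x", d2, panel)
        single = two_stage_least_squares(d1, "score", "x", d2, "y")
        assert batch["y"].estimate == pytest.approx(single.estimate, abs=1e-12)
        assert batch["y"].se == pytest.approx(single.se, abs=1e-12)

    def test_weak_instrument_warns(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "score": rng.standard_normal(200),
                "x": rng.standard_normal(200),
                "y": rng.standard_normal(200),
            }
        )
        with pytest.warns(UserWarning, match="weak instrument"):
            two_stage_least_squares(df, "score", "x", df, "y")


class TestRescale:
    def _res(self, est=0.103, se=0.02):
        from adipomr.mr import _result

        return _result("tsls", est, se, n_variants=1)

    def test_per_unit_times_sd(self):
        out = rescale_per_exposure_sd(self._res(), 3.4)
        assert out.estimate == pytest.approx(0.3502)
        assert out.se == pytest.approx(0.068)

    def test_identity_at_sd_one(self):
        res = self._res()
        out = rescale_per_exposure_sd(res, 1.0)
        assert out.estimate == res.estimate and out.se == res.se

    def test_round_trip(self):
        res = self._res()
        back = rescale_per_exposure_sd(rescale_per_exposure_sd(res, 3.4), 1 / 3.4)
        assert back.estimate == pytest.approx(res.estimate, abs=1e-12)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            rescale_per_exposure_sd(self._res(), 0.0)
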