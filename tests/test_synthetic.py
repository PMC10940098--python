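"""Synthetic cohort generator: determinism, effect-null collapses, phantom
geometry and outcome calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from immunorad import (LatentContext, PhantomGeometry, SyntheticConfig,
                       cohort_table, generate_cohort, generate_phantom,
                       roc_auc, simulate_ihc_counts, simulate_outcomes)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(subtype_response_probs=(0.2, 1.4, 0.1, 0.3))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=1)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(rho=1.5)


class TestGenerateCohort:
    def test_same_seed_bitwise_identical(self):
        cfg = SyntheticConfig(n_patients=20, seed=9,
                              semi_axis_range_mm=(8, 10))
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(cohort_table(a), cohort_table(b))
        np.testing.assert_array_equal(a[0].volume.values, b[0].volume.values)

    def test_n_patients_respected(self):
        cfg = SyntheticConfig(n_patients=13, seed=1, include_images=False)
        assert len(generate_cohort(cfg)) == 13

    def test_rho_one_makes_latents_equal(self):
        cfg = SyntheticConfig(n_patients=50, seed=2, rho=1.0,
                              include_images=False)
        df = cohort_table(generate_cohort(cfg))
        np.testing.assert_allclose(df["lymphoid_latent"], df["myeloid_latent"])

    def test_latent_correlation_near_rho(self):
        cfg = SyntheticConfig(n_patients=2000, seed=3, rho=0.4,
                              include_images=False)
        df = cohort_table(generate_cohort(cfg))
        r = np.corrcoef(df["lymphoid_latent"], df["myeloid_latent"])[0, 1]
        assert abs(r - 0.4) < 0.07

    def test_null_effects_make_image_features_uninformative(self):
        """texture_effect = 0 and count_effect = 0: within-mask variance
        carries no information about the latent context (AUC ~ 0.5)."""
        cfg = SyntheticConfig(n_patients=400, seed=4, texture_effect=0.0,
                              count_effect=0.0, semi_axis_range_mm=(6, 9),
                              spacing_mm=(2.0, 2.0, 2.0))
        pts = generate_cohort(cfg)
        var = np.array([p.volume.values[p.tumor_mask.values].var()
                        for p in pts])
        label = np.array([p.latent.lymphoid > 0 for p in pts]).astype(int)
        assert abs(roc_auc(var, label).auc - 0.5) < 0.08

    def test_response_only_for_immunotherapy_patients(self):
        cfg = SyntheticConfig(n_patients=100, seed=5, include_images=False,
                              immunotherapy_fraction=0.4)
        df = cohort_table(generate_cohort(cfg))
        assert df.loc[df.immunotherapy == 0, "response"].isna().all()
        assert df.loc[df.immunotherapy == 1, "response"].notna().all()


class TestGeneratePhantom:
    GEOM = PhantomGeometry((12.0, 10.0, 10.0), (1.0, 1.0, 1.0))

    def test_zero_noise_gives_constant_interior(self):
        vol, mask = generate_phantom(LatentContext(0.0, 0.0), self.GEOM, 7,
                                     texture_effect=0.0, base_noise_sd=0.0)
        inside = vol.values[mask.values]
        assert np.ptp(inside) == 0.0

    def test_variance_monotone_in_lymphoid_latent(self):
        grid = [-1.0, -0.5, 0.0, 0.5, 1.0]
        variances = []
        for lat in grid:
            vol, mask = generate_phantom(LatentContext(lat, 0.0), self.GEOM,
                                         seed=11, texture_effect=4.0,
                                         base_noise_sd=10.0)
            variances.append(vol.values[mask.values].var())
        assert all(a < b for a, b in zip(variances, variances[1:]))

    def test_mask_volume_close_to_analytic_ellipsoid(self):
        geom = PhantomGeometry((14.0, 12.0, 11.0), (1.0, 1.0, 1.0))
        _, mask = generate_phantom(LatentContext(0, 0), geom, 1)
        analytic = 4 / 3 * np.pi * 14 * 12 * 11
        assert abs(mask.voxel_count * mask.voxel_volume - analytic) / analytic < 0.05

    def test_degenerate_geometry_rejected(self):
        geom = PhantomGeometry((2.0, 10.0, 10.0), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            generate_phantom(LatentContext(0, 0), geom, 1)

    def test_correlation_length_rises_with_myeloid_latent(self):
        """Higher myeloid latent -> smoother field -> higher lag-1
        autocorrelation inside the mask."""
        def lag1(myeloid):
            vol, mask = generate_phantom(LatentContext(0.0, myeloid),
                                         self.GEOM, seed=13,
                                         corr_effect_mm=0.8)
            v = vol.values - vol.values[mask.values].mean()
            prod = v[:, :, :-1] * v[:, :, 1:]
            both = mask.values[:, :, :-1] & mask.values[:, :, 1:]
            return prod[both].mean() / vol.values[mask.values].var()
        assert lag1(1.5) > lag1(-1.5)


class TestSimulateCounts:
    CFG = SyntheticConfig(n_patients=2, include_images=False)

    def test_reproducible_under_seed(self):
        lat = LatentContext(0.3, -0.4)
        assert (simulate_ihc_counts(lat, self.CFG, 5)
                == simulate_ihc_counts(lat, self.CFG, 5))

    def test_zero_effect_counts_independent_of_latent(self):
        cfg = SyntheticConfig(n_patients=2, count_effect=0.0,
                              include_images=False)
        rng = np.random.default_rng(17)
        lats = rng.normal(size=1000)
        counts = [simulate_ihc_counts(LatentContext(l, 0.0), cfg, 100 + i)
                  ["cd3_intra"] for i, l in enumerate(lats)]
        rho = spearmanr(lats, counts).statistic
        assert abs(rho) < 0.08

    def test_unit_effect_gives_strong_rank_correlation(self):
        cfg = SyntheticConfig(n_patients=2, count_effect=1.0,
                              include_images=False)
        rng = np.random.default_rng(19)
        lats = rng.normal(size=1000)
        counts = [simulate_ihc_counts(LatentContext(l, 0.0), cfg, 200 + i)
                  ["cd3_intra"] for i, l in enumerate(lats)]
        assert spearmanr(lats, counts).statistic > 0.5

    def test_overdispersion_beyond_poisson(self):
        cfg = SyntheticConfig(n_patients=2, count_effect=0.0,
                              count_dispersion=2.0, include_images=False)
        rng = np.random.default_rng(23)
        lat = LatentContext(0.0, 0.0)
        vals = np.array([simulate_ihc_counts(lat, cfg, int(s))["cd3_intra"]
                         for s in rng.integers(0, 2 ** 31, 800)])
        assert vals.var() > 1.5 * vals.mean()     # NB variance ~ mu + mu^2/2


class TestSimulateOutcomes:
    def test_zero_probability_subtype_has_no_responders(self):
        cfg = SyntheticConfig(n_patients=2, include_images=False,
                              subtype_response_probs=(0.0, 0.5, 0.1, 0.3))
        _, _, resp = simulate_outcomes(["low"] * 500, ["low"] * 500,
                                       [1] * 500, cfg, 3)
        assert not np.isin(resp, ["CR", "PR"]).any()

    def test_orr_concentrates_on_configured_probability(self):
        cfg = SyntheticConfig(n_patients=2, include_images=False)
        n = 2000
        for subtype, prob in zip(range(1, 5), cfg.subtype_response_probs):
            lis = ["high" if subtype in (2, 4) else "low"] * n
            mis = ["high" if subtype in (3, 4) else "low"] * n
            _, _, resp = simulate_outcomes(lis, mis, [subtype] * n, cfg,
                                           seed=subtype)
            orr = np.isin(resp, ["CR", "PR"]).mean()
            assert abs(orr - prob) <= 0.025

    def test_unknown_subtype_rejected(self):
        cfg = SyntheticConfig(n_patients=2, include_images=False)
        with pytest.raises(ValueError):
            simulate_outcomes(["low"], ["low"], [5], cfg, 1)

    def test_unit_hazard_ratios_remove_group_differences(self):
        """hr = 1 for both statuses: log-rank between status groups rejects
        at ~ the nominal 5% level."""
        from immunorad import logrank_test
        cfg = SyntheticConfig(n_patients=2, include_images=False,
                              hr_lis_high=1.0, hr_mis_high=1.0)
        rejections = 0
        reps = 100
        rng = np.random.default_rng(31)
        for _ in range(reps):
            n = 120
            lis = np.where(rng.uniform(size=n) < 0.5, "high", "low")
            t, e, _ = simulate_outcomes(lis, ["low"] * n,
                                        np.where(lis == "high", 2, 1),
                                        cfg, int(rng.integers(2 ** 31)))
            if logrank_test(t, e, lis)[2] < 0.05:
                rejections += 1
        assert 0.025 * reps - 3 <= rejections <= 0.075 * reps + 3

    def test_cox_recovers_configured_hazard_ratio(self):
        """Cox fit on simulated status data covers the true log HR."""
        from immunorad import cox_fit
        cfg = SyntheticConfig(n_patients=2, include_images=False,
                              hr_lis_high=0.25, hr_mis_high=3.0)
        rng = np.random.default_rng(37)
        n = 1000
        lis = np.where(rng.uniform(size=n) < 0.5, "high", "low")
        mis = np.where(rng.uniform(size=n) < 0.5, "high", "low")
        sub = np.array([{"lowlow": 1, "highlow": 2, "lowhigh": 3,
                         "highhigh": 4}[a + b] for a, b in zip(lis, mis)])
        t, e, _ = simulate_outcomes(lis, mis, sub, cfg, 41)
        X = pd.DataFrame({"lis_high": (lis == "high").astype(float),
                          "mis_high": (mis == "high").astype(float)})
        res = cox_fit(X, t, e)
        s = res.summary()
        assert s.loc["lis_high", "hr_ci_low"] <= 0.25 <= s.loc["lis_high", "hr_ci_high"]
        assert s.loc["mis_high", "hr_ci_low"] <= 3.0 <= s.loc["mis_high", "hr_ci_high"]
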