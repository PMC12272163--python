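"""Generator tests: cohort laws, the piecewise myelin relation, fibre
sampling mechanisms, rendering, and the model-based outcome simulator."""

import numpy as np
import pandas as pd
import pytest

import nervemorph as nm
from nervemorph.exceptions import ConfigurationError, DesignError, PackingError


class TestCohort:
    def test_age_marginals_over_replicates(self):
        # mean/SD of simulated ages match the configured 92.0 / 5.4
        ages = np.concatenate([
            nm.sample_cohort(nm.CohortConfig(seed=s))["age_at_death"].to_numpy()
            for s in range(30)])
        assert abs(ages.mean() - 92.0) < 0.15
        assert abs(ages.std() - 5.4) < 0.15

    def test_degenerate_age_sd_forbidden_but_tiny_sd_concentrates(self):
        cfg = nm.CohortConfig(n_participants=1, age_sd=1e-9, seed=0)
        age = nm.sample_cohort(cfg)["age_at_death"].iloc[0]
        assert age == pytest.approx(92.0, abs=1e-6)

    def test_female_fraction_binomial(self):
        n = 100_000
        cfg = nm.CohortConfig(n_participants=n, seed=5)
        frac = (nm.sample_cohort(cfg)["sex"] == "female").mean()
        se = np.sqrt(0.721 * 0.279 / n)
        assert abs(frac - 0.721) < 3 * se

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="p_female"):
            nm.CohortConfig(p_female=1.4).validate()
        with pytest.raises(ConfigurationError, match="age_sd"):
            nm.CohortConfig(age_sd=-1.0).validate()

    def test_seed_reproducibility_bit_identical(self, small_cfg):
        a = nm.sample_cohort_fibres(small_cfg)
        b = nm.sample_cohort_fibres(small_cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestPiecewiseMyelin:
    def test_origin_is_intercept(self):
        cfg = nm.CohortConfig()
        assert nm.piecewise_myelin_mean(0.0, cfg) == pytest.approx(
            cfg.myelin_intercept)

    def test_rise_between_breakpoints_is_half_um(self):
        # slope 0.125 over the 4 um between the breakpoints
        cfg = nm.CohortConfig()
        rise = nm.piecewise_myelin_mean(8.0, cfg) - nm.piecewise_myelin_mean(4.0, cfg)
        assert rise == pytest.approx(0.5)

    def test_plateau_above_second_breakpoint(self):
        cfg = nm.CohortConfig()
        assert nm.piecewise_myelin_mean(12.0, cfg) == pytest.approx(
            nm.piecewise_myelin_mean(9.0, cfg))

    def test_continuity_at_breakpoints(self):
        cfg = nm.CohortConfig()
        for b in cfg.myelin_breakpoints:
            lo = nm.piecewise_myelin_mean(b - 1e-9, cfg)
            hi = nm.piecewise_myelin_mean(b + 1e-9, cfg)
            assert hi == pytest.approx(lo, abs=1e-6)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            nm.piecewise_myelin_mean(-0.1)


class TestFibreSampling:
    def test_null_shrinkage_decorrelates_age(self):
        # with tail_shrink_per_year=0 the person-mean diameter carries no
        # age signal (person scale still varies, so use Spearman on means)
        cfg = nm.CohortConfig(n_participants=80, tail_shrink_per_year=0.0,
                              person_scale_logsd=0.0,
                              fibre_count_logmean=float(np.log(200.0)),
                              fibre_count_logsd=0.2, fibre_count_min=50,
                              fibre_count_max=500, seed=77)
        participants, fibres = nm.sample_cohort_fibres(cfg)
        means = fibres.groupby("participant_id")["axon_diameter_um"].mean()
        merged = participants.set_index("participant_id").join(means)
        rho, _ = nm.spearman(merged["age_at_death"], merged["axon_diameter_um"])
        assert abs(rho) < 0.25

    def test_pooled_axon_mean_near_target(self, default_cohort):
        _, _, kept = default_cohort
        assert kept["axon_diameter_um"].mean() == pytest.approx(2.0, abs=0.1)

    def test_older_participants_have_shrunken_tails(self):
        cfg = nm.CohortConfig(seed=2)
        parts = nm.sample_cohort(cfg).iloc[:1].copy()
        parts["person_log_scale"] = 0.0
        parts["n_fibres_true"] = 20_000
        young, old = parts.copy(), parts.copy()
        young["age_at_death"] = 85.0
        old["age_at_death"] = 100.0
        fy = nm.sample_fibres(young.iloc[0], cfg, np.random.default_rng(1))
        fo = nm.sample_fibres(old.iloc[0], cfg, np.random.default_rng(1))
        qy = np.quantile(fy["axon_diameter_um"], 0.95)
        qo = np.quantile(fo["axon_diameter_um"], 0.95)
        expected_ratio = np.exp(-cfg.tail_shrink_per_year * 15.0)
        assert qo / qy == pytest.approx(expected_ratio, rel=0.03)

    def test_unimodal_diameter_histogram(self, default_cohort):
        # smoothed histogram of fibre diameter has a single interior peak
        _, _, kept = default_cohort
        h, _ = np.histogram(kept["fibre_diameter_um"], bins=40, range=(0, 16))
        sm = np.convolve(h, np.ones(3) / 3, mode="valid")
        peaks = [i for i in range(1, len(sm) - 1)
                 if sm[i] > sm[i - 1] and sm[i] >= sm[i + 1]]
        assert len(peaks) == 1


class TestRenderSection:
    def test_single_fibre_pixel_area_oracle(self):
        fib = pd.DataFrame({"participant_id": "P1",
                            "axon_diameter_um": [4.0],
                            "myelin_thickness_um": [1.0]})
        section, _ = nm.render_section(fib, 0.05, (12.0, 12.0),
                                       np.random.default_rng(3))
        axon_area = (section.axon_mask > 0).sum() * 0.05**2
        assert axon_area == pytest.approx(np.pi * 2.0**2, rel=0.02)

    def test_empty_fibre_list(self):
        empty = pd.DataFrame(columns=["participant_id", "axon_diameter_um",
                                      "myelin_thickness_um"])
        section, _ = nm.render_section(empty, 0.1, (20.0, 20.0),
                                       np.random.default_rng(0))
        assert section.axon_mask.sum() == 0
        assert section.analysed_area_mm2 > 0

    def test_density_target_placement_count(self):
        # 0.2 mm^2 at ~4993/mm^2 -> ~999 small fibres must fit
        rng = np.random.default_rng(9)
        n = 999
        fib = pd.DataFrame({"participant_id": "P1",
                            "axon_diameter_um": np.full(n, 1.0),
                            "myelin_thickness_um": np.full(n, 0.3)})
        field = np.sqrt(0.2) * 1000.0  # um
        section, placed = nm.render_section(fib, 0.5, (field, field), rng,
                                            margin_um=0.2)
        assert placed["centre_x_um"].notna().all()
        dens = nm.fibre_density(n, section.analysed_area_mm2)
        assert dens.density_per_mm2 == pytest.approx(4993.4, rel=0.01)

    def test_packing_error_reports_achieved(self):
        fib = pd.DataFrame({"participant_id": "P1",
                            "axon_diameter_um": [8.0] * 20,
                            "myelin_thickness_um": [2.0] * 20})
        with pytest.raises(PackingError) as exc:
            nm.render_section(fib, 0.2, (30.0, 30.0),
                              np.random.default_rng(0), max_attempts=50)
        assert 0 <= exc.value.achieved < 20

    def test_masks_disjoint_and_area_identity(self, three_fibre_section):
        section, _ = three_fibre_section
        assert not np.any((section.axon_mask > 0) & (section.myelin_mask > 0))
        npx = section.image.size
        assert section.analysed_area_mm2 == pytest.approx(
            npx * section.pixel_size_um**2 / 1e6)


class TestSimulateFromFittedModel:
    def test_all_zero_coefficients_give_standard_noise(self):
        rng = np.random.default_rng(0)
        n = 20_000
        X = np.ones((n, 1))
        Z = np.ones((n, 1))
        grp = np.arange(n) % 50
        y = nm.simulate_from_fitted_model(X, [0.0], Z, [0.0], grp, 0.0, rng)
        assert abs(y.mean()) < 0.02
        assert y.std() == pytest.approx(1.0, abs=0.02)

    def test_between_group_variance_matches_tau(self):
        # tau=2 -> between-participant variance ~ 4 (ANOVA decomposition)
        rng = np.random.default_rng(4)
        G, m = 600, 40
        grp = np.repeat(np.arange(G), m)
        n = G * m
        y = nm.simulate_from_fitted_model(
            np.ones((n, 1)), [0.0], np.ones((n, 1)), [np.log(0.5)],
            grp, 2.0, rng)
        gm = y.reshape(G, m).mean(axis=1)
        between = gm.var(ddof=1) - 0.25 / m
        assert between == pytest.approx(4.0, rel=0.15)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(DesignError):
            nm.simulate_from_fitted_model(
                np.ones((10, 2)), [1.0], np.ones((10, 1)), [0.0],
                np.zeros(10), 1.0, np.random.default_rng(0))
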