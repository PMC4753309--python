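"""Synthetic field-data generators: exactness, reproducibility, round-trips."""

import numpy as np
import pytest

from ferromat.config import NoiseSpec, SiteConfig
from ferromat.kinetics import fit_exponential
from ferromat.synthetic import (
    gen_accretion_series,
    gen_community_table,
    gen_count_fields,
    gen_dna_series,
    gen_extraction_table,
    gen_microprofile,
)
from ferromat.oxygen import ReactionDiffusionModel, dimensionless_profile


def custom_site(**overrides) -> SiteConfig:
    base = dict(
        site_name="osp", fe_k=0.05, fe_x0=0.5, dna_r=0.028, dna_x0=2.0,
        coloniz_rate_rod=3.7e6, coloniz_rate_coccus=9.2e5, o2_bulk=55.0,
        profile_params=(0.0955, 4.5e-5, 0.608), as_fe_ratio=0.5,
        p_fe_ratio=0.01, w_fe_ratio=0.002,
    )
    base.update(overrides)
    return SiteConfig(**base)


class TestAccretionSeries:
    def test_initial_value(self):
        cfg = custom_site(fe_k=0.05, fe_x0=0.5)
        series = gen_accretion_series(cfg, [0.0, 1.0])
        assert series.x[0] == pytest.approx(0.5)

    def test_direct_exponential_evaluation(self):
        cfg = custom_site(fe_k=0.05, fe_x0=0.5)
        series = gen_accretion_series(cfg, [0.0, 70.0])
        assert series.x[-1] == pytest.approx(0.5 * np.exp(3.5), rel=1e-12)  # 16.56

    def test_noiseless_loglinear_slope_equals_configured_k(self, osp, incubation_times):
        series = gen_accretion_series(osp, incubation_times)
        slope = np.polyfit(series.t, np.log(series.x), 1)[0]
        assert slope == pytest.approx(osp.fe_k, rel=1e-9)

    def test_censoring_below_detection_limit(self):
        cfg = custom_site(fe_x0=0.01, fe_k=0.05)
        series = gen_accretion_series(cfg, [0.0, 7.0, 70.0], detection_limit=0.05)
        assert series.censored[0]
        assert not series.censored[-1]
        assert series.x[0] == 0.05  # reported at the limit

    def test_seeded_noise_is_reproducible(self, osp, incubation_times):
        a = gen_accretion_series(osp, incubation_times, NoiseSpec("lognormal", 0.2, 42))
        b = gen_accretion_series(osp, incubation_times, NoiseSpec("lognormal", 0.2, 42))
        assert (a.x == b.x).all()
        c = gen_accretion_series(osp, incubation_times, NoiseSpec("lognormal", 0.2, 43))
        assert (a.x != c.x).any()

    def test_lognormal_noise_has_unit_mean_factor(self, osp):
        series = gen_accretion_series(osp, [10.0], NoiseSpec("lognormal", 0.2, 0))
        draws = [
            gen_accretion_series(osp, [10.0], NoiseSpec("lognormal", 0.2, s)).x[0]
            for s in range(500)
        ]
        mean_true = osp.fe_x0 * np.exp(osp.fe_k * 10.0)
        assert np.mean(draws) == pytest.approx(mean_true, rel=0.05)

    @pytest.mark.parametrize("bad_times", [[], [-1.0, 2.0], [3.0, 3.0]])
    def test_invalid_times_raise(self, osp, bad_times):
        with pytest.raises(ValueError):
            gen_accretion_series(osp, bad_times)


class TestDnaSeries:
    def test_zero_rate_is_flat(self):
        cfg = custom_site(dna_r=0.0, dna_x0=10.0)
        series = gen_dna_series(cfg, [0.0, 25.0, 100.0])
        assert (series.x == 10.0).all()

    def test_direct_evaluation(self):
        cfg = custom_site(dna_r=0.043, dna_x0=1.0)
        series = gen_dna_series(cfg, [0.0, 50.0])
        assert series.x[-1] == pytest.approx(np.exp(2.15), rel=1e-12)  # 8.58

    def test_noiseless_fit_round_trip(self, beowulf, incubation_times):
        fit = fit_exponential(gen_dna_series(beowulf, incubation_times))
        assert fit.k == pytest.approx(beowulf.dna_r, rel=1e-6)
        assert fit.x0 == pytest.approx(beowulf.dna_x0, rel=1e-6)


class TestMicroprofile:
    def test_interface_concentration_is_bulk(self, osp):
        model = osp.reaction_diffusion_model()
        prof = gen_microprofile(model, [0.0, 100.0])
        assert prof.C[0] == pytest.approx(model.C0)

    def test_first_order_bottom_value(self):
        model = ReactionDiffusionModel(kinetic_order="first", k1=4.5e-5 * 4 / 0.01,
                                       D_e=4.5e-5, L_f=0.1, C0=55.0)  # phi = 2
        prof = gen_microprofile(model, [0.0, 1000.0])
        assert prof.C[-1] == pytest.approx(55 / np.cosh(2), rel=1e-9)  # 14.62 uM

    def test_zero_order_anoxic_bottom(self):
        # phi^2 = 2: quadratic hits exactly zero at the slab bottom
        model = ReactionDiffusionModel(kinetic_order="zero", k1=2 * 4.5e-5 / 0.01,
                                       D_e=4.5e-5, L_f=0.1, C0=55.0)
        prof = gen_microprofile(model, [0.0, 500.0, 1000.0])
        assert prof.C[-1] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_clipped_at_zero(self, osp):
        model = osp.reaction_diffusion_model()
        z = np.arange(0.0, model.L_f * 1e4, 50.0)
        prof = gen_microprofile(model, z, NoiseSpec("gaussian", 0.1, 3))
        assert (prof.C >= 0).all()

    def test_grid_beyond_slab_raises(self, osp):
        model = osp.reaction_diffusion_model()
        with pytest.raises(ValueError, match="L_f"):
            gen_microprofile(model, [0.0, model.L_f * 1e4 * 1.5])


class TestCountFields:
    def test_zero_rate_gives_all_zeros(self):
        obs = gen_count_fields(0.0, [4, 7, 14])
        assert all(o.counts["rod"] == 0 for o in obs)

    def test_deterministic_expected_count(self):
        obs = gen_count_fields(3.7e6, [7.0], field_area=1e-5, n_fields=1)
        assert obs[0].counts["rod"] == 259

    def test_poisson_mean_variance_ratio(self):
        obs = gen_count_fields(3.7e6, [7.0], field_area=1e-5, n_fields=10000,
                               noise=NoiseSpec("poisson", 0.0, 3))
        counts = np.array([o.counts["rod"] for o in obs])
        assert counts.mean() / counts.var() == pytest.approx(1.0, rel=0.05)

    def test_negative_rate_raises(self):
        with pytest.raises(ValueError):
            gen_count_fields(-1.0, [7.0])


class TestCommunityTable:
    def test_rod_taxon_starts_dominant(self, osp):
        t = gen_community_table(osp, [4.0])
        assert t.values.loc["Hydrogenobaculum"].iloc[0] == pytest.approx(0.85)

    def test_linear_decline_reaches_printed_value(self, osp):
        t = gen_community_table(osp, [70.0])
        assert t.values.loc["Hydrogenobaculum"].iloc[0] == pytest.approx(0.19)  # 0.85-0.66

    def test_rows_sum_to_one(self, osp):
        t = gen_community_table(osp, [4, 15, 30, 55, 70],
                                NoiseSpec("dirichlet", 200.0, 9))
        assert np.allclose(t.values.sum(axis=0), 1.0, atol=1e-9)

    def test_feox_taxon_constant(self, osp):
        t = gen_community_table(osp, [4, 30, 70])
        row = t.values.loc["Metallosphaera yellowstonensis"]
        assert np.allclose(row, 0.15, atol=1e-12)

    def test_heterotrophs_rise_over_time(self, osp):
        t = gen_community_table(osp, [4, 70])
        het = t.values.drop(index=["Hydrogenobaculum", "Metallosphaera yellowstonensis"])
        assert het.sum(axis=0).iloc[0] < 1e-9
        assert het.sum(axis=0).iloc[-1] == pytest.approx(0.66, abs=1e-9)

    def test_dirichlet_reproducible_with_seed(self, osp):
        a = gen_community_table(osp, [4, 30], NoiseSpec("dirichlet", 200.0, 5))
        b = gen_community_table(osp, [4, 30], NoiseSpec("dirichlet", 200.0, 5))
        assert (a.values.values == b.values.values).all()

    def test_sample_ids_encode_site_and_day(self, osp):
        t = gen_community_table(osp, [4.0, 70.0])
        assert t.samples == ["osp_day04", "osp_day70"]

    def test_out_of_range_times_raise(self, osp):
        with pytest.raises(ValueError):
            gen_community_table(osp, [4.0, 150.0])


class TestExtractionTable:
    def test_equal_molar_ratio_concentration(self):
        cfg = custom_site(as_fe_ratio=1.0)
        recs = gen_extraction_table(cfg, [70.0])
        fe, as_ = recs[0].concentrations["Fe"], recs[0].concentrations["As"]
        assert as_ / fe == pytest.approx(74.922 / 55.845, rel=1e-12)

    def test_tungsten_concentration_from_ratio(self):
        # 0.002 mol W per mol Fe at 55.85 mg/L Fe -> 0.368 mg/L W
        cfg = custom_site(as_fe_ratio=0.5)
        recs = gen_extraction_table(cfg, [1.0])
        fe = recs[0].concentrations["Fe"]
        w = recs[0].concentrations["W"]
        assert w == pytest.approx(0.002 * fe / 55.845 * 183.84, rel=1e-12)

    def test_fe_tracks_accretion_series(self, beowulf):
        times = [14.0, 28.0, 70.0]
        recs = gen_extraction_table(beowulf, times)
        series = gen_accretion_series(beowulf, times, detection_limit=0.0)
        for rec, loading in zip(recs, series.x):
            expected = loading * beowulf.slide_area_cm2 * 55.845 / 1000 / beowulf.extraction_volume_l
            assert rec.concentrations["Fe"] == pytest.approx(expected, rel=1e-12)
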