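"""Generator properties: ratio preservation, gel rendering, gas and culture tables."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcrquant import METHANOGEN, PROTOZOA
from cpcrquant.gas import gas_model
from cpcrquant.synthetic import (
    SimConfig,
    render_gel_lane,
    simulate_competitive_pcr,
    simulate_culture_dataset,
    simulate_dilution_series,
    simulate_gas_curve,
    simulate_gas_experiment,
)


class TestCompetitivePcr:
    def test_symmetric_templates_give_molar_ratio_one(self, noiseless_cfg):
        m_t, m_c = simulate_competitive_pcr(1e5, 1e5, METHANOGEN, noiseless_cfg)
        # molar ratio = (mass/length) ratio
        assert (m_t / 296) / (m_c / 196) == pytest.approx(1.0, rel=1e-12)

    @given(
        ratio_log10=st.floats(-4, 4),
        target=st.floats(1e2, 1e8),
        cycles=st.integers(10, 40),
        eff=st.floats(0.3, 1.0),
        plateau=st.floats(1e9, 1e14),
    )
    @settings(max_examples=200, derandomize=True)
    def test_molar_ratio_preserved_for_any_plateau(self, ratio_log10, target, cycles, eff, plateau):
        cfg = SimConfig(
            seed=0, pcr_cycles=cycles, pcr_efficiency=eff, plateau_total_copies=plateau
        )
        comp = target / 10.0**ratio_log10
        m_t, m_c = simulate_competitive_pcr(target, comp, METHANOGEN, cfg)
        assert (m_t / 296) / (m_c / 196) == pytest.approx(target / comp, rel=1e-9)

    def test_hand_derived_product_mass(self):
        # 1e4 copies of 296 bp, 25 cycles at e=1, plateau off:
        # mass = 1e4 * 2^25 * 296 * 650 / 6.022e23 * 1e9 ng
        cfg = SimConfig(seed=0, pcr_cycles=25, pcr_efficiency=1.0, plateau_total_copies=0)
        m_t, _ = simulate_competitive_pcr(1e4, 0.0, METHANOGEN, cfg)
        expected = 1e4 * 2**25 * 296 * 650 / 6.022e23 * 1e9
        assert m_t == pytest.approx(expected, rel=1e-12)

    def test_zero_and_negative_templates(self, noiseless_cfg):
        assert simulate_competitive_pcr(0.0, 0.0, METHANOGEN, noiseless_cfg) == (0.0, 0.0)
        with pytest.raises(ValueError):
            simulate_competitive_pcr(-1.0, 1e3, METHANOGEN, noiseless_cfg)


class TestGelRendering:
    def test_area_conserved_at_zero_noise(self):
        cfg = SimConfig(
            seed=0, intensity_noise_cv=0.0, profile_noise_sd=0.0, baseline_height=0.0
        )
        profile, truth = render_gel_lane([(METHANOGEN.target, 7.5)], cfg)
        integrated = np.trapezoid(profile.intensities, profile.positions)
        assert integrated == pytest.approx(truth["areas"][0], rel=0.01)
        assert truth["areas"][0] == pytest.approx(cfg.gel_gain * 7.5, rel=1e-12)

    def test_shorter_fragment_migrates_farther(self, noiseless_cfg):
        _, truth = render_gel_lane(
            [(METHANOGEN.target, 1.0), (METHANOGEN.competitor, 1.0)], noiseless_cfg
        )
        assert truth["centers"][1] > truth["centers"][0]

    def test_equal_masses_give_equal_areas(self, noiseless_cfg):
        # signal tracks mass (ethidium stains base pairs), not molarity
        _, truth = render_gel_lane(
            [(METHANOGEN.target, 3.0), (METHANOGEN.competitor, 3.0)], noiseless_cfg
        )
        assert truth["areas"][0] == pytest.approx(truth["areas"][1], rel=1e-12)

    def test_overlap_flag_for_close_bands(self, noiseless_cfg):
        from cpcrquant.assays import AmpliconSpec

        a = AmpliconSpec("a", 300, "target")
        b = AmpliconSpec("b", 295, "competitor")
        _, truth = render_gel_lane([(a, 1.0), (b, 1.0)], noiseless_cfg)
        assert truth["overlap"]


class TestDilutionSeries:
    def test_exactly_one_near_equimolar_dilution(self, noiseless_cfg):
        series = simulate_dilution_series(1e5, METHANOGEN, noiseless_cfg)
        molar_ratio = (series.points["target_intensity"] / 296) / (
            series.points["competitor_intensity"] / 196
        )
        near_unity = (molar_ratio > 1 / 10) & (molar_ratio < 10)
        assert near_unity.sum() == 1

    def test_seed_fixes_series_bitwise(self, noisy_cfg):
        a = simulate_dilution_series(1e5, METHANOGEN, noisy_cfg)
        b = simulate_dilution_series(1e5, METHANOGEN, noisy_cfg)
        pd.testing.assert_frame_equal(a.points, b.points)
        for pa, pb in zip(a.profiles, b.profiles):
            np.testing.assert_array_equal(pa.intensities, pb.intensities)

    def test_emits_profiles_and_truth(self, noisy_cfg):
        series = simulate_dilution_series(1e5, PROTOZOA, noisy_cfg)
        assert len(series.profiles) == noisy_cfg.n_dilutions
        assert series.truth.true_target_copies == 1e5
        frame = series.profiles_frame()
        assert set(frame.columns) == {"lane_id", "position", "intensity"}


class TestGasGeneration:
    def test_noiseless_curve_is_exact_model(self, noiseless_cfg):
        curve, truth = simulate_gas_curve(100.0, 0.1, noiseless_cfg)
        np.testing.assert_allclose(curve.volumes, gas_model(curve.times, 100.0, 0.1))
        assert truth.true_V == 100.0

    def test_half_volume_at_half_time(self, noiseless_cfg):
        # V=105.8, k=0.0625: y(ln2/k = 11.09 h) = V/2 = 52.9
        t_half = math.log(2) / 0.0625
        assert t_half == pytest.approx(11.09, abs=0.005)
        assert gas_model(t_half, 105.8, 0.0625) == pytest.approx(52.9, abs=1e-9)

    def test_asymptote(self, noiseless_cfg):
        assert gas_model(1e6, 100.0, 0.1) == pytest.approx(100.0, rel=1e-12)

    def test_rejects_nonpositive_parameters(self, noiseless_cfg):
        with pytest.raises(ValueError):
            simulate_gas_curve(-1.0, 0.1, noiseless_cfg)
        with pytest.raises(ValueError):
            simulate_gas_curve(100.0, 0.0, noiseless_cfg)

    def test_experiment_has_blanks_and_substrate(self, noisy_cfg):
        df, truth = simulate_gas_experiment({"s1": (120.0, 0.08)}, noisy_cfg)
        assert df["is_blank"].sum() == 3 * len(noisy_cfg.time_grid)
        assert truth["syringes"]["s1"]["V"] == 120.0


class TestCultureDataset:
    def test_all_zero_effects_give_constant_cells(self):
        cfg = SimConfig(seed=0, gas_noise_sd=0.0)
        responses = {"resp": {"mu": 5.0, "species": {}, "treatment": {}, "sd": 0.0}}
        table, _ = simulate_culture_dataset(cfg, responses=responses)
        assert (table["resp"] == 5.0).all()
        assert len(table) == 2 * 3 * 3 * 3

    def test_species_shift_recovered_at_large_n(self):
        cfg = SimConfig(seed=3)
        responses = {
            "pop_log10": {
                "mu": 5.0,
                "species": {"goat": 0.35, "camel": -0.35},
                "treatment": {},
                "sd": 0.25,
            }
        }
        table, _ = simulate_culture_dataset(cfg, responses=responses, reps_per_cell=23)
        means = table.groupby("species")["pop_log10"].mean()
        diff = means["goat"] - means["camel"]
        n = (table["species"] == "goat").sum()
        sem_diff = 0.25 * math.sqrt(2.0 / n)
        assert abs(diff - 0.7) <= 3 * sem_diff

    def test_seed_fixes_table(self, noisy_cfg):
        a, _ = simulate_culture_dataset(noisy_cfg)
        b, _ = simulate_culture_dataset(noisy_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_masses_consistent_with_degradability(self, noisy_cfg):
        table, _ = simulate_culture_dataset(noisy_cfg)
        assert (table["residue_mg"] <= table["substrate_in_mg"]).all()
        assert (table["ndf_residue_mg"] <= table["ndf_in_mg"]).all()
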