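"""Copy-number arithmetic and equivalence-point calibration."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpcrquant import METHANOGEN, PROTOZOA
from cpcrquant.exceptions import InsufficientDataError, InvalidTitrationError
from cpcrquant.quantify import (
    AVOGADRO,
    DilutionPoint,
    build_calibration,
    copies_from_mass,
    copies_per_ml,
    enumerate_population,
    mass_from_copies,
)
from cpcrquant.synthetic import SimConfig, simulate_dilution_series


class TestMassCopiesFormula:
    def test_one_ng_of_296bp(self):
        # direct evaluation of copies = ng * N_A / (L * 1e9 * 650)
        expected = 6.022e23 / (296 * 1e9 * 650)
        assert copies_from_mass(1.0, 296) == pytest.approx(expected, rel=1e-12)
        assert copies_from_mass(1.0, 296) == pytest.approx(3.129e9, rel=1e-3)

    def test_zero_and_errors(self):
        assert copies_from_mass(0.0, 196) == 0.0
        assert mass_from_copies(0.0, 196) == 0.0
        with pytest.raises(ValueError):
            copies_from_mass(1.0, 0)
        with pytest.raises(ValueError):
            copies_from_mass(-1.0, 296)
        with pytest.raises(ValueError):
            mass_from_copies(-5.0, 296)

    def test_inverse_of_printed_example(self):
        assert mass_from_copies(6.022e23 / (296 * 1e9 * 650), 296) == pytest.approx(1.0, rel=1e-12)

    @given(
        amount=st.floats(1e-6, 1e3),
        length=st.integers(50, 5000),
        c=st.floats(0.1, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_linearity_length_scaling_and_roundtrip(self, amount, length, c):
        n = copies_from_mass(amount, length)
        # linear in mass
        assert copies_from_mass(c * amount, length) == pytest.approx(c * n, rel=1e-12)
        # inversely proportional to length
        assert copies_from_mass(amount, 2 * length) == pytest.approx(n / 2, rel=1e-12)
        # exact round trip
        assert copies_from_mass(mass_from_copies(n, length), length) == pytest.approx(n, rel=1e-12)


class TestCalibration:
    @staticmethod
    def exact_line_points():
        # y = log10 ratio of 1, 0, -1 at x = 4, 5, 6
        return [
            DilutionPoint(1e4, 10.0, 1.0),
            DilutionPoint(1e5, 1.0, 1.0),
            DilutionPoint(1e6, 0.1, 1.0),
        ]

    def test_exact_line(self):
        fit = build_calibration(self.exact_line_points(), mode="raw")
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-12)
        assert fit.equivalence_copies == pytest.approx(1e5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.extrapolated

    def test_noiseless_molar_series_is_ideal(self, noiseless_cfg):
        series = simulate_dilution_series(1e5, METHANOGEN, noiseless_cfg)
        fit = build_calibration(series.points, mode="molar", pair=METHANOGEN)
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)
        assert fit.equivalence_copies == pytest.approx(1e5, rel=1e-9)

    def test_raw_mode_bias_is_exactly_the_length_ratio(self, noiseless_cfg):
        # intensity tracks mass, so the raw ratio over-weights the longer
        # target by L_t/L_c; the molar mode removes exactly that factor
        for pair in (METHANOGEN, PROTOZOA):
            series = simulate_dilution_series(1e5, pair, noiseless_cfg)
            raw = build_calibration(series.points, mode="raw", pair=pair)
            molar = build_calibration(series.points, mode="molar", pair=pair)
            assert raw.equivalence_copies / molar.equivalence_copies == pytest.approx(
                pair.length_ratio, rel=1e-9
            )
            assert math.log10(pair.length_ratio) <= 0.19

    def test_unusable_points_are_dropped(self):
        pts = self.exact_line_points() + [DilutionPoint(1e7, 0.0, 1.0)]
        fit = build_calibration(pts, mode="raw")
        assert fit.n_points == 3

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            build_calibration(self.exact_line_points()[:2], mode="raw")

    def test_flat_ratio_is_invalid_titration(self):
        pts = [DilutionPoint(10.0**x, 2.0, 1.0) for x in range(3, 8)]
        with pytest.raises(InvalidTitrationError):
            build_calibration(pts, mode="raw")

    def test_equivalence_monotone_in_target_copies(self, noiseless_cfg):
        eqs = []
        for truth in (1e4, 1e5, 1e6):
            series = simulate_dilution_series(truth, METHANOGEN, noiseless_cfg)
            eqs.append(
                build_calibration(series.points, mode="molar", pair=METHANOGEN).equivalence_copies
            )
        assert eqs[0] < eqs[1] < eqs[2]

    def test_extrapolation_flagged(self):
        # line crosses zero below the sampled dilution range
        pts = [DilutionPoint(10.0**x, 10.0 ** (3 - x), 1.0) for x in (4, 5, 6)]
        fit = build_calibration(pts, mode="raw")
        assert fit.extrapolated


class TestCopiesPerMl:
    def _fit(self, eq=1e5):
        return build_calibration(
            [
                DilutionPoint(eq / 10, 10.0, 1.0),
                DilutionPoint(eq, 1.0, 1.0),
                DilutionPoint(eq * 10, 0.1, 1.0),
            ],
            mode="raw",
        )

    def test_unit_chain(self):
        est = copies_per_ml(self._fit(), 0.001, [1.0], taxon="methanogen")
        assert est.log10_copies_per_ml == pytest.approx(8.0, abs=1e-9)

    def test_tenfold_chain(self):
        est = copies_per_ml(self._fit(), 0.001, [10.0])
        assert est.log10_copies_per_ml == pytest.approx(9.0, abs=1e-9)

    def test_chain_is_mandatory(self):
        with pytest.raises(ValueError):
            copies_per_ml(self._fit(), 0.001, [])

    def test_provenance_records_every_factor(self):
        est = copies_per_ml(self._fit(), 0.001, [10.0, 0.5])
        factors = [p["factor"] for p in est.provenance]
        assert factors == [
            "equivalence_copies_per_reaction",
            "per_template_volume_ml",
            "chain_0",
            "chain_1",
        ]


class TestEnumeratePopulation:
    @pytest.mark.parametrize("pair", [METHANOGEN, PROTOZOA], ids=lambda p: p.taxon)
    def test_full_profile_path_recovers_truth(self, pair):
        # truth 5.3 log10/mL, 1 uL template from a 10x-concentrated extract
        true_log10 = 5.3
        cfg = SimConfig(seed=7, competitor_stock=1e7, intensity_noise_cv=0.1)
        reaction_copies = 10.0**true_log10 * 0.001 / 0.1
        series = simulate_dilution_series(reaction_copies, pair, cfg)
        est, fit, table = enumerate_population(
            series.profiles,
            series.points[["lane_id", "competitor_copies"]],
            pair,
            template_volume_ml=0.001,
            extract_dilution_chain=[0.1],
            mode="molar",
        )
        assert abs(est.log10_copies_per_ml - true_log10) <= 0.1
        assert fit.slope < -0.5
        assert set(table.columns) >= {"lane_id", "usable", "log10_intensity_ratio"}

    def test_same_seed_same_estimate(self):
        cfg = SimConfig(seed=11, competitor_stock=1e7)
        out = []
        for _ in range(2):
            series = simulate_dilution_series(2000.0, METHANOGEN, cfg)
            est, _, _ = enumerate_population(
                series.profiles,
                series.points[["lane_id", "competitor_copies"]],
                METHANOGEN,
                template_volume_ml=0.001,
                extract_dilution_chain=[1.0],
                mode="molar",
            )
            out.append(est.log10_copies_per_ml)
        assert out[0] == out[1]

    def test_intensity_table_input(self, noiseless_cfg):
        series = simulate_dilution_series(1e5, METHANOGEN, noiseless_cfg)
        est, _, _ = enumerate_population(
            series.points[["lane_id", "target_intensity", "competitor_intensity"]],
            series.points[["lane_id", "competitor_copies"]],
            METHANOGEN,
            template_volume_ml=0.001,
            extract_dilution_chain=[1.0],
            mode="molar",
        )
        assert est.log10_copies_per_ml == pytest.approx(8.0, abs=1e-6)
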