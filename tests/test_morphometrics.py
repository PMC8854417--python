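import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyvis.io_fixtures import SpecimenMeasurements
from flyvis.morphometrics import (
    aggregate_species,
    body_mass,
    derive_specimen,
    eye_area,
    interommatidial_angle,
    ommatidia_number,
    ommatidium_area,
    relative_trait,
)

positive = st.floats(min_value=1.0, max_value=1e4)


class TestEyeArea:
    def test_equal_chords_give_hemisphere(self):
        # all three chords equal L collapses the shell to a hemisphere 2*pi*L^2
        assert eye_area(100, 100, 100) == pytest.approx(2 * math.pi * 100**2, rel=1e-15)
        assert eye_area(100, 100, 100) == pytest.approx(62831.85, abs=0.01)

    @settings(max_examples=200, deadline=None)
    @given(positive, positive, positive)
    def test_long_form_equals_simplified_form(self, w, h, wl):
        L = (h + wl) / 2.0
        assert eye_area(w, h, wl) == pytest.approx(
            math.pi * (L**2 + w**2), rel=1e-12
        )

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError):
            eye_area(0, 100, 100)


class TestOmmatidiumArea:
    def test_unit_radius(self):
        assert ommatidium_area(2.0) == pytest.approx(2.598, rel=1e-15)

    def test_close_to_exact_hexagon_area(self):
        exact = 1.5 * math.sqrt(3)  # unit-circumradius regular hexagon
        rel = abs(ommatidium_area(2.0) - exact) / exact
        assert 0 < rel < 5e-5  # the fixed 2.598 truncates 3*sqrt(3)/2

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            ommatidium_area(0.0)


class TestOmmatidiaNumber:
    def test_study_species_back_calculation(self):
        # species-mean areas give a count within 1% of the printed species
        # mean (the study averages per-specimen counts, hence the gap)
        n = ommatidia_number(887826.7, 341.2)
        assert n == pytest.approx(2602.07, abs=0.01)
        assert abs(n - 2585.2) / 2585.2 < 0.01

    def test_identity(self):
        assert ommatidia_number(123.4, 123.4) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ommatidia_number(100.0, 0.0)

    def test_mean_of_ratios_jensen_gap_shrinks_with_noise(self):
        # E[A/B] != E[A]/E[B]; the gap is O(CV^2) and vanishes as noise -> 0
        rng = np.random.default_rng(0)
        gaps = []
        for cv in (0.2, 0.02):
            a = 1000.0 * (1 + cv * rng.standard_normal(4000))
            b = 10.0 * (1 + cv * rng.standard_normal(4000))
            gap = abs(np.mean(a / b) - np.mean(a) / np.mean(b)) / (
                np.mean(a) / np.mean(b)
            )
            assert gap < 3 * cv**2
            gaps.append(gap)
        assert gaps[1] < gaps[0]


class TestInterommatidialAngle:
    @pytest.mark.parametrize(
        "om_number,expected,printed",
        [(2635.3, 3.006, 3.01), (1123.8, 4.604, 4.63)],
    )
    def test_study_rows(self, om_number, expected, printed):
        angle = interommatidial_angle(om_number)
        assert angle == pytest.approx(expected, abs=0.001)
        assert abs(angle - printed) < 0.05

    def test_back_calculation_over_all_species(self, table1):
        computed = interommatidial_angle(table1.mean("OM_number").to_numpy())
        printed = table1.mean("delta_gamma").to_numpy()
        assert np.median(np.abs(computed - printed)) < 0.06

    def test_monotone_and_sqrt2_scaling(self):
        n = np.array([500.0, 1000.0, 2000.0, 4000.0])
        angles = interommatidial_angle(n)
        assert np.all(np.diff(angles) < 0)
        assert angles[0] / angles[2] == pytest.approx(2.0, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            interommatidial_angle(-1.0)


class TestBodyMass:
    def test_power_law(self):
        assert body_mass(1.0) == pytest.approx(0.655, rel=1e-15)
        assert body_mass(2.0) == pytest.approx(0.655 * 2**2.526, rel=1e-12)
        assert body_mass(2.0) == pytest.approx(3.773, abs=0.001)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            body_mass(0.0)


class TestRelativeTrait:
    def test_identity_and_linearity(self):
        assert relative_trait(2135.0, 2135.0) == 100.0
        assert relative_trait(2 * 471.3, 2049.0) == pytest.approx(
            2 * relative_trait(471.3, 2049.0), rel=1e-15
        )

    def test_funiculus_head_ratio_matches_study_range(self):
        # a NON-SAT funiculus/head ratio falls inside the quoted 17.6-31.1
        assert relative_trait(471.3, 2049.0) == pytest.approx(23.0, abs=0.05)

    def test_zero_head_width_rejected(self):
        with pytest.raises(ValueError):
            relative_trait(100.0, 0.0)


def _specimen(species, sid, scale=1.0, rng=None):
    jitter = (lambda: 1.0) if rng is None else (lambda: 1 + 0.03 * rng.standard_normal())
    return SpecimenMeasurements(
        species_id=species,
        specimen_id=sid,
        H_width=2000 * scale * jitter(),
        E_widthA=900 * scale * jitter(),
        E_height=800 * scale * jitter(),
        E_widthL=850 * scale * jitter(),
        OM_diameters=[20 * scale * jitter() for _ in range(10)],
        OC_diameter=60 * scale * jitter(),
        F_length=400 * scale * jitter(),
        P_length=200 * scale * jitter(),
        A_length=500 * scale * jitter(),
    )


class TestAggregateSpecies:
    def test_count_identity_per_specimen(self):
        derived = derive_specimen(_specimen("A", "s1"))
        assert derived["E_area"] / derived["OM_area"] == pytest.approx(
            derived["OM_number"], rel=1e-15
        )
        assert derived["ANT_length"] == derived["F_length"] + derived["P_length"] + derived["A_length"]

    def test_single_specimen_se_missing(self):
        table = aggregate_species([_specimen("A", "s1")])
        assert table.df.loc["A", "E_area_n"] == 1
        assert np.isnan(table.df.loc["A", "E_area_se"])

    def test_two_identical_specimens(self):
        table = aggregate_species([_specimen("A", "s1"), _specimen("A", "s2")])
        assert table.df.loc["A", "H_width_mean"] == 2000.0
        assert table.df.loc["A", "H_width_se"] == 0.0

    def test_species_mean_recovery_from_noisy_specimens(self):
        rng = np.random.default_rng(1)
        specimens = [
            _specimen(f"sp{k}", f"sp{k}_{i}", scale=0.8 + 0.05 * k, rng=rng)
            for k in range(10)
            for i in range(7)
        ]
        table = aggregate_species(specimens)
        # recovered means stay within 3 SE of the noise-free derivation
        clean = {
            f"sp{k}": derive_specimen(_specimen(f"sp{k}", "x", scale=0.8 + 0.05 * k))
            for k in range(10)
        }
        checks, hits = 0, 0
        for sp, truth in clean.items():
            for trait, value in truth.items():
                se = table.df.loc[sp, f"{trait}_se"]
                if np.isnan(se) or se == 0:
                    continue
                checks += 1
                hits += abs(table.df.loc[sp, f"{trait}_mean"] - value) < 3 * se
        assert checks > 50
        assert hits / checks > 0.9

    def test_no_specimens_rejected(self):
        with pytest.raises(ValueError):
            aggregate_species([])
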