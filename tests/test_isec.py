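"""Unit tests for the iSEC characterization stage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsorbkit import fixtures
from adsorbkit.errors import InconsistentVolumesError, KdRangeError
from adsorbkit.isec import (
    ColumnGeometry,
    ColumnVolumes,
    Eq2Constants,
    IsecProfile,
    PolystyreneStandard,
    StokesCalibration,
    accessible_pore_bracket,
    characterize_adsorbent,
    clamp_kd,
    column_bed_volume,
    compute_kd,
    eq2_diameter_from_mass,
    eq2_mass_from_diameter,
    fit_stokes_calibration,
    pore_volume,
    porosity,
    stokes_radius,
)


class TestComputeKd:
    @pytest.mark.parametrize(
        "vr, expected",
        [
            (2.30, 1.0),  # fully permeating tracer: vr == vt
            (1.06, 0.0),  # fully excluded probe: vr == v0
            (1.8908, 0.67),  # mid-ladder retention
        ],
    )
    def test_anchor_and_mid_values(self, cg161c_volumes, vr, expected):
        assert compute_kd(vr, cg161c_volumes) == pytest.approx(expected, abs=1e-12)

    def test_raw_value_not_clamped(self, cg161c_volumes):
        assert compute_kd(2.35, cg161c_volumes) > 1.0

    def test_negative_retention_rejected(self, cg161c_volumes):
        with pytest.raises(ValueError):
            compute_kd(-0.1, cg161c_volumes)

    def test_degenerate_column_rejected(self):
        with pytest.raises(InconsistentVolumesError):
            ColumnVolumes(v0=1.06, vt=1.06)


class TestClampKd:
    def test_small_excursion_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert clamp_kd(-0.03) == 0.0
        with pytest.warns(UserWarning):
            assert clamp_kd(1.04) == 1.0

    def test_large_excursion_is_error(self):
        with pytest.raises(KdRangeError):
            clamp_kd(1.2)

    def test_in_range_passthrough(self):
        assert clamp_kd(0.42) == 0.42


class TestEq2:
    def test_unit_diameter(self):
        assert eq2_diameter_from_mass(2.25) == pytest.approx(1.0)

    def test_round_trip_100_angstrom(self):
        mass = eq2_mass_from_diameter(100.0)
        assert mass == pytest.approx(5651.8, abs=0.1)
        assert eq2_diameter_from_mass(mass) == pytest.approx(100.0)

    def test_megadalton_probe(self):
        assert eq2_diameter_from_mass(1e6) == pytest.approx((1e6 / 2.25) ** (1 / 1.7), rel=1e-12)
        assert eq2_diameter_from_mass(1e6) == pytest.approx(2100, rel=0.01)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e2, max_value=1e7))
    def test_round_trip_identity(self, mass):
        back = eq2_mass_from_diameter(eq2_diameter_from_mass(mass))
        assert back == pytest.approx(mass, rel=1e-10)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            eq2_diameter_from_mass(0.0)


class TestStokesCalibration:
    def test_fit_on_bundled_ladder(self, calibration):
        assert calibration.prefactor == pytest.approx(0.0123, abs=0.0005)
        assert calibration.exponent == pytest.approx(0.588, abs=0.002)
        assert calibration.r_squared > 0.999

    def test_two_point_power_law_exact(self):
        cal = fit_stokes_calibration(
            [PolystyreneStandard(100, 1.0), PolystyreneStandard(10000, 10.0)]
        )
        assert cal.exponent == pytest.approx(0.5, rel=1e-12)
        assert cal.prefactor == pytest.approx(0.1, rel=1e-12)

    def test_predict_at_17300(self, calibration):
        assert round(stokes_radius(17300, calibration), 2) == pytest.approx(3.82, abs=0.01)

    @pytest.mark.parametrize("mass, printed", [(570, 0.51), (27500, 5.01)])
    def test_predicted_radii_match_measured(self, calibration, mass, printed):
        assert round(stokes_radius(mass, calibration), 2) == printed

    def test_leave_one_out_within_one_percent(self):
        standards = fixtures.standards()
        for left_out in standards:
            rest = [s for s in standards if s.molecular_mass != left_out.molecular_mass]
            cal = fit_stokes_calibration(rest)
            pred = stokes_radius(left_out.molecular_mass, cal)
            assert pred == pytest.approx(left_out.stokes_radius, rel=0.01)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_stokes_calibration([PolystyreneStandard(100, 1.0)])

    def test_flat_exponent_violates_invariant(self):
        with pytest.raises(ValueError):
            StokesCalibration(prefactor=1.0, exponent=0.0)

    def test_calibration_inversion(self, calibration):
        mass = calibration.invert(5.0)
        assert stokes_radius(float(mass), calibration) == pytest.approx(5.0, rel=1e-12)


class TestBracket:
    @pytest.mark.parametrize(
        "adsorbent, d_lower, d_upper",
        [("CG161c", 10.0, 16.2), ("CG300m", 20.9, 26.0), ("HAC", 7.6, 10.0)],
    )
    def test_bundled_ladders_with_measured_radii(self, calibration, adsorbent, d_lower, d_upper):
        profile = fixtures.isec_profile(adsorbent)
        res = accessible_pore_bracket(
            profile, calibration=calibration, radii=fixtures.measured_radii(adsorbent)
        )
        rep = res.to_report()
        assert rep["pore_diameter_lower_nm"] == d_lower
        assert rep["pore_diameter_upper_nm"] == d_upper
        assert res.r_lower < res.r_upper

    @pytest.mark.parametrize(
        "adsorbent, d_lower, d_upper",
        [("CG161c", 10.0, 16.2), ("CG300m", 20.9, 26.0), ("HAC", 7.6, 10.0)],
    )
    def test_bundled_ladders_with_fitted_radii(self, calibration, adsorbent, d_lower, d_upper):
        profile = fixtures.isec_profile(adsorbent)
        res = accessible_pore_bracket(profile, calibration=calibration)
        rep = res.to_report()
        assert rep["pore_diameter_lower_nm"] == d_lower
        assert rep["pore_diameter_upper_nm"] == d_upper

    def test_exact_threshold_tie_counts_accessible(self, calibration):
        # HAC's Kd ladder touches 0.10 exactly at M_r 17300
        profile = fixtures.isec_profile("HAC")
        res = accessible_pore_bracket(profile, calibration=calibration)
        assert res.mass_lower == 17300

    def test_all_permeating_is_open_above(self, cg161c_volumes, calibration):
        profile = IsecProfile("open", cg161c_volumes, [(100, 1.0), (1000, 1.0)])
        res = accessible_pore_bracket(profile, calibration=calibration)
        assert res.open_high and not res.open_low
        assert res.r_upper is None

    def test_all_excluded_is_open_below(self, cg161c_volumes, calibration):
        profile = IsecProfile("closed", cg161c_volumes, [(100, 0.01), (1000, 0.0)])
        res = accessible_pore_bracket(profile, calibration=calibration)
        assert res.open_low and res.r_lower is None

    def test_noisy_ladder_smoothed_isotonic(self, cg161c_volumes, calibration):
        # local bump above threshold must not create a second crossing:
        # (0.06, 0.10) pools to 0.08 < 0.1, so the crossing stays below 3000
        points = [(100, 0.9), (1000, 0.5), (3000, 0.06), (10000, 0.10), (30000, 0.0)]
        res = accessible_pore_bracket(
            IsecProfile("noisy", cg161c_volumes, points), calibration=calibration
        )
        assert res.smoothed
        assert res.mass_lower == 1000

    def test_pooled_tie_at_threshold_counts_accessible(self, cg161c_volumes, calibration):
        # isotonic pooling that lands exactly on the threshold is accessible
        points = [(100, 0.9), (1000, 0.5), (3000, 0.08), (10000, 0.12), (30000, 0.0)]
        res = accessible_pore_bracket(
            IsecProfile("noisy", cg161c_volumes, points), calibration=calibration
        )
        assert res.mass_lower == 10000

    def test_eq2_route_labelled_and_uses_masses(self, calibration):
        profile = fixtures.isec_profile("CG161c")
        res = accessible_pore_bracket(profile, calibration=calibration, route="eq2")
        assert res.route == "eq2"
        # diameters derive from the bracketing masses, in nm
        assert res.d_lower == pytest.approx(eq2_diameter_from_mass(27500) / 10.0)
        assert res.d_upper == pytest.approx(eq2_diameter_from_mass(62300) / 10.0)


class TestVolumesAndPorosity:
    def test_geometric_bed_volume(self):
        assert column_bed_volume(ColumnGeometry(0.46, 15.0)) == pytest.approx(2.493, abs=0.001)

    def test_unit_cross_section(self):
        assert column_bed_volume(ColumnGeometry(2 / math.sqrt(math.pi), 1.0)) == pytest.approx(1.0)

    def test_length_linearity(self):
        one = column_bed_volume(ColumnGeometry(0.46, 15.0))
        two = column_bed_volume(ColumnGeometry(0.46, 30.0))
        assert two == pytest.approx(2 * one)

    def test_hac_porosity(self):
        vb = column_bed_volume(ColumnGeometry(0.46, 15.0))
        vol = ColumnVolumes(v0=1.13, vt=2.31, vb=vb)
        assert round(porosity(vol), 1) == 86.6

    def test_fully_porous_limit(self):
        vol = ColumnVolumes(v0=1.0, vt=2.0, vb=2.0)
        assert porosity(vol) == pytest.approx(100.0)

    def test_mobile_phase_exceeding_bed_rejected_with_values(self):
        with pytest.raises(InconsistentVolumesError, match="1.792"):
            ColumnVolumes(v0=1.06, vt=2.30, vb=1.792)

    @pytest.mark.parametrize(
        "v0, vt, expected", [(1.14, 2.25, 1.11), (1.13, 2.31, 1.18), (1.0, 1.0 + 1e-9, 1e-9)]
    )
    def test_pore_volume(self, v0, vt, expected):
        assert pore_volume(ColumnVolumes(v0=v0, vt=vt)) == pytest.approx(expected)


class TestCharacterize:
    def test_cg300m_full_record(self, calibration):
        profile = fixtures.isec_profile("CG300m")
        res = characterize_adsorbent(
            profile, calibration=calibration, radii=fixtures.measured_radii("CG300m")
        )
        rep = res.to_report()
        assert (rep["pore_diameter_lower_nm"], rep["pore_diameter_upper_nm"]) == (20.9, 26.0)
        assert rep["porosity_percent"] == 82.0
        assert rep["pore_volume_ml"] == 1.11

    def test_empty_profile_rejected(self, cg161c_volumes):
        with pytest.raises(ValueError):
            IsecProfile("empty", cg161c_volumes, [])

    def test_porosity_in_unit_interval_for_valid_volumes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v0 = rng.uniform(0.5, 1.5)
            vt = v0 + rng.uniform(0.01, 1.5)
            vb = vt + rng.uniform(0.0, 1.0)
            vol = ColumnVolumes(v0=v0, vt=vt, vb=vb)
            assert 0 < porosity(vol) <= 100
            assert pore_volume(vol) > 0
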