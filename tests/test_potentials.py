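"""Potential generators, curve invariants, file round trips, resampling."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import protonvib as pv

GRID = pv.GridSpec(-1.0, 1.0, 201)


class TestHarmonic:
    def test_symmetric_about_minimum_with_zero_floor(self):
        curve = pv.make_harmonic(force_constant=3.0, q_min=0.0, R0=1.0, grid=GRID)
        assert curve.energies[GRID.n_points // 2] == 0.0
        np.testing.assert_allclose(curve.energies, curve.energies[::-1], atol=1e-14)

    def test_energy_value(self):
        curve = pv.make_harmonic(force_constant=2.0, q_min=0.0, R0=1.0, grid=GRID)
        assert curve.energies[-1] == pytest.approx(1.0)  # E(1) = 0.5*2*1^2

    def test_rejects_nonpositive_force_constant(self):
        with pytest.raises(pv.ParameterError):
            pv.make_harmonic(force_constant=-1.0, q_min=0.0, R0=1.0, grid=GRID)

    def test_rejects_minimum_outside_grid(self):
        with pytest.raises(pv.ParameterError):
            pv.make_harmonic(force_constant=1.0, q_min=5.0, R0=1.0, grid=GRID)


class TestMorse:
    def test_minimum_and_dissociation_plateau(self):
        grid = pv.GridSpec(-1.0, 30.0, 3101)
        curve = pv.make_morse(D_e=5.0, a=2.0, q_min=0.0, R0=1.0, grid=grid)
        assert curve.spline()(0.0) == pytest.approx(0.0, abs=1e-12)
        assert curve.energies[-1] == pytest.approx(5.0, rel=1e-10)

    @pytest.mark.parametrize("bad", [dict(D_e=0.0, a=1.0), dict(D_e=1.0, a=-2.0)])
    def test_rejects_nonpositive_parameters(self, bad):
        with pytest.raises(pv.ParameterError):
            pv.make_morse(q_min=0.0, R0=1.0, grid=GRID, **bad)


class TestDoubleWell:
    def test_symmetric_case_is_closed_form_quartic(self):
        b, h = 0.4, 2.0
        grid = pv.GridSpec(-0.8, 0.8, 161)
        curve = pv.make_double_well(
            min1_q=-b, barrier_q=0.0, min2_q=b,
            barrier_height=h, asymmetry=0.0, R0=1.0, grid=grid,
        )
        a = h / b**4
        expected = a * (grid.points() ** 2 - b**2) ** 2
        np.testing.assert_allclose(curve.energies, expected, atol=1e-9)

    def test_zero_asymmetry_gives_equal_minima(self):
        curve = pv.make_double_well(
            min1_q=-0.3, barrier_q=0.05, min2_q=0.4,
            barrier_height=3.0, asymmetry=0.0, R0=1.0,
            grid=pv.GridSpec(-0.7, 0.8, 151),
        )
        s = curve.spline()
        assert float(s(-0.3)) == pytest.approx(float(s(0.4)), abs=1e-7)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min1_q=0.2, barrier_q=0.1, min2_q=0.4),   # unordered
            dict(barrier_height=-1.0),
            dict(asymmetry=5.0),                            # >= barrier
        ],
    )
    def test_rejects_infeasible_constraints(self, kwargs):
        base = dict(
            min1_q=-0.3, barrier_q=0.0, min2_q=0.3,
            barrier_height=2.0, asymmetry=0.0, R0=1.0,
            grid=pv.GridSpec(-0.7, 0.7, 141),
        )
        base.update(kwargs)
        with pytest.raises(pv.ParameterError):
            pv.make_double_well(**base)

    @given(
        b=st.floats(0.15, 0.45),
        h=st.floats(0.5, 8.0),
        asym_frac=st.floats(0.0, 0.8),
        skew=st.floats(-0.3, 0.3),
    )
    def test_generated_wells_satisfy_constraints(self, b, h, asym_frac, skew):
        """Every successfully generated double well reproduces its
        prescribed stationary structure when re-analysed from the sampled
        table (geometrically infeasible requests raise instead)."""
        grid = pv.GridSpec(-b - 0.5, b + 0.5, 801)
        try:
            curve = pv.make_double_well(
                min1_q=-b, barrier_q=b * skew, min2_q=b,
                barrier_height=h, asymmetry=asym_frac * h, R0=1.2, grid=grid,
            )
        except pv.ConstructionError:
            assume(False)
        assert len(curve) == grid.n_points
        assert np.all(np.isfinite(curve.energies))
        report = pv.barrier_analysis(curve)
        assert report.classification == "double-well"
        assert report.barrier_height == pytest.approx(h, abs=1e-6)
        assert report.barrier_q == pytest.approx(b * skew, abs=1e-6)
        assert report.global_min_energy == pytest.approx(0.0, abs=1e-6)


class TestFixtures:
    def test_equilibrium_is_a_single_anharmonic_well(self, equilibrium_curve):
        assert equilibrium_curve.R0 == 1.08
        report = pv.barrier_analysis(equilibrium_curve)
        assert report.classification == "single-well"
        kinds = [p.kind for p in report.stationary_points]
        assert kinds == ["minimum"]
        assert report.global_min_q == pytest.approx(0.0, abs=1e-6)
        positive = equilibrium_curve.q_values > 0
        assert np.all(np.diff(equilibrium_curve.energies[positive]) > 0)
        # anharmonicity: compression wall stiffer than elongation side
        s = equilibrium_curve.spline()
        assert float(s(-0.2)) > float(s(0.2))

    def test_crystal_matches_published_calibration(self, crystal_curve):
        assert crystal_curve.R0 == 1.21
        report = pv.barrier_analysis(crystal_curve)
        assert report.classification == "double-well"
        assert report.barrier_height == pytest.approx(2.36, abs=1e-6)
        assert report.barrier_q == pytest.approx(0.10, abs=1e-6)
        assert report.barrier_bond_length == pytest.approx(1.31, abs=1e-6)
        assert report.global_min_bond_length == pytest.approx(1.06, abs=1e-6)
        assert report.global_min_energy == pytest.approx(0.0, abs=1e-9)
        assert crystal_curve.energies.min() == pytest.approx(0.0, abs=1e-12)

    @given(
        st.sampled_from(["harmonic", "morse"]),
        st.floats(0.5, 50.0),
        st.floats(0.5, 4.0),
    )
    def test_generators_return_valid_curves(self, kind, scale, width):
        if kind == "harmonic":
            curve = pv.make_harmonic(scale, q_min=0.1, R0=1.0, grid=GRID)
        else:
            curve = pv.make_morse(scale, width, q_min=0.1, R0=1.0, grid=GRID)
        assert np.all(np.diff(curve.q_values) > 0)
        assert np.all(np.isfinite(curve.energies))
        assert len(curve) == GRID.n_points


class TestCurveIO:
    def test_round_trip_is_bit_exact(self, tmp_path, crystal_curve):
        path = pv.write_curve(crystal_curve, tmp_path / "c.dat")
        back = pv.read_curve(path)
        np.testing.assert_array_equal(back.q_values, crystal_curve.q_values)
        np.testing.assert_array_equal(back.energies, crystal_curve.energies)
        assert back.R0 == crystal_curve.R0
        assert back.label == crystal_curve.label

    def test_unsorted_rows_are_sorted_with_warning(self, tmp_path, caplog):
        path = tmp_path / "u.dat"
        path.write_text(
            "# R0_angstrom=1.0\n0.2 4.0\n0.0 0.0\n0.1 1.0\n0.3 9.0\n0.4 16.0\n"
        )
        with caplog.at_level("WARNING", logger="protonvib"):
            curve = pv.read_curve(path)
        assert "unsorted" in caplog.text
        np.testing.assert_array_equal(curve.q_values, [0.0, 0.1, 0.2, 0.3, 0.4])
        np.testing.assert_array_equal(curve.energies, [0.0, 1.0, 4.0, 9.0, 16.0])

    def test_missing_r0_header_is_a_format_error(self, tmp_path):
        path = tmp_path / "no_r0.dat"
        path.write_text("0.0 0.0\n0.1 1.0\n0.2 4.0\n0.3 9.0\n0.4 16.0\n")
        with pytest.raises(pv.CurveFormatError, match="R0_angstrom"):
            pv.read_curve(path)

    def test_non_numeric_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("# R0_angstrom=1.0\n0.0 0.0\n0.1 oops\n")
        with pytest.raises(pv.CurveFormatError, match=":3"):
            pv.read_curve(path)

    def test_duplicate_q_is_a_format_error(self, tmp_path):
        path = tmp_path / "dup.dat"
        path.write_text("# R0_angstrom=1.0\n0.0 0.0\n0.1 1.0\n0.1 2.0\n")
        with pytest.raises(pv.CurveFormatError, match="duplicate"):
            pv.read_curve(path)

    def test_csv_export(self, tmp_path, crystal_curve):
        path = pv.curve_to_csv(crystal_curve, tmp_path / "c.csv")
        header, first = path.read_text().splitlines()[:2]
        assert header == "q_angstrom,R_angstrom,energy_kcal_per_mol"
        assert len(first.split(",")) == 3


class TestInterpolation:
    def test_identity_on_uniform_grid(self, crystal_curve):
        same = pv.interpolate_curve(crystal_curve, len(crystal_curve))
        np.testing.assert_allclose(same.energies, crystal_curve.energies, atol=1e-12)

    def test_spline_reproduces_cubic_exactly(self):
        q = np.linspace(-1, 1, 21)
        cubic = 2.0 + 0.5 * q - 1.5 * q**2 + 0.75 * q**3
        curve = pv.PotentialCurve(q, cubic, R0=1.0)
        dense = pv.interpolate_curve(curve, 501)
        expected = 2.0 + 0.5 * dense.q_values - 1.5 * dense.q_values**2 \
            + 0.75 * dense.q_values**3
        np.testing.assert_allclose(dense.energies, expected, atol=1e-12)

    def test_rejects_tiny_or_decimating_resample(self, crystal_curve):
        with pytest.raises(pv.ParameterError):
            pv.interpolate_curve(crystal_curve, 4)
        with pytest.raises(pv.ParameterError):
            pv.interpolate_curve(crystal_curve, len(crystal_curve) - 1)


class TestCurveInvariants:
    @pytest.mark.parametrize(
        "q,e",
        [
            ([0, 1, 2, 3], [0, 1, 2, 3]),              # too short
            ([0, 1, 1, 2, 3], [0, 1, 2, 3, 4]),         # not strictly increasing
            ([0, 1, 2, 3, 4], [0, 1, np.nan, 3, 4]),    # missing value
            ([0, 1, 2, 3, 4], [0, 1, 2, 3]),            # length mismatch
        ],
    )
    def test_invalid_tables_are_rejected(self, q, e):
        with pytest.raises(pv.ParameterError):
            pv.PotentialCurve(np.array(q, float), np.array(e, float), R0=1.0)

    def test_bond_length_mapping_is_affine_slope_one(self, crystal_curve):
        np.testing.assert_allclose(
            np.diff(crystal_curve.bond_lengths), np.diff(crystal_curve.q_values)
        )
        assert crystal_curve.bond_length(0.0) == crystal_curve.R0

    def test_noise_keeps_curve_valid_and_is_seeded(self, crystal_curve):
        n1 = pv.add_noise(crystal_curve, 0.05, seed=7)
        n2 = pv.add_noise(crystal_curve, 0.05, seed=7)
        np.testing.assert_array_equal(n1.energies, n2.energies)
        assert n1.energies.min() == pytest.approx(0.0, abs=1e-15)
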