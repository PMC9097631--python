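"""Crystal-field analysis: coefficient maps, Taylor ratios, uncertainty rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemepr.crystal_field import (
    GTensor,
    OrbitalCoefficients,
    analyze_table,
    coefficients_from_g,
    crystal_field_ratios,
    g_from_coefficients,
    normalization_flag,
    propagate_uncertainties,
    read_gtensor_table,
    reference_gtensors,
    rounded_report,
)
from hemepr.errors import (
    ConfigurationError,
    DegenerateGError,
    InvalidCoefficientsError,
    InvalidGTensorError,
)


class TestGTensor:
    def test_canonical_reordering_warns(self):
        with pytest.warns(UserWarning, match="reordered"):
            g = GTensor(1.92, 2.44, 2.25, 0.002, 0.005, 0.002)
        assert (g.gz, g.gy, g.gx) == (2.44, 2.25, 1.92)
        # sigmas travel with their g-values
        assert (g.sigma_gz, g.sigma_gy, g.sigma_gx) == (0.005, 0.002, 0.002)

    @pytest.mark.parametrize("bad", [(0.0, 2.0, 1.9), (2.4, -2.2, 1.9)])
    def test_nonpositive_g_rejected(self, bad):
        with pytest.raises(InvalidGTensorError):
            GTensor(*bad)

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidGTensorError):
            GTensor(2.4, 2.2, 1.9, sigma_gz=-0.01)


class TestCoefficientMaps:
    @pytest.mark.parametrize(
        "g, expected",
        [
            # resting-state enzyme; a and b match the published table,
            # c follows the inversion formula itself (0.0701)
            ((2.440, 2.25, 1.92), (0.996, 0.110, 0.070)),
            # benchmark enzyme row, direct evaluation of the inversion
            ((2.418, 2.26, 1.92), (0.9959, 0.1060, 0.0724)),
        ],
    )
    def test_coefficients_from_g(self, g, expected):
        c = coefficients_from_g(GTensor(*g))
        assert c.a == pytest.approx(expected[0], abs=5e-4)
        assert c.b == pytest.approx(expected[1], abs=5e-4)
        assert c.c == pytest.approx(expected[2], abs=5e-4)

    def test_benchmark_normalization(self):
        c = coefficients_from_g(GTensor(2.418, 2.26, 1.92))
        assert c.m_squared == pytest.approx(1.008, abs=1e-3)

    def test_isotropic_closed_form(self):
        # isotropic g0 gives b = c = 0 and a = sqrt(g0/2): unity only at g0 = 2
        for g0 in (2.0023, 2.0, 1.5):
            c = coefficients_from_g(GTensor(g0, g0, g0))
            assert c.b == 0 and c.c == 0
            assert c.a == pytest.approx(np.sqrt(g0 / 2.0), rel=1e-12)
        assert coefficients_from_g(GTensor(2.0, 2.0, 2.0)).a == pytest.approx(1.0)

    def test_forward_map_examples(self):
        g = g_from_coefficients(OrbitalCoefficients(1.0, 0.0, 0.0))
        assert (g.gz, g.gy, g.gx) == (2.0, 2.0, 2.0)
        g = g_from_coefficients(OrbitalCoefficients(0.9964, 0.1105, 0.0701))
        assert np.allclose([g.gz, g.gy, g.gx], [2.440, 2.250, 1.920], atol=1e-3)
        # b = c forces gz = gy
        g = g_from_coefficients(OrbitalCoefficients(0.99, 0.10, 0.10))
        assert g.gz == pytest.approx(2.3562) and g.gy == pytest.approx(2.3562)
        assert g.gx == pytest.approx(1.8802)

    def test_degenerate_gx_equal_gy_gz_permitted(self):
        c = coefficients_from_g(GTensor(2.1, 2.1, 2.1))
        assert c.b == 0 and c.c == 0

    def test_all_zero_coefficients_rejected(self):
        # canonical ordering guarantees gz + gy - gx > 0, so the inversion is
        # always defined; only the forward map has a reachable error state
        with pytest.raises(InvalidCoefficientsError):
            g_from_coefficients(OrbitalCoefficients(0.0, 0.0, 0.0))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        a=st.floats(0.7, 1.2),
        b=st.floats(0.0, 0.3),
        frac=st.floats(0.0, 1.0),
    )
    def test_round_trip_is_algebraically_exact(self, a, b, frac):
        """coefficients -> g -> coefficients is the identity in the physical
        regime a >= b >= c with a dominant (gx > 0)."""
        c = b * frac
        back = coefficients_from_g(g_from_coefficients(OrbitalCoefficients(a, b, c)))
        assert back.a == pytest.approx(a, abs=1e-12)
        assert back.b == pytest.approx(b, abs=1e-12)
        assert back.c == pytest.approx(c, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(a=st.floats(0.9, 1.0), b=st.floats(0.0, 0.25), frac=st.floats(0.0, 1.0))
    def test_unit_norm_recovered(self, a, b, frac):
        """For a normalized doublet the recovered m^2 is exactly one."""
        c = b * frac
        n = np.sqrt(a * a + b * b + c * c)
        a, b, c = a / n, b / n, c / n
        back = coefficients_from_g(g_from_coefficients(OrbitalCoefficients(a, b, c)))
        assert back.m_squared == pytest.approx(1.0, abs=1e-12)


class TestCrystalFieldRatios:
    def test_resting_state_published_ratios(self):
        cf = crystal_field_ratios(GTensor(2.440, 2.25, 1.92))
        assert round(cf.v_over_xi, 2) == 4.74
        assert round(cf.delta_over_xi, 2) == 5.44
        assert round(cf.rhombicity, 2) == 0.87

    def test_histidine_adduct_published_ratio(self):
        assert round(crystal_field_ratios(GTensor(2.42, 2.24, 1.92)).v_over_xi, 2) == 4.89

    def test_absolute_splittings_with_free_iron_xi(self):
        cf = crystal_field_ratios(GTensor(2.440, 2.25, 1.92), xi=400.0)
        assert cf.v_abs == pytest.approx(cf.v_over_xi * 400.0, rel=1e-12)
        assert cf.v_abs == pytest.approx(1894, abs=1.0)
        assert cf.delta_abs == pytest.approx(2174, abs=1.0)

    def test_rhombicity_identity(self):
        cf = crystal_field_ratios(GTensor(2.47, 2.26, 1.90))
        assert cf.rhombicity * cf.delta_over_xi == pytest.approx(cf.v_over_xi, abs=1e-12)

    def test_degenerate_denominator_named(self):
        with pytest.raises(DegenerateGError, match="gy - gx"):
            crystal_field_ratios(GTensor(2.4, 1.9, 1.9))
        with pytest.raises(DegenerateGError, match="gz - gx"):
            crystal_field_ratios(GTensor(1.9, 1.9, 1.9))

    def test_ratio_decreases_with_gz(self):
        # d(V/xi)/dgz < 0 across the physical range of the reference table
        for gz in np.linspace(2.40, 2.62, 12):
            v0 = crystal_field_ratios(GTensor(gz, 2.25, 1.92)).v_over_xi
            v1 = crystal_field_ratios(GTensor(gz + 1e-6, 2.25, 1.92)).v_over_xi
            assert v1 < v0


class TestUncertaintyPropagation:
    G = GTensor(2.440, 2.25, 1.92, 0.005, 0.002, 0.002)

    def test_linear_sum_matches_analytic_partials(self):
        # |dV/dgz| = 8.408, |dV/dgy| = 1.836, |dV/dgx| = 8.534 at this point
        out = propagate_uncertainties(self.G, method="linear_sum")
        assert out.sigma_v == pytest.approx(0.063, abs=1e-3)

    def test_zero_sigmas_give_zero_output(self):
        g = GTensor(2.44, 2.25, 1.92, 0.0, 0.0, 0.0)
        for method in ("linear_sum", "quadrature", "monte_carlo"):
            out = propagate_uncertainties(g, method=method, seed=1)
            # analytic rules give exactly zero; monte-carlo only to rounding
            tol = 1e-10 if method == "monte_carlo" else 0.0
            assert abs(out.sigma_v) <= tol
            assert abs(out.sigma_delta) <= tol
            assert abs(out.sigma_rhombicity) <= tol

    def test_monte_carlo_deterministic_under_seed(self):
        a = propagate_uncertainties(self.G, "monte_carlo", seed=11)
        b = propagate_uncertainties(self.G, "monte_carlo", seed=11)
        assert (a.sigma_v, a.sigma_delta, a.sigma_rhombicity) == (
            b.sigma_v, b.sigma_delta, b.sigma_rhombicity)

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            propagate_uncertainties(GTensor(2.44, 2.25, 1.92))  # sigmas unset
        with pytest.raises(ConfigurationError):
            propagate_uncertainties(self.G, "monte_carlo")  # no seed
        with pytest.raises(ConfigurationError):
            propagate_uncertainties(self.G, "monte_carlo", n_draws=10, seed=1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        gz=st.floats(2.30, 2.65), gy=st.floats(2.1, 2.29), gx=st.floats(1.80, 2.0),
        sz=st.floats(0.0, 0.02), sy=st.floats(0.0, 0.02), sx=st.floats(0.0, 0.02),
    )
    def test_quadrature_never_exceeds_linear_sum(self, gz, gy, gx, sz, sy, sx):
        g = GTensor(gz, gy, gx, sz, sy, sx)
        lin = propagate_uncertainties(g, "linear_sum")
        quad = propagate_uncertainties(g, "quadrature")
        assert quad.sigma_v <= lin.sigma_v + 1e-15
        assert quad.sigma_delta <= lin.sigma_delta + 1e-15
        assert quad.sigma_rhombicity <= lin.sigma_rhombicity + 1e-15


class TestBatchReport:
    def test_reference_table_reproduces_published_row(self):
        df = rounded_report(analyze_table(reference_gtensors()))
        assert len(df) == 5
        row = df[df.label == "CYP116B5hd"].iloc[0]
        assert (row.V_xi, row.Delta_xi, row.V_Delta) == (4.74, 5.44, 0.87)
        assert (row.a, row.b) == (0.996, 0.110)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            analyze_table([])

    def test_degenerate_row_isolated(self):
        rows = [GTensor(2.44, 2.25, 1.92, label="ok"),
                GTensor(2.4, 1.9, 1.9, label="bad")]
        df = analyze_table(rows)
        assert df.iloc[0].error == "" and np.isfinite(df.iloc[0].V_xi)
        assert "gy - gx" in df.iloc[1].error and np.isnan(df.iloc[1].V_xi)

    def test_normalization_flag_thresholds(self):
        assert normalization_flag(1.0) == ""
        assert "covalent" in normalization_flag(0.95)
        assert "excited" in normalization_flag(1.05)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("label,gz,gy,gx,sgz,sgy,sgx\nX,2.44,2.25,1.92,0.005,0.002,0.002\n")
        rows = read_gtensor_table(path)
        assert rows[0].label == "X" and rows[0].sigma_gz == 0.005
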