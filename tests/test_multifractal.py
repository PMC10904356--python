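"""Mass-exponent, dimension and spectrum estimators against analytic oracles."""

import numpy as np
import pytest

from fractmorph import (
    ConfigError,
    EmptyMeasureError,
    analytic_cascade_alpha,
    analytic_cascade_tau,
    box_masses,
    default_q_grid,
    dyadic_box_sizes,
    generalized_dimensions,
    is_monofractal,
    singularity_spectrum,
    tau_function,
    triadic_box_sizes,
)
from .conftest import CASCADE_WEIGHTS


class TestBoxMasses:
    def test_equipartition(self):
        p = box_masses(np.ones((4, 4)), 2)
        assert np.allclose(sorted(p), [0.25] * 4)

    def test_point_mass(self):
        field = np.zeros((8, 8))
        field[3, 5] = 2.5
        assert box_masses(field, 4).tolist() == [1.0]

    def test_unit_boxes_return_normalized_field(self):
        field = np.array([[0.4, 0.3], [0.2, 0.1]])
        assert np.allclose(sorted(box_masses(field, 1)), [0.1, 0.2, 0.3, 0.4])

    def test_partial_edge_boxes_discarded(self):
        field = np.ones((5, 5))
        p = box_masses(field, 2)  # 2x2 grid retained, 4 boxes of 4 px
        assert len(p) == 4 and np.allclose(p, 0.25)

    def test_empty_field_rejected(self):
        with pytest.raises(EmptyMeasureError):
            box_masses(np.zeros((4, 4)), 2)


class TestTau:
    def test_uniform_square_is_exactly_linear(self, uniform_field):
        t = tau_function(uniform_field)
        assert np.allclose(t.tau, 2 * (t.q_grid - 1), atol=1e-9)
        assert np.all(t.fit_r2 >= 0.999)

    def test_tau_at_one_is_identity_zero(self, cascade_field):
        """Z(1, eps) = 1 for any normalized partition, so tau(1) = 0 exactly."""
        for s in (2, 8, 32):
            assert abs(box_masses(cascade_field, s).sum() - 1.0) < 1e-12
        t = tau_function(cascade_field)
        assert t.tau[np.isclose(t.q_grid, 1.0)][0] == 0.0

    def test_cascade_matches_closed_form(self, cascade_field):
        """Dyadic grids resolve the cascade exactly: tau-hat = -log2(sum w^q)."""
        t = tau_function(cascade_field)
        expect = np.array([analytic_cascade_tau(CASCADE_WEIGHTS, q) for q in t.q_grid])
        assert np.max(np.abs(t.tau - expect)) < 0.05

    def test_concave_and_nondecreasing(self, cascade_field):
        t = tau_function(cascade_field)
        assert np.all(np.diff(t.tau) >= -1e-9)
        assert np.all(np.diff(t.tau, 2) <= 1e-9)

    def test_normalization_invariance(self, cascade_field):
        t1 = tau_function(cascade_field)
        t2 = tau_function(cascade_field * 37.5)
        assert np.allclose(t1.tau, t2.tau, atol=1e-9)

    def test_degenerate_ladder_rejected(self, uniform_field):
        with pytest.raises(ConfigError):
            tau_function(uniform_field, box_sizes=[4])


class TestDimensions:
    def test_uniform_square_is_two_everywhere(self, uniform_field):
        D = generalized_dimensions(tau_function(uniform_field))
        assert np.allclose(D.D, 2.0, atol=1e-9)

    def test_cascade_capacity_dimension_is_two(self, cascade_field):
        """The cascade's support is the whole square."""
        D = generalized_dimensions(tau_function(cascade_field))
        d0 = D.D[np.isclose(D.q_grid, 0.0)][0]
        assert d0 == pytest.approx(2.0, abs=0.01)

    def test_cascade_information_dimension(self, cascade_field):
        """D(1) equals the weight-vector entropy sum w log2(1/w) ~ 1.846."""
        t = tau_function(cascade_field)
        expect = sum(w * np.log2(1 / w) for w in CASCADE_WEIGHTS)
        assert t.info_dimension == pytest.approx(expect, abs=0.05)
        D = generalized_dimensions(t)
        assert D.D[np.isclose(D.q_grid, 1.0)][0] == pytest.approx(expect, abs=0.05)

    def test_nonincreasing_in_q(self, cascade_field, carpet5, uniform_field):
        for field, sizes in (
            (cascade_field, None),
            (carpet5, triadic_box_sizes(carpet5.shape)),
            (uniform_field, None),
        ):
            D = generalized_dimensions(tau_function(field, box_sizes=sizes))
            assert np.all(np.diff(D.D) <= 1e-9)


class TestSpectrum:
    def test_uniform_collapses_to_point(self, uniform_field):
        sp = singularity_spectrum(uniform_field)
        assert np.allclose(sp.alpha, 2.0, atol=1e-9)
        assert np.allclose(sp.f, 2.0, atol=1e-9)
        assert sp.width < 1e-9

    def test_cascade_alpha_matches_closed_form(self, cascade_field):
        sp = singularity_spectrum(cascade_field)
        expect = np.array([analytic_cascade_alpha(CASCADE_WEIGHTS, q) for q in sp.q_grid])
        assert np.max(np.abs(sp.alpha - expect)) < 0.1
        # grid-end values approach the extreme quadrant exponents
        assert sp.alpha[0] == pytest.approx(analytic_cascade_alpha(CASCADE_WEIGHTS, -5), abs=0.1)
        assert sp.alpha[-1] == pytest.approx(analytic_cascade_alpha(CASCADE_WEIGHTS, 5), abs=0.1)

    def test_cascade_apex_and_monotonicity(self, cascade_field):
        sp = singularity_spectrum(cascade_field)
        i0 = np.argmin(np.abs(sp.q_grid))
        assert sp.f[i0] == pytest.approx(2.0, abs=0.05)  # f(alpha0) = D(0)
        assert np.max(sp.f) <= sp.f[i0] + 1e-6  # apex at q = 0
        assert np.all(np.diff(sp.alpha) <= 1e-9)  # alpha non-increasing in q

    def test_legendre_consistency(self, cascade_field):
        """f(q) = q alpha(q) - tau(q) within tolerance across the grid."""
        t = tau_function(cascade_field)
        sp = singularity_spectrum(cascade_field)
        gap = np.abs(sp.f - (sp.q_grid * sp.alpha - t.tau))
        assert np.max(gap) <= 0.05

    def test_f_bounded_by_alpha_for_positive_q(self, cascade_field):
        sp = singularity_spectrum(cascade_field)
        pos = sp.q_grid >= 1
        assert np.all(sp.f[pos] <= sp.alpha[pos] + 1e-6)

    def test_carpet_apex_near_log8_log3(self, carpet5):
        sp = singularity_spectrum(carpet5, box_sizes=triadic_box_sizes(carpet5.shape))
        assert sp.alpha0 == pytest.approx(np.log(8) / np.log(3), abs=0.05)
        assert sp.width < 0.05

    def test_missing_q0_rejected(self, uniform_field):
        with pytest.raises(ConfigError):
            singularity_spectrum(uniform_field, q_grid=np.array([0.5, 1.0, 2.0]))

    def test_offset_averaging_is_seeded(self, cascade_field):
        a = singularity_spectrum(cascade_field, n_offsets=4, seed=11)
        b = singularity_spectrum(cascade_field, n_offsets=4, seed=11)
        assert np.array_equal(a.alpha, b.alpha)


class TestMonofractality:
    def test_uniform_square_is_monofractal(self, uniform_field):
        res = is_monofractal(tau_function(uniform_field), singularity_spectrum(uniform_field))
        assert res.monofractal and res.linear_tau and res.narrow_spectrum

    def test_carpet_is_monofractal(self, carpet5):
        sizes = triadic_box_sizes(carpet5.shape)
        res = is_monofractal(
            tau_function(carpet5, box_sizes=sizes),
            singularity_spectrum(carpet5, box_sizes=sizes),
        )
        assert res.monofractal

    def test_cascade_is_multifractal(self, cascade_field):
        """Analytic spectrum width ~1.9 dwarfs the 0.15 monofractal cap."""
        res = is_monofractal(tau_function(cascade_field), singularity_spectrum(cascade_field))
        assert not res.monofractal
        assert not res.narrow_spectrum
        assert res.spectrum_width > 1.0


def test_default_q_grid_contains_special_orders():
    q = default_q_grid()
    assert q[0] == -5 and q[-1] == 5
    assert np.any(q == 0.0) and np.any(q == 1.0)


def test_dyadic_ladder_spans_to_quarter_dimension():
    assert dyadic_box_sizes((256, 256)).tolist() == [2, 4, 8, 16, 32, 64]
    assert triadic_box_sizes((243, 243)).tolist() == [3, 9, 27, 81]
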