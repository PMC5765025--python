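"""Energy-functional primitives: closed forms, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfclust import (
    WeightedPointSet,
    adaptive_gamma,
    energy_fields,
    fermi_wavevector,
    hf_statistic,
    kedf,
    pedf,
)
from dfclust.errors import (
    DegenerateDensityError,
    DimensionMismatchError,
    DomainError,
    InvalidParameterError,
)


class TestFermiWavevector:
    def test_zero_density_maps_to_zero(self):
        assert fermi_wavevector(0.0, 2) == 0.0

    def test_unit_density_2d_closed_form(self):
        assert fermi_wavevector(1.0, 2) == pytest.approx(2 * np.pi * np.sqrt(2))

    @given(st.floats(1e-6, 1e3), st.integers(1, 5))
    def test_algebraic_round_trip(self, rho, d):
        kf = fermi_wavevector(rho, d)
        back = (1.0 / d) * (kf / (2 * np.pi)) ** d
        assert back == pytest.approx(rho, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"D": 0}, {"D": 2, "alpha": 0.0}, {"D": 2, "alpha": -1}])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            fermi_wavevector(1.0, bad.get("D", 2), alpha=bad.get("alpha", 1.0))


class TestKedf:
    def test_zero_density(self):
        assert kedf(np.array([0.0]), 2) == pytest.approx([0.0])

    def test_2d_closed_form_is_two_pi_squared_rho(self):
        rho = np.array([0.5, 1.0, 2.0])
        np.testing.assert_array_equal(kedf(rho, 2), 2 * np.pi**2 * rho)
        assert kedf(np.array([0.5]), 2)[0] == pytest.approx(np.pi**2)

    def test_3d_value(self):
        expect = (6 * np.pi**2 / 5) * 3 ** (2.0 / 3.0)
        assert kedf(np.array([1.0]), 3)[0] == pytest.approx(expect, rel=1e-6)

    @given(st.floats(1e-6, 1e3), st.integers(1, 4), st.floats(0.1, 10))
    def test_homogeneity(self, c, d, rho):
        scaled = kedf(np.array([c * rho]), d)[0]
        assert scaled == pytest.approx(c ** (2.0 / d) * kedf(np.array([rho]), d)[0], rel=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(DomainError):
            kedf(np.array([-0.1]), 2)


class TestPedf:
    def test_self_exclusion_single_source(self):
        src = WeightedPointSet([[1.0, 2.0]], [1.0])
        assert pedf(src, [[1.0, 2.0]])[0] == 0.0

    def test_one_term_sum(self):
        src = WeightedPointSet([[0.0, 0.0], [3.0, 0.0]], [0.5, 0.5])
        assert pedf(src, [[0.0, 0.0]])[0] == pytest.approx(0.5 / 3.0)

    def test_matches_brute_force_double_loop(self, rng):
        srcs = rng.normal(size=(200, 3))
        w = rng.random(200)
        w /= w.sum()
        queries = rng.normal(size=(50, 3))
        got = pedf(WeightedPointSet(srcs, w), queries)
        expect = np.zeros(50)
        for i, q in enumerate(queries):
            for s, wn in zip(srcs, w):
                d = np.linalg.norm(q - s)
                if d > 0:
                    expect[i] += wn / d
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_exclude_radius_drops_near_sources(self):
        src = WeightedPointSet([[0.0, 0.0], [3.0, 0.0]], [0.5, 0.5])
        assert pedf(src, [[0.1, 0.0]], exclude_radius=0.5)[0] == pytest.approx(0.5 / 2.9)

    def test_dimension_mismatch(self):
        src = WeightedPointSet([[0.0, 0.0]], [1.0])
        with pytest.raises(DimensionMismatchError):
            pedf(src, [[0.0, 0.0, 0.0]])


class TestAdaptiveGamma:
    def test_constant_fields(self):
        assert adaptive_gamma([2, 2], [3, 3], [0.5, 0.5]) == pytest.approx(0.75)

    def test_equal_fields_give_half(self, rng):
        v = rng.random(20) + 0.1
        assert adaptive_gamma(v, v, np.full(20, 1 / 20)) == pytest.approx(0.5)

    def test_degenerate_density(self):
        with pytest.raises(DegenerateDensityError):
            adaptive_gamma([0.0, 0.0], [1.0, 1.0], [0.5, 0.5])

    def test_gamma_scales_linearly_with_coordinates(self):
        # analytic density of a 2-component mixture, sample-based PEDF
        from dfclust import MixtureDensity, density_at, sample_mixture

        model = MixtureDensity(
            weights=[0.5, 0.5], means=[[0, 0], [6, 0]], covariances=[np.eye(2)] * 2
        )
        data, _ = sample_mixture(model, 2000, seed=3)
        mass = np.full(2000, 1 / 2000)

        def gamma_of(X, mdl):
            rho = density_at(mdl, X)
            t = kedf(rho, 2)
            u = pedf(WeightedPointSet(X, mass), X)
            return adaptive_gamma(t, u, mass)

        s = 3.0
        scaled = MixtureDensity(
            weights=[0.5, 0.5],
            means=[[0, 0], [6 * s, 0]],
            covariances=[s**2 * np.eye(2)] * 2,
        )
        g1 = gamma_of(data, model)
        g2 = gamma_of(data * s, scaled)
        assert g2 / g1 == pytest.approx(s, rel=0.02)


class TestEnergyFields:
    def test_basic_assembly(self):
        fv = energy_fields([1.0], [1.0], 1.0)
        assert fv.H[0] == pytest.approx(2.0) and fv.L[0] == pytest.approx(0.0)

    def test_no_interaction_term(self):
        fv = energy_fields([1.0], [0.0], 2.0)
        assert fv.H[0] == pytest.approx(4.0) and fv.L[0] == pytest.approx(4.0)

    @given(st.integers(0, 2**31 - 1))
    def test_h_l_identities(self, seed):
        r = np.random.default_rng(seed)
        t, u, g = r.random(10), r.random(10), r.random() + 0.1
        fv = energy_fields(t, u, g)
        np.testing.assert_allclose((fv.H - fv.L) / (2 * g), u, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(fv.H + fv.L, 2 * g**2 * t, rtol=1e-9, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            energy_fields([1.0, 2.0], [1.0], 1.0)


class TestHFStatistic:
    def test_single_point(self):
        assert hf_statistic([1.0], [1.0], 1.0) == pytest.approx(2.0)

    def test_duplicating_points_halves_the_statistic(self, rng):
        t, u = rng.random(7), rng.random(7)
        one = hf_statistic(t, u, 0.7)
        two = hf_statistic(np.tile(t, 2), np.tile(u, 2), 0.7)
        assert two == pytest.approx(one / 2)

    def test_positive_on_fitted_single_cluster(self, rng):
        from dfclust import density_at, fit_mixture_em, gen_gaussian_case

        b = gen_gaussian_case(1, n_points=200, seed=4)
        model = fit_mixture_em(b.data, 1, seed=0)
        rho = density_at(model, b.data)
        t = kedf(rho, 2)
        mass = np.full(len(b.data), 1 / len(b.data))
        u = pedf(WeightedPointSet(b.data, mass), b.data)
        val = hf_statistic(t, u, adaptive_gamma(t, u, mass))
        assert np.isfinite(val) and val > 0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            hf_statistic([], [], 1.0)


class TestWeightedPointSet:
    def test_sample_weights_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            WeightedPointSet([[0.0], [1.0]], [0.4, 0.4], quadrature="sample")

    def test_grid_weights_unconstrained(self):
        s = WeightedPointSet([[0.0], [1.0]], [0.4, 0.4], quadrature="grid")
        assert s.n_points == 2

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DomainError):
            WeightedPointSet([[0.0]], [0.0], quadrature="grid")


def test_scale_free_energy_fields_at_n2000():
    """H and L per point change <3% (median relative) when all coordinates are
    rescaled and the density is re-estimated — the scale-freeness gamma buys."""
    from dfclust import MixtureDensity, density_at, fit_mixture_em, sample_mixture

    model = MixtureDensity(
        weights=[0.5, 0.5], means=[[0, 0], [5, 0]], covariances=[np.eye(2)] * 2
    )
    data, _ = sample_mixture(model, 2000, seed=1)
    mass = np.full(2000, 1 / 2000)

    def fields(X):
        mdl = fit_mixture_em(X, 2, seed=9)
        rho = density_at(mdl, X)
        t = kedf(rho, 2)
        u = pedf(WeightedPointSet(X, mass), X)
        return energy_fields(t, u, adaptive_gamma(t, u, mass))

    a = fields(data)
    b = fields(data * 2.5)
    med_h = np.median(np.abs(b.H - a.H) / np.abs(a.H))
    med_l = np.median(np.abs(b.L - a.L) / np.abs(a.L))
    assert med_h < 0.03 and med_l < 0.03
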