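import math

import numpy as np
import pytest

from mitoreticulum.config import SimulationConfig
from mitoreticulum.errors import OverloadedCytoskeletonError, ParameterError
from mitoreticulum.wlc_theory import (
    cap_area,
    crossing_density,
    crossing_density_asymptotic,
    end_to_end_pdf,
    occupancy,
    radial_density,
)


class TestOccupancy:
    def test_reference_value(self, ref_config):
        """M/(n_f (l2-l1)) = 1000/2900 at the reference cell."""
        eps = occupancy(ref_config)
        assert eps(5.0) == pytest.approx(0.34483, abs=1e-5)
        assert eps(0.5) == eps(15.0) == eps(5.0)  # uniform for psi = 0

    def test_zero_outside_support_and_bounds(self):
        for psi in (-0.2, 0.0, 0.2):
            eps = occupancy(SimulationConfig(psi=psi))
            rho = np.linspace(0, 16, 1601)
            v = eps(rho)
            assert np.all(v >= 0) and np.all(v <= 1 + 1e-12)
            assert np.all(v[rho < 0.5] == 0)
            assert np.all(v[rho > 15.0] == 0)

    @pytest.mark.parametrize("psi", [-0.2, 0.0, 0.2])
    def test_mass_conservation(self, psi):
        cfg = SimulationConfig(psi=psi)
        eps = occupancy(cfg)
        rho = np.linspace(cfg.l1, cfg.l2, 200001)
        mass = cfg.n_f * np.trapezoid(eps(rho), rho)
        assert mass == pytest.approx(cfg.M, rel=1e-5)

    def test_monotonicity_and_sign_flip_symmetry(self):
        cfg_p = SimulationConfig(psi=0.15)
        cfg_m = SimulationConfig(psi=-0.15)
        rho = np.linspace(0.5, 15.0, 500)
        up = occupancy(cfg_p)(rho)
        down = occupancy(cfg_m)(rho)
        assert np.all(np.diff(up) >= -1e-12)
        assert np.all(np.diff(down) <= 1e-12)
        # eps(rho; -psi) = eps(l1 + l2 - rho; psi)
        assert down == pytest.approx(occupancy(cfg_p)(cfg_p.l1 + cfg_p.l2 - rho), rel=1e-9)

    def test_saturated_profile_conserves_mass_and_caps_at_one(self):
        cfg = SimulationConfig(psi=-0.2)
        eps = occupancy(cfg)
        assert eps.saturated
        assert eps(0.6) == pytest.approx(1.0)
        rho = np.linspace(cfg.l1, cfg.l2, 200001)
        assert cfg.n_f * np.trapezoid(eps(rho), rho) == pytest.approx(cfg.M, rel=1e-5)

    def test_overload_raises(self):
        with pytest.raises(OverloadedCytoskeletonError):
            occupancy(SimulationConfig(M=3000.0))  # capacity is 2900 um

    def test_invalid_interval(self):
        with pytest.raises(ParameterError):
            occupancy(SimulationConfig(), l1=5.0, l2=2.0)


class TestEndToEndPdf:
    @pytest.mark.parametrize("L_p", [10.0, 32.0, 100.0])
    @pytest.mark.parametrize("rho", [2.0, 8.0, 16.0])
    def test_normalization(self, L_p, rho):
        r = np.linspace(0, rho, 8001)
        P = end_to_end_pdf(r, rho, L_p)
        assert np.all(P >= 0)
        assert np.trapezoid(P, r) == pytest.approx(1.0, abs=2e-4)

    def test_zero_beyond_contour(self):
        assert end_to_end_pdf(np.array([1.2]), 1.0, 32.0)[0] == 0.0

    def test_rigid_limit_concentrates_at_full_extension(self):
        rho = 1.0
        r = np.linspace(0, rho, 40001)
        P = end_to_end_pdf(r, rho, 100.0)  # L_p >> rho
        mean = np.trapezoid(P * r, r)
        # stiff expansion: <r> ~ rho (1 - 1/(6 kappa)) = 0.99833 rho
        assert mean > 0.995 * rho

    def test_series_branches_continuous_at_split(self):
        """The oscillating and dual (Hermite-type) series must agree where
        they hand over (y = kappa (1 - r/rho) = 0.3)."""
        L_p, rho = 32.0, 2.0  # kappa = 16
        kappa = L_p / rho
        r_split = rho * (1 - 0.3 / kappa)
        r = np.array([r_split * (1 - 1e-9), r_split * (1 + 1e-9)])
        P = end_to_end_pdf(r, rho, L_p, method="series")
        assert P[0] == pytest.approx(P[1], rel=1e-6)

    def test_series_and_spectral_agree_at_moderate_stiffness(self):
        """At kappa ~ 8 the stiff-limit series approaches the exact
        spectral evaluation (few-percent shape accuracy)."""
        rho, L_p = 2.0, 16.0  # kappa = 8
        r = np.linspace(0.5, rho, 2001)
        Ps = end_to_end_pdf(r, rho, L_p, method="series")
        Pt = end_to_end_pdf(r, rho, L_p, method="spectral")
        assert np.abs(Ps - Pt).max() < 0.05 * Pt.max()

    def test_method_validation(self):
        with pytest.raises(ParameterError):
            end_to_end_pdf(1.0, 2.0, 32.0, method="nope")
        with pytest.raises(ParameterError):
            end_to_end_pdf(1.0, 2.0, 320.0, method="spectral")  # kappa > table
        with pytest.raises(ParameterError):
            end_to_end_pdf(1.0, 2.0, -1.0)


class TestRadialDensities:
    def test_mass_conservation_all_drifts(
        self, ref_densities, densities_psi_neg, densities_psi_pos
    ):
        """int Q1 dr = M to 0.1% for psi in {-0.2, 0, 0.2} (the r-grid is
        segmented at the occupancy kinks l1, l2)."""
        for dens in (ref_densities, densities_psi_neg, densities_psi_pos):
            cfg = dens.config
            nodes, weights = [], []
            for a, b, n in [(0.0, cfg.l1, 32), (cfg.l1, cfg.l2, 256), (cfg.l2, cfg.L, 32)]:
                xg, wg = np.polynomial.legendre.leggauss(n)
                nodes.append(0.5 * (a + b) + 0.5 * (b - a) * xg)
                weights.append(0.5 * (b - a) * wg)
            r = np.concatenate(nodes)
            w = np.concatenate(weights)
            total = float(np.sum(w * radial_density(r, 1, cfg, eps=dens.eps)))
            assert total == pytest.approx(cfg.M, rel=1e-3)

    def test_uniform_occupancy_identity(self, ref_config, ref_densities):
        """psi = 0: Q2 = eps * Q1 pointwise (eps constant)."""
        r = np.array([2.0, 5.0, 9.0, 13.0])
        eps_val = ref_densities.eps(5.0)
        assert ref_densities.Q2(r) == pytest.approx(eps_val * ref_densities.Q1(r), rel=1e-9)

    def test_q2_below_q1(self, ref_densities, densities_psi_pos):
        r = np.linspace(0.6, 14.9, 100)
        for dens in (ref_densities, densities_psi_pos):
            assert np.all(dens.Q2(r) <= dens.Q1(r) + 1e-12)

    def test_invalid_power(self, ref_config):
        with pytest.raises(ParameterError):
            radial_density(1.0, 3, ref_config)


class TestCapArea:
    def test_center_value(self):
        """xi = r gives a hemisphere-free cap of area pi sigma^2 (algebraic
        substitution into the printed formula)."""
        assert cap_area(2.0, 2.0, 0.2) == pytest.approx(math.pi * 0.04)

    def test_vanishes_at_outer_contact(self):
        assert cap_area(2.2, 2.0, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_ball_volume_identity(self):
        """int A(xi, r) dxi over the ball recovers (4/3) pi sigma^3
        (numerical quadrature oracle)."""
        r, sigma = 2.0, 0.2
        xi = np.linspace(r - sigma, r + sigma, 40001)
        vol = np.trapezoid(cap_area(xi, r, sigma), xi)
        assert vol == pytest.approx(4.0 / 3.0 * math.pi * sigma**3, rel=1e-6)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            cap_area(3.0, 2.0, 0.2)
        with pytest.raises(ParameterError):
            cap_area(1.0, -2.0, 0.2)


class TestCrossingDensity:
    def test_zero_density_gives_zero_crossings(self, ref_config):
        S = crossing_density(
            np.array([2.0, 8.0]), 0, ref_config, Q_func=lambda x: np.zeros_like(x)
        )
        assert np.all(S == 0)

    def test_asymptotic_scalings(self):
        r = np.array([2.0, 8.0])
        base = crossing_density_asymptotic(r, np.array([10.0, 10.0]), 0.2)
        assert crossing_density_asymptotic(r, np.array([20.0, 20.0]), 0.2) == pytest.approx(
            4 * base
        )
        assert np.all(crossing_density_asymptotic(r, np.array([10.0, 10.0]), 1e-6) < 1e-12)

    def test_crossing_sharper_than_contour(self, ref_densities):
        """S11/Q1^2 falls like 1/r^2 in the bulk: the structural driver of
        the perinuclear/peripheral contrast."""
        ratio = lambda r: ref_densities.S11(np.array([r]))[0] / ref_densities.Q1(
            np.array([r])
        ) ** 2
        assert ratio(4.0) / ratio(12.0) == pytest.approx((12.0 / 4.0) ** 2, rel=0.1)

    def test_invalid_order(self, ref_config):
        with pytest.raises(ParameterError):
            crossing_density(1.0, 2, ref_config)
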