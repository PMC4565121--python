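import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoreticulum.config import SimulationConfig
from mitoreticulum.cytoskeleton_mc import (
    CytoskeletonArray,
    bond_angle_for_persistence,
    detect_crossings,
    estimate_persistence,
    generate_cytoskeleton,
    generate_frc_chain,
    persistence_from_bond,
    radial_histogram,
    _segment_pair_distance,
)
from mitoreticulum.errors import ParameterError

from conftest import straight_chain


class TestPersistenceBondRelation:
    @pytest.mark.parametrize(
        "a, theta, expected",
        [
            (0.02, 0.035355, 32.0),  # the reference MT stiffness
            (1.0, math.sqrt(2.0), 1.0),  # identity case
        ],
    )
    def test_forward(self, a, theta, expected):
        assert persistence_from_bond(a, theta) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize(
        "a, L_p, expected",
        [(0.02, 32.0, 0.0353553), (0.02, 10.0, 0.0632456)],
    )
    def test_inverse(self, a, L_p, expected):
        assert bond_angle_for_persistence(a, L_p) == pytest.approx(expected, rel=1e-5)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(1e-4, 1.0),
        L_p=st.floats(1e-3, 1e4),
    )
    def test_round_trip(self, a, L_p):
        from hypothesis import assume

        assume(2 * a / L_p < math.pi**2)  # FRC bond-angle resolution limit
        theta = bond_angle_for_persistence(a, L_p)
        assert persistence_from_bond(a, theta) == pytest.approx(L_p, rel=1e-12)

    @pytest.mark.parametrize(
        "call",
        [
            lambda: persistence_from_bond(-0.02, 0.1),
            lambda: persistence_from_bond(0.02, 0.0),
            lambda: persistence_from_bond(0.02, math.pi),
            lambda: bond_angle_for_persistence(0.02, -1.0),
            lambda: bond_angle_for_persistence(0.0, 1.0),
        ],
    )
    def test_domain_errors(self, call):
        with pytest.raises(ParameterError):
            call()


class TestChainGeneration:
    def test_construction_invariants(self):
        """Bond length, bond angle and bond count are exact by construction."""
        L, a, theta = 2.0, 0.02, 0.05
        chain = generate_frc_chain(L, a, theta, [0.0, 0.0, 1.0], seed=3)
        assert chain.n_bonds == int(L / a)
        assert chain.contour_length == pytest.approx(L)
        bonds = np.diff(chain.vertices, axis=0)
        assert np.linalg.norm(bonds, axis=1) == pytest.approx(a, rel=1e-12)
        t = chain.tangents()
        cos_angles = np.einsum("ij,ij->i", t[:-1], t[1:])
        assert cos_angles == pytest.approx(math.cos(theta), abs=1e-10)
        assert t[0] == pytest.approx([0.0, 0.0, 1.0])

    def test_rigid_rod_limit(self):
        chain = generate_frc_chain(1.0, 0.02, 0.0, [1.0, 0.0, 0.0], seed=0)
        assert chain.end_to_end() == pytest.approx(1.0, rel=1e-12)

    def test_zero_graft_direction_rejected(self):
        with pytest.raises(ParameterError):
            generate_frc_chain(1.0, 0.02, 0.1, [0.0, 0.0, 0.0])

    def test_mean_square_end_to_end_matches_wlc(self):
        """MC <R^2> agrees with 2 Lp L - 2 Lp^2 (1 - exp(-L/Lp)) within
        sampling error (closed-form oracle)."""
        L, L_p = 16.0, 32.0
        cfg = SimulationConfig(n_f=400, L=L, L_p=L_p, seed=11)
        arr = generate_cytoskeleton(cfg)
        r2 = np.array([c.end_to_end() ** 2 for c in arr.chains])
        exact = 2 * L_p * L - 2 * L_p**2 * (1 - math.exp(-L / L_p))
        se = r2.std(ddof=1) / math.sqrt(len(r2))
        assert abs(r2.mean() - exact) < 3 * se

    def test_graft_directions_uniform_on_sphere(self):
        """First and second spherical moments of the graft directions match
        the uniform distribution (oracle: 0 and I/3)."""
        cfg = SimulationConfig(n_f=2000, L=0.1, seed=21)
        arr = generate_cytoskeleton(cfg)
        u = np.stack([c.tangents()[0] for c in arr.chains])
        n = len(u)
        assert np.abs(u.mean(axis=0)).max() < 4 / math.sqrt(3 * n)
        second = u[:, :, None] * u[:, None, :]
        dev = second.mean(axis=0) - np.eye(3) / 3
        assert np.abs(dev).max() < 4 / math.sqrt(n)

    def test_seed_reproducibility_and_extension(self):
        cfg = SimulationConfig(n_f=5, L=1.0, seed=42)
        a1 = generate_cytoskeleton(cfg)
        a2 = generate_cytoskeleton(cfg)
        for c1, c2 in zip(a1.chains, a2.chains):
            assert np.array_equal(c1.vertices, c2.vertices)
        # growing n_f must not reshuffle the existing chains
        a3 = generate_cytoskeleton(SimulationConfig(n_f=8, L=1.0, seed=42))
        for c1, c3 in zip(a1.chains, a3.chains):
            assert np.array_equal(c1.vertices, c3.vertices)


class TestCrossingDetection:
    def test_orthogonal_chains_single_crossing(self):
        a = straight_chain([0.0, -0.5, 0.0], [0.0, 1.0, 0.0], L=1.0)
        b = straight_chain([-0.5, 0.0, 0.05], [1.0, 0.0, 0.0], L=1.0)
        arr = CytoskeletonArray(chains=[a, b], seed=0, sigma=0.2)
        cs = detect_crossings(arr, 0.2)
        assert len(cs) == 1
        assert cs.d[0] == pytest.approx(0.05, abs=1e-6)
        assert cs.rho_i[0] == pytest.approx(0.5, abs=0.02)
        assert cs.rho_j[0] == pytest.approx(0.5, abs=0.02)

    def test_parallel_chains_no_crossing(self):
        a = straight_chain([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], L=1.0)
        b = straight_chain([0.0, 0.4, 0.0], [1.0, 0.0, 0.0], L=1.0)
        arr = CytoskeletonArray(chains=[a, b], seed=0, sigma=0.2)
        assert len(detect_crossings(arr, 0.2)) == 0

    def test_order_and_rotation_invariance(self):
        cfg = SimulationConfig(n_f=8, L=4.0, L_p=10.0, seed=5)
        arr = generate_cytoskeleton(cfg)
        cs = detect_crossings(arr, cfg.sigma)
        # chain order
        rev = CytoskeletonArray(chains=arr.chains[::-1], seed=0, sigma=cfg.sigma)
        cs_rev = detect_crossings(rev, cfg.sigma)
        assert len(cs) == len(cs_rev)
        n = cfg.n_f
        pairs = sorted(zip(cs.chain_i, cs.chain_j))
        pairs_rev = sorted(zip(n - 1 - cs_rev.chain_j, n - 1 - cs_rev.chain_i))
        assert pairs == pairs_rev
        # global rotation
        rng = np.random.default_rng(0)
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot = CytoskeletonArray(
            chains=[
                type(c)(vertices=c.vertices @ q.T, bond_length=c.bond_length, bond_angle=c.bond_angle)
                for c in arr.chains
            ],
            seed=0,
            sigma=cfg.sigma,
        )
        cs_rot = detect_crossings(rot, cfg.sigma)
        assert len(cs_rot) == len(cs)
        assert np.sort(cs_rot.r) == pytest.approx(np.sort(cs.r), abs=1e-8)

    def test_prune_matches_brute_force(self):
        """The KD-tree candidate prune must reproduce the all-pairs scan."""
        cfg = SimulationConfig(n_f=6, L=2.0, L_p=5.0, seed=9)
        arr = generate_cytoskeleton(cfg)
        cs = detect_crossings(arr, cfg.sigma)
        verts = arr.vertex_array()
        n_f, n_v, _ = verts.shape
        found = set()
        for i in range(n_f):
            for j in range(i + 1, n_f):
                p1 = np.repeat(verts[i, :-1], n_v - 1, axis=0)
                d1 = np.repeat(verts[i, 1:] - verts[i, :-1], n_v - 1, axis=0)
                p2 = np.tile(verts[j, :-1], (n_v - 1, 1))
                d2 = np.tile(verts[j, 1:] - verts[j, :-1], (n_v - 1, 1))
                dist, _, _ = _segment_pair_distance(p1, d1, p2, d2)
                if (dist < cfg.sigma).any():
                    found.add((i, j))
        assert found == set(zip(cs.chain_i, cs.chain_j))


class TestRadialEstimators:
    def test_straight_chain_uniform_profile(self):
        chain = straight_chain([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], L=1.0)
        arr = CytoskeletonArray(chains=[chain], seed=0)
        r, dens = radial_histogram(arr, dr=0.1, L=1.0)
        assert dens[:10] == pytest.approx(np.ones(10), rel=1e-9)

    def test_contour_conservation(self):
        cfg = SimulationConfig(n_f=20, L=2.0, L_p=10.0, seed=1)
        arr = generate_cytoskeleton(cfg)
        r, dens = radial_histogram(arr, dr=0.05, L=4.0)
        total = dens.sum() * 0.05
        assert total == pytest.approx(cfg.n_f * cfg.L, rel=1e-9)

    def test_histogram_rejects_bad_input(self):
        with pytest.raises(ParameterError):
            radial_histogram(object(), dr=0.1)


class TestPersistenceEstimation:
    def test_frc_estimate_matches_closed_form(self):
        """Tangent-correlation fit recovers 2a/theta^2 (closed-form oracle)."""
        cfg = SimulationConfig(n_f=100, L=16.0, L_p=10.0, seed=2)
        arr = generate_cytoskeleton(cfg)
        fit = estimate_persistence(arr)
        assert fit.reliable
        assert fit.L_p == pytest.approx(10.0, rel=0.15)

    def test_rigid_chains_flagged(self):
        chains = [
            generate_frc_chain(1.0, 0.02, 0.0, [0.0, 0.0, 1.0], seed=s) for s in range(3)
        ]
        fit = estimate_persistence(chains)
        assert not fit.reliable

    def test_too_short_chain_rejected(self):
        chain = straight_chain([0, 0, 0], [1, 0, 0], L=0.02)
        with pytest.raises(ParameterError):
            estimate_persistence([chain])
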