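"""Helical stepping, condensed-history transport, and run-level invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betamag import physics, transport
from betamag.physics import ParticleState
from betamag.transport import (
    HitCloud,
    TransportConfig,
    helix_advance,
    run_simulation,
    transport_particle,
)


class TestKernelPhysicsConsistency:
    """The numba scalar kernels must agree with the reference formulas."""

    def test_stopping_power(self):
        ts = np.geomspace(0.011, 5.0, 40)
        ref = physics.collision_stopping_power(ts)
        got = np.array([transport._nb_stopping(t, 1.0, 75.0, 0.5551) for t in ts])
        np.testing.assert_allclose(got, ref, rtol=1e-12)

    def test_momentum(self):
        for t in (0.01, 0.5, 2.28):
            assert transport._nb_momentum(t) == pytest.approx(
                physics.momentum_from_kinetic(t), rel=1e-12)

    def test_highland(self):
        for t, s in ((0.1, 0.05), (1.0, 0.1), (2.0, 1.0)):
            assert transport._nb_highland(t, s, 1.0, 36.08) == pytest.approx(
                physics.highland_sigma(t, s), rel=1e-12)

    def test_beta_density(self):
        ts = np.linspace(0.05, 2.25, 20)
        ref = physics.beta_spectrum_density(ts)
        got = np.array([transport._nb_beta_density(t, 2.28, 40.0) for t in ts])
        np.testing.assert_allclose(got, ref, rtol=1e-12)

    def test_cumulative_step_sigma_quadrature(self):
        # summed in quadrature, per-step widths reconstruct the full-path width
        total = 1.0
        n = 100
        acc = 0.0
        for i in range(n):
            s = transport._nb_step_sigma(1.0, total / n, i * total / n, 1.0, 36.08)
            acc += s * s
        assert np.sqrt(acc) == pytest.approx(physics.highland_sigma(1.0, total),
                                             rel=1e-9)


class TestHelixAdvance:
    def test_zero_field_straight_line(self):
        s = ParticleState(np.zeros(3), np.array([0.6, 0.0, 0.8]), 1.0)
        out = helix_advance(s, np.zeros(3), 2.5)
        np.testing.assert_allclose(out.position, [1.5, 0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(out.direction, s.direction)
        assert out.kinetic_energy == s.kinetic_energy

    def test_parallel_motion_unaffected_by_field(self):
        s = ParticleState(np.zeros(3), np.array([1.0, 0.0, 0.0]), 1.0)
        out = helix_advance(s, np.array([3.0, 0.0, 0.0]), 1.0)
        np.testing.assert_allclose(out.position, [1.0, 0.0, 0.0], atol=1e-12)

    def test_full_gyroperiod_closes_circle(self):
        T, B = 2.0, 2.0
        r = physics.gyroradius(T, B, 1.0)
        period = 2 * np.pi * r  # perpendicular launch: arc of one turn
        n = 1000
        s = ParticleState(np.zeros(3), np.array([0.0, 0.0, 1.0]), T)
        zs = []
        for _ in range(n):
            s = helix_advance(s, np.array([B, 0.0, 0.0]), period / n)
            zs.append(s.position[2])
        np.testing.assert_allclose(s.direction, [0.0, 0.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(s.position, 0.0, atol=1e-9)
        # perpendicular-plane extent of the sampled circle is one diameter
        assert max(zs) - min(zs) == pytest.approx(2 * r, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_preserves_norm_and_energy(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        s = ParticleState(rng.standard_normal(3), u, float(rng.uniform(0.05, 3)))
        out = helix_advance(s, rng.standard_normal(3), float(rng.uniform(0.01, 1)))
        assert np.linalg.norm(out.direction) == pytest.approx(1.0, abs=1e-12)
        assert out.kinetic_energy == s.kinetic_energy


class TestTransportParticle:
    CFG = TransportConfig(source_energy=2.0, n_particles=1, seed=4)

    def test_subcutoff_birth_absorbed_at_source(self):
        st0 = ParticleState(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 1.0]), 0.005)
        hits = transport_particle(st0, self.CFG)
        assert len(hits) == 1
        np.testing.assert_allclose(hits[0].position, [1.0, 2.0, 3.0])
        assert hits[0].deposited_energy == pytest.approx(0.005)

    def test_outside_sphere_rejected(self):
        st0 = ParticleState(np.array([20.0, 0, 0]), np.array([0, 0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            transport_particle(st0, self.CFG)

    def test_csda_straight_line_displacement(self):
        cfg = dataclasses.replace(self.CFG, scattering=False)
        st0 = ParticleState(np.zeros(3), np.array([0, 0, 1.0]), 2.0)
        hits = transport_particle(st0, cfg)
        disp = np.linalg.norm(hits[-1].position)
        assert disp == pytest.approx(physics.csda_range(2.0),
                                     abs=cfg.max_step_length)

    def test_helix_confinement_bound(self):
        cfg = dataclasses.replace(self.CFG, B_magnitude=3.0, scattering=False)
        st0 = ParticleState(np.zeros(3), np.array([0, 0, 1.0]), 2.0)
        hits = transport_particle(st0, cfg)
        rho = np.array([np.hypot(h.position[1], h.position[2]) for h in hits])
        bound = 2 * physics.gyroradius(2.0, 3.0) + cfg.max_step_length
        assert rho.max() <= bound


class TestRunSimulation:
    def test_deterministic(self):
        cfg = TransportConfig(source_energy=1.0, n_particles=1, seed=99)
        a, b = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.dE, b.dE)

    def test_chunk_independent_substreams(self):
        cfg = TransportConfig(source_energy=1.0, n_particles=500, seed=13)
        a = run_simulation(cfg, chunk_size=100)
        b = run_simulation(cfg, chunk_size=500)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.particle_id, b.particle_id)

    def test_range_bound_at_zero_field(self, small_run_0T):
        r = np.sqrt(small_run_0T.x.astype(float) ** 2
                    + small_run_0T.y.astype(float) ** 2
                    + small_run_0T.z.astype(float) ** 2)
        assert r.max() <= physics.csda_range(2.0) + 0.1

    def test_isotropy_mean_position(self, small_run_0T):
        # hits within one history are correlated, so average per history first
        cloud = small_run_0T
        n = cloud.n_particles
        counts = np.bincount(cloud.particle_id, minlength=n)
        for axis in "xyz":
            sums = np.zeros(n)
            np.add.at(sums, cloud.particle_id, cloud.coord(axis).astype(float))
            per_hist = sums / np.maximum(counts, 1)
            assert abs(per_hist.mean()) < 3 * per_hist.std() / np.sqrt(n)

    def test_energy_conservation(self, small_run_0T):
        assert np.abs(small_run_0T.energy_balance()).max() < 1e-6

    def test_energy_conservation_with_escape(self):
        cfg = TransportConfig(source_energy=2.0, n_particles=500, seed=21,
                              sphere_radius=2.0)
        cloud = run_simulation(cfg)
        assert cloud.escaped_energy.sum() > 0
        assert np.abs(cloud.energy_balance()).max() < 1e-6
        r = np.sqrt(cloud.x.astype(float) ** 2 + cloud.y.astype(float) ** 2
                    + cloud.z.astype(float) ** 2)
        assert r.max() <= 2.0  # hits only inside the sphere

    def test_axial_symmetry_about_field(self, small_run_3T):
        ey = np.percentile(np.abs(small_run_3T.y.astype(float)), 99.5)
        ez = np.percentile(np.abs(small_run_3T.z.astype(float)), 99.5)
        assert abs(ey - ez) / ey < 0.05

    def test_step_convergence(self):
        base = TransportConfig(source_energy=2.0, n_particles=30_000,
                               B_magnitude=2.0, seed=7)
        fine = dataclasses.replace(base, max_step_length=0.05,
                                   max_fractional_energy_loss_per_step=0.01)
        ca, cb = run_simulation(base), run_simulation(fine)
        for axis in "xyz":
            ea = np.percentile(np.abs(ca.coord(axis).astype(float)), 99.5)
            eb = np.percentile(np.abs(cb.coord(axis).astype(float)), 99.5)
            assert abs(ea - eb) / ea < 0.02


class TestSerialization:
    def test_npz_roundtrip(self, small_run_3T, tmp_path):
        p = tmp_path / "cloud.npz"
        small_run_3T.to_npz(p)
        back = HitCloud.from_npz(p)
        np.testing.assert_array_equal(back.x, small_run_3T.x)
        np.testing.assert_array_equal(back.dE, small_run_3T.dE)
        assert back.config == small_run_3T.config

    def test_csv_has_config_header(self, tmp_path):
        cfg = TransportConfig(source_energy=0.5, n_particles=5, seed=1)
        cloud = run_simulation(cfg)
        p = tmp_path / "cloud.csv"
        cloud.to_csv(p)
        text = p.read_text()
        assert text.startswith("# config=")
        assert "particle_id,x,y,z,dE" in text
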