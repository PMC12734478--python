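"""Particle tracking, capture, batch challenge, and LRV statistics."""

import math

import numpy as np
import pytest

from conftest import make_duct
from poreflow import (
    ChallengeConfig,
    Particle,
    VoxelStructure,
    compute_lrv,
    run_batch_challenge,
    seed_particles,
    solve_stokes,
    stokes_einstein_diffusivity,
    track_particle,
)
from poreflow.transport import capture_depth_profile, rasterize_spheres
from poreflow.stokes import FlowField


class TestLRV:
    def test_full_retention_750_reports_287(self):
        lrv = compute_lrv(750, 0)
        assert lrv.lower_bound
        assert lrv.report(2) == 2.87
        assert lrv.value == pytest.approx(math.log10(751))

    def test_full_retention_3750_reports_357(self):
        lrv = compute_lrv(3750, 0)
        assert lrv.lower_bound
        assert lrv.report(2) == 3.57

    def test_partial_transmission_is_exact_log(self):
        lrv = compute_lrv(100, 1)
        assert not lrv.lower_bound
        assert lrv.value == pytest.approx(2.0)
        assert lrv.report(2) == 2.0

    def test_more_out_than_in_is_an_error(self):
        with pytest.raises(ValueError):
            compute_lrv(10, 11)
        with pytest.raises(ValueError):
            compute_lrv(0, 0)


@pytest.fixture(scope="module")
def duct_field():
    s = make_duct(16, 16)
    f = solve_stokes(s, n_buffer_in=17)  # covers the 100 nm offset
    return s, f


class TestSeeding:
    def test_canonical_20x15_grid_gives_300_unique_positions(self, membrane_small):
        f = solve_stokes(membrane_small, n_buffer_in=17)
        pos = seed_particles(0, membrane_small, f, mode="grid", grid_shape=(20, 15))
        assert pos.shape == (300, 3)
        assert len(np.unique(pos[:, :2], axis=0)) == 300

    def test_axial_coordinate_is_offset_above_inlet(self, duct_field):
        s, f = duct_field
        pos = seed_particles(50, s, f, offset_nm=100.0, seed=3)
        z_inlet = f.n_buffer_in * s.voxel_size_nm
        assert np.allclose(pos[:, 2], z_inlet - 100.0)

    def test_same_seed_reproduces_positions(self, duct_field):
        s, f = duct_field
        a = seed_particles(40, s, f, seed=9)
        b = seed_particles(40, s, f, seed=9)
        assert np.array_equal(a, b)

    def test_grid_larger_than_face_is_an_error(self, duct_field):
        s, f = duct_field
        with pytest.raises(ValueError, match="larger than"):
            seed_particles(0, s, f, mode="grid", grid_shape=(100, 100))

    def test_offset_beyond_buffer_seeds_above_solved_domain(self):
        """Seeds farther above the inlet than the solved buffer get
        negative axial coordinates (tracked kinematically)."""
        s = make_duct(8, 12)
        f = solve_stokes(s)  # 3-layer buffer = 21 nm
        pos = seed_particles(10, s, f, offset_nm=100.0, seed=1)
        assert np.allclose(pos[:, 2], 3 * 7.0 - 100.0)


class TestTracking:
    def test_point_tracer_follows_straight_streamline(self):
        """D = 0 tracer seeded off-axis in a duct: the analytic
        streamline is a straight line at constant lateral position."""
        s = make_duct(16, 32)
        f = solve_stokes(s, n_buffer_in=17, buffer_mode="extend")
        x0 = np.array([5 * 7.0, 8 * 7.0, 10 * 7.0])
        p = Particle(position=x0.copy(), diameter_nm=0.0)
        p = track_particle(p, f, s, diffusivity_m2_s=0.0, seed=0, record_trajectory_every=5)
        assert p.fate == "transmitted"
        traj = p.trajectory
        assert np.abs(traj[:, 0] - x0[0]).max() < 0.5  # nm
        assert np.abs(traj[:, 1] - x0[1]).max() < 0.5

    def test_tracer_in_open_duct_is_never_captured(self):
        s = make_duct(16, 32)
        f = solve_stokes(s, n_buffer_in=17)
        for y in (6.0, 10.0):
            p = Particle(position=np.array([8 * 7.0, y * 7.0, 30.0]), diameter_nm=0.0)
            p = track_particle(p, f, s, diffusivity_m2_s=0.0, seed=1)
            assert p.fate == "transmitted"

    def test_particle_wedges_in_subdiameter_throat(self):
        """A 20 nm particle carried into a 14 nm constriction is captured
        there by geometric confinement."""
        grid = np.zeros((10, 10, 32), bool)
        grid[2:8, 2:8, :16] = True  # 42 nm wide entry channel
        grid[4:6, 4:6, 16:] = True  # 14 nm exit throat
        s = VoxelStructure(grid, 7.0)
        f = solve_stokes(s, n_buffer_in=17)
        p = Particle(position=np.array([5 * 7.0, 5 * 7.0, 40.0]), diameter_nm=20.0)
        p = track_particle(p, f, s, seed=4)
        assert p.fate == "captured"
        # capture at/before the throat (z <= throat entrance + margin)
        z_throat = (f.n_buffer_in + 16) * 7.0
        assert p.capture_position[2] <= z_throat + 21.0

    def test_seeding_inside_solid_is_an_error(self):
        s = make_duct(8, 16)
        f = solve_stokes(s)
        p = Particle(position=np.array([3.5, 3.5, 56.0]), diameter_nm=20.0)  # in the wall
        with pytest.raises(ValueError, match="solid"):
            track_particle(p, f, s, seed=0)

    def test_brownian_msd_matches_stokes_einstein(self, brownian_msd_stats):
        """Quiescent box: ensemble MSD after n steps must equal 6*D*t
        within 5% (D = kT/(3 pi mu d) ~ 2.1e-11 m^2/s for 20 nm at 293 K)."""
        D = stokes_einstein_diffusivity(20.0, 293.15, 1.0e-3)
        assert D == pytest.approx(2.14e-11, rel=0.02)
        msd, t, D_used = brownian_msd_stats
        assert D_used == D
        assert msd == pytest.approx(6.0 * D * t, rel=0.05)


class TestRasterization:
    def test_sphere_volume_is_conserved(self):
        h = 7.0
        r = 10.0
        out = rasterize_spheres(np.array([[35.0, 35.0, 35.0]]), r, (10, 10, 10), h)
        vol = out.sum() * h**3
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * r**3, rel=0.02)

    def test_fractions_bounded_by_one_per_sphere(self):
        out = rasterize_spheres(np.array([[35.0, 35.0, 35.0]]), 10.0, (10, 10, 10), 7.0)
        assert out.max() <= 1.0


@pytest.fixture(scope="module")
def small_run(membrane_small):
    cfg = ChallengeConfig(n_batches=3, batch_size=6, ghosts_per_batch=4, max_steps=60_000)
    return run_batch_challenge(membrane_small, cfg, seed=21)


class TestBatchChallenge:

    def test_bookkeeping_is_conserved(self, small_run):
        r = small_run
        for b in range(3):
            assert r.captured_real[b] + r.transmitted_real[b] + r.in_transit_real[b] == 6
            assert r.captured_ghost[b] + r.transmitted_ghost[b] + r.in_transit_ghost[b] == 4

    def test_blocked_voxels_were_pore(self, membrane_small, small_run):
        for blocked in small_run.blocked_voxels:
            for ijk in blocked:
                assert membrane_small.grid[tuple(ijk)]

    def test_permeability_non_increasing(self, small_run):
        k = small_run.permeability_per_batch
        assert all(k[i + 1] <= k[i] * (1 + 1e-6) for i in range(len(k) - 1))

    def test_ghost_designation_does_not_change_fates(self, membrane_small):
        """With blocking disabled the geometry never changes, so the
        same seed slots produce identical fates whether the particles
        are labelled real or ghost."""
        cfg_real = ChallengeConfig(
            n_batches=2, batch_size=8, ghosts_per_batch=0,
            blocking_enabled=False, max_steps=40_000,
        )
        cfg_split = ChallengeConfig(
            n_batches=2, batch_size=4, ghosts_per_batch=4,
            blocking_enabled=False, max_steps=40_000,
        )
        a = run_batch_challenge(membrane_small, cfg_real, seed=33)
        b = run_batch_challenge(membrane_small, cfg_split, seed=33)
        for batch in range(2):
            assert (
                a.captured_real[batch]
                == b.captured_real[batch] + b.captured_ghost[batch]
            )

    def test_capture_depth_profile_conserves_counts(self, small_run):
        prof = capture_depth_profile(small_run)
        assert prof.counts.sum() == prof.n_captured
        assert prof.n_captured == sum(small_run.captured_real) + sum(small_run.captured_ghost)

    def test_single_depth_profile_mean(self):
        from poreflow.transport import BatchChallengeResult

        cfg = ChallengeConfig(n_batches=1, batch_size=1)
        r = BatchChallengeResult(config=cfg, n_buffer_in=3)
        r.capture_positions_nm.append(np.array([[10.0, 10.0, 3 * 7.0 + 500.0]]))
        r.final_structure = VoxelStructure(np.ones((4, 4, 100), bool), 7.0)
        prof = capture_depth_profile(r)
        assert prof.mean_um == pytest.approx(0.5)
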