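"""Stokes solver checks against closed-form duct/tube solutions.

The duct oracle is the classical rectangular-duct series solution; the
tube oracle is Hagen–Poiseuille.  Both use the ``extend`` buffer mode
so the geometry is translation-invariant and the closed forms apply
without open-end entrance corrections.  The multigrid backend is also
cross-checked against the independent direct (Schur/LU) backend on a
random membrane.
"""

import numpy as np
import pytest

from conftest import make_duct, make_tube
from poreflow import (
    VoxelStructure,
    flux_ratio,
    permeability,
    solve_stokes,
    verify_pressure_match,
)
from poreflow.stokes import LMH_PER_KPA, PercolationError


def duct_flow_rate(a_m: float, dpdz_pa_m: float, mu: float, n_terms: int = 50) -> float:
    """Series solution for volumetric flow in a square duct of side a.

    Q = (a^4 dp/dz / (12 mu)) * [1 - 192/pi^5 * sum_{n odd} tanh(n pi/2)/n^5],
    the aspect-ratio-1 case of the rectangular-duct Fourier solution
    (numerically Q ≈ 0.035144 a^4 dp/dz / mu).
    """
    s = sum(np.tanh((2 * i + 1) * np.pi / 2.0) / (2 * i + 1) ** 5 for i in range(n_terms))
    coeff = (1.0 - 192.0 / np.pi**5 * s) / 12.0
    return coeff * a_m**4 * dpdz_pa_m / mu


def tube_flow_rate(r_m: float, dpdz_pa_m: float, mu: float) -> float:
    return np.pi * r_m**4 * dpdz_pa_m / (8.0 * mu)


class TestDuctOracle:
    def test_square_duct_flow_within_5pct_of_series(self):
        width, length = 32, 24
        s = make_duct(width, length)
        f = solve_stokes(s, buffer_mode="extend")
        h_m = s.voxel_size_nm * 1e-9
        dpdz = f.delta_p_kpa * 1e3 / (length * h_m)
        q_ref = duct_flow_rate(width * h_m, dpdz, f.viscosity_pa_s)
        q = f.exit_flux()
        assert q == pytest.approx(q_ref, rel=0.05)

    def test_grid_convergence_is_monotone(self):
        errors = []
        for width in (16, 32, 64):
            s = make_duct(width, 12)
            f = solve_stokes(s, buffer_mode="extend")
            h_m = s.voxel_size_nm * 1e-9
            dpdz = f.delta_p_kpa * 1e3 / (12 * h_m)
            q_ref = duct_flow_rate(width * h_m, dpdz, f.viscosity_pa_s)
            errors.append(abs(f.exit_flux() - q_ref) / q_ref)
        assert errors[0] > errors[1] > errors[2]

    def test_blocked_cross_section_raises_percolation_error(self):
        s = make_duct(8, 16)
        grid = s.grid.copy()
        grid[:, :, 8] = False
        with pytest.raises(PercolationError):
            solve_stokes(VoxelStructure(grid))

    def test_linearity_in_pressure(self):
        s = make_duct(8, 12)
        f1 = solve_stokes(s, delta_p_kpa=105.0, buffer_mode="extend")
        f2 = solve_stokes(s, delta_p_kpa=210.0, buffer_mode="extend")
        assert np.allclose(f2.w, 2.0 * f1.w, rtol=1e-6, atol=abs(f2.w).max() * 1e-9)


class TestPermeability:
    def test_tube_matches_hagen_poiseuille_within_5pct(self):
        diameter, length = 24, 32
        s = make_tube(diameter, length)
        f = solve_stokes(s, buffer_mode="extend")
        k = permeability(f, s)
        h_m = s.voxel_size_nm * 1e-9
        # effective radius from the voxelized cross-section area
        n_pore = s.grid[:, :, 0].sum()
        r_eff = np.sqrt(n_pore * h_m**2 / np.pi)
        area = np.prod(s.shape[:2]) * h_m**2
        dpdz = f.delta_p_kpa * 1e3 / (length * h_m)
        kappa_ref = tube_flow_rate(r_eff, dpdz, f.viscosity_pa_s) / area / (
            f.delta_p_kpa * 1e3
        ) / LMH_PER_KPA
        assert k.kappa == pytest.approx(kappa_ref, rel=0.05)

    def test_kappa_independent_of_applied_pressure(self):
        s = make_duct(8, 12)
        k1 = permeability(solve_stokes(s, delta_p_kpa=105.0), s)
        k2 = permeability(solve_stokes(s, delta_p_kpa=210.0), s)
        assert k1.kappa == pytest.approx(k2.kappa, rel=1e-9)

    def test_blocking_single_voxels_never_increases_kappa(self, membrane_small):
        """Superset monotonicity probed by closing individual pore throats."""
        s = membrane_small
        base = permeability(solve_stokes(s, rtol=1e-9), s).kappa
        rng = np.random.default_rng(0)
        pores = np.argwhere(s.grid)
        for idx in rng.choice(len(pores), size=3, replace=False):
            grid = s.grid.copy()
            grid[tuple(pores[idx])] = False
            blocked = VoxelStructure(grid, s.voxel_size_nm)
            if not blocked.percolates():
                continue
            k = permeability(solve_stokes(blocked, rtol=1e-9), blocked).kappa
            assert k <= base * (1.0 + 1e-6)

    def test_mass_conservation_across_planes(self, membrane_small):
        f = solve_stokes(membrane_small)
        fluxes = [f.plane_flux(k) for k in range(f.w.shape[2])]
        mean = np.mean(fluxes)
        assert np.max(np.abs(np.array(fluxes) - mean)) <= 1e-3 * abs(mean)


class TestBackendsAgree:
    def test_mg_and_direct_give_same_field(self, membrane_small):
        """The multigrid-preconditioned solve must reproduce the
        independent exact-factorization Schur solve."""
        f_mg = solve_stokes(membrane_small, method="mg", rtol=1e-10)
        f_lu = solve_stokes(membrane_small, method="direct", rtol=1e-11)
        k_mg = permeability(f_mg, membrane_small).kappa
        k_lu = permeability(f_lu, membrane_small).kappa
        assert k_mg == pytest.approx(k_lu, rel=1e-5)
        scale = np.abs(f_lu.w).max()
        assert np.allclose(f_mg.w, f_lu.w, atol=1e-5 * scale)


class TestReporting:
    def test_flux_ratio_reporting(self):
        assert flux_ratio(3.5, 5.9) == 0.59
        assert flux_ratio(2.9, 5.9) == 0.49
        assert flux_ratio(5.9, 5.9) == 1.00

    def test_flux_ratio_zero_clean_is_error(self):
        with pytest.raises(ValueError):
            flux_ratio(1.0, 0.0)

    def test_pressure_match_tolerance(self, membrane_small):
        f = solve_stokes(membrane_small, delta_p_kpa=210.0)
        ok, achieved = verify_pressure_match(f, 210.0, rel_tol=1e-3)
        assert ok
        assert abs(achieved - 210.0) <= 0.21

    def test_pressure_match_rejects_mismatch(self, membrane_small):
        f = solve_stokes(membrane_small, delta_p_kpa=210.0)
        off = f.scaled(1.0 + 2e-3)  # off by 2x the tolerance
        ok, _ = verify_pressure_match(off, 210.0, rel_tol=1e-3)
        assert not ok

    def test_divergent_field_refuses_permeability(self, membrane_small):
        f = solve_stokes(membrane_small)
        f.max_divergence = 1.0
        with pytest.raises(RuntimeError, match="divergence"):
            permeability(f, membrane_small)
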