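"""Shared fixtures.

Expensive artifacts (the default membrane, its fouling calibrations,
and the full batch challenge) are session-scoped so acceptance-level
checks can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from poreflow import (
    ChallengeConfig,
    MembraneProfile,
    generate_membrane,
    run_batch_challenge,
)
from poreflow.render import RenderSpec, render_stack
from poreflow.synthetic import calibrate_fouling, substream


def make_duct(width: int, length: int, voxel_size_nm: float = 7.0):
    """Square duct of `width` pore voxels through a solid block."""
    from poreflow import VoxelStructure

    n = width + 2
    grid = np.zeros((n, n, length), dtype=bool)
    grid[1:-1, 1:-1, :] = True
    return VoxelStructure(grid, voxel_size_nm, provenance=f"duct({width})")


def make_tube(diameter: int, length: int, voxel_size_nm: float = 7.0):
    """Voxelized cylindrical tube through a solid block."""
    from poreflow import VoxelStructure

    n = diameter + 2
    r = diameter / 2.0
    c = n / 2.0
    ii, jj = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5, indexing="ij")
    disk = (ii - c) ** 2 + (jj - c) ** 2 < r**2
    grid = np.repeat(disk[:, :, None], length, axis=2)
    return VoxelStructure(grid, voxel_size_nm, provenance=f"tube(d={diameter})")


@pytest.fixture(scope="session")
def membrane_small():
    """32³ default-profile membrane for fast structural tests."""
    return generate_membrane(MembraneProfile.default(thickness_um=32 * 7e-3), (32, 32, 32), seed=11)


@pytest.fixture(scope="session")
def membrane_default():
    """The 64³ default asymmetric membrane used by flow-level checks."""
    return generate_membrane(MembraneProfile.default(thickness_um=64 * 7e-3), (64, 64, 64), seed=42)


@pytest.fixture(scope="session")
def rendered_fixture():
    """Rendered stack of a 48³ membrane with known drift/gradient/noise."""
    s = generate_membrane(MembraneProfile.default(thickness_um=48 * 7e-3), (48, 48, 48), seed=5)
    rng = substream(11, "drift")
    drift = rng.integers(-5, 6, size=(48, 2))
    drift[0] = 0
    spec = RenderSpec(
        drift=drift, depth_gradient=np.linspace(1.0, 2.0, 48), noise_sd=6.0
    )
    stack, truth = render_stack(s, spec, seed=6)
    return stack, truth


@pytest.fixture(scope="session")
def calibration_06(membrane_default):
    """Fouling calibrated to J/J0 = 0.6 ± 0.05 on the default membrane."""
    return calibrate_fouling(membrane_default, 0.6, tol=0.05, seed=42, solver_kwargs={"rtol": 1e-7})


@pytest.fixture(scope="session")
def calibration_01(membrane_default):
    """Fouling calibrated to J/J0 = 0.1 ± 0.05 on the default membrane."""
    return calibrate_fouling(membrane_default, 0.1, tol=0.05, seed=42, solver_kwargs={"rtol": 1e-7})


@pytest.fixture(scope="session")
def brownian_msd_stats():
    """Ensemble MSD of 20 nm particles in a quiescent open box.

    Returns (measured MSD, elapsed time, diffusivity) averaged over 600
    deterministic walkers of 2000 steps each.
    """
    from poreflow import Particle, VoxelStructure, stokes_einstein_diffusivity, track_particle
    from poreflow.stokes import FlowField

    D = stokes_einstein_diffusivity(20.0, 293.15, 1.0e-3)
    shape = (64, 64, 70)
    field = FlowField(
        u=np.zeros((65, 64, 70)),
        v=np.zeros((64, 65, 70)),
        w=np.zeros((64, 64, 71)),
        pressure=np.zeros(shape),
        pore=np.ones(shape, bool),
        voxel_size_nm=7.0,
        n_buffer_in=3,
        n_buffer_out=3,
        delta_p_kpa=0.0,
        viscosity_pa_s=1e-3,
        max_divergence=0.0,
        momentum_residual=0.0,
        cg_iterations=0,
    )
    s = VoxelStructure(np.ones((64, 64, 64), bool), 7.0)
    start = np.array([32 * 7.0, 32 * 7.0, 35 * 7.0])
    msd, ts = [], []
    for i in range(600):
        p = Particle(position=start.copy(), diameter_nm=20.0)
        p = track_particle(
            p, field, s, seed=1000 + i, max_steps=2000, window=100_000,
            diffusivity_m2_s=D,
        )
        msd.append(((p.position - start) ** 2).sum() * 1e-18)
        ts.append(p.elapsed_s)
    return float(np.mean(msd)), float(np.mean(ts)), D


@pytest.fixture(scope="session")
def full_challenge(membrane_default):
    """30 batches × (25 real + 100 ghost) on the default membrane."""
    cfg = ChallengeConfig(n_batches=30, batch_size=25, ghosts_per_batch=100)
    return run_batch_challenge(membrane_default, cfg, seed=42)
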