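"""Steady incompressible Stokes flow through a binary voxel pore space.

Discretization is the marker-and-cell (MAC) staggered finite-volume
scheme: pressures at pore-cell centres, velocity components on cell
faces.  No-slip walls are enforced exactly for the face-normal
component and by half-cell reflection ghosts for tangential components
(second order).  Lateral domain faces carry symmetry conditions (zero
normal velocity, zero tangential shear); the inlet and outlet are open
faces at fixed pressure, with a few fully open buffer layers appended
on each end to decouple the boundary condition from the structure.

The linear saddle-point system

    [ A  G ] [u]   [b]
    [ G' 0 ] [p] = [0]

(A the vector Laplacian, G the discrete gradient) is reduced to its
pressure Schur complement S = G' A^-1 G, which is SPD, and solved by
conjugate gradients; A^-1 is applied exactly through sparse LU
factorizations of the three per-component Laplacians.  By linearity the
problem is solved once at unit pressure forcing and rescaled so the
achieved pressure drop across the structure (buffer excluded) matches
the requested transmembrane pressure.

Units: voxel size in nm, pressures in kPa internally converted to Pa,
velocities in m/s, permeability in L m^-2 h^-1 kPa^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .structure import VoxelStructure, percolating_pore_mask

__all__ = [
    "FlowField",
    "PermeabilityResult",
    "solve_stokes",
    "permeability",
    "flux_ratio",
    "verify_pressure_match",
]

#: 1 L m^-2 h^-1 kPa^-1 expressed as (m/s)/Pa.
LMH_PER_KPA = 1.0 / 3.6e6 / 1e3  # 2.7778e-10


@dataclass
class FlowField:
    """Converged MAC Stokes solution on a buffered voxel grid.

    Velocity components live on faces of the buffered grid (physical
    m/s); pressure at pore-cell centres (Pa).  ``n_buffer_in/out`` give
    the number of fully open layers prepended/appended along the flow
    axis; index 0 of the *structure* corresponds to buffered index
    ``n_buffer_in``.
    """

    u: np.ndarray  # (nx+1, ny, nzb) x-face velocities
    v: np.ndarray  # (nx, ny+1, nzb)
    w: np.ndarray  # (nx, ny, nzb+1) flow-axis face velocities
    pressure: np.ndarray  # (nx, ny, nzb), Pa, zero in solid
    pore: np.ndarray  # buffered pore mask actually solved (flow-connected)
    voxel_size_nm: float
    n_buffer_in: int
    n_buffer_out: int
    delta_p_kpa: float  # achieved pressure drop across the structure
    viscosity_pa_s: float
    max_divergence: float  # max abs discrete divergence, relative to mean face speed
    momentum_residual: float  # relative momentum residual of the inner solves
    cg_iterations: int
    _p_hat: np.ndarray | None = None  # dimensionless pressure vector (warm starts)
    _x_hat: np.ndarray | None = None  # dimensionless full solution (warm starts)

    # -- fluxes ----------------------------------------------------------

    def plane_flux(self, k_face: int) -> float:
        """Volumetric flow rate (m^3/s) through transverse face-plane k."""
        h_m = self.voxel_size_nm * 1e-9
        return float(self.w[:, :, k_face].sum()) * h_m * h_m

    def exit_flux(self) -> float:
        """Volumetric flow rate through the structure's exit plane."""
        return self.plane_flux(self.w.shape[2] - 1 - self.n_buffer_out)

    def scaled(self, factor: float) -> "FlowField":
        """Field with all velocities and pressures scaled (Stokes linearity)."""
        return FlowField(
            u=self.u * factor,
            v=self.v * factor,
            w=self.w * factor,
            pressure=self.pressure * factor,
            pore=self.pore,
            voxel_size_nm=self.voxel_size_nm,
            n_buffer_in=self.n_buffer_in,
            n_buffer_out=self.n_buffer_out,
            delta_p_kpa=self.delta_p_kpa * factor,
            viscosity_pa_s=self.viscosity_pa_s,
            max_divergence=self.max_divergence,
            momentum_residual=self.momentum_residual,
            cg_iterations=self.cg_iterations,
            _p_hat=self._p_hat,
            _x_hat=self._x_hat,
        )


@dataclass(frozen=True)
class PermeabilityResult:
    """Membrane permeability κ = (Q/A)/ΔP in L m^-2 h^-1 kPa^-1."""

    kappa: float
    flow_rate_m3_s: float
    area_m2: float
    delta_p_kpa: float
    thickness_um: float


class PercolationError(RuntimeError):
    """Raised when no 6-connected pore path joins inlet and exit."""


def _component_laplacian(
    active: np.ndarray,
    axis: int,
    pore: np.ndarray,
) -> sp.csr_matrix:
    """SPD 7-point operator (-∇² scaled by h²=1) for one velocity component.

    ``active`` marks faces carrying unknowns.  For each of the six
    neighbour directions the stencil contribution is: -1 off-diagonal to
    an active neighbour face; +1 diagonal toward an inactive face along
    the component axis (the face itself sits on a no-slip wall or
    symmetry plane, where the normal velocity vanishes); +2 diagonal
    toward an inactive tangential neighbour (half-cell reflection ghost
    across the wall); 0 toward a domain boundary in a tangential
    direction (symmetry/open ⇒ zero normal gradient).
    """
    shape = active.shape
    n = int(active.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[active] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    act_idx = index[active]

    for ax in range(3):
        for step in (-1, 1):
            nb_active = np.zeros(shape, dtype=bool)
            nb_index = np.full(shape, -1, dtype=np.int64)
            in_range = np.zeros(shape, dtype=bool)
            sl_src = [slice(None)] * 3
            sl_dst = [slice(None)] * 3
            if step == 1:
                sl_dst[ax] = slice(0, shape[ax] - 1)
                sl_src[ax] = slice(1, shape[ax])
            else:
                sl_dst[ax] = slice(1, shape[ax])
                sl_src[ax] = slice(0, shape[ax] - 1)
            nb_active[tuple(sl_dst)] = active[tuple(sl_src)]
            nb_index[tuple(sl_dst)] = index[tuple(sl_src)]
            in_range[tuple(sl_dst)] = True

            here = active
            # active neighbour: standard -1 / +1 pair
            m = here & nb_active
            if m.any():
                rows.append(index[m])
                cols.append(nb_index[m])
                vals.append(-np.ones(int(m.sum())))
            np.add.at(diag, index[here & nb_active], 1.0)
            # inactive neighbour within range
            m2 = here & in_range & ~nb_active
            if ax == axis:
                # neighbour face location is a wall/symmetry face: velocity 0 there
                np.add.at(diag, index[m2], 1.0)
            else:
                # wall halfway between the two faces: reflection ghost (u_ghost=-u)
                np.add.at(diag, index[m2], 2.0)
            # out of range in tangential direction: symmetry/open, zero gradient
            m3 = here & ~in_range
            if ax == axis:
                # should not occur: component-axis boundary faces handled by activity
                np.add.at(diag, index[m3], 0.0)

    rows.append(act_idx)
    cols.append(act_idx)
    vals.append(diag)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A


class _StokesOperator:
    """Assembled MAC Stokes system for one buffered pore geometry."""

    def __init__(self, pore: np.ndarray):
        nx, ny, nzb = pore.shape
        self.pore = pore
        self.shape = pore.shape

        # face activity ------------------------------------------------
        au = np.zeros((nx + 1, ny, nzb), dtype=bool)
        au[1:nx] = pore[:-1] & pore[1:]
        av = np.zeros((nx, ny + 1, nzb), dtype=bool)
        av[:, 1:ny] = pore[:, :-1] & pore[:, 1:]
        aw = np.zeros((nx, ny, nzb + 1), dtype=bool)
        aw[:, :, 1:nzb] = pore[:, :, :-1] & pore[:, :, 1:]
        aw[:, :, 0] = pore[:, :, 0]
        aw[:, :, nzb] = pore[:, :, -1]
        self.active = (au, av, aw)

        self.n_faces = tuple(int(a.sum()) for a in self.active)
        self.face_index = []
        for a, n in zip(self.active, self.n_faces):
            ix = -np.ones(a.shape, dtype=np.int64)
            ix[a] = np.arange(n)
            self.face_index.append(ix)

        # pressure numbering -------------------------------------------
        self.n_cells = int(pore.sum())
        self.cell_index = -np.ones(pore.shape, dtype=np.int64)
        self.cell_index[pore] = np.arange(self.n_cells)

        # momentum operators -------------------------------------------
        self.A = [
            _component_laplacian(self.active[c], c, pore) for c in range(3)
        ]

        # gradient operators G_c: pressure -> faces --------------------
        self.G = []
        self.b = []  # unit-pressure-drop forcing per component
        for c in range(3):
            self.G.append(self._gradient(c))

    def _gradient(self, c: int) -> sp.csr_matrix:
        pore = self.pore
        a = self.active[c]
        fidx = self.face_index[c]
        cidx = self.cell_index
        shape = a.shape
        n = self.n_faces[c]
        rows, cols, vals = [], [], []
        b = np.zeros(n)

        # face at position i along axis c separates cell i-1 ("left") and i
        idx = np.indices(shape)[c]
        interior = a & (idx > 0) & (idx < pore.shape[c])
        # right cell = same index as face along axis c
        right = np.zeros(shape, dtype=np.int64)
        left = np.zeros(shape, dtype=np.int64)
        sl_face = [slice(None)] * 3
        sl_cell = [slice(None)] * 3
        sl_face[c] = slice(0, pore.shape[c])
        right[tuple(sl_face)] = cidx
        sl_face[c] = slice(1, pore.shape[c] + 1)
        left[tuple(sl_face)] = cidx

        m = interior
        rows += [fidx[m], fidx[m]]
        cols += [right[m], left[m]]
        vals += [np.ones(int(m.sum())), -np.ones(int(m.sum()))]

        if c == 2:
            # open inlet face (k=0): ghost pressure = 1 (unit drop); row = p0 - 1
            m_in = a.copy()
            m_in[:, :, 1:] = False
            rows.append(fidx[m_in])
            cols.append(self.cell_index[:, :, 0][m_in[:, :, 0]])
            vals.append(np.ones(int(m_in.sum())))
            b[fidx[m_in]] = 1.0  # moves to RHS with +1
            # open outlet face: ghost pressure = 0; row = -p_last
            m_out = a.copy()
            m_out[:, :, :-1] = False
            rows.append(fidx[m_out])
            cols.append(self.cell_index[:, :, -1][m_out[:, :, -1]])
            vals.append(-np.ones(int(m_out.sum())))
        G = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, self.n_cells),
        ).tocsr()
        self.b.append(b)
        return G

    # -- solving --------------------------------------------------------

    def factorize(self):
        self.lu = [spla.splu(A.tocsc()) for A in self.A]
        # SIMPLE-type Schur approximation: the cell-centred network
        # Laplacian with face conductances 1/diag(A).  It captures the
        # throat-conductance structure of the pore network, which is
        # what conditions the true Schur complement.
        S_hat = None
        for c in range(3):
            d = self.A[c].diagonal()
            Dinv = sp.diags(1.0 / d)
            term = (self.G[c].T @ Dinv @ self.G[c]).tocsc()
            S_hat = term if S_hat is None else S_hat + term
        self.schur_prec = spla.splu(S_hat)

    def solve_component(self, c: int, rhs: np.ndarray) -> np.ndarray:
        return self.lu[c].solve(rhs)

    def schur_matvec(self, p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        for c in range(3):
            q = self.G[c] @ p
            x = self.solve_component(c, q)
            out += self.G[c].T @ x
        return out

    def solve_mg(
        self,
        rtol: float = 1e-8,
        x0: np.ndarray | None = None,
        n_cycles: int = 1,
    ):
        """Krylov solve of the full saddle system with a multigrid preconditioner.

        Outer iteration is restarted GMRES on ``[[A, G], [G', 0]]``; the
        preconditioner is the block triangular factor ``[[Â, 0], [G', -Ŝ]]``
        with Â applied as geometric V-cycles per velocity component and
        Ŝ an incomplete LU of the SIMPLE (throat-conductance) Schur
        approximation.  Converges in a size-independent number of outer
        iterations and needs no exact velocity factorizations, which is
        what makes repeated solves on evolving geometries affordable.
        """
        from ._multigrid import pressure_hierarchy, velocity_hierarchy

        if not hasattr(self, "_mg"):
            self._mg = [velocity_hierarchy(self.pore, c, self.A[c]) for c in range(3)]
            S_hat = None
            for c in range(3):
                Dinv = sp.diags(1.0 / self.A[c].diagonal())
                term = (self.G[c].T @ Dinv @ self.G[c]).tocsr()
                S_hat = term if S_hat is None else S_hat + term
            self._mg_p = pressure_hierarchy(self.pore, S_hat)

        nf = self.n_faces
        off = np.cumsum([0, *nf])
        n_tot = off[3] + self.n_cells

        def matvec(x):
            u = [x[off[c] : off[c + 1]] for c in range(3)]
            p = x[off[3] :]
            out = np.empty_like(x)
            for c in range(3):
                out[off[c] : off[c + 1]] = self.A[c] @ u[c] + self.G[c] @ p
            out[off[3] :] = sum(self.G[c].T @ u[c] for c in range(3))
            return out

        def precond(r):
            z = np.empty_like(r)
            zu = []
            for c in range(3):
                rc = r[off[c] : off[c + 1]]
                acc = self._mg[c].vcycle(rc)
                for _ in range(n_cycles - 1):
                    acc += self._mg[c].vcycle(rc - self.A[c] @ acc)
                z[off[c] : off[c + 1]] = acc
                zu.append(acc)
            rp = r[off[3] :]
            rhs_p = sum(self.G[c].T @ zu[c] for c in range(3)) - rp
            zp = self._mg_p.vcycle(rhs_p)
            zp += self._mg_p.vcycle(rhs_p - self._mg_p.A[0] @ zp)
            z[off[3] :] = zp
            return z

        K = spla.LinearOperator((n_tot, n_tot), matvec=matvec, dtype=float)
        M = spla.LinearOperator((n_tot, n_tot), matvec=precond, dtype=float)
        b_full = np.zeros(n_tot)
        for c in range(3):
            b_full[off[c] : off[c + 1]] = self.b[c]
        iters = [0]

        def cb(_):
            iters[0] += 1

        x, info = spla.gmres(
            K, b_full, x0=x0, M=M, rtol=rtol, atol=0.0,
            restart=100, maxiter=12, callback=cb, callback_type="pr_norm",
        )
        if info != 0:
            raise RuntimeError(f"Stokes GMRES did not converge (info={info})")
        vel = [x[off[c] : off[c + 1]] for c in range(3)]
        p = x[off[3] :]
        return vel, p, iters[0], x

    def solve(self, rtol: float = 1e-9, p0: np.ndarray | None = None):
        """Solve for the dimensionless field at unit applied pressure drop."""
        self.factorize()
        rhs = np.zeros(self.n_cells)
        for c in range(3):
            rhs += self.G[c].T @ self.solve_component(c, self.b[c])
        S = spla.LinearOperator(
            (self.n_cells, self.n_cells), matvec=self.schur_matvec, dtype=float
        )
        M = spla.LinearOperator(
            (self.n_cells, self.n_cells), matvec=self.schur_prec.solve, dtype=float
        )
        iters = [0]

        def cb(_):
            iters[0] += 1

        p, info = spla.cg(S, rhs, x0=p0, rtol=rtol, atol=0.0, maxiter=2000, M=M, callback=cb)
        if info != 0:
            raise RuntimeError(f"Stokes pressure solve did not converge (info={info})")
        vel = []
        for c in range(3):
            vel.append(self.solve_component(c, self.b[c] - self.G[c] @ p))
        return vel, p, iters[0]


def solve_stokes(
    structure: VoxelStructure,
    delta_p_kpa: float = 210.0,
    viscosity_pa_s: float = 1.0e-3,
    n_buffer_in: int = 3,
    n_buffer_out: int = 3,
    rtol: float | None = None,
    warm_start: FlowField | None = None,
    buffer_mode: str = "open",
    method: str = "mg",
    operator_cache: dict | None = None,
) -> FlowField:
    """Solve MAC Stokes flow through the structure at a fixed pressure drop.

    The system is solved once at unit dimensionless forcing and rescaled
    so the achieved pressure drop across the structure (excluding the
    buffer layers) equals ``delta_p_kpa`` — equivalent, by linearity, to
    iterating on the inlet velocity.

    ``buffer_mode`` controls the appended layers: ``"open"`` (default)
    makes them fully pore, decoupling the pressure condition from the
    structure; ``"extend"`` replicates the inlet/exit slices, giving
    fully developed in/outflow for translation-invariant geometries
    (used by the analytic duct and tube checks).

    Raises :class:`PercolationError` if no 6-connected pore path joins
    inlet and exit.
    """
    grid = structure.grid
    nx, ny, nz = grid.shape
    mask = percolating_pore_mask(grid)
    if mask is None:
        raise PercolationError("no connected flow path from inlet to exit")

    pore = np.ones((nx, ny, nz + n_buffer_in + n_buffer_out), dtype=bool)
    pore[:, :, n_buffer_in : n_buffer_in + nz] = mask
    if buffer_mode == "extend":
        pore[:, :, :n_buffer_in] = mask[:, :, :1]
        pore[:, :, n_buffer_in + nz :] = mask[:, :, -1:]
    elif buffer_mode != "open":
        raise ValueError(f"unknown buffer_mode {buffer_mode!r}")
    # re-extract the flow-connected component on the buffered grid so
    # dead pores opened only through the buffer faces are included
    pore = percolating_pore_mask(pore)

    op = _StokesOperator(pore)
    x_full = None
    if method == "mg":
        x0 = None
        if warm_start is not None and warm_start._x_hat is not None:
            x0 = _remap_warm_start(warm_start, op, pore)
        vel, p_hat, iters, x_full = op.solve_mg(rtol=rtol or 1e-8, x0=x0)
    elif method == "direct":
        p0 = None
        if warm_start is not None and warm_start._p_hat is not None:
            if warm_start.pore.shape == pore.shape:
                prev = np.zeros(pore.shape)
                prev[warm_start.pore] = warm_start._p_hat
                p0 = prev[pore]
        vel, p_hat, iters = op.solve(rtol=rtol or 1e-9, p0=p0)
    else:
        raise ValueError(f"unknown method {method!r} (use 'mg' or 'direct')")

    # residual diagnostics on the dimensionless system
    div = np.zeros(op.n_cells)
    for c in range(3):
        div += op.G[c].T @ vel[c]
    mom = 0.0
    scale = max(np.linalg.norm(np.concatenate([op.G[c] @ p_hat for c in range(3)])), 1e-300)
    for c in range(3):
        r = op.A[c] @ vel[c] + op.G[c] @ p_hat - op.b[c]
        mom = max(mom, np.linalg.norm(r) / scale)
    speed = max(max(np.abs(v).max() for v in vel), 1e-300)
    max_div = float(np.abs(div).max() / speed)

    # achieved dimensionless pressure drop across the structure, with
    # half-cell extrapolation to the inlet/exit faces through the buffer
    z0, z1 = n_buffer_in, n_buffer_in + nz - 1
    p_grid_hat = np.zeros(pore.shape)
    p_grid_hat[pore] = p_hat
    p_in = 0.5 * (_plane_mean(p_grid_hat, pore, z0 - 1) + _plane_mean(p_grid_hat, pore, z0))
    p_out = 0.5 * (_plane_mean(p_grid_hat, pore, z1) + _plane_mean(p_grid_hat, pore, z1 + 1))
    drop_hat = p_in - p_out
    if drop_hat <= 0:
        raise RuntimeError("non-positive pressure drop across structure; degenerate solve")
    # include the half-cell extrapolation to the structure faces
    scale_hat = 1.0 / drop_hat

    h_m = structure.voxel_size_nm * 1e-9
    dp_pa = delta_p_kpa * 1e3
    u_scale = scale_hat * dp_pa * h_m / viscosity_pa_s  # m/s per unit dimensionless u

    def expand(vec: np.ndarray, c: int) -> np.ndarray:
        out = np.zeros(op.active[c].shape)
        out[op.active[c]] = vec * u_scale
        return out

    field = FlowField(
        u=expand(vel[0], 0),
        v=expand(vel[1], 1),
        w=expand(vel[2], 2),
        pressure=p_grid_hat * scale_hat * dp_pa,
        pore=pore,
        voxel_size_nm=structure.voxel_size_nm,
        n_buffer_in=n_buffer_in,
        n_buffer_out=n_buffer_out,
        delta_p_kpa=delta_p_kpa,
        viscosity_pa_s=viscosity_pa_s,
        max_divergence=max_div,
        momentum_residual=float(mom),
        cg_iterations=iters,
        _p_hat=p_hat,
        _x_hat=x_full,
    )
    return field


def _remap_warm_start(prev_field: FlowField, op: _StokesOperator, pore: np.ndarray):
    """Re-index a previous dimensionless solution onto a new geometry."""
    if prev_field.pore.shape != pore.shape:
        return None
    from ._multigrid import face_activity

    x_prev = prev_field._x_hat
    nf_prev = [int(face_activity(prev_field.pore, c).sum()) for c in range(3)]
    off_prev = np.cumsum([0, *nf_prev])
    x0 = []
    for c in range(3):
        full = np.zeros(op.active[c].shape)
        prev_active = face_activity(prev_field.pore, c)
        full[prev_active] = x_prev[off_prev[c] : off_prev[c + 1]]
        x0.append(full[op.active[c]])
    p_full = np.zeros(pore.shape)
    prev_pore = prev_field.pore
    n_prev_cells = int(prev_pore.sum())
    p_full[prev_pore] = x_prev[off_prev[3] : off_prev[3] + n_prev_cells]
    x0.append(p_full[pore])
    return np.concatenate(x0)


def _plane_mean(p_grid: np.ndarray, pore: np.ndarray, k: int) -> float:
    m = pore[:, :, k]
    if not m.any():
        raise RuntimeError(f"no pore voxels at plane {k}")
    return float(p_grid[:, :, k][m].mean())


def permeability(
    field: FlowField, structure: VoxelStructure, div_tol: float = 1e-6
) -> PermeabilityResult:
    """κ = (Q/A)/ΔP from the exit-plane flux, in L m^-2 h^-1 kPa^-1.

    ``A`` is the full cross-section (pore + solid); the open buffer
    layers are excluded from the thickness and pressure accounting.
    Refuses to report if the divergence diagnostic exceeds ``div_tol``
    (relative to the peak face speed).
    """
    if field.max_divergence > div_tol:
        raise RuntimeError(
            f"flow field divergence {field.max_divergence:.2e} above tolerance; "
            "refusing to report permeability"
        )
    nx, ny, _ = structure.shape
    h_m = structure.voxel_size_nm * 1e-9
    area = nx * ny * h_m * h_m
    q = field.exit_flux()
    kappa = (q / area) / (field.delta_p_kpa * 1e3) / LMH_PER_KPA
    return PermeabilityResult(
        kappa=float(kappa),
        flow_rate_m3_s=q,
        area_m2=area,
        delta_p_kpa=field.delta_p_kpa,
        thickness_um=structure.thickness_um,
    )


def flux_ratio(k_fouled: float, k_clean: float, ndigits: int = 2) -> float:
    """Fouled-to-clean flux ratio J/J0, rounded to reporting precision."""
    if k_clean <= 0:
        raise ValueError("clean permeability must be positive")
    return round(k_fouled / k_clean, ndigits)


def verify_pressure_match(
    field: FlowField, target_kpa: float = 210.0, rel_tol: float = 1e-3
) -> tuple[bool, float]:
    """Check the achieved transmembrane pressure drop against a target.

    Returns ``(ok, achieved_kpa)`` with ``ok`` true iff
    ``|achieved - target| <= rel_tol * target`` (0.21 kPa at 210 kPa).
    """
    achieved = field.delta_p_kpa
    return abs(achieved - target_kpa) <= rel_tol * target_kpa, achieved
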