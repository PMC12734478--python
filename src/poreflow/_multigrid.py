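"""Galerkin algebraic-geometric multigrid for the voxel Stokes blocks.

Two kinds of scalar SPD operators need fast approximate inverses inside
the Stokes preconditioner: the three masked face Laplacians (velocity
momentum blocks) and the cell-centred throat-conductance network
Laplacian (SIMPLE Schur approximation).  Both live on voxel masks, so a
geometric hierarchy is natural: pore masks are coarsened by logical OR
over 2x2x2 blocks (preserving channel connectivity), prolongation is
piecewise constant in tangential directions and linear along a face
component's own axis, and coarse operators are Galerkin products
P' A P — which keeps every level consistent with the fine-grid energy
and makes the V-cycle a safe preconditioner even on rough, nearly
disconnected geometries.  The coarsest level is solved directly with a
tiny diagonal shift guarding the near-singular open-boundary modes of
the flow-axis component.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["face_activity", "GalerkinMG", "velocity_hierarchy", "pressure_hierarchy"]


def face_activity(pore: np.ndarray, c: int) -> np.ndarray:
    """Active (unknown-carrying) faces of velocity component ``c``.

    Interior faces are active when both adjacent cells are pore; faces
    on the two flow-axis domain boundaries are active when the adjacent
    interior cell is pore (open inlet/outlet); lateral boundary faces of
    the normal component are symmetry planes and carry no unknown.
    """
    nx, ny, nzb = pore.shape
    if c == 0:
        a = np.zeros((nx + 1, ny, nzb), dtype=bool)
        a[1:nx] = pore[:-1] & pore[1:]
    elif c == 1:
        a = np.zeros((nx, ny + 1, nzb), dtype=bool)
        a[:, 1:ny] = pore[:, :-1] & pore[:, 1:]
    else:
        a = np.zeros((nx, ny, nzb + 1), dtype=bool)
        a[:, :, 1:nzb] = pore[:, :, :-1] & pore[:, :, 1:]
        a[:, :, 0] = pore[:, :, 0]
        a[:, :, nzb] = pore[:, :, -1]
    return a


def coarsen_pore(pore: np.ndarray) -> np.ndarray:
    """OR-coarsen a pore mask over 2x2x2 blocks (edge-padding odd dims)."""
    nx, ny, nz = pore.shape
    p = np.pad(pore, [(0, (-d) % 2) for d in (nx, ny, nz)], mode="edge")
    out = np.zeros((p.shape[0] // 2, p.shape[1] // 2, p.shape[2] // 2), dtype=bool)
    for dx in range(2):
        for dy in range(2):
            for dz in range(2):
                out |= p[dx::2, dy::2, dz::2]
    return out


def _index_map(active: np.ndarray) -> np.ndarray:
    idx = -np.ones(active.shape, dtype=np.int64)
    idx[active] = np.arange(int(active.sum()))
    return idx


def _face_prolongator(
    active_f: np.ndarray, active_c: np.ndarray, c: int
) -> sp.csr_matrix:
    """P mapping coarse face unknowns to fine face unknowns.

    Tangential axes: the fine face inherits from the coarse face at the
    halved index (piecewise constant).  Along the component axis fine
    even faces coincide with coarse faces; odd faces average the two
    flanking coarse faces.
    """
    idx_f = _index_map(active_f)
    idx_c = _index_map(active_c)
    coords = np.argwhere(active_f)
    rows_f = idx_f[active_f]

    tang = [ax for ax in range(3) if ax != c]
    jc = coords[:, tang[0]] // 2
    kc = coords[:, tang[1]] // 2
    jc = np.minimum(jc, active_c.shape[tang[0]] - 1)
    kc = np.minimum(kc, active_c.shape[tang[1]] - 1)

    i = coords[:, c]
    rows, cols, vals = [], [], []

    def add(ic, w, mask):
        ic = np.minimum(ic, active_c.shape[c] - 1)
        tgt = np.empty((mask.sum(), 3), dtype=np.int64)
        tgt[:, c] = ic[mask]
        tgt[:, tang[0]] = jc[mask]
        tgt[:, tang[1]] = kc[mask]
        cid = idx_c[tgt[:, 0], tgt[:, 1], tgt[:, 2]]
        ok = cid >= 0
        rows.append(rows_f[mask][ok])
        cols.append(cid[ok])
        vals.append(np.full(int(ok.sum()), w))

    even = i % 2 == 0
    add(i // 2, 1.0, even)
    odd = ~even
    add((i - 1) // 2, 0.5, odd)
    add((i + 1) // 2, 0.5, odd)

    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(int(active_f.sum()), int(active_c.sum())),
    ).tocsr()


def _cell_prolongator(pore_f: np.ndarray, pore_c: np.ndarray) -> sp.csr_matrix:
    """Piecewise-constant prolongation between pore-cell masks."""
    idx_f = _index_map(pore_f)
    idx_c = _index_map(pore_c)
    coords = np.argwhere(pore_f)
    parents = np.minimum(coords // 2, np.array(pore_c.shape) - 1)
    cid = idx_c[parents[:, 0], parents[:, 1], parents[:, 2]]
    ok = cid >= 0
    return sp.coo_matrix(
        (np.ones(int(ok.sum())), (idx_f[pore_f][ok], cid[ok])),
        shape=(int(pore_f.sum()), int(pore_c.sum())),
    ).tocsr()


class GalerkinMG:
    """V-cycle preconditioner with Galerkin coarse operators.

    Smoothing is damped Jacobi (SPD-symmetric when applied with equal
    pre/post sweeps, so the cycle is a valid SPD preconditioner); the
    coarsest operator is factorized with a relative diagonal shift of
    1e-10 to guard exactly singular open-boundary modes.
    """

    def __init__(
        self,
        A: sp.csr_matrix,
        prolongators: list[sp.csr_matrix],
        omega: float = 0.7,
        sweeps: int = 2,
    ):
        self.omega = omega
        self.sweeps = sweeps
        self.A = [A.tocsr()]
        self.P = prolongators
        for P in prolongators:
            A = (P.T @ A @ P).tocsr()
            self.A.append(A)
        self.inv_diag = []
        for Al in self.A:
            d = Al.diagonal()
            d[d <= 0] = 1.0
            self.inv_diag.append(1.0 / d)
        bottom = self.A[-1].tocsc()
        shift = 1e-10 * abs(bottom.diagonal()).max()
        n = bottom.shape[0]
        self._bottom = spla.splu(bottom + shift * sp.identity(n, format="csc"))

    def _smooth(self, level: int, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        A = self.A[level]
        for _ in range(self.sweeps):
            x = x + self.omega * self.inv_diag[level] * (b - A @ x)
        return x

    def vcycle(self, b: np.ndarray, level: int = 0) -> np.ndarray:
        if level == len(self.A) - 1:
            return self._bottom.solve(b)
        x = self._smooth(level, np.zeros_like(b), b)
        r = b - self.A[level] @ x
        rc = self.P[level].T @ r
        ec = self.vcycle(rc, level + 1)
        x = x + self.P[level] @ ec
        return self._smooth(level, x, b)

    def as_linear_operator(self) -> spla.LinearOperator:
        n = self.A[0].shape[0]
        return spla.LinearOperator((n, n), matvec=self.vcycle, dtype=float)


def velocity_hierarchy(
    pore: np.ndarray, c: int, A: sp.csr_matrix, max_levels: int = 8, min_unknowns: int = 2500
) -> GalerkinMG:
    """Build the Galerkin hierarchy for one velocity component."""
    prolongators = []
    p_f = pore
    a_f = face_activity(p_f, c)
    while len(prolongators) < max_levels - 1 and int(a_f.sum()) > min_unknowns:
        p_c = coarsen_pore(p_f)
        a_c = face_activity(p_c, c)
        if int(a_c.sum()) == 0:
            break
        prolongators.append(_face_prolongator(a_f, a_c, c))
        p_f, a_f = p_c, a_c
    return GalerkinMG(A, prolongators)


def pressure_hierarchy(
    pore: np.ndarray, S_hat: sp.csr_matrix, max_levels: int = 8, min_unknowns: int = 2500
) -> GalerkinMG:
    """Build the Galerkin hierarchy for the pressure network Laplacian."""
    prolongators = []
    p_f = pore
    while len(prolongators) < max_levels - 1 and int(p_f.sum()) > min_unknowns:
        p_c = coarsen_pore(p_f)
        prolongators.append(_cell_prolongator(p_f, p_c))
        p_f = p_c
    return GalerkinMG(S_hat, prolongators)
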