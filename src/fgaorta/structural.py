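"""Axisymmetric elastodynamics of a thick-walled, radially graded vessel wall.

Governing equations (displacements u_r(r, z, t), u_z(r, z, t), axisymmetric,
no torsion), with isotropic Hooke's law and radially varying Lame moduli
lambda(r), G(r) and density rho(r):

    d(s_rr)/dr + d(s_rz)/dz + (s_rr - s_tt)/r = rho * u_r_tt
    d(s_rz)/dr + d(s_zz)/dz +  s_rz / r       = rho * u_z_tt + rho * g

Boundary conditions: prescribed normal traction on the inner surface
(s_rr = -P(z, t), s_rz = 0), traction-free outer surface, and built-in ends
(u_r = u_z = 0 at z = 0 and z = L).

The strong form is collocated on a tensor-product grid with two
interchangeable discretizations:

* ``dqm`` — differential quadrature on Chebyshev–Gauss–Lobatto nodes
  (spectral accuracy for smooth fields),
* ``fd``  — second-order finite differences on a uniform grid, serving as an
  independent cross-check of the DQM solution.

Time integration is Newmark-beta (average acceleration by default); boundary
rows carry no mass, so tractions and clamped ends are enforced exactly at
every time level.  Stresses are recovered from the displacement solution by
collocation differentiation and Hooke's law.
"""

from __future__ import annotations

import hashlib
import logging
import time as _time
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RectBivariateSpline
from scipy.linalg import lu_factor, lu_solve

from .dqm import make_grid
from .hemodynamics import Waveform, axial_pressure_profile, sinusoid
from .materials import (
    NU_CAP,
    HomogeneousWall,
    Material,
    PowerLawWall,
    WallModel,
    radial_property_field,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Geometry",
    "Scenario",
    "FieldSolution",
    "AssembledSystem",
    "NewmarkStepper",
    "assemble",
    "solve",
    "solve_static",
    "lame_solution",
    "validation_scenario",
    "run_validation_case",
    "compare_solutions",
    "STRESS_NAMES",
]

STRESS_NAMES = ("s_rr", "s_tt", "s_zz", "s_rz")

# Systems at or below this many unknowns are factorized dense.
_DENSE_CUTOFF = 4000


@dataclass(frozen=True)
class Geometry:
    """Thick-walled cylinder geometry (metres)."""

    r_in: float
    r_out: float
    L: float

    def __post_init__(self) -> None:
        if not (self.r_out > self.r_in > 0):
            raise ValueError("radii must satisfy r_out > r_in > 0")
        if self.L <= 0:
            raise ValueError("length must be positive")

    @property
    def h(self) -> float:
        """Wall thickness r_out - r_in."""
        return self.r_out - self.r_in


@dataclass(frozen=True)
class Scenario:
    """One complete simulation definition: geometry, wall, loading, solver.

    ``method`` selects the discretization (``"dqm"`` or ``"fd"``); ``n_r`` /
    ``n_z`` default per method when left as None.  ``gravity`` is the axial
    body-force magnitude (m/s^2, acting in -z).  Ends are built in
    (u_r = u_z = 0); the inner surface carries the waveform pressure,
    uniform along z unless a coupled/axial pressure field is supplied at
    solve time.
    """

    geometry: Geometry
    wall: WallModel
    waveform: Waveform
    gravity: float = 0.0
    t_end: float = 2.0
    dt: float = 0.01
    method: str = "dqm"
    n_r: int | None = None
    n_z: int | None = None
    beta: float = 0.25
    gamma: float = 0.5
    alpha_K: float = 0.0  # stiffness-proportional damping coefficient, s
    grid_family: str = "cgl"
    layer_smoothing: float = 0.0
    ends: str = "fixed"  # "fixed" (built-in) or "sliding" (u_z=0, s_rz=0)

    def __post_init__(self) -> None:
        if self.method not in ("dqm", "fd"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.ends not in ("fixed", "sliding"):
            raise ValueError(f"unknown end condition {self.ends!r}")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("time step and window must be positive")
        for nm in ("n_r", "n_z"):
            v = getattr(self, nm)
            if v is not None and v < 3:
                raise ValueError(f"{nm} must be >= 3")

    @property
    def grid_shape(self) -> tuple[int, int]:
        if self.method == "dqm":
            return (self.n_r or 13, self.n_z or 21)
        return (self.n_r or 41, self.n_z or 161)

    def hash(self) -> str:
        """Short identifying hash of the scenario definition."""
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


# ----------------------------------------------------------------------------
# Discretization: nodes + derivative matrices per direction
# ----------------------------------------------------------------------------

def _fd_matrices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform-grid FD matrices on [0, 1]: second-order central stencils with
    second-order one-sided closures at the ends."""
    if n < 4:
        raise ValueError("FD discretization needs at least 4 nodes")
    h = 1.0 / (n - 1)
    D1 = np.zeros((n, n))
    D2 = np.zeros((n, n))
    for i in range(1, n - 1):
        D1[i, i - 1], D1[i, i + 1] = -0.5 / h, 0.5 / h
        D2[i, i - 1 : i + 2] = np.array([1.0, -2.0, 1.0]) / h**2
    D1[0, :3] = np.array([-1.5, 2.0, -0.5]) / h
    D1[-1, -3:] = np.array([0.5, -2.0, 1.5]) / h
    D2[0, :4] = np.array([2.0, -5.0, 4.0, -1.0]) / h**2
    D2[-1, -4:] = np.array([-1.0, 4.0, -5.0, 2.0]) / h**2
    return np.linspace(0.0, 1.0, n), D1, D2


@dataclass(frozen=True)
class Discretization:
    r: np.ndarray
    z: np.ndarray
    D1r: np.ndarray
    D2r: np.ndarray
    D1z: np.ndarray
    D2z: np.ndarray


def make_discretization(scenario: Scenario) -> Discretization:
    geom = scenario.geometry
    n_r, n_z = scenario.grid_shape
    if scenario.method == "dqm":
        gr = make_grid(n_r, scenario.grid_family).scaled(geom.r_in, geom.r_out)
        gz = make_grid(n_z, scenario.grid_family).scaled(0.0, geom.L)
        return Discretization(gr.nodes, gz.nodes, gr.D1, gr.D2, gz.D1, gz.D2)
    xr, D1r, D2r = _fd_matrices(n_r)
    xz, D1z, D2z = _fd_matrices(n_z)
    return Discretization(
        geom.r_in + geom.h * xr, geom.L * xz,
        D1r / geom.h, D2r / geom.h**2, D1z / geom.L, D2z / geom.L**2,
    )


# ----------------------------------------------------------------------------
# Operator assembly
# ----------------------------------------------------------------------------

def _place_rows(target_rows: np.ndarray, block: sp.spmatrix, shape: tuple[int, int]):
    """Sparse matrix with the rows of ``block`` placed at ``target_rows``."""
    coo = block.tocoo()
    return sp.coo_matrix(
        (coo.data, (np.asarray(target_rows)[coo.row], coo.col)), shape=shape
    ).tocsr()


@dataclass
class AssembledSystem:
    """Discrete operators of one scenario: M u_tt + C u_t + K u = F(t).

    ``K`` already contains the boundary rows (traction operators on the
    surfaces, identity on the clamped ends); ``M_diag`` and the damping are
    zero on those rows, so the constraint equations hold exactly at each
    time level.
    """

    scenario: Scenario
    disc: Discretization
    K: sp.csr_matrix
    M_diag: np.ndarray
    stress_ops: dict[str, sp.csr_matrix]
    interior_mask: np.ndarray
    P_load: sp.csr_matrix       # maps inner-pressure samples P(z) to load rows
    gravity_F: np.ndarray       # constant body-force part of the load
    inv_row_scale: np.ndarray   # row equilibration applied to K/M/F

    @property
    def n_nodes(self) -> int:
        return self.disc.r.size * self.disc.z.size

    def load_from_inner_pressure(self, P_inner: np.ndarray) -> np.ndarray:
        """Load vector for a pressure sampled on the full z grid (Pa)."""
        return self.gravity_F + self.P_load @ np.asarray(P_inner, float)

    def load(self, t: float) -> np.ndarray:
        """Load vector for the scenario waveform, uniform along the axis."""
        P = float(self.scenario.waveform(t))
        return self.load_from_inner_pressure(np.full(self.disc.z.size, P))

    def recover_stresses(self, u: np.ndarray) -> dict[str, np.ndarray]:
        return {k: S @ u for k, S in self.stress_ops.items()}


def assemble(scenario: Scenario) -> AssembledSystem:
    """Discretize the scenario into mass/stiffness operators and load builders."""
    geom = scenario.geometry
    disc = make_discretization(scenario)
    r, z = disc.r, disc.z
    n_r, n_z, n = r.size, z.size, r.size * z.size

    E, nu, rho = radial_property_field(
        scenario.wall, r, geom.r_in, geom.r_out,
        layer_smoothing=scenario.layer_smoothing,
    )
    if np.any(nu > NU_CAP):
        logger.warning(
            "Poisson ratio capped at %.4f (near-incompressible wall)", NU_CAP
        )
        nu = np.minimum(nu, NU_CAP)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    G = E / (2.0 * (1.0 + nu))
    c1 = lam + 2.0 * G

    Ir, Iz = sp.identity(n_r, format="csr"), sp.identity(n_z, format="csr")
    D1r = sp.csr_matrix(disc.D1r)
    D1z, D2z = sp.csr_matrix(disc.D1z), sp.csr_matrix(disc.D2z)
    Dr = sp.kron(D1r, Iz, format="csr")
    Dz = sp.kron(Ir, D1z, format="csr")
    Dzz = sp.kron(Ir, D2z, format="csr")
    Drz = sp.kron(D1r, D1z, format="csr")

    def X(c_r: np.ndarray) -> sp.dia_matrix:
        return sp.diags(np.repeat(c_r, n_z))

    # Stress recovery operators, shape (n, 2n)
    S_rr = sp.hstack([X(c1) @ Dr + X(lam / r), X(lam) @ Dz], format="csr")
    S_tt = sp.hstack([X(lam) @ Dr + X(c1 / r), X(lam) @ Dz], format="csr")
    S_zz = sp.hstack([X(lam) @ Dr + X(lam / r), X(c1) @ Dz], format="csr")
    S_rz = sp.hstack([X(G) @ Dz, X(G) @ Dr], format="csr")
    stress_ops = {"s_rr": S_rr, "s_tt": S_tt, "s_zz": S_zz, "s_rz": S_rz}

    # Momentum operator A: rho * u_tt = A u + f.  Assembled in divergence
    # form — the moduli are never differentiated, which keeps the scheme
    # consistent for steeply graded walls (a grading index below 1 has an
    # unbounded property slope at the inner surface, though the stresses
    # entering the divergence stay smooth there).
    if scenario.method == "dqm":
        # Nodal divergence of the collocated stresses.
        R_r = Dr @ S_rr + Dz @ S_rz + X(1.0 / r) @ (S_rr - S_tt)
        R_z = Dr @ S_rz + Dz @ S_zz + X(1.0 / r) @ S_rz
    else:
        # Flux-conservative radial terms on a staggered (midpoint) grid:
        # d/dr(c * g) ~ [c_{i+1/2} g_{i+1/2} - c_{i-1/2} g_{i-1/2}] / h,
        # with midpoint moduli sampled from the material model directly.
        h_r = r[1] - r[0]
        r_mid = 0.5 * (r[1:] + r[:-1])
        E_m, nu_m, _ = radial_property_field(
            scenario.wall, r_mid, geom.r_in, geom.r_out,
            layer_smoothing=scenario.layer_smoothing,
        )
        nu_m = np.minimum(nu_m, NU_CAP)
        lam_m = E_m * nu_m / ((1.0 + nu_m) * (1.0 - 2.0 * nu_m))
        G_m = E_m / (2.0 * (1.0 + nu_m))
        c1_m = lam_m + 2.0 * G_m

        m = n_r - 1
        Dmid = sp.csr_matrix(
            (np.concatenate([-np.ones(m), np.ones(m)]) / h_r,
             (np.tile(np.arange(m), 2),
              np.concatenate([np.arange(m), np.arange(1, m + 1)]))),
            shape=(m, n_r))
        Amid = sp.csr_matrix(
            (np.full(2 * m, 0.5),
             (np.tile(np.arange(m), 2),
              np.concatenate([np.arange(m), np.arange(1, m + 1)]))),
            shape=(m, n_r))
        rows = np.arange(1, n_r - 1)
        Dnode = sp.csr_matrix(
            (np.concatenate([-np.ones(n_r - 2), np.ones(n_r - 2)]) / h_r,
             (np.tile(rows, 2), np.concatenate([rows - 1, rows]))),
            shape=(n_r, m))

        def Xm(c_mid: np.ndarray) -> sp.dia_matrix:
            return sp.diags(np.repeat(c_mid, n_z))

        DmidK = sp.kron(Dmid, Iz, format="csr")
        DnodeK = sp.kron(Dnode, Iz, format="csr")
        AmidDz = sp.kron(Amid, D1z, format="csr")
        AmidK = sp.kron(Amid, Iz, format="csr")

        # d/dr sigma_rr: flux c1 du_r/dr + lam u_r/r + lam du_z/dz
        flux_rr = sp.hstack(
            [Xm(c1_m) @ DmidK + Xm(lam_m) @ AmidK @ X(1.0 / r), Xm(lam_m) @ AmidDz],
            format="csr")
        # d/dr sigma_rz: flux G (du_r/dz + du_z/dr)
        flux_rz = sp.hstack([Xm(G_m) @ AmidDz, Xm(G_m) @ DmidK], format="csr")

        R_r = (DnodeK @ flux_rr
               + sp.hstack([X(G) @ Dzz, X(G) @ Drz], format="csr")  # d/dz sigma_rz
               + X(1.0 / r) @ (S_rr - S_tt))
        R_z = (DnodeK @ flux_rz
               + sp.hstack([X(lam) @ Drz + X(lam / r) @ Dz, X(c1) @ Dzz],
                           format="csr")                            # d/dz sigma_zz
               + X(1.0 / r) @ S_rz)

    A = sp.vstack([R_r, R_z], format="csr")

    # Node index bookkeeping (row-major: node = i * n_z + j)
    ids = np.arange(n).reshape(n_r, n_z)
    end_nodes = np.unique(np.concatenate([ids[:, 0], ids[:, -1]]))
    if scenario.ends == "fixed":
        # Built-in ends take precedence at the corners.
        inner_nodes = ids[0, 1:-1]
        outer_nodes = ids[-1, 1:-1]
        rz_inner, rz_outer = inner_nodes, outer_nodes
        identity_rows = np.concatenate([end_nodes, n + end_nodes])
        end_srz_nodes = np.array([], dtype=int)
    else:
        # Sliding ends: u_z = 0 and s_rz = 0 on the end planes; the corners
        # keep the surface normal-traction condition (s_rr = -P / 0).
        inner_nodes = ids[0, :]
        outer_nodes = ids[-1, :]
        rz_inner, rz_outer = ids[0, 1:-1], ids[-1, 1:-1]
        identity_rows = n + end_nodes
        end_srz_nodes = np.unique(np.concatenate([ids[1:-1, 0], ids[1:-1, -1]]))

    bc_rows = np.concatenate([
        inner_nodes, outer_nodes, end_srz_nodes,
        n + rz_inner, n + rz_outer, identity_rows,
    ])
    interior_mask = np.ones(2 * n)
    interior_mask[bc_rows] = 0.0

    # Surface condition rows and the pressure-load map P(z) -> F.
    # DQM: collocated traction operators (one-sided radial derivatives of the
    # global polynomial handle graded moduli well on the clustered grid).
    # FD: half-cell (finite-volume) momentum balances in which the prescribed
    # traction enters as the boundary flux, and the radial displacement
    # gradient at the surface is eliminated through the traction condition
    # itself — a one-sided difference there is badly inconsistent when the
    # property slope is unbounded (grading index < 1).
    P_load = sp.lil_matrix((2 * n, n_z))
    if scenario.method == "dqm":
        row_in_rr = S_rr[inner_nodes]
        row_out_rr = S_rr[outer_nodes]
        row_in_rz = S_rz[rz_inner]
        row_out_rz = S_rz[rz_outer]
        P_load[inner_nodes, inner_nodes % n_z] = -1.0
    else:
        lam0, c10, lamN, c1N = lam[0], c1[0], lam[-1], c1[-1]
        r0, rN = r[0], r[-1]
        e0 = sp.csr_matrix((np.ones(1), (np.zeros(1), np.zeros(1))), shape=(1, n_r))
        eN = sp.csr_matrix((np.ones(1), (np.zeros(1), [n_r - 1])), shape=(1, n_r))
        R0 = sp.kron(e0, Iz, format="csr")
        RN = sp.kron(eN, Iz, format="csr")
        Z0 = sp.csr_matrix((n_z, n))
        two_h = 2.0 / h_r

        def _surface_rows(flux_blk, sgn, lam_s, c1_s, r_s, Rsel):
            k_u = c1_s - lam_s**2 / c1_s
            k_w = lam_s - lam_s**2 / c1_s
            B_r = (sgn * two_h * flux_blk[0]
                   - (1.0 / r_s) * sp.hstack(
                       [(k_u / r_s) * Rsel, k_w * (D1z @ Rsel)], format="csr"))
            B_z = (sgn * two_h * flux_blk[1]
                   + sp.hstack([(k_w / r_s) * (D1z @ Rsel),
                                k_u * (D2z @ Rsel)], format="csr"))
            return B_r, B_z

        B_in_r, B_in_z = _surface_rows(
            (flux_rr[:n_z], flux_rz[:n_z]), +1.0, lam0, c10, r0, R0)
        B_out_r, B_out_z = _surface_rows(
            (flux_rr[-n_z:], flux_rz[-n_z:]), -1.0, lamN, c1N, rN, RN)

        j_in = inner_nodes            # node (0, j) has id j
        j_out = outer_nodes - (n_r - 1) * n_z
        jz_in = rz_inner
        jz_out = rz_outer - (n_r - 1) * n_z
        row_in_rr = B_in_r[j_in]
        row_out_rr = B_out_r[j_out]
        row_in_rz = B_in_z[jz_in]
        row_out_rz = B_out_z[jz_out]

        c_in = -two_h + (1.0 - lam0 / c10) / r0
        P_load[inner_nodes, j_in] = c_in
        P_load[n + rz_inner, :] = (lam0 / c10) * sp.csr_matrix(D1z)[jz_in, :]
    P_load = P_load.tocsr()

    K = sp.diags(interior_mask) @ (-A)
    shape = (2 * n, 2 * n)
    K = K + _place_rows(inner_nodes, row_in_rr, shape)
    K = K + _place_rows(outer_nodes, row_out_rr, shape)
    K = K + _place_rows(n + rz_inner, row_in_rz, shape)
    K = K + _place_rows(n + rz_outer, row_out_rz, shape)
    if end_srz_nodes.size:
        K = K + _place_rows(end_srz_nodes, S_rz[end_srz_nodes], shape)
    K = K + sp.coo_matrix(
        (np.ones(identity_rows.size), (identity_rows, identity_rows)), shape=shape
    ).tocsr()

    M_diag = np.concatenate([np.repeat(rho, n_z)] * 2) * interior_mask

    gravity_F = np.zeros(2 * n)
    if scenario.gravity:
        gravity_F[n : 2 * n] = -np.repeat(rho, n_z) * scenario.gravity
        gravity_F *= interior_mask

    # Row equilibration: momentum rows scale like E/h^2 while constraint rows
    # are O(E/h) or O(1); scaling each row of (M, C, K, F) by its max |K|
    # entry preserves the solution and keeps the LU factorization accurate.
    K = K.tocsr()
    row_max = np.maximum(np.abs(K).max(axis=1).toarray().ravel(), 1e-300)
    inv_row_scale = 1.0 / row_max
    D = sp.diags(inv_row_scale)
    K = (D @ K).tocsr()
    M_diag = M_diag * inv_row_scale
    gravity_F = gravity_F * inv_row_scale
    P_load = (D @ P_load).tocsr()

    return AssembledSystem(
        scenario=scenario, disc=disc, K=K, M_diag=M_diag,
        stress_ops=stress_ops, interior_mask=interior_mask,
        P_load=P_load,
        gravity_F=gravity_F, inv_row_scale=inv_row_scale,
    )


# ----------------------------------------------------------------------------
# Time integration
# ----------------------------------------------------------------------------

class _Factorized:
    """Uniform dense/sparse LU front-end."""

    def __init__(self, Amat: sp.spmatrix):
        if Amat.shape[0] <= _DENSE_CUTOFF:
            self._lu = lu_factor(Amat.toarray())
            self._solve = lambda b: lu_solve(self._lu, b)
        else:
            self._splu = spla.splu(Amat.tocsc())
            self._solve = self._splu.solve

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._solve(b)


class NewmarkStepper:
    """Newmark-beta integrator over M u_tt + C u_t + K u = F(t).

    Boundary rows (zero mass/damping) are enforced exactly at the new time
    level.  ``trial(F_next)`` solves a step without committing it, which is
    what the partitioned fluid-structure iteration needs; ``commit`` advances
    the state.
    """

    def __init__(self, system: AssembledSystem, dt: float | None = None):
        sc = system.scenario
        self.system = system
        self.dt = dt if dt is not None else sc.dt
        beta, gamma = sc.beta, sc.gamma
        self.a0 = 1.0 / (beta * self.dt**2)
        self.a2 = 1.0 / (beta * self.dt)
        self.a3 = 1.0 / (2.0 * beta) - 1.0
        self.a1 = gamma / (beta * self.dt)
        self.a4 = gamma / beta - 1.0
        self.a5 = self.dt * (gamma / (2.0 * beta) - 1.0)
        self.beta, self.gamma = beta, gamma

        n2 = system.K.shape[0]
        self.C = None
        Keff = system.K + sp.diags(self.a0 * system.M_diag)
        if sc.alpha_K > 0:
            self.C = sp.diags(system.interior_mask) @ (sc.alpha_K * system.K)
            Keff = Keff + self.a1 * self.C
        self._solve = _Factorized(Keff.tocsr())

        self.u = np.zeros(n2)
        self.v = np.zeros(n2)
        # Initial acceleration from the initial load (diagonal mass)
        F0 = system.load(0.0)
        self.a = np.zeros(n2)
        m = system.M_diag > 0
        self.a[m] = (F0[m] - (system.K @ self.u)[m]) / system.M_diag[m]
        self.step_count = 0

    def trial(self, F_next: np.ndarray) -> np.ndarray:
        """Solve for the next displacement under a candidate load, uncommitted."""
        sys_ = self.system
        rhs = F_next + sys_.M_diag * (self.a0 * self.u + self.a2 * self.v + self.a3 * self.a)
        if self.C is not None:
            rhs = rhs + self.C @ (self.a1 * self.u + self.a4 * self.v + self.a5 * self.a)
        u1 = self._solve(rhs)
        if not np.all(np.isfinite(u1)):
            raise FloatingPointError(
                f"Newmark step {self.step_count + 1} produced non-finite values"
            )
        return u1

    def commit(self, u1: np.ndarray) -> None:
        a1 = self.a0 * (u1 - self.u) - self.a2 * self.v - self.a3 * self.a
        self.v = self.v + self.dt * ((1.0 - self.gamma) * self.a + self.gamma * a1)
        self.u, self.a = u1, a1
        self.step_count += 1

    def step(self, F_next: np.ndarray) -> np.ndarray:
        u1 = self.trial(F_next)
        self.commit(u1)
        return u1

    def energy(self) -> float:
        """Discrete total energy proxy: kinetic + strain (interior rows)."""
        e_kin = 0.5 * float(self.v @ (self.system.M_diag * self.v))
        Ku = self.system.interior_mask * (self.system.K @ self.u)
        return e_kin + 0.5 * float(self.u @ Ku)


def newmark_integrate(
    system: AssembledSystem,
    load: Callable[[float], np.ndarray],
    dt: float,
    t_end: float,
    beta: float = 0.25,
    gamma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate and return (times, displacement history as (2n, n_t) array)."""
    sc = replace(system.scenario, dt=dt, beta=beta, gamma=gamma)
    stepper = NewmarkStepper(replace_system_scenario(system, sc), dt)
    n_t = int(round(t_end / dt)) + 1
    times = np.linspace(0.0, t_end, n_t)
    hist = np.zeros((system.K.shape[0], n_t))
    for k in range(1, n_t):
        hist[:, k] = stepper.step(load(times[k]))
    return times, hist


def replace_system_scenario(system: AssembledSystem, scenario: Scenario) -> AssembledSystem:
    """System with integrator-relevant scenario fields swapped (no reassembly)."""
    return AssembledSystem(
        scenario=scenario, disc=system.disc, K=system.K, M_diag=system.M_diag,
        stress_ops=system.stress_ops, interior_mask=system.interior_mask,
        P_load=system.P_load,
        gravity_F=system.gravity_F, inv_row_scale=system.inv_row_scale,
    )


# ----------------------------------------------------------------------------
# Field container
# ----------------------------------------------------------------------------

@dataclass
class FieldSolution:
    """Displacement and stress fields over the (r, z, t) grid."""

    r: np.ndarray
    z: np.ndarray
    t: np.ndarray
    u_r: np.ndarray
    u_z: np.ndarray
    s_rr: np.ndarray
    s_tt: np.ndarray
    s_zz: np.ndarray
    s_rz: np.ndarray
    metadata: dict = field(default_factory=dict)

    FIELD_NAMES = ("u_r", "u_z") + STRESS_NAMES

    def field(self, name: str) -> np.ndarray:
        if name not in self.FIELD_NAMES:
            raise KeyError(f"unknown field {name!r}")
        return getattr(self, name)

    def interp(self, name: str, r_pts, z_pts, t_index=None) -> np.ndarray:
        """Cubic tensor-spline evaluation of a field at off-grid points.

        Returns an array of shape (len(r_pts), len(z_pts), n_t_selected).
        """
        f = self.field(name)
        kx = min(3, self.r.size - 1)
        ky = min(3, self.z.size - 1)
        t_sel = np.arange(f.shape[2]) if t_index is None else np.atleast_1d(t_index)
        out = np.empty((np.size(r_pts), np.size(z_pts), t_sel.size))
        for m, k in enumerate(t_sel):
            spl = RectBivariateSpline(self.r, self.z, f[:, :, k], kx=kx, ky=ky)
            out[:, :, m] = spl(np.atleast_1d(r_pts), np.atleast_1d(z_pts))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        R, Z, T = np.meshgrid(self.r, self.z, self.t, indexing="ij")
        cols = {"r_m": R.ravel(), "z_m": Z.ravel(), "t_s": T.ravel()}
        for nm, col in zip(self.FIELD_NAMES,
                           ("u_r_m", "u_z_m", "s_rr_Pa", "s_tt_Pa", "s_zz_Pa", "s_rz_Pa")):
            cols[col] = self.field(nm).ravel()
        return pd.DataFrame(cols)

    def export(self, path) -> None:
        """Long-format delimited text export."""
        self.to_dataframe().to_csv(path, index=False)

    def save(self, path) -> None:
        """Binary round-trip container (NumPy archive)."""
        np.savez_compressed(
            path, r=self.r, z=self.z, t=self.t,
            **{nm: self.field(nm) for nm in self.FIELD_NAMES},
        )

    @classmethod
    def load(cls, path) -> "FieldSolution":
        d = np.load(path)
        return cls(r=d["r"], z=d["z"], t=d["t"],
                   **{nm: d[nm] for nm in cls.FIELD_NAMES})


# ----------------------------------------------------------------------------
# Drivers
# ----------------------------------------------------------------------------

def _collect(system: AssembledSystem, times: np.ndarray,
             u_hist_iter, runtime0: float) -> FieldSolution:
    disc = system.disc
    n_r, n_z, n = disc.r.size, disc.z.size, disc.r.size * disc.z.size
    n_t = times.size
    arrays = {nm: np.zeros((n_r, n_z, n_t)) for nm in FieldSolution.FIELD_NAMES}
    energy = np.zeros(n_t)
    for k, (u, e) in enumerate(u_hist_iter):
        arrays["u_r"][:, :, k] = u[:n].reshape(n_r, n_z)
        arrays["u_z"][:, :, k] = u[n:].reshape(n_r, n_z)
        for nm, s in system.recover_stresses(u).items():
            arrays[nm][:, :, k] = s.reshape(n_r, n_z)
        energy[k] = e
    meta = {
        "scenario_hash": system.scenario.hash(),
        "solver": system.scenario.method,
        "runtime_s": _time.perf_counter() - runtime0,
        "energy": energy,
    }
    return FieldSolution(r=disc.r, z=disc.z, t=times, metadata=meta, **arrays)


def solve(
    scenario: Scenario,
    pressure_field: Callable[[np.ndarray, float], np.ndarray] | None = None,
    flow=None,
) -> FieldSolution:
    """Run the elastodynamic simulation of a scenario.

    By default the inner surface carries the scenario waveform uniformly
    along the axis.  ``pressure_field(z_grid, t)`` overrides it with an
    axially varying load; passing ``flow`` (FlowParams) instead derives that
    field from the reduced-order lumen model (one-way coupling).
    """
    t0 = _time.perf_counter()
    system = assemble(scenario)
    n_t = int(round(scenario.t_end / scenario.dt)) + 1
    times = np.linspace(0.0, scenario.t_end, n_t)

    if pressure_field is None and flow is not None:
        z = system.disc.z
        P_xt = axial_pressure_profile(scenario.waveform, flow, z, times)
        pressure_field = lambda zg, t: P_xt[:, int(round(t / scenario.dt))]  # noqa: E731

    stepper = NewmarkStepper(system)

    def history():
        yield stepper.u, stepper.energy()
        for k in range(1, n_t):
            if pressure_field is None:
                F = system.load(times[k])
            else:
                F = system.load_from_inner_pressure(pressure_field(system.disc.z, times[k]))
            stepper.step(F)
            yield stepper.u, stepper.energy()

    return _collect(system, times, history(), t0)


def solve_static(scenario: Scenario, P_in: float) -> FieldSolution:
    """Static solve under a uniform inner pressure (single time level)."""
    t0 = _time.perf_counter()
    system = assemble(scenario)
    F = system.load_from_inner_pressure(np.full(system.disc.z.size, P_in))
    u = _Factorized(system.K)(F)
    times = np.array([0.0])
    return _collect(system, times, iter([(u, 0.0)]), t0)


# ----------------------------------------------------------------------------
# Lame closed form (plane-strain thick cylinder)
# ----------------------------------------------------------------------------

def lame_solution(geometry: Geometry, E: float, nu: float, P_in: float):
    """Plane-strain Lame fields of a homogeneous cylinder under inner pressure.

    Returns (s_rr(r), s_tt(r), s_zz(r), u_r(r)) as vectorized callables:

        s_rr = A - B / r^2,  s_tt = A + B / r^2,  s_zz = 2 nu A,
        u_r  = (1 + nu)/E * ((1 - 2 nu) A r + B / r)

    with A = P_in r_in^2 / (r_out^2 - r_in^2) and B = A r_out^2, so that
    s_rr(r_in) = -P_in and s_rr(r_out) = 0.
    """
    a2, b2 = geometry.r_in**2, geometry.r_out**2
    A = P_in * a2 / (b2 - a2)
    B = A * b2
    s_rr = lambda r: A - B / np.asarray(r, float) ** 2  # noqa: E731
    s_tt = lambda r: A + B / np.asarray(r, float) ** 2  # noqa: E731
    s_zz = lambda r: 2.0 * nu * A * np.ones_like(np.asarray(r, float))  # noqa: E731
    u_r = lambda r: (1.0 + nu) / E * (  # noqa: E731
        (1.0 - 2.0 * nu) * A * np.asarray(r, float) + B / np.asarray(r, float)
    )
    return s_rr, s_tt, s_zz, u_r


# ----------------------------------------------------------------------------
# Cross-method validation experiment
# ----------------------------------------------------------------------------

def validation_scenario(method: str = "dqm", **overrides) -> Scenario:
    """Graded-cylinder benchmark: r in [0.8, 1.0] m, nu = 0.3, power-law
    density and modulus, half-sine pressure pulse of 16 kPa over one period.

    The benchmark geometry has no printed length; L = 2.0 m (L/h = 10) keeps
    the mid-length section in the plane-strain regime.
    """
    base = dict(
        geometry=Geometry(r_in=0.8, r_out=1.0, L=2.0),
        wall=PowerLawWall(),
        waveform=sinusoid(16000.0),
        t_end=2.0,
        dt=0.01,
        method=method,
    )
    base.update(overrides)
    return Scenario(**base)


def compare_solutions(
    ref: FieldSolution,
    other: FieldSolution,
    fields: tuple[str, ...] = ("u_r", "s_tt", "s_zz"),
    r_pts: np.ndarray | None = None,
    z_pts: np.ndarray | None = None,
    t_window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Normalized max discrepancies (%) between two solutions.

    Both solutions are evaluated (cubic tensor splines) on a common
    evaluation grid — by default the coarser solution's own nodes — at the
    shared time levels; per field the result is
    ``100 * max|a - b| / max|ref|`` over the full space-time evaluation grid.
    """
    if ref.t.size != other.t.size or not np.allclose(ref.t, other.t):
        raise ValueError("solutions must share the time grid")
    if r_pts is None:
        r_pts = ref.r if ref.r.size <= other.r.size else other.r
    if z_pts is None:
        z_pts = ref.z if ref.z.size <= other.z.size else other.z
    if t_window is None:
        t_idx = np.arange(ref.t.size)
    else:
        t_idx = np.where((ref.t >= t_window[0]) & (ref.t <= t_window[1]))[0]

    errors = {}
    for nm in fields:
        a = ref.interp(nm, r_pts, z_pts, t_index=t_idx)
        b = other.interp(nm, r_pts, z_pts, t_index=t_idx)
        scale = np.max(np.abs(a))
        errors[nm] = 100.0 * float(np.max(np.abs(a - b)) / scale)
    return errors


def run_validation_case(
    dqm_shape: tuple[int, int] | None = None,
    fd_shape: tuple[int, int] | None = None,
    dt: float = 0.01,
    t_end: float = 2.0,
    fd_refine: int = 1,
) -> dict:
    """Run the benchmark with both discretizations and report discrepancies.

    Returns a dict with per-quantity max relative discrepancies (%) keyed
    ``u_r``, ``s_tt``, ``s_zz``, plus the two solutions.  ``fd_refine``
    multiplies the FD grid density (used by convergence checks).

    The discrepancy norm is the max over the mid-thickness report line
    (all axial positions, all times) of the absolute difference, normalized
    by the reference max on that line.  Mid-thickness is where the model's
    outputs are reported; at the clamped-end corners the continuum stress
    field is singular, so a pointwise norm evaluated arbitrarily close to
    the corners would not converge under grid refinement.
    """
    kw_dqm = {"dt": dt, "t_end": t_end}
    if dqm_shape is not None:
        kw_dqm.update(n_r=dqm_shape[0], n_z=dqm_shape[1])
    sc_dqm = validation_scenario("dqm", **kw_dqm)

    nr_fd, nz_fd = fd_shape if fd_shape is not None else (41, 161)
    if fd_refine > 1:
        nr_fd = (nr_fd - 1) * fd_refine + 1
        nz_fd = (nz_fd - 1) * fd_refine + 1
    sc_fd = validation_scenario("fd", dt=dt, t_end=t_end, n_r=nr_fd, n_z=nz_fd)

    sol_dqm = solve(sc_dqm)
    sol_fd = solve(sc_fd)
    r_mid = np.array([0.5 * (sc_dqm.geometry.r_in + sc_dqm.geometry.r_out)])
    errors = compare_solutions(sol_dqm, sol_fd, r_pts=r_mid, z_pts=sol_dqm.z)
    return {"errors_pct": errors, "dqm": sol_dqm, "fd": sol_fd}
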