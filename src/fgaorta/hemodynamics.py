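"""Reduced-order blood model for a compliant vessel segment.

The lumen flow is treated as laminar, incompressible and Newtonian.  The
pressure field P(x, t) over axial position and time is built from:

* an inlet waveform (half-sine systolic pulse ``P0 sin(pi t)`` or a tabulated
  periodic physiological waveform),
* the Poiseuille axial pressure gradient ``dP/dx = -8 mu Q / (pi r(x)^4)``,
* a local quasi-static thin-wall balance between the pressure-induced hoop
  stress ``P r / t_wall`` and the linear-elastic hoop strain
  ``E_in (r - r_in)/r_in`` which yields the distended radius r(x).

This reduced model is what the structural solver is coupled against; it
replaces a discretized lumen and is valid for the small viscous pressure
drops of a short, wide aorta segment.

Two flow-rate-like parameters are deliberately kept distinct and never
interchanged: ``Q_vol`` (m^3/s) is the volumetric rate entering the
Poiseuille gradient, while ``Q_shear`` (1/s) is the velocity-to-distance
ratio entering the wall-shear relation ``tau = mu * U / d = mu * Q_shear``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "sinusoid",
    "tabulated",
    "FlowParams",
    "sinusoid_pressure",
    "poiseuille_gradient",
    "thinwall_hoop_stress",
    "hoop_strain",
    "wall_shear",
    "wall_shear_from_Q",
    "equilibrium_radius",
    "axial_pressure_profile",
    "exponential_decay_profile",
]


@dataclass(frozen=True)
class Waveform:
    """Inlet pressure (or velocity) waveform.

    ``kind`` is ``"sinusoid"`` (half-sine pulse of amplitude ``P0``) or
    ``"tabulated"`` (periodic linear interpolation of (time, value) samples
    over ``period`` seconds).  The sinusoid ``P0 sin(pi t)`` has period 2 s.
    """

    kind: str
    P0: float = 0.0
    times: np.ndarray | None = None
    values: np.ndarray | None = None
    period: float | None = None
    seam_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind == "sinusoid":
            if self.P0 <= 0:
                raise ValueError("sinusoid waveform requires P0 > 0")
        elif self.kind == "tabulated":
            t = np.asarray(self.times, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError("tabulated waveform needs matching 1D time/value arrays")
            if np.any(np.diff(t) <= 0):
                raise ValueError("tabulated sample times must be strictly increasing")
            period = self.period if self.period is not None else t[-1] - t[0]
            if period <= 0:
                raise ValueError("waveform period must be positive")
            object.__setattr__(self, "period", float(period))
            object.__setattr__(self, "times", t)
            object.__setattr__(self, "values", v)
            # Periodic extension must be continuous at the seam.
            scale = max(np.max(np.abs(v)), 1.0)
            if t[-1] - t[0] >= period - 1e-12 and abs(v[-1] - v[0]) > self.seam_tol * scale:
                raise ValueError("tabulated waveform discontinuous at the periodic seam")
        else:
            raise ValueError(f"unknown waveform kind {self.kind!r}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoid":
            out = self.P0 * np.sin(np.pi * t)
        else:
            tau = self.times[0] + np.mod(t - self.times[0], self.period)
            out = np.interp(tau, self.times, self.values)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_table(cls, path) -> "Waveform":
        """Read a tabulated waveform from two-column delimited text (time_s, value)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        t, v = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        return cls(kind="tabulated", times=t, values=v)

    def to_table(self, path) -> None:
        if self.kind != "tabulated":
            raise ValueError("only tabulated waveforms are exported as tables")
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(path, index=False)


def sinusoid(P0: float) -> Waveform:
    return Waveform(kind="sinusoid", P0=P0)


def tabulated(times, values, period: float | None = None) -> Waveform:
    return Waveform(kind="tabulated", times=np.asarray(times), values=np.asarray(values),
                    period=period)


@dataclass(frozen=True)
class FlowParams:
    """Reduced-order fluid parameters.

    Attributes
    ----------
    mu : dynamic viscosity, Pa.s.
    Q_shear : velocity-to-travelled-distance ratio at the wall, 1/s
        (feeds the wall shear ``tau = mu * Q_shear``).
    Q_vol : volumetric flow rate, m^3/s (feeds the Poiseuille gradient).
    t_wall : thin-wall thickness used by the local distension balance, m.
    E_in : elastic modulus at the inner radius, Pa.
    r_in, r_out : unloaded internal / external radii, m.
    """

    mu: float = 0.0035
    Q_shear: float = 11.91
    Q_vol: float = 1e-4
    t_wall: float = 0.00232
    E_in: float = 1.9e6
    r_in: float = 0.0168
    r_out: float = 0.01912

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")
        if self.t_wall <= 0:
            raise ValueError("thin-wall thickness must be positive")
        if not (self.r_out > self.r_in > 0):
            raise ValueError("radii must satisfy r_out > r_in > 0")

    @property
    def tau(self) -> float:
        """Wall shear stress from the velocity/distance ratio, Pa."""
        return wall_shear_from_Q(self.mu, self.Q_shear)

    @staticmethod
    def Q_vol_from_velocity(U: float, r_in: float) -> float:
        """Volumetric rate from a mean inlet velocity and the lumen area."""
        return float(U * np.pi * r_in**2)


def sinusoid_pressure(t, P0: float):
    """Half-sine inlet pressure ``P0 sin(pi t)`` (Pa); period 2 s."""
    out = P0 * np.sin(np.pi * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def poiseuille_gradient(Q_vol: float, mu: float, r) -> float:
    """Poiseuille axial pressure gradient ``-8 mu Q / (pi r^4)``, Pa/m."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lumen radius must be positive")
    out = -8.0 * mu * Q_vol / (np.pi * r**4)
    return float(out) if out.ndim == 0 else out


def thinwall_hoop_stress(P: float, r: float, t_wall: float) -> float:
    """Thin-wall hoop stress ``P r / t_wall`` (Pa)."""
    if t_wall <= 0:
        raise ValueError("wall thickness must be positive")
    return P * r / t_wall


def hoop_strain(r: float, r_in: float) -> float:
    """Engineering hoop strain ``(r - r_in) / r_in`` of the distended wall."""
    if r_in <= 0:
        raise ValueError("reference radius must be positive")
    return (r - r_in) / r_in


def wall_shear(mu: float, U: float, d: float) -> float:
    """Wall shear stress ``mu U / d`` (Pa)."""
    if d <= 0:
        raise ValueError("distance travelled by the flow must be positive")
    return mu * U / d


def wall_shear_from_Q(mu: float, Q_shear: float) -> float:
    """Wall shear ``mu * Q_shear`` with Q_shear = U/d (1/s)."""
    return mu * Q_shear


def equilibrium_radius(P: float, params: FlowParams) -> float:
    """Distended local radius from the quasi-static thin-wall balance.

    Solves ``P r / t_wall = E_in (r - r_in) / r_in`` for r.  The balance is
    linear in r with the unique root ``r = E t r_in / (E t - P r_in)``; a
    physical (positive, bounded) root requires ``P < E_in t_wall / r_in``.
    For P = 0 the unloaded radius is returned; a rigid wall (E_in -> inf)
    likewise returns r_in.
    """
    E, t, r_in = params.E_in, params.t_wall, params.r_in
    denom = E * t - P * r_in
    if denom <= 0:
        raise ValueError(
            f"pressure {P:.6g} Pa beyond the thin-wall distension limit "
            f"{E * t / r_in:.6g} Pa: no physical equilibrium radius"
        )
    return E * t * r_in / denom


def _rk4_march(x_grid: np.ndarray, P_inlet: float, radius_of: Callable[[float, float], float],
               mu: float, Q_vol: float, substeps: int) -> np.ndarray:
    """March dP/dx = -8 mu Q / (pi r(x, P)^4) along x with classical RK4."""

    def f(x, P):
        return poiseuille_gradient(Q_vol, mu, radius_of(x, P))

    P = np.empty_like(x_grid)
    P[0] = P_inlet
    for k in range(len(x_grid) - 1):
        x0, x1 = x_grid[k], x_grid[k + 1]
        h = (x1 - x0) / substeps
        p, x = P[k], x0
        for _ in range(substeps):
            k1 = f(x, p)
            k2 = f(x + h / 2, p + h * k1 / 2)
            k3 = f(x + h / 2, p + h * k2 / 2)
            k4 = f(x + h, p + h * k3)
            p = p + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            x += h
        P[k + 1] = p
    return P


def axial_pressure_profile(
    waveform: Waveform,
    params: FlowParams,
    x_grid: np.ndarray,
    t_grid: np.ndarray,
    wall_radius: Callable[[np.ndarray], np.ndarray] | None = None,
    n_march: int = 200,
) -> np.ndarray:
    """Pressure field P(x, t) over the vessel length, shape (len(x), len(t)).

    For each time the inlet value is the waveform sample and the Poiseuille
    gradient is marched along x with a fixed-step classical fourth-order
    integrator (``n_march`` steps over the full length).  The local lumen
    radius is the thin-wall equilibrium radius of the local pressure, or,
    when ``wall_radius`` is given (two-way coupling), the structural wall
    radius interpolated at x — in that case the profile is independent of P
    and the march reduces to quadrature of a known gradient.

    With zero flow or zero viscosity the profile equals the inlet waveform
    everywhere; with positive flow each time-column is non-increasing in x.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if x_grid.size == 0 or t_grid.size == 0:
        raise ValueError("empty evaluation grid")
    if x_grid[0] != 0 or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x grid must start at the inlet (0) and increase")

    if wall_radius is not None:
        r_of_x = wall_radius(x_grid)
        r_interp = lambda x, P: float(np.interp(x, x_grid, r_of_x))  # noqa: E731
    else:
        r_interp = lambda x, P: equilibrium_radius(P, params)  # noqa: E731

    L = x_grid[-1]
    if L == 0:
        return np.tile(waveform(t_grid), (1, 1)).reshape(1, -1)
    substeps = max(1, int(np.ceil(n_march * np.max(np.diff(x_grid)) / L)))

    P = np.empty((x_grid.size, t_grid.size))
    for j, t in enumerate(t_grid):
        P[:, j] = _rk4_march(x_grid, float(waveform(t)), r_interp,
                             params.mu, params.Q_vol, substeps)
    return P


def exponential_decay_profile(waveform: Waveform, params: FlowParams,
                              x_grid, t_grid) -> np.ndarray:
    """Reconstructed closed-form comparison profile (labelled, not primary).

    ``P(x, t) = P0(t) * exp(-2 tau x / (E_in * t_wall))`` — an exponential
    axial decay driven by the wall shear ``tau = mu * Q_shear``.  Provided
    only as a comparison mode for the numerically marched profile.
    """
    x = np.asarray(x_grid, dtype=float)[:, None]
    t = np.asarray(t_grid, dtype=float)[None, :]
    decay = np.exp(-2.0 * params.tau * x / (params.E_in * params.t_wall))
    return decay * waveform(t)


def export_pressure_field(path, x_grid, t_grid, P) -> None:
    """Write P(x, t) as long-format delimited text (x_m, t_s, P_Pa)."""
    X, T = np.meshgrid(np.asarray(x_grid), np.asarray(t_grid), indexing="ij")
    pd.DataFrame({"x_m": X.ravel(), "t_s": T.ravel(), "P_Pa": np.asarray(P).ravel()}
                 ).to_csv(path, index=False)
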