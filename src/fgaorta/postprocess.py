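"""Derived quantities and report surfaces.

Nondimensionalization of the solution fields, von Mises equivalent stress,
1D profile extraction along length / thickness / time, and peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structural import FieldSolution

__all__ = [
    "Nondimensionalization",
    "nondim",
    "redim",
    "von_mises",
    "extract_profile",
    "peak_times",
]

# Fixed reference stress scale for the dimensionless radial displacement.
K_STRESS_SCALE = 10e9  # Pa


@dataclass(frozen=True)
class Nondimensionalization:
    """Scales turning (t, z, r, u_r, sigma) into (T, Z, R, Ur, S_i).

    T = t/te, Z = z/L, R = r/r_i, Ur = u_r * K / (P0 * h), S_i = sigma_i/P0
    with the fixed stress scale K = 10 GPa.
    """

    te: float          # loading duration, s
    L: float           # vessel length, m
    r_i: float         # internal radius, m
    h: float           # wall thickness, m
    P0: float          # pressure scale, Pa
    K: float = K_STRESS_SCALE

    def __post_init__(self) -> None:
        for nm in ("te", "L", "r_i", "h", "P0", "K"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"nondimensional scale {nm} must be positive")


def nondim(solution: FieldSolution, scales: Nondimensionalization) -> dict[str, np.ndarray]:
    """Dimensionless fields of a solution: T, Z, R, Ur, S_r, S_t, S_z, S_rz."""
    return {
        "T": solution.t / scales.te,
        "Z": solution.z / scales.L,
        "R": solution.r / scales.r_i,
        "Ur": solution.u_r * scales.K / (scales.P0 * scales.h),
        "S_r": solution.s_rr / scales.P0,
        "S_t": solution.s_tt / scales.P0,
        "S_z": solution.s_zz / scales.P0,
        "S_rz": solution.s_rz / scales.P0,
    }


def redim(fields: dict[str, np.ndarray], scales: Nondimensionalization) -> dict[str, np.ndarray]:
    """Inverse of :func:`nondim` (round-trip identity)."""
    return {
        "t": fields["T"] * scales.te,
        "z": fields["Z"] * scales.L,
        "r": fields["R"] * scales.r_i,
        "u_r": fields["Ur"] * scales.P0 * scales.h / scales.K,
        "s_rr": fields["S_r"] * scales.P0,
        "s_tt": fields["S_t"] * scales.P0,
        "s_zz": fields["S_z"] * scales.P0,
        "s_rz": fields["S_rz"] * scales.P0,
    }


def von_mises(s_rr, s_tt, s_zz, s_rz=0.0) -> np.ndarray:
    """Equivalent (von Mises) stress of an axisymmetric state.

    sqrt(((s_rr-s_tt)^2 + (s_tt-s_zz)^2 + (s_zz-s_rr)^2)/2 + 3 s_rz^2);
    invariant under hydrostatic shifts and equal to |s| for uniaxial states.
    """
    s_rr, s_tt, s_zz = (np.asarray(x, float) for x in (s_rr, s_tt, s_zz))
    s_rz = np.asarray(s_rz, float)
    out = np.sqrt(
        ((s_rr - s_tt) ** 2 + (s_tt - s_zz) ** 2 + (s_zz - s_rr) ** 2) / 2.0
        + 3.0 * s_rz**2
    )
    return float(out) if out.ndim == 0 else out


def _nearest(grid: np.ndarray, value: float, label: str) -> int:
    grid = np.asarray(grid)
    if value < grid.min() - 1e-12 or value > grid.max() + 1e-12:
        raise ValueError(f"{label}={value} outside the solution domain "
                         f"[{grid.min()}, {grid.max()}]")
    return int(np.argmin(np.abs(grid - value)))


def extract_profile(
    solution: FieldSolution,
    name: str,
    axis: str,
    r: float | None = None,
    z: float | None = None,
    t: float | None = None,
) -> pd.DataFrame:
    """1D profile of a field along ``length`` (z), ``thickness`` (r) or ``time``.

    The two remaining coordinates are fixed at the *nearest grid node* (no
    interpolation, so values are bit-identical to the stored field); defaults
    are mid-thickness, mid-length, and the final time.  Returns a two-column
    DataFrame whose attrs record the fixed coordinates actually used.
    """
    if axis not in ("length", "thickness", "time"):
        raise ValueError(f"unknown profile axis {axis!r}")
    f = solution.field(name)
    ir = _nearest(solution.r, r if r is not None else
                  0.5 * (solution.r[0] + solution.r[-1]), "r")
    iz = _nearest(solution.z, z if z is not None else
                  0.5 * (solution.z[0] + solution.z[-1]), "z")
    it = _nearest(solution.t, t if t is not None else solution.t[-1], "t")

    if axis == "length":
        df = pd.DataFrame({"z_m": solution.z, name: f[ir, :, it]})
        fixed = {"r_m": solution.r[ir], "t_s": solution.t[it]}
    elif axis == "thickness":
        df = pd.DataFrame({"r_m": solution.r, name: f[:, iz, it]})
        fixed = {"z_m": solution.z[iz], "t_s": solution.t[it]}
    else:
        df = pd.DataFrame({"t_s": solution.t, name: f[ir, iz, :]})
        fixed = {"r_m": solution.r[ir], "z_m": solution.z[iz]}
    df.attrs["fixed"] = fixed
    return df


def export_profile(df: pd.DataFrame, path) -> None:
    """Two-column delimited text with a header naming the fixed coordinates."""
    with open(path, "w") as fh:
        fixed = df.attrs.get("fixed", {})
        fh.write("# fixed: " + ", ".join(f"{k}={v:.8g}" for k, v in fixed.items()) + "\n")
        df.to_csv(fh, index=False)


def peak_times(t: np.ndarray, series: np.ndarray) -> float:
    """Time of the series maximum (earliest sample on plateau ties).

    Raises on a constant series, which has no unique peak.
    """
    t = np.asarray(t, float)
    y = np.asarray(series, float)
    if y.size < 3:
        raise ValueError("need at least 3 samples to locate a peak")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no unique peak")
    return float(t[int(np.argmax(y))])
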