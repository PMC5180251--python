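"""Constituent biomaterials and radial property distributions of the vessel wall.

Four wall models are supported:

* **homogeneous** — a single isotropic material.
* **power-law** — properties of the form ``a * r**b + c`` in the physical radial
  coordinate, the classic graded-cylinder benchmark used to validate the solver.
* **grading** — a two-constituent functionally graded wall, blending an inner
  graft material into an outer one through the thickness via a power-law volume
  fraction controlled by the heterogeneous index ``n``.
* **layered** — a piecewise-constant three-layer wall (intima/media/adventitia)
  emulating the natural arterial wall.

All models reduce to the same interface: arrays of E(r), nu(r), rho(r) sampled
on a radial grid (see :func:`radial_property_field`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Material",
    "PowerLawProperty",
    "GradingLaw",
    "LayeredWall",
    "PowerLawWall",
    "HomogeneousWall",
    "NU_CAP",
    "PU",
    "DACRON",
    "eval_power_law",
    "grade",
    "layer_property",
    "radial_property_field",
]

# Near-incompressible cap: nu = 0.5 makes the linear-elastic constitutive
# matrix singular, so effective Poisson ratios are clamped just below.
NU_CAP = 0.4995


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material.

    Parameters
    ----------
    name : str
        Label used in configs and output headers.
    E : float
        Elastic modulus, Pa.
    nu : float
        Poisson's ratio (0 < nu <= 0.5; values at 0.5 are capped to
        :data:`NU_CAP` when the constitutive matrix is formed).
    rho : float
        Density, kg/m^3.
    """

    name: str
    E: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"elastic modulus must be positive, got {self.E}")
        if not (0 < self.nu <= 0.5):
            raise ValueError(f"Poisson's ratio must be in (0, 0.5], got {self.nu}")
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")

    @property
    def nu_effective(self) -> float:
        """Poisson's ratio clamped below the incompressible limit."""
        return min(self.nu, NU_CAP)


# Graft constituents for the functionally graded artificial vessel.
PU = Material("polyurethane", E=25e6, nu=0.49, rho=1200.0)
DACRON = Material("dacron", E=1.9e6, nu=0.37, rho=1380.0)


@dataclass(frozen=True)
class PowerLawProperty:
    """Radial property law ``p(r) = a * r**b + c`` (r in metres)."""

    a: float
    b: float
    c: float = 0.0

    def __call__(self, r):
        return eval_power_law(self, r)


def eval_power_law(law: PowerLawProperty, r):
    """Evaluate ``a * r**b + c`` at radius ``r`` (> 0, scalar or array)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("power-law property requires r > 0")
    out = law.a * r**law.b + law.c
    return float(out) if out.ndim == 0 else out


# Graded-cylinder benchmark property laws: rho(r) = 8900 r^0.08 - 5.93 (kg/m^3),
# E(r) = 223e9 r^0.082 (Pa), defined on r in [0.8, 1.0] m.
BENCHMARK_DENSITY = PowerLawProperty(a=8900.0, b=0.08, c=-5.93)
BENCHMARK_MODULUS = PowerLawProperty(a=223e9, b=0.082, c=0.0)


@dataclass(frozen=True)
class GradingLaw:
    """Two-constituent functionally graded wall.

    Each property varies through the normalized thickness coordinate
    ``xi in [0, 1]`` as ``p(xi) = p_inner + (p_outer - p_inner) * xi**n``
    where ``n`` is the heterogeneous index.  ``n = 2`` is the literal
    parabola; the continuous family supports the index sweeps used to match
    a graft to the natural vessel.  Endpoints return the constituents
    exactly for every ``n``.
    """

    inner: Material = DACRON
    outer: Material = PU
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"heterogeneous index must be > 0, got {self.n}")

    def __call__(self, xi):
        return grade(self, xi)


def grade(law: GradingLaw, xi):
    """Graded properties (E, nu, rho) at normalized thickness ``xi`` in [0, 1].

    Endpoints are exact: ``grade(law, 0)`` returns the inner constituent's
    properties and ``grade(law, 1)`` the outer's, for any index.
    """
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < 0) or np.any(xi_arr > 1):
        raise ValueError("normalized thickness coordinate must lie in [0, 1]")
    w = xi_arr**law.n
    # Force exact endpoints (xi**n is exact at 0 and 1 anyway; keep explicit).
    E = law.inner.E + (law.outer.E - law.inner.E) * w
    nu = law.inner.nu + (law.outer.nu - law.inner.nu) * w
    rho = law.inner.rho + (law.outer.rho - law.inner.rho) * w
    if xi_arr.ndim == 0:
        return float(E), float(nu), float(rho)
    return E, nu, rho


@dataclass(frozen=True)
class LayeredWall:
    """Piecewise-constant layered wall (default intima:media:adventitia = 1:6:3).

    ``layers`` is an ordered inner-to-outer list of (thickness fraction,
    material).  Fractions must be strictly positive and sum to 1.  Layer k
    occupies the half-open span [cum_{k-1}, cum_k) of the normalized
    thickness; the last layer is closed at 1.
    """

    layers: tuple[tuple[float, Material], ...]

    def __post_init__(self) -> None:
        fracs = np.array([f for f, _ in self.layers], dtype=float)
        if len(fracs) == 0:
            raise ValueError("layered wall needs at least one layer")
        if np.any(fracs <= 0):
            raise ValueError("layer thickness fractions must be strictly positive")
        if abs(fracs.sum() - 1.0) > 1e-12:
            raise ValueError(f"layer fractions must sum to 1, got {fracs.sum()!r}")

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative fraction boundaries, including 0 and 1."""
        fracs = [f for f, _ in self.layers]
        b = np.concatenate([[0.0], np.cumsum(fracs)])
        b[-1] = 1.0
        return b

    def __call__(self, xi) -> Material:
        return layer_property(self, xi)


def natural_wall(
    intima: Material, media: Material, adventitia: Material,
    fractions: Sequence[float] = (0.1, 0.6, 0.3),
) -> LayeredWall:
    """Three-layer natural vessel wall with 1:6:3 default thickness ratio."""
    f = tuple(float(x) for x in fractions)
    return LayeredWall(layers=((f[0], intima), (f[1], media), (f[2], adventitia)))


def layer_property(wall: LayeredWall, xi: float) -> Material:
    """Material occupying normalized thickness ``xi`` (half-open layer spans)."""
    if not (0 <= xi <= 1):
        raise ValueError("normalized thickness coordinate must lie in [0, 1]")
    b = wall.boundaries
    if xi >= 1.0:
        return wall.layers[-1][1]
    k = int(np.searchsorted(b, xi, side="right") - 1)
    return wall.layers[k][1]


@dataclass(frozen=True)
class PowerLawWall:
    """Wall with independent power laws for E and rho and constant nu."""

    E_law: PowerLawProperty = BENCHMARK_MODULUS
    rho_law: PowerLawProperty = BENCHMARK_DENSITY
    nu: float = 0.3


@dataclass(frozen=True)
class HomogeneousWall:
    material: Material = field(default_factory=lambda: Material("wall", 1e6, 0.45, 1090.0))


WallModel = GradingLaw | LayeredWall | PowerLawWall | HomogeneousWall


def radial_property_field(
    model: WallModel, r: np.ndarray, r_in: float, r_out: float,
    layer_smoothing: float = 0.0,
):
    """Sample E, nu, rho on a radial grid ``r`` within [r_in, r_out].

    Maps physical radius to the normalized thickness xi = (r - r_in)/(r_out -
    r_in) and dispatches on the wall model; the power-law model evaluates its
    laws in the physical radius directly.  Returns (E, nu, rho) arrays.

    ``layer_smoothing`` (fraction of the thickness, e.g. 0.05) replaces the
    sharp interfaces of a layered wall with tanh transitions of that width —
    needed by collocation solvers, which differentiate the property profile.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty radial grid")
    tol = 1e-9 * (r_out - r_in)
    if np.any(r < r_in - tol) or np.any(r > r_out + tol):
        raise ValueError("radial grid outside the wall thickness")
    xi = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)

    if isinstance(model, HomogeneousWall):
        m = model.material
        ones = np.ones_like(r)
        return m.E * ones, m.nu * ones, m.rho * ones
    if isinstance(model, PowerLawWall):
        E = eval_power_law(model.E_law, r)
        rho = eval_power_law(model.rho_law, r)
        return np.asarray(E), model.nu * np.ones_like(r), np.asarray(rho)
    if isinstance(model, GradingLaw):
        E, nu, rho = grade(model, xi)
        return np.asarray(E), np.asarray(nu), np.asarray(rho)
    if isinstance(model, LayeredWall):
        if layer_smoothing > 0:
            return _smoothed_layer_field(model, xi, layer_smoothing)
        mats = [layer_property(model, x) for x in xi]
        return (
            np.array([m.E for m in mats]),
            np.array([m.nu for m in mats]),
            np.array([m.rho for m in mats]),
        )
    raise TypeError(f"unknown wall model: {type(model).__name__}")


def _smoothed_layer_field(wall: LayeredWall, xi: np.ndarray, width: float):
    """Layered properties with tanh-blended interfaces of normalized ``width``."""
    mats = [m for _, m in wall.layers]
    interfaces = wall.boundaries[1:-1]
    out = []
    for prop in ("E", "nu", "rho"):
        vals = np.array([getattr(m, prop) for m in mats])
        p = np.full_like(xi, vals[0], dtype=float)
        for b, step in zip(interfaces, np.diff(vals)):
            p = p + step * 0.5 * (1.0 + np.tanh((xi - b) / width))
        out.append(p)
    return tuple(out)
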