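"""Opening-angle kinematics between the stress-free sector and closed annulus.

An unloaded artery ring carries residual stress: cutting it radially lets it
spring open into a stress-free circular sector with opening angle ``alpha``.
Closing the sector of inner/outer radii (R_i, R_o) back into a full annulus
with inner radius r_i is, for an incompressible plane-strain material, the
purely kinematic map

    r(R) = sqrt((R² − R_i²)/k + r_i²),   θ = k Θ,   k = 2π/(2π − α),

with principal stretches λ_r = R/(r k), λ_θ = k r/R, λ_z = 1.  The value of
r_i is not free — it is fixed by radial equilibrium (see
:mod:`arterymech.residual`); this module only provides the maps and the two
immutable configuration types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .constitutive import DeformationPoint

__all__ = [
    "OpenSector",
    "ClosedAnnulus",
    "TearSpec",
    "k_factor",
    "close_map",
    "open_map",
    "stretches",
]

_EDGE_RTOL = 1.0e-9


@dataclass(frozen=True)
class OpenSector:
    """Stress-free open-sector configuration Ω₀.

    Radii in mm: inner ``R_i``, media–adventitia interface ``R_m``, outer
    ``R_o``; ``alpha`` is the opening angle in degrees.
    """

    R_i: float
    R_m: float
    R_o: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.R_i < self.R_m < self.R_o:
            raise ValueError(f"radii must satisfy 0 < R_i < R_m < R_o, got "
                             f"({self.R_i}, {self.R_m}, {self.R_o})")
        if not 0.0 <= self.alpha < 360.0:
            raise ValueError(f"opening angle must lie in [0, 360) degrees, got {self.alpha}")

    @property
    def T_m(self) -> float:
        """Media thickness (mm)."""
        return self.R_m - self.R_i

    @property
    def T_a(self) -> float:
        """Adventitia thickness (mm)."""
        return self.R_o - self.R_m

    @property
    def k(self) -> float:
        return k_factor(self.alpha)

    def with_alpha(self, alpha: float) -> "OpenSector":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class ClosedAnnulus:
    """Closed two-layer annulus (the unloaded Ω_r, or a loaded configuration).

    Radii in mm: inner ``r_i``, interface ``r_m``, outer ``r_o``;
    ``p_lumen`` is the lumen pressure in kPa (0 for the residual state).
    """

    r_i: float
    r_m: float
    r_o: float
    p_lumen: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_i < self.r_m < self.r_o:
            raise ValueError(f"radii must satisfy 0 < r_i < r_m < r_o, got "
                             f"({self.r_i}, {self.r_m}, {self.r_o})")
        if self.p_lumen < 0.0:
            raise ValueError(f"lumen pressure must be non-negative, got {self.p_lumen}")

    @property
    def t_m(self) -> float:
        return self.r_m - self.r_i

    @property
    def t_a(self) -> float:
        return self.r_o - self.r_m


@dataclass(frozen=True)
class TearSpec:
    """Metadata for an idealized circumferential tear (not simulated here).

    ``r_t`` is the radius of the tear surface in the closed configuration and
    ``eta`` the arc angle it subtends, in degrees.
    """

    r_t: float
    eta: float

    def validate_in(self, annulus: ClosedAnnulus) -> None:
        if not annulus.r_i < self.r_t < annulus.r_o:
            raise ValueError(f"tear radius {self.r_t} outside wall "
                             f"({annulus.r_i}, {annulus.r_o})")
        if not 0.0 < self.eta < 360.0:
            raise ValueError(f"tear arc must lie in (0, 360) degrees, got {self.eta}")


def k_factor(alpha: float) -> float:
    """Circumferential compression factor k = 2π/(2π − α) for α in degrees."""
    if not 0.0 <= alpha < 360.0:
        raise ValueError(f"opening angle must lie in [0, 360) degrees, got {alpha}")
    return 2.0 * math.pi / (2.0 * math.pi - math.radians(alpha))


def _check_range(x: float, lo: float, hi: float, what: str) -> None:
    slack = _EDGE_RTOL * hi
    if not (lo - slack <= x <= hi + slack):
        raise ValueError(f"{what}={x} outside [{lo}, {hi}]")


def close_map(R, sector: OpenSector, r_i: float):
    """Deformed radius r in the closed annulus for reference radius R in Ω₀.

    Accepts scalars or numpy arrays. Strictly increasing in R with
    close_map(R_i) = r_i.
    """
    import numpy as np

    Ra = np.asarray(R, dtype=float)
    _check_range(float(Ra.min()), sector.R_i, sector.R_o, "R")
    _check_range(float(Ra.max()), sector.R_i, sector.R_o, "R")
    if r_i <= 0:
        raise ValueError(f"candidate inner radius must be positive, got {r_i}")
    r2 = (Ra**2 - sector.R_i**2) / sector.k + r_i**2
    out = np.sqrt(r2)
    return float(out) if np.isscalar(R) or out.ndim == 0 else out


def open_map(r, annulus: ClosedAnnulus, R_i: float, alpha: float):
    """Reference radius R in Ω₀ for radius r in the closed annulus (inverse map)."""
    import numpy as np

    ra = np.asarray(r, dtype=float)
    _check_range(float(ra.min()), annulus.r_i, annulus.r_o, "r")
    _check_range(float(ra.max()), annulus.r_i, annulus.r_o, "r")
    if R_i <= 0:
        raise ValueError(f"stress-free inner radius must be positive, got {R_i}")
    k = k_factor(alpha)
    out = np.sqrt(k * (ra**2 - annulus.r_i**2) + R_i**2)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def stretches(R: float, sector: OpenSector, r_i: float) -> DeformationPoint:
    """Principal stretches of the closing map at reference radius R."""
    r = close_map(float(R), sector, r_i)
    k = sector.k
    lam_r = float(R) / (r * k)
    lam_t = k * r / float(R)
    return DeformationPoint(lam_r=lam_r, lam_t=lam_t, lam_z=1.0)
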