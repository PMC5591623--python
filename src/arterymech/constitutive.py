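"""Incompressible plane-strain HGO (Holzapfel–Gasser–Ogden) constitutive law.

The arterial wall layer is a fibre-reinforced incompressible hyperelastic
solid with strain energy

    W = c (I1 - 3) + sum_{n=4,6} w(I_n),
    w(I_n) = k1/(2 k2) { exp[k2 (I_n - 1)^2] - 1 }   for I_n > 1, else 0,

where ``c`` is the matrix (neo-Hookean) stiffness, ``k1``/``k2`` control the
exponential stiffening of two symmetric collagen-fibre families at angle
``±beta`` from the circumferential direction, and ``I4``, ``I6`` are the
squared stretches along the fibre directions.  Fibres carry load only in
extension (the switch at I_n = 1).

Deformations here are axisymmetric plane strain with principal axes aligned
to (r, θ, z), so the two mirrored fibre families see the same invariant
(I4 = I6) and the Cauchy stress is diagonal.  In this plane-strain
idealization the axial component of the fibre direction is ignored: the
effective fibre vector is (0, cosβ, 0), so I4 = λ_θ² cos²β, the fibre angle
only scales the circumferential fibre contribution, and fibres engage only
where λ_θ > 1/cosβ.  Fibres have no radial or axial component, so σ_rr and
σ_zz receive no fibre term.  A practical consequence: for β ≥ 30° the
engagement threshold λ_θ > 1.155 is never reached in physiological
residual-stress states, and the response coincides with the fibre-free
matrix.

Units: lengths mm, stresses/energies kPa, cohesive energy N/mm (= kPa·mm /
1000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HGOLayer",
    "DeformationPoint",
    "InvariantSet",
    "StressComponents",
    "invariants",
    "fibre_energy",
    "fibre_stress_derivative",
    "stress_difference",
    "cauchy_stress",
    "KPA_MM_TO_N_PER_MM",
]

#: 1 kPa·mm = 1 N/m = 1e-3 N/mm — converts triangle areas of the cohesive
#: law (traction kPa × separation mm) to the N/mm in which G_c is quoted.
KPA_MM_TO_N_PER_MM = 1.0e-3

_INCOMP_TOL = 1.0e-9
_COHESIVE_RTOL = 1.0e-3


class InvalidDeformationError(ValueError):
    """Raised for non-positive or non-isochoric principal stretches."""


@dataclass(frozen=True)
class HGOLayer:
    """Material and cohesive parameters of one wall layer.

    Parameters
    ----------
    c : float
        Matrix stiffness (kPa), half the shear modulus of the ground matrix.
    k1 : float
        Fibre stiffness (kPa); ``k1 = 0`` removes the fibres.
    k2 : float
        Dimensionless fibre exponent.
    beta : float
        Fibre angle from the circumferential direction (degrees, in [0, 90]).
    T_c, G_c, du_c : float, optional
        Cohesive peak traction (kPa), separation energy (N/mm) and maximum
        displacement jump (mm).  Only two are independent
        (G_c = ½·T_c·du_c·1e-3); a supplied triple is checked.
    name : str
        Layer label, e.g. ``"media"`` or ``"adventitia"``.
    """

    c: float
    k1: float
    k2: float
    beta: float
    T_c: float | None = None
    G_c: float | None = None
    du_c: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"matrix stiffness c must be positive, got {self.c}")
        if self.k1 < 0:
            raise ValueError(f"fibre stiffness k1 must be non-negative, got {self.k1}")
        if not self.k2 > 0:
            raise ValueError(f"fibre exponent k2 must be positive, got {self.k2}")
        if not 0.0 <= self.beta <= 90.0:
            raise ValueError(f"fibre angle beta must lie in [0, 90] degrees, got {self.beta}")
        if None not in (self.T_c, self.G_c, self.du_c):
            implied = 0.5 * self.T_c * self.du_c * KPA_MM_TO_N_PER_MM
            if abs(implied - self.G_c) > _COHESIVE_RTOL * abs(self.G_c):
                raise ValueError(
                    "inconsistent cohesive triple: "
                    f"G_c={self.G_c} N/mm but ½·T_c·du_c={implied:.6g} N/mm"
                )

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beta)

    @property
    def cos2_beta(self) -> float:
        return math.cos(self.beta_rad) ** 2

    @property
    def sin2_beta(self) -> float:
        return math.sin(self.beta_rad) ** 2


@dataclass(frozen=True)
class DeformationPoint:
    """Principal stretches (λ_r, λ_θ, λ_z) of an isochoric deformation."""

    lam_r: float
    lam_t: float
    lam_z: float = 1.0

    def __post_init__(self) -> None:
        if self.lam_r <= 0 or self.lam_t <= 0 or self.lam_z <= 0:
            raise InvalidDeformationError(
                f"principal stretches must be positive: {(self.lam_r, self.lam_t, self.lam_z)}"
            )
        det = self.lam_r * self.lam_t * self.lam_z
        if abs(det - 1.0) > _INCOMP_TOL * max(1.0, abs(det)):
            raise InvalidDeformationError(
                f"incompressibility violated: lam_r*lam_t*lam_z = {det!r}"
            )


@dataclass(frozen=True)
class InvariantSet:
    """Deformation invariants I1 = tr C and fibre invariants I4 = I6 = C:M."""

    I1: float
    I4: float
    I6: float


@dataclass(frozen=True)
class StressComponents:
    """Diagonal Cauchy stress (kPa) and the incompressibility multiplier 𝔭."""

    s_rr: float
    s_tt: float
    s_zz: float
    p_lag: float

    def max_principal(self) -> float:
        """Largest principal stress; valid because the state is shear-free."""
        return max(self.s_rr, self.s_tt, self.s_zz)


def invariants(point: DeformationPoint, beta: float) -> InvariantSet:
    """Invariants of C = F^T F for fibres at ±beta (degrees) from θ.

    The fibre directions are A = (0, cosβ, ±sinβ) in (r, θ, z), but under
    the plane-strain idealization the axial component is ignored, so the
    effective structure tensor is diag(0, cos²β, 0) for both families and
    I4 = I6 = λ_θ² cos²β.
    """
    b = math.radians(beta)
    i1 = point.lam_r**2 + point.lam_t**2 + point.lam_z**2
    i4 = point.lam_t**2 * math.cos(b) ** 2
    return InvariantSet(I1=i1, I4=i4, I6=i4)


def fibre_energy(I_n: float, layer: HGOLayer) -> float:
    """Energy density (kPa) of one fibre family; zero unless stretched (I_n > 1)."""
    if I_n < 0:
        raise InvalidDeformationError(f"fibre invariant must be non-negative, got {I_n}")
    if I_n <= 1.0 or layer.k1 == 0.0:
        return 0.0
    e = I_n - 1.0
    return layer.k1 / (2.0 * layer.k2) * math.expm1(layer.k2 * e * e)


def fibre_stress_derivative(I_n: float, layer: HGOLayer) -> float:
    """w'(I_n) = k1 (I_n - 1) exp[k2 (I_n - 1)²] for I_n > 1, else 0 (kPa)."""
    if I_n < 0:
        raise InvalidDeformationError(f"fibre invariant must be non-negative, got {I_n}")
    if I_n <= 1.0 or layer.k1 == 0.0:
        return 0.0
    e = I_n - 1.0
    return layer.k1 * e * math.exp(layer.k2 * e * e)


def stress_difference(point: DeformationPoint, layer: HGOLayer) -> float:
    """σ_θθ − σ_rr (kPa): the multiplier-free combination driving equilibrium.

    σ_θθ − σ_rr = 2c(λ_θ² − λ_r²) + 4 w'(I4) λ_θ² cos²β; both fibre families
    contribute equally and neither adds to σ_rr.
    """
    i4 = invariants(point, layer.beta).I4
    matrix = 2.0 * layer.c * (point.lam_t**2 - point.lam_r**2)
    fibre = 4.0 * fibre_stress_derivative(i4, layer) * point.lam_t**2 * layer.cos2_beta
    return matrix + fibre


def cauchy_stress(point: DeformationPoint, layer: HGOLayer, s_rr_known: float) -> StressComponents:
    """Full diagonal Cauchy stress given σ_rr from the equilibrium integral.

    The Lagrange multiplier follows from the radial component of
    σ = −𝔭 I + 2c B + Σ 2w'(I_n) m_n, where the in-plane fibre tensors m_n
    have neither rr- nor zz-components: 𝔭 = −σ_rr + 2c λ_r².
    """
    i4 = invariants(point, layer.beta).I4
    wp = fibre_stress_derivative(i4, layer)
    p_lag = -s_rr_known + 2.0 * layer.c * point.lam_r**2
    s_tt = -p_lag + 2.0 * layer.c * point.lam_t**2 + 4.0 * wp * point.lam_t**2 * layer.cos2_beta
    s_zz = -p_lag + 2.0 * layer.c * point.lam_z**2
    return StressComponents(s_rr=s_rr_known, s_tt=s_tt, s_zz=s_zz, p_lag=p_lag)
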