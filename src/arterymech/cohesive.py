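"""Linear cohesive traction–separation law and tear-initiation criteria.

A tear in the wall is bridged by a cohesive zone whose normal traction T
decays linearly with the displacement jump Δu, from the peak T_c at
Δu = 0⁺ (initially rigid law) to zero at the maximum jump Δu_c.  The area
under the triangle is the separation energy,

    G_c = ½ · T_c · Δu_c,

so only two of the three parameters are independent.  With T_c in kPa and
Δu_c in mm, G_c is quoted in N/mm (1 kPa·mm = 1e-3 N/mm).

Damage is irreversible: unloading from a partially damaged state follows
the secant to the origin through the envelope point at the largest jump
seen, and reloading retraces it.  Initiation uses a maximum-principal-
stress criterion, σ_mp ≥ T_c, and propagation is perpendicular to the
largest tensile principal stress — for an artery wall whose largest tensile
component is circumferential, that is radially outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .constitutive import KPA_MM_TO_N_PER_MM, StressComponents

__all__ = [
    "CohesiveLaw",
    "DamageState",
    "from_two_parameters",
    "traction",
    "dissipated_energy",
    "initiation_check",
    "propagation_direction",
]

_CONSISTENCY_RTOL = 1e-3


@dataclass(frozen=True)
class CohesiveLaw:
    """Linear (triangular) cohesive law: peak traction T_c (kPa), maximum
    displacement jump du_c (mm), separation energy G_c (N/mm)."""

    T_c: float
    du_c: float
    G_c: float

    def __post_init__(self) -> None:
        if self.T_c <= 0 or self.du_c <= 0 or self.G_c <= 0:
            raise ValueError("cohesive parameters must all be positive")
        implied = 0.5 * self.T_c * self.du_c * KPA_MM_TO_N_PER_MM
        if abs(implied - self.G_c) > _CONSISTENCY_RTOL * self.G_c:
            raise ValueError(
                f"inconsistent triple: G_c={self.G_c} N/mm, ½·T_c·du_c={implied:.6g} N/mm"
            )


@dataclass
class DamageState:
    """Irreversibility bookkeeping: the largest jump seen and the damage scalar."""

    du_max_seen: float = 0.0

    def damage(self, law: CohesiveLaw) -> float:
        return min(self.du_max_seen / law.du_c, 1.0)


def from_two_parameters(
    T_c: float | None = None,
    G_c: float | None = None,
    du_c: float | None = None,
) -> CohesiveLaw:
    """Build the law from exactly two of (T_c [kPa], G_c [N/mm], du_c [mm]).

    The third parameter follows from G_c = ½·T_c·du_c (with the kPa·mm →
    N/mm conversion).  Supplying all three is accepted only if consistent to
    0.1% relative.
    """
    given = sum(v is not None for v in (T_c, G_c, du_c))
    if given < 2:
        raise ValueError("need at least two of T_c, G_c, du_c")
    if given == 3:
        return CohesiveLaw(T_c=T_c, du_c=du_c, G_c=G_c)  # consistency checked there
    if T_c is None:
        T_c = 2.0 * G_c / (du_c * KPA_MM_TO_N_PER_MM)
    elif du_c is None:
        du_c = 2.0 * G_c / (T_c * KPA_MM_TO_N_PER_MM)
    else:
        G_c = 0.5 * T_c * du_c * KPA_MM_TO_N_PER_MM
    return CohesiveLaw(T_c=T_c, du_c=du_c, G_c=G_c)


def _envelope(du: float, law: CohesiveLaw) -> float:
    return law.T_c * (1.0 - du / law.du_c) if du < law.du_c else 0.0


def traction(du: float, law: CohesiveLaw, state: DamageState | None = None) -> float:
    """Cohesive traction (kPa) at displacement jump ``du`` (mm), with damage.

    On the virgin envelope T = T_c (1 − Δu/Δu_c); once ``du`` falls below
    the largest jump seen, the response is the linear secant to the origin
    through the envelope point at ``state.du_max_seen``.  Updates ``state``.
    """
    if du < 0:
        raise ValueError(f"displacement jump must be non-negative, got {du}")
    if state is None:
        state = DamageState()
    if du >= state.du_max_seen:
        state.du_max_seen = du
        return _envelope(du, law)
    du_m = state.du_max_seen
    if du_m >= law.du_c:
        return 0.0
    secant_stiffness = _envelope(du_m, law) / du_m
    return secant_stiffness * du


def dissipated_energy(history: Iterable[float], law: CohesiveLaw) -> float:
    """Path integral ∫ T d(Δu) over a jump history, in N/mm.

    Monotonic loading to Δu_c dissipates exactly G_c; unloading/reloading
    along the secant stores and returns energy but, in this linear law with
    secant unloading, the work done along any closed sub-cycle cancels, so
    the integral equals the area swept under the actual path.
    """
    state = DamageState()
    prev_du = 0.0
    prev_T = traction(0.0, law, state)
    work = 0.0
    for du in history:
        if du < 0:
            raise ValueError("displacement-jump history must be non-negative")
        T = traction(du, law, state)
        work += 0.5 * (T + prev_T) * (du - prev_du)
        prev_du, prev_T = du, T
    return work * KPA_MM_TO_N_PER_MM


def initiation_check(stress: StressComponents, law: CohesiveLaw) -> tuple[bool, float]:
    """Maximum-principal-stress initiation criterion σ_mp ≥ T_c (inclusive).

    Returns ``(initiates, margin)`` where margin = σ_mp − T_c in kPa.
    """
    margin = stress.max_principal() - law.T_c
    return margin >= 0.0, margin


def propagation_direction(stress: StressComponents) -> str | None:
    """Direction of tear propagation: perpendicular to the largest tensile
    principal stress, restricted to the (r, θ) plane.

    Returns ``"radial"`` when σ_θθ dominates (the usual arterial case:
    tears run radially outward), ``"circumferential"`` when σ_rr dominates,
    and ``None`` when no in-plane component is tensile.
    """
    candidates = {"radial": stress.s_tt, "circumferential": stress.s_rr}
    label, value = max(candidates.items(), key=lambda kv: kv[1])
    if value <= 0.0:
        return None
    return label
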