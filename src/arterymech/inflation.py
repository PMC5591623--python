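"""Pressurized inflation of the residually-stressed artery (plane strain).

The intact wall under lumen pressure p is the same axisymmetric
boundary-value problem as the residual-stress state, with the inner
traction changed to σ_rr(r_i) = −p.  Because the total deformation from the
stress-free sector Ω₀ to the loaded annulus is a single incompressible
radial map with the same circumferential factor k, the loaded inner radius
a is the root of

    ∫_{a-wall} (σ_θθ − σ_rr) dr/r = p.

This module also provides a deliberately approximate tear-initiation
pressure: the smallest lumen pressure at which the maximum principal stress
anywhere in the *intact, axisymmetric* wall reaches the cohesive strength
T_c.  It carries no tear geometry (no arc length η, no tear radius, no
inner-wall buckling), so it is a lower-fidelity surrogate for crack-resolved
critical pressures — useful for trends across opening angles, not for
absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ClosedAnnulus, OpenSector, close_map
from .residual import (
    ConvergenceError,
    LayerMaterials,
    SolveDiagnostics,
    WallState,
    _brent,
    residual_stress_profile,
    wall_residual,
)

__all__ = ["LoadedSolution", "solve_loaded", "pressure_radius_curve", "initiation_pressure"]


@dataclass(frozen=True)
class LoadedSolution:
    """A solved pressurized configuration with its transmural state."""

    annulus: ClosedAnnulus
    state: WallState
    p_norm: float  # lumen pressure / media matrix stiffness, dimensionless

    @property
    def p_lumen(self) -> float:
        return self.annulus.p_lumen


def solve_loaded(
    sector: OpenSector,
    materials: LayerMaterials,
    p_lumen: float,
    n_nodes: int = 401,
) -> LoadedSolution:
    """Inflate the artery defined by stress-free sector Ω₀ to lumen pressure p.

    At p = 0 this reduces exactly to the unloaded residual-stress solve.
    """
    if p_lumen < 0:
        raise ValueError(f"lumen pressure must be non-negative, got {p_lumen}")
    c_m = materials["media"].c
    if sector.alpha == 0.0 and p_lumen == 0.0:
        annulus = ClosedAnnulus(r_i=sector.R_i, r_m=sector.R_m, r_o=sector.R_o)
        state = residual_stress_profile(sector, annulus, materials, n_nodes)
        return LoadedSolution(annulus=annulus, state=state, p_norm=0.0)

    lo, hi = 0.01 * sector.R_i, 10.0 * sector.R_o
    root, its = _brent(
        lambda a: wall_residual(sector, a, materials) - p_lumen,
        lo, hi, f"loaded inner radius at p={p_lumen:g} kPa",
    )
    annulus = ClosedAnnulus(
        r_i=root,
        r_m=close_map(sector.R_m, sector, root),
        r_o=close_map(sector.R_o, sector, root),
        p_lumen=p_lumen,
    )
    state = residual_stress_profile(sector, annulus, materials, n_nodes)
    state.diagnostics = SolveDiagnostics(
        iterations=its,
        residual=wall_residual(sector, root, materials) - p_lumen,
        bracket=(lo, hi), root=root,
    )
    return LoadedSolution(annulus=annulus, state=state, p_norm=p_lumen / c_m)


def pressure_radius_curve(
    sector: OpenSector,
    materials: LayerMaterials,
    p_grid,
    n_nodes: int = 101,
) -> list[dict]:
    """Sweep :func:`solve_loaded` over a non-decreasing pressure grid.

    Returns one summary row per pressure: p_kPa, p_norm, r_i_mm, r_o_mm and
    the peak circumferential stress.  Failures propagate with the offending
    pressure named.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(p_grid < 0) or np.any(np.diff(p_grid) < 0):
        raise ValueError("pressure grid must be non-negative and non-decreasing")
    rows = []
    for p in p_grid:
        try:
            sol = solve_loaded(sector, materials, float(p), n_nodes=n_nodes)
        except ConvergenceError as exc:
            raise ConvergenceError(f"inflation failed at p = {p:g} kPa: {exc}") from exc
        rows.append({
            "p_kPa": float(p),
            "p_norm": sol.p_norm,
            "r_i_mm": sol.annulus.r_i,
            "r_o_mm": sol.annulus.r_o,
            "max_s_tt_kPa": float(np.max(sol.state.s_tt)),
        })
    return rows


def initiation_pressure(
    sector: OpenSector,
    materials: LayerMaterials,
    T_c: float,
    n_nodes: int = 201,
    tol_factor: float = 1e-6,
    at_radius: float | None = None,
) -> tuple[float, float, float]:
    """Approximate tear-initiation pressure for the intact axisymmetric wall.

    Returns ``(p_c, p_norm, location)``: the smallest lumen pressure (kPa,
    by bisection to ``tol_factor``·c_media) at which the maximum principal
    stress reaches the cohesive strength ``T_c``, its dimensionless form
    p_c/c_media, and the radius (mm) where the criterion is met.  If the
    residual state already violates the criterion the result is
    (0, 0, location).  The estimate ignores tear geometry and buckling.

    By default the criterion is evaluated at the worst point across the
    whole wall.  ``at_radius`` instead monitors one material point — given
    by its radius in the unloaded configuration Ω_r, e.g. the tear-surface
    radius or the inner surface where an intimal defect sits — tracked
    through the deformation.  The wall-wide maximum is conservative but at
    large opening angles is dominated by the residual hoop tension in the
    outer media, a location an intimal tear never probes; the defect-local
    estimate is the one that mirrors crack-resolved critical-pressure
    trends.
    """
    if T_c <= 0:
        raise ValueError(f"cohesive strength must be positive, got {T_c}")
    c_m = materials["media"].c

    R_t = None
    if at_radius is not None:
        from .geometry import open_map
        from .residual import solve_unloaded
        unloaded, _ = solve_unloaded(sector, materials, n_nodes=11)
        R_t = open_map(at_radius, unloaded, sector.R_i, sector.alpha)

    def overshoot(p: float) -> tuple[float, float] | None:
        """(σ_mp − T_c, radius), or None beyond the static limit pressure."""
        try:
            sol = solve_loaded(sector, materials, p, n_nodes=n_nodes)
        except ConvergenceError:
            return None
        smp = sol.state.max_principal()
        if R_t is None:
            i = int(np.argmax(smp))
            return float(smp[i]) - T_c, float(sol.state.radii[i])
        r_pt = close_map(R_t, sector, sol.annulus.r_i)
        return float(np.interp(r_pt, sol.state.radii, smp)) - T_c, float(r_pt)

    f0, loc0 = overshoot(0.0)
    if f0 >= 0.0:
        return 0.0, 0.0, loc0

    # expand the bracket while the wall demonstrably stays below strength
    hi = 5.0 * c_m
    expansions = 0
    while True:
        res = overshoot(hi)
        if res is None or res[0] >= 0.0:
            break
        if expansions >= 3:
            raise ConvergenceError(
                f"maximum principal stress stays below T_c = {T_c:g} kPa "
                f"up to p = {hi:g} kPa"
            )
        hi *= 2.0
        expansions += 1

    # bisect; pressures beyond the static limit point count as upper bounds
    lo = 0.0
    tol = tol_factor * c_m
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        res = overshoot(mid)
        if res is None or res[0] >= 0.0:
            hi = mid
        else:
            lo = mid
    final = overshoot(hi)
    if final is None or final[0] < 0.0:
        raise ConvergenceError(
            f"no static solution reaches T_c = {T_c:g} kPa before the "
            f"pressure limit point near p = {hi:g} kPa"
        )
    return hi, hi / c_m, final[1]
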