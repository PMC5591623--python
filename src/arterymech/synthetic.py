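"""Seeded synthetic parameter sets and packaged reference fixtures.

Provides three things: (1) the packaged fixtures — rabbit carotid geometry
and HGO/cohesive materials, the stress-free geometries tabulated per
opening angle, and a provisional human-aorta entry; (2) seeded random draws
of physiologically plausible two-layer geometries and material sets for
property and parameter-recovery testing; (3) multiplicative noise injection
for stress profiles.

Randomness uses :class:`numpy.random.Generator` with the PCG64 bit
generator, pinned so that a seed reproduces the same draw across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Any

import numpy as np
import yaml

from .constitutive import HGOLayer
from .geometry import ClosedAnnulus, OpenSector
from .residual import WallState

__all__ = ["ParameterDraw", "Fixture", "draw_parameter_set", "fixture", "fixture_names",
           "noisy_profile"]

# admissible ranges for random draws; they bracket both packaged material sets
ALPHA_RANGE = (0.0, 220.0)
C_RANGE = (0.1, 50.0)
K1_RANGE = (1e-2, 120.0)
K2_RANGE = (0.1, 30.0)
BETA_RANGE = (0.0, 90.0)
R_I_RANGE = (0.4, 3.0)
THICKNESS_FRACTION_RANGE = (0.05, 0.30)  # per layer, relative to R_i


@dataclass(frozen=True)
class ParameterDraw:
    """One seeded admissible parameter set for the forward problem."""

    seed: int
    sector: OpenSector
    materials: dict[str, HGOLayer]

    @property
    def alpha(self) -> float:
        return self.sector.alpha


@dataclass(frozen=True)
class Fixture:
    """A packaged parameter set: geometry and/or materials plus metadata."""

    name: str
    sector: OpenSector | None = None
    annulus: ClosedAnnulus | None = None
    materials: dict[str, HGOLayer] | None = None
    provisional: bool = False
    meta: dict[str, Any] | None = None


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def draw_parameter_set(seed: int) -> ParameterDraw:
    """Draw an admissible two-layer geometry + material set from a seed.

    Stiffness parameters (c, k1, k2) are log-uniform over their admissible
    ranges; angles and radius ratios are uniform.  Cohesive strength is tied
    to the media matrix stiffness (T_c = 2c) with a uniform maximum jump.
    The same seed always returns the identical draw.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    R_i = rng.uniform(*R_I_RANGE)
    T_m = R_i * rng.uniform(*THICKNESS_FRACTION_RANGE)
    T_a = R_i * rng.uniform(*THICKNESS_FRACTION_RANGE)
    alpha = rng.uniform(*ALPHA_RANGE)
    sector = OpenSector(R_i=R_i, R_m=R_i + T_m, R_o=R_i + T_m + T_a, alpha=alpha)

    materials: dict[str, HGOLayer] = {}
    for name in ("media", "adventitia"):
        c = _loguniform(rng, *C_RANGE)
        layer = HGOLayer(
            c=c,
            k1=_loguniform(rng, *K1_RANGE),
            k2=_loguniform(rng, *K2_RANGE),
            beta=rng.uniform(*BETA_RANGE),
            T_c=2.0 * c,
            du_c=rng.uniform(0.1, 1.0),
            name=name,
        )
        materials[name] = layer
    return ParameterDraw(seed=seed, sector=sector, materials=materials)


def _load_raw() -> dict:
    text = resources.files("arterymech").joinpath("data/fixtures.yaml").read_text()
    return yaml.safe_load(text)


def _rabbit_materials(raw: dict) -> dict[str, HGOLayer]:
    out = {}
    for name, p in raw["rabbit"]["materials"].items():
        out[name] = HGOLayer(name=name, **p)
    return out


def fixture_names() -> list[str]:
    names = ["rabbit_omega0", "rabbit_omega_r", "human_aorta"]
    raw = _load_raw()
    names += [f"omega0_row:{int(row[0])}" for row in raw["rabbit"]["omega0_vs_alpha"]]
    return names


def fixture(name: str, alpha: float | None = None) -> Fixture:
    """Look up a packaged fixture by name.

    Known names: ``rabbit_omega0`` (stress-free sector + materials),
    ``rabbit_omega_r`` (unloaded annulus + materials), ``omega0_row`` with
    an ``alpha`` argument (or ``omega0_row:<alpha>``) for the tabulated
    stress-free geometry at that opening angle, and ``human_aorta``
    (provisional metadata only).
    """
    raw = _load_raw()
    rab = raw["rabbit"]

    if name.startswith("omega0_row"):
        if ":" in name:
            alpha = float(name.split(":", 1)[1])
        if alpha is None:
            raise KeyError("omega0_row fixture needs an opening angle")
        for row in rab["omega0_vs_alpha"]:
            if abs(row[0] - alpha) < 1e-9:
                R_i, T_m, T_a = row[1], row[2], row[3]
                return Fixture(
                    name=f"omega0_row:{int(row[0])}",
                    sector=OpenSector(R_i=R_i, R_m=R_i + T_m, R_o=R_i + T_m + T_a,
                                      alpha=row[0]),
                    materials=_rabbit_materials(raw),
                )
        raise KeyError(f"no tabulated stress-free geometry at alpha = {alpha}")

    if name == "rabbit_omega0":
        g = rab["omega0"]
        return Fixture(
            name=name,
            sector=OpenSector(R_i=g["R_i"], R_m=g["R_i"] + g["T_m"],
                              R_o=g["R_i"] + g["T_m"] + g["T_a"], alpha=g["alpha"]),
            materials=_rabbit_materials(raw),
        )
    if name == "rabbit_omega_r":
        g = rab["omega_r"]
        return Fixture(
            name=name,
            annulus=ClosedAnnulus(r_i=g["r_i"], r_m=g["r_i"] + g["t_m"],
                                  r_o=g["r_i"] + g["t_m"] + g["t_a"]),
            materials=_rabbit_materials(raw),
        )
    if name == "human_aorta":
        h = raw["human_aorta"]
        return Fixture(name=name, provisional=True, meta=h)
    raise KeyError(f"unknown fixture {name!r}; known: {fixture_names()}")


def noisy_profile(profile: WallState, noise_sd_rel: float, seed: int) -> WallState:
    """Multiplicative Gaussian perturbation of the stress arrays.

    Each interior node's stress components are scaled by independent
    (1 + noise_sd_rel·N(0,1)) factors; the boundary nodes keep their exact
    traction values.  Kinematic arrays and the multiplier are untouched.
    """
    if noise_sd_rel < 0:
        raise ValueError(f"noise level must be non-negative, got {noise_sd_rel}")
    rng = np.random.Generator(np.random.PCG64(seed))
    out = WallState(
        radii=profile.radii.copy(), lam_r=profile.lam_r.copy(), lam_t=profile.lam_t.copy(),
        s_rr=profile.s_rr.copy(), s_tt=profile.s_tt.copy(), s_zz=profile.s_zz.copy(),
        p_lag=profile.p_lag.copy(), layer_id=profile.layer_id.copy(), lam_z=profile.lam_z,
    )
    if noise_sd_rel == 0.0:
        return out
    n = len(out.radii)
    for arr in (out.s_rr, out.s_tt, out.s_zz):
        factors = 1.0 + noise_sd_rel * rng.standard_normal(n)
        arr[1:-1] *= factors[1:-1]
    return out
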