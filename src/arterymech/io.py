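"""Deterministic CSV output for transmural wall profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .residual import WallState

__all__ = ["write_profile_csv", "read_profile_csv"]

_HEADER = "r_mm,layer,lambda_r,lambda_t,sigma_rr_kPa,sigma_tt_kPa,sigma_zz_kPa,p_lag_kPa"
_UNITS_COMMENT = "# radii in mm, stresses in kPa, angles in degrees, stretches dimensionless"


def write_profile_csv(state: WallState, path) -> Path:
    """Write a wall profile as CSV with a fixed column order.

    Numbers are formatted at 12 significant digits, so an identical state
    always produces a byte-identical file.
    """
    path = Path(path)
    lines = [_UNITS_COMMENT, _HEADER]
    for i in range(len(state)):
        nums = (state.radii[i], state.lam_r[i], state.lam_t[i], state.s_rr[i],
                state.s_tt[i], state.s_zz[i], state.p_lag[i])
        formatted = [f"{x:.12g}" for x in nums]
        lines.append(",".join([formatted[0], str(state.layer_id[i])] + formatted[1:]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_profile_csv(path) -> WallState:
    """Read a profile written by :func:`write_profile_csv`."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or line.startswith("r_mm") or not line.strip():
            continue
        parts = line.split(",")
        rows.append(parts)
    radii = np.array([float(p[0]) for p in rows])
    layer_id = np.array([p[1] for p in rows])
    cols = np.array([[float(x) for x in p[2:]] for p in rows])
    return WallState(
        radii=radii, layer_id=layer_id,
        lam_r=cols[:, 0], lam_t=cols[:, 1],
        s_rr=cols[:, 2], s_tt=cols[:, 3], s_zz=cols[:, 4], p_lag=cols[:, 5],
    )
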