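"""Site climate: saturated vapour pressure and vapour pressure deficit.

The drying power of the air at a site is summarised as the vapour pressure
deficit (VPD, kPa): the gap between the saturated vapour pressure (SVP) at
the animal's body temperature and the ambient vapour pressure (VP).  For an
ectotherm whose respiratory surfaces are saturated and whose body temperature
tracks the environment, ``VPD = SVP(T) - VP``.

SVP follows the Tetens relation, ``SVP = a * exp(b*T / (T + c))`` with the
standard meteorological constants a=0.61078 kPa, b=17.27, c=237.3 degC.  The
constants are keyword arguments so a Magnus-form variant can be substituted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["svp", "vpd", "annotate_sites", "SITE_SCHEMA"]

#: Required columns of a site-climate table.
SITE_SCHEMA = ["site_id", "altitude_m", "tmin_c", "pdry_mm", "vp_kpa", "side"]

TETENS_A = 0.61078  # kPa
TETENS_B = 17.27
TETENS_C = 237.3  # degC


def svp(temp_c, *, a: float = TETENS_A, b: float = TETENS_B, c: float = TETENS_C):
    """Saturated water vapour pressure (kPa) at air temperature ``temp_c`` (degC).

    Tetens form; strictly increasing in temperature.  Accepts scalars or
    arrays.  Raises ``ValueError`` below absolute zero.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temperature below absolute zero")
    out = a * np.exp(b * t / (t + c))
    return float(out) if np.isscalar(temp_c) or out.ndim == 0 else out


def vpd(temp_c, vp_kpa):
    """Vapour pressure deficit (kPa): ``svp(temp_c) - vp_kpa``, floored at 0.

    Monthly-mean VP can exceed SVP evaluated at the coldest-month mean
    temperature because both inputs are climatological averages; a negative
    deficit is non-physical, so it is clamped to zero with a warning.

    Raises ``ValueError`` for negative vapour pressure.
    """
    vp = np.asarray(vp_kpa, dtype=float)
    if np.any(vp < 0):
        raise ValueError("vapour pressure must be non-negative")
    deficit = svp(temp_c) - vp
    d = np.asarray(deficit, dtype=float)
    if np.any(d < 0):
        warnings.warn(
            "VP exceeds SVP at the stated temperature; VPD floored at 0",
            stacklevel=2,
        )
        d = np.maximum(d, 0.0)
    return float(d) if np.isscalar(vp_kpa) and d.ndim == 0 else d


def annotate_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``sites`` with ``svp_kpa`` and ``vpd_kpa`` columns added.

    ``sites`` must contain ``tmin_c`` and ``vp_kpa`` (see :data:`SITE_SCHEMA`).
    The input frame is not modified; row count and order are preserved, and
    the operation is idempotent.
    """
    for col in ("tmin_c", "vp_kpa"):
        if col not in sites.columns:
            raise KeyError(f"site table is missing required column {col!r}")
    out = sites.copy()
    out["svp_kpa"] = svp(out["tmin_c"].to_numpy())
    out["vpd_kpa"] = vpd(out["tmin_c"].to_numpy(), out["vp_kpa"].to_numpy())
    return out
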