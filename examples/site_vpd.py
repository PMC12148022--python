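"""Vapour pressure deficit for a transect of collection sites.

VPD = SVP(Tmin) - VP is the drying power of the air a resting insect
experiences if its respiratory surfaces are saturated and its body tracks
air temperature.  Higher-altitude sites are cooler, so their SVP (and with
humid tropical air, their VPD) is lower.
"""

import pandas as pd

import respclim as rc

sites = pd.DataFrame({
    "site_id": ["coast", "foothill", "ridge"],
    "altitude_m": [10.0, 500.0, 1050.0],
    "tmin_c": [23.0, 20.5, 17.7],
    "pdry_mm": [85.0, 135.0, 190.0],
    "vp_kpa": [2.10, 1.85, 1.60],
    "side": ["dry", "dry", "wet"],
})
print(rc.annotate_sites(sites).round(3).to_string(index=False))
# svp_kpa falls with altitude (cooler air holds less vapour) and vpd_kpa is
# the gap left after subtracting ambient vapour pressure -- the covariate the
# hygric hypothesis says should suppress gas-exchange frequency.
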