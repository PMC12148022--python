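"""Trait covariation: per-species FGE~MR slopes regressed on species climate.

Stage one fits, separately for each species with at least ``min_n``
individuals, the mixed model ``FGE ~ log10 MR + log10 mass`` with crossed
block/channel random intercepts, and keeps the log10 MR slope and its
standard error.  Stage two summarises each species' climate as the mean over
its individual bees (so sites weight by how many bees were collected there)
and compares five ordinary linear regressions of slope on climate —
altitude, VPD, Tmin, Tmin+Pdry, Pdry — by AIC, Akaike weight and R^2.

With as few as four species the second stage has 1-2 residual degrees of
freedom; estimates are reported with finite AICs but should be read as the
fragile small-sample comparison they are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import CLIMATE_SETS, ModelSpec, akaike_weights, fit_lmm

__all__ = [
    "SlopeEstimate",
    "species_slopes",
    "species_climate_means",
    "slope_climate_set",
    "gaussian_aic",
]

CLIMATE_MEAN_COLS = {
    "altitude_m": "altitude_mean",
    "tmin_c": "tmin_mean",
    "pdry_mm": "pdry_mean",
    "vpd_kpa": "vpd_mean",
}


@dataclass
class SlopeEstimate:
    """Per-species FGE~MR slope (mass-adjusted) plus its climate summary."""

    species: str
    slope: float            # FGE per unit log10 MR
    se: float
    n: int
    altitude_mean: float
    altitude_min: float
    altitude_max: float
    tmin_mean: float
    pdry_mean: float
    vpd_mean: float


def species_climate_means(data: pd.DataFrame) -> pd.DataFrame:
    """Mean collection climate per species, averaged over individual bees.

    Each bee contributes its collection site's values, so sites weight in
    proportion to how many individuals came from them ("mean collection
    altitude" semantics).  Requires climate columns to be joined already.
    """
    missing = [c for c in CLIMATE_MEAN_COLS if c not in data.columns]
    if missing:
        raise KeyError(f"trait table lacks joined climate columns: {missing}")
    g = data.groupby("species")
    out = g[list(CLIMATE_MEAN_COLS)].mean().rename(columns=CLIMATE_MEAN_COLS)
    out["altitude_min"] = g["altitude_m"].min()
    out["altitude_max"] = g["altitude_m"].max()
    out["n"] = g.size()
    return out.reset_index()


def species_slopes(data: pd.DataFrame, min_n: int = 10,
                   method: str = "ml") -> list[SlopeEstimate]:
    """Mass-adjusted FGE~MR slope for every species with ``n >= min_n``.

    Species below the sample-size rule, or whose mixed-model fit fails or
    does not converge, are excluded with a warning.
    """
    clim = species_climate_means(data).set_index("species")
    spec = ModelSpec(name="fge_mr", response="fge_min",
                     fixed_terms=("log10_mr", "log10_mass"))
    out: list[SlopeEstimate] = []
    for species, sub in data.groupby("species"):
        if len(sub) < min_n:
            warnings.warn(
                f"species {species!r} has n={len(sub)} < {min_n}; excluded",
                stacklevel=2,
            )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_lmm(spec, sub, method=method)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"species {species!r}: fit failed ({exc}); excluded",
                          stacklevel=2)
            continue
        if not fit.converged:
            warnings.warn(f"species {species!r}: singular/non-converged fit; excluded",
                          stacklevel=2)
            continue
        row = clim.loc[species]
        out.append(SlopeEstimate(
            species=str(species),
            slope=float(fit.coefficients.loc["log10_mr", "estimate"]),
            se=float(fit.coefficients.loc["log10_mr", "se"]),
            n=int(len(sub)),
            altitude_mean=float(row["altitude_mean"]),
            altitude_min=float(row["altitude_min"]),
            altitude_max=float(row["altitude_max"]),
            tmin_mean=float(row["tmin_mean"]),
            pdry_mean=float(row["pdry_mean"]),
            vpd_mean=float(row["vpd_mean"]),
        ))
    return out


def gaussian_aic(rss: float, n: int, n_coef: int) -> float:
    """AIC of a Gaussian linear model, constant included.

    ``AIC = n log(2 pi RSS / n) + n + 2 (n_coef + 1)``; the +1 counts the
    residual variance, matching mixed-model software output so first- and
    second-stage tables are on one scale.
    """
    if n <= 0 or rss < 0:
        raise ValueError("need n > 0 and RSS >= 0")
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (n_coef + 1)


_SLOPE_PREDICTORS = {
    name: tuple(CLIMATE_MEAN_COLS[c] for c in cols)
    for name, cols in CLIMATE_SETS.items()
}


def slope_climate_set(slopes: list[SlopeEstimate],
                      weighted: bool = False) -> pd.DataFrame:
    """Compare the five slope-vs-climate linear models by AIC.

    One OLS regression of the per-species slope on each climate summary
    (altitude, VPD, Tmin, Tmin+Pdry, Pdry).  ``weighted=True`` weights
    species by 1/se^2 (off by default: species slopes enter unweighted).
    Models with more coefficients than species are flagged ``rank_deficient``
    and excluded from the weights.  Returns a frame sorted by AIC with
    coefficient estimates in ``attrs["coefs"]``.
    """
    if len(slopes) < 3:
        raise ValueError("need at least 3 species slopes")
    df = pd.DataFrame([vars(s) for s in slopes])
    y = df["slope"].to_numpy()
    n = len(df)
    w = 1.0 / df["se"].to_numpy() ** 2 if weighted else np.ones(n)

    rows, coefs = [], {}
    for name, preds in _SLOPE_PREDICTORS.items():
        X = np.column_stack([np.ones(n)] + [df[p].to_numpy() for p in preds])
        k = X.shape[1]
        if n <= k or np.linalg.matrix_rank(X) < k:
            rows.append({"name": name, "df": k + 1, "aic": np.nan,
                         "r2": np.nan, "rank_deficient": True})
            warnings.warn(f"slope model {name!r} is rank deficient with "
                          f"{n} species; excluded", stacklevel=2)
            continue
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        resid = y - X @ beta
        rss = float(np.sum(w * resid**2))
        tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
        rows.append({
            "name": name,
            "df": k + 1,  # coefficients + residual variance
            "aic": gaussian_aic(rss, n, k),
            "r2": 1.0 - rss / tss if tss > 0 else np.nan,
            "rank_deficient": False,
        })
        coefs[name] = dict(zip(["intercept", *preds], beta))

    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - np.nanmin(table["aic"])
    table["weight"] = akaike_weights(table["aic"])
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table.attrs["coefs"] = coefs
    table.attrs["n_species"] = n
    return table
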