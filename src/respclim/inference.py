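"""Strong-inference mixed-model comparison of trait-climate hypotheses.

Two a-priori candidate sets of five Gaussian linear mixed models each:

* metabolic-rate set (tests metabolic cold adaptation): response log10 MR,
  climate term one of {Tmin, Pdry, VPD, Tmin+Pdry, altitude};
* gas-exchange-frequency set (tests the hygric hypothesis): response FGE,
  same five climate terms, with log10 MR always included because frequency
  of gas exchange scales with metabolic rate.

Every model carries log10 body mass; multispecies scope adds species and its
interaction with mass (and with MR in the FGE set).  Measurement block and
analyser channel enter as crossed random intercepts.  Candidate models are
ranked by AIC; evidence is summarised by Akaike weights and marginal R^2
(fixed-effect variance over total variance).

The climate terms are modelled one at a time — except Tmin+Pdry, whose
variance inflation stays low because the rain shadow decouples temperature
from precipitation — since altitude, temperature and VPD are otherwise
strongly collinear; :func:`compute_vif` provides the screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitSummary",
    "CLIMATE_SETS",
    "build_mca_set",
    "build_hygric_set",
    "prepare_traits",
    "fit_lmm",
    "marginal_r2",
    "akaike_weights",
    "compare_models",
    "compute_vif",
]

#: name -> climate columns; one candidate model per entry.
CLIMATE_SETS: dict[str, tuple[str, ...]] = {
    "T_min": ("tmin_c",),
    "P_dry": ("pdry_mm",),
    "VPD": ("vpd_kpa",),
    "T_min+P_dry": ("tmin_c", "pdry_mm"),
    "Altitude": ("altitude_m",),
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, crossed random intercepts."""

    name: str
    response: str                       # "log10_mr" or "fge_min"
    fixed_terms: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ("block_id", "channel_id")
    scope: str = "within"               # "within" or "multispecies"

    @property
    def formula(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.fixed_terms)

    def columns(self) -> set[str]:
        cols = {self.response, *self.random_intercepts}
        for term in self.fixed_terms:
            for part in term.split(":"):
                cols.add(part.replace("C(", "").replace(")", "").strip())
        return cols


@dataclass
class FitSummary:
    """Everything reported for one fitted candidate model."""

    spec: ModelSpec
    coefficients: pd.DataFrame          # estimate, se, df, t, p per fixed term
    variance_components: dict[str, float]
    sigma2_resid: float
    sigma2_fixed: float
    loglik: float
    n_params: int
    aic: float
    n_obs: int
    converged: bool
    method: str = "ml"

    @property
    def marginal_r2(self) -> float:
        return marginal_r2(self)


def build_mca_set(scope: str = "within") -> list[ModelSpec]:
    """The five metabolic-rate candidate models (response: log10 MR)."""
    _check_scope(scope)
    specs = []
    for name, clim in CLIMATE_SETS.items():
        terms = ["log10_mass", *clim]
        if scope == "multispecies":
            terms += ["species", "log10_mass:species"]
        specs.append(ModelSpec(name=name, response="log10_mr",
                               fixed_terms=tuple(terms), scope=scope))
    return specs


def build_hygric_set(scope: str = "within") -> list[ModelSpec]:
    """The five gas-exchange-frequency candidate models (response: FGE).

    Every spec includes log10 MR; the altitude-only model is the null.
    """
    _check_scope(scope)
    specs = []
    for name, clim in CLIMATE_SETS.items():
        terms = ["log10_mass", "log10_mr", *clim]
        if scope == "multispecies":
            terms += ["species", "log10_mass:species", "log10_mr:species"]
        specs.append(ModelSpec(name=name, response="fge_min",
                               fixed_terms=tuple(terms), scope=scope))
    return specs


def _check_scope(scope: str) -> None:
    if scope not in ("within", "multispecies"):
        raise ValueError(f"unknown scope {scope!r}")


def prepare_traits(traits: pd.DataFrame,
                   sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join site climate onto a trait table and add the log10 model columns."""
    df = traits.copy()
    if sites is not None:
        clim_cols = [c for c in sites.columns if c != "site_id"]
        drop = [c for c in clim_cols if c in df.columns]
        df = df.drop(columns=drop).merge(sites, on="site_id", how="left",
                                         validate="many_to_one")
    if "log10_mr" not in df.columns:
        df["log10_mr"] = np.log10(df["vco2_ml_min"])
    if "log10_mass" not in df.columns:
        df["log10_mass"] = np.log10(df["mass_mg"])
    return df


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, method: str = "ml") -> FitSummary:
    """Fit one candidate model with crossed random intercepts.

    Implemented as a variance-components mixed model (single trivial group;
    one component per random-intercept factor), which is the standard way to
    express crossed random intercepts.  ``method`` is ``"ml"`` (default,
    required for AIC comparison across fixed-effect structures) or
    ``"reml"``.

    AIC is ``-2 loglik + 2 k`` with ``k`` = fixed effects + variance
    components + residual.  Denominator degrees of freedom for the t tests
    use the containment-style approximation ``n - n_blocks - n_channels``.
    Random factors with fewer than 2 levels are dropped with a warning.
    """
    if method not in ("ml", "reml"):
        raise ValueError(f"unknown estimation method {method!r}")
    missing = spec.columns() - set(data.columns)
    if missing:
        raise KeyError(f"data lacks columns required by {spec.name}: {sorted(missing)}")
    df = data.dropna(subset=sorted(spec.columns())).copy()
    n = len(df)

    vc = {}
    n_levels = {}
    for factor in spec.random_intercepts:
        k = df[factor].nunique()
        n_levels[factor] = k
        if k >= 2:
            vc[factor] = f"0 + C({factor})"
        else:
            warnings.warn(
                f"random factor {factor!r} has {k} level(s); dropped",
                stacklevel=2,
            )
    df["_one"] = 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, df, groups="_one",
                            re_formula="0", vc_formula=vc or None)
        # aliased fixed effects -> refuse rather than silently rank
        rank = np.linalg.matrix_rank(model.exog)
        if rank < model.exog.shape[1]:
            raise ValueError(
                f"rank-deficient fixed effects in {spec.name}: "
                f"{model.exog_names[rank]} is aliased"
            )
        # the profiled likelihood is occasionally awkward for one optimiser;
        # walk through a few before declaring non-convergence
        result, converged = None, False
        for opt in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                candidate = model.fit(reml=(method == "reml"), method=opt)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result is None:
                result = candidate
            if getattr(candidate, "converged", True):
                result, converged = candidate, True
                break
        if result is None:
            raise ValueError(f"mixed-model fit failed for {spec.name}")

    fe = result.fe_params
    se = result.bse_fe
    ddf = max(n - sum(min(v, n) for v in n_levels.values()), 1)
    tvals = fe / se
    pvals = 2 * stats.t.sf(np.abs(tvals), ddf)
    coefs = pd.DataFrame({
        "estimate": fe, "se": se, "df": ddf, "t": tvals, "p": pvals,
    })

    vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, result.vcomp)}
    sigma2_resid = float(result.scale)
    eta = np.asarray(model.exog @ fe.to_numpy())
    sigma2_fixed = float(np.var(eta, ddof=1))

    n_params = len(fe) + len(vcomp) + 1
    loglik = float(result.llf)
    return FitSummary(
        spec=spec, coefficients=coefs, variance_components=vcomp,
        sigma2_resid=sigma2_resid, sigma2_fixed=sigma2_fixed,
        loglik=loglik, n_params=n_params, aic=-2.0 * loglik + 2.0 * n_params,
        n_obs=n, converged=converged, method=method,
    )


def marginal_r2(fit: FitSummary) -> float:
    """Fixed-effect variance share: s2_fixed / (s2_fixed + sum(s2_re) + s2_resid)."""
    total = fit.sigma2_fixed + sum(fit.variance_components.values()) + fit.sigma2_resid
    if total <= 0:
        raise ValueError("zero total variance; marginal R^2 undefined")
    return fit.sigma2_fixed / total


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)``.

    Non-finite AICs are excluded with a warning and get weight NaN; the
    remaining weights sum to 1.
    """
    a = np.asarray(aics, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AIC values")
    if not finite.all():
        warnings.warn("non-finite AIC values excluded from weights", stacklevel=2)
    w = np.full(a.shape, np.nan)
    rel = np.exp(-0.5 * (a[finite] - a[finite].min()))
    w[finite] = rel / rel.sum()
    return w


def compare_models(specs, data: pd.DataFrame, method: str = "ml") -> pd.DataFrame:
    """Fit a candidate set on one common row set and rank by AIC.

    Rows missing any column referenced by *any* spec are dropped once before
    all fits, so every AIC describes the same data.  Returns a frame sorted
    ascending by AIC with columns name, df (= parameter count), aic,
    delta_aic, weight, marginal_r2, converged, plus ``n_obs`` in ``attrs``.
    Non-converged fits are retained in the table but flagged and excluded
    from the weight normalisation.
    """
    all_cols = set()
    for spec in specs:
        all_cols |= spec.columns()
    missing = all_cols - set(data.columns)
    if missing:
        raise KeyError(f"data lacks columns: {sorted(missing)}")
    common = data.dropna(subset=sorted(all_cols))

    fits = [fit_lmm(spec, common, method=method) for spec in specs]
    aics = []
    for f in fits:
        if not f.converged:
            warnings.warn(
                f"model {f.spec.name} did not converge; excluded from ranking",
                stacklevel=2,
            )
            aics.append(np.nan)
        else:
            aics.append(f.aic)
    weights = akaike_weights(aics)
    aic_arr = np.asarray(aics)
    delta = aic_arr - np.nanmin(aic_arr)

    table = pd.DataFrame({
        "name": [f.spec.name for f in fits],
        "df": [f.n_params for f in fits],
        "aic": aic_arr,
        "delta_aic": delta,
        "weight": weights,
        "marginal_r2": [f.marginal_r2 for f in fits],
        "converged": [f.converged for f in fits],
    })
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table.attrs["n_obs"] = len(common)
    table.attrs["fits"] = {f.spec.name: f for f in fits}
    return table


def compute_vif(data: pd.DataFrame, terms) -> pd.Series:
    """Variance inflation factor per term: ``1 / (1 - R^2_j)``.

    ``R^2_j`` comes from the OLS regression of term j on the other terms
    (with intercept).  Perfect collinearity yields ``inf``.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("VIF needs at least two terms")
    X = data[terms].astype(float).dropna()
    out = {}
    for j, term in enumerate(terms):
        others = [t for t in terms if t != term]
        exog = sm.add_constant(X[others])
        r2 = sm.OLS(X[term], exog).fit().rsquared
        out[term] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
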