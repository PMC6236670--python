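"""Longitudinal trend analysis with a linear mixed-effects model.

The whole-brain biomarker value of subject i at time t (days scaled by
1/60 so t ∈ [0, 1] over the 60-day follow-up) is modelled as

    y_it = β0 + β_dose·1[dose=20 Gy] + β_t·t + β_t²·t² + u0_i + u1_i·t + ε_it

with per-subject random intercept and slope (u0, u1) ~ N(0, G) and residual
ε ~ N(0, σ²), estimated by restricted maximum likelihood (REML).  Dose is a
two-level indicator (20 Gy vs the 5 Gy baseline).  The quadratic time
effect and the dose effect are tested by Wald z-tests (no small-sample
correction).

Estimation is delegated to :class:`statsmodels` MixedLM; the scientific
contract is the restricted likelihood itself, and :func:`reml_loglike`
provides a direct, optimizer-free evaluation of that objective for
cross-checking any fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["TrendFit", "fit_trend", "predict_trend", "reml_loglike"]

TIME_SCALE_DAYS = 60.0


@dataclass
class TrendFit:
    """Fitted quadratic mixed model.

    Fixed effects and their standard errors are on the scaled-time axis
    (t = days/60); ``fixed_effects_days`` re-expresses the time terms per
    day and per day².  ``re_cov`` is the 2x2 random intercept/slope
    covariance, ``resid_var`` the residual variance, ``loglike_reml`` the
    REML objective at the estimate.  ``slope_dropped`` flags the fallback
    to a random-intercept-only model when the slope variance was singular.
    """

    fixed_effects: dict[str, float]
    fixed_se: dict[str, float]
    fixed_cov: np.ndarray
    re_cov: np.ndarray
    resid_var: float
    loglike_reml: float
    p_quadratic: float
    p_dose: float
    n_obs: int
    n_subjects: int
    dose_levels: tuple[float, float]
    slope_dropped: bool = False
    converged: bool = True

    @property
    def fixed_effects_days(self) -> dict[str, float]:
        fe = self.fixed_effects
        return {
            "intercept": fe["intercept"],
            "dose": fe["dose"],
            "t_per_day": fe["t"] / TIME_SCALE_DAYS,
            "t2_per_day2": fe["t2"] / TIME_SCALE_DAYS**2,
        }

    def to_dict(self) -> dict:
        return {
            "fixed_effects_scaled_time": self.fixed_effects,
            "fixed_effects_se": self.fixed_se,
            "fixed_effects_days": self.fixed_effects_days,
            "random_effect_cov": self.re_cov.tolist(),
            "residual_variance": self.resid_var,
            "reml_loglike": self.loglike_reml,
            "p_quadratic_wald": self.p_quadratic,
            "p_dose_wald": self.p_dose,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "slope_dropped": self.slope_dropped,
            "converged": self.converged,
        }


def _design(df: pd.DataFrame, high_dose: float) -> pd.DataFrame:
    d = df.copy()
    d["t"] = d["time_days"] / TIME_SCALE_DAYS
    d["t2"] = d["t"] ** 2
    d["dose20"] = (d["dose_Gy"] == high_dose).astype(float)
    return d


def fit_trend(whole_brain: pd.DataFrame, response: str = "whole_brain") -> TrendFit:
    """Fit the quadratic random-slope model by REML.

    ``whole_brain`` must carry columns subject, dose_Gy, time_days and the
    response (one row per scan; use :func:`neuroquant.roi.whole_brain_series`
    to build it from a region table).  If the random-slope covariance is
    singular at the optimum, the model is refitted with a random intercept
    only and flagged.
    """
    df = whole_brain.dropna(subset=[response])
    if df["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    if df["time_days"].nunique() < 2:
        raise ValueError("all observations at a single time point")
    per_subj = df.groupby("subject")["time_days"].nunique()
    if (per_subj < 2).all():
        raise ValueError("need >= 2 time points per subject")
    doses = tuple(sorted(df["dose_Gy"].unique()))
    high = doses[-1]
    d = _design(df, high)
    formula = f"{response} ~ dose20 + t + t2"

    import warnings

    def _fit(re_formula):
        model = smf.mixedlm(formula, d, groups=d["subject"], re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "nm"):
                try:
                    res = model.fit(reml=True, method=method, maxiter=500)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.all(np.isfinite(np.asarray(res.fe_params))):
                    return res
        return None

    res = _fit("~t")
    slope_dropped = False
    if res is not None:
        cov_re = np.asarray(res.cov_re)
        eig = np.linalg.eigvalsh(cov_re)
        if not np.all(np.isfinite(eig)) or eig.min() < 1e-12 * max(eig.max(), 1e-30) \
                or not getattr(res, "converged", True):
            res = None
    if res is None:
        res = _fit("1")
        slope_dropped = True
        if res is not None:
            v0 = float(np.asarray(res.cov_re).ravel()[0])
            cov_re = np.array([[v0, 0.0], [0.0, 0.0]])
    if res is None:
        # no between-subject structure estimable: zero-variance REML solution
        # (pooled OLS with the residual variance on n - p degrees of freedom)
        return _ols_trendfit(d, doses, response)

    names = {"Intercept": "intercept", "dose20": "dose", "t": "t", "t2": "t2"}
    fe = {names[k]: float(v) for k, v in res.fe_params.items()}
    bse = res.bse_fe
    se = {names[k]: float(bse[k]) for k in res.fe_params.index}
    fcov = np.asarray(res.cov_params())[:4, :4]
    pvals = res.pvalues
    return TrendFit(
        fixed_effects=fe,
        fixed_se=se,
        fixed_cov=fcov,
        re_cov=cov_re,
        resid_var=float(res.scale),
        loglike_reml=float(res.llf),
        p_quadratic=float(pvals["t2"]),
        p_dose=float(pvals["dose20"]),
        n_obs=int(len(d)),
        n_subjects=int(d["subject"].nunique()),
        dose_levels=(doses[0], doses[-1]) if len(doses) > 1 else (doses[0], doses[0]),
        slope_dropped=slope_dropped,
        converged=bool(getattr(res, "converged", True)),
    )


def _ols_trendfit(d: pd.DataFrame, doses, response: str) -> TrendFit:
    from scipy.stats import norm

    X = np.column_stack([np.ones(len(d)), d["dose20"], d["t"], d["t2"]])
    y = d[response].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid / (len(d) - 4))
    fcov = s2 * np.linalg.inv(X.T @ X)
    se_arr = np.sqrt(np.diag(fcov))
    names = ("intercept", "dose", "t", "t2")
    fe = dict(zip(names, map(float, beta)))
    se = dict(zip(names, map(float, se_arr)))
    z = beta / se_arr
    p = 2.0 * norm.sf(np.abs(z))
    tmp = d.copy()
    ll = reml_loglike(tmp, fe, np.zeros((2, 2)), s2, response=response)
    return TrendFit(
        fixed_effects=fe,
        fixed_se=se,
        fixed_cov=fcov,
        re_cov=np.zeros((2, 2)),
        resid_var=s2,
        loglike_reml=ll,
        p_quadratic=float(p[3]),
        p_dose=float(p[1]),
        n_obs=int(len(d)),
        n_subjects=int(d["subject"].nunique()),
        dose_levels=(doses[0], doses[-1]) if len(doses) > 1 else (doses[0], doses[0]),
        slope_dropped=True,
        converged=True,
    )


def reml_loglike(
    whole_brain: pd.DataFrame,
    fixed_effects: dict[str, float],
    re_cov: np.ndarray,
    resid_var: float,
    response: str = "whole_brain",
) -> float:
    """Direct evaluation of the restricted log-likelihood.

    Computes, subject by subject, V_i = Z_i G Z_i' + σ² I with Z_i = [1, t]
    and returns

        −½ [ Σ log|V_i| + log|Σ X_i'V_i⁻¹X_i| + r'V⁻¹r ] − ½(n−p)·log 2π

    at the supplied parameters.  Used to verify that any optimizer's
    reported REML objective is the actual restricted likelihood.
    """
    df = whole_brain.dropna(subset=[response])
    doses = sorted(df["dose_Gy"].unique())
    d = _design(df, doses[-1])
    beta = np.array(
        [fixed_effects["intercept"], fixed_effects["dose"], fixed_effects["t"],
         fixed_effects["t2"]]
    )
    G = np.asarray(re_cov, dtype=float)
    logdet = 0.0
    quad = 0.0
    xtvx = np.zeros((4, 4))
    n = 0
    for _, g in d.groupby("subject"):
        X = np.column_stack([np.ones(len(g)), g["dose20"], g["t"], g["t2"]])
        Z = np.column_stack([np.ones(len(g)), g["t"]])
        V = Z @ G @ Z.T + resid_var * np.eye(len(g))
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        Vinv = np.linalg.inv(V)
        r = g[response].to_numpy(dtype=float) - X @ beta
        logdet += ld
        quad += float(r @ Vinv @ r)
        xtvx += X.T @ Vinv @ X
    n = len(d)
    p = 4
    sign, ldx = np.linalg.slogdet(xtvx)
    return float(-0.5 * (logdet + ldx + quad) - 0.5 * (n - p) * np.log(2.0 * np.pi))


def predict_trend(
    fit: TrendFit,
    times_days: np.ndarray,
    dose_Gy: float,
    level: float = 0.95,
) -> pd.DataFrame:
    """Population-level fitted quadratic curve with a delta-method band.

    Returns a frame of (time_days, fitted, se, lo, hi); the band covers the
    fixed-effect mean curve, not individual-subject predictions.
    """
    if not all(np.isfinite(v) for v in fit.fixed_effects.values()):
        raise ValueError("cannot predict from an invalid fit")
    from scipy.stats import norm

    t = np.asarray(times_days, dtype=float) / TIME_SCALE_DAYS
    is_high = float(dose_Gy == fit.dose_levels[1] and fit.dose_levels[1] != fit.dose_levels[0])
    X = np.column_stack([np.ones_like(t), np.full_like(t, is_high), t, t**2])
    beta = np.array(
        [fit.fixed_effects["intercept"], fit.fixed_effects["dose"],
         fit.fixed_effects["t"], fit.fixed_effects["t2"]]
    )
    mu = X @ beta
    var = np.einsum("ij,jk,ik->i", X, fit.fixed_cov, X)
    se = np.sqrt(np.clip(var, 0.0, None))  # boundary fits can return a non-PSD cov
    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "time_days": np.asarray(times_days, dtype=float),
            "fitted": mu,
            "se": se,
            "lo": mu - z * se,
            "hi": mu + z * se,
        }
    )
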