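"""Maximum-likelihood estimation of the survival-model parameters.

The survival model has 13 cell/beam-specific constants; two are fixed by
convention (``s_p_max = 1`` and the microdosimetric ``gamma``, taken from
upstream simulation), leaving 11 free parameters estimated jointly from a
clonogenic survival table.

Likelihood: Gaussian on natural-log survival.  Clonogenic surviving
fractions are ratio statistics spanning several decades, so multiplicative
(lognormal) error is the standard assumption.  The per-point standard
deviation comes from reported errors via the delta method
(``sigma_ln = se / sf``) when present; otherwise a single common sigma is
profiled out analytically.

Search: seeded Latin-hypercube restarts over a parameter box, each refined
by a bounded local optimizer; the sublethal-damage repair rate ``a_plus_c``
is boxed to the literature interval (2.18, 2.23) /h as prior information.
Ties between restarts break to the lowest restart index, so a fit is
bit-reproducible given (data, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import optimize
from scipy.stats import qmc

from .exceptions import ConvergenceError, IdentifiabilityError
from .model import _log_survival_parts, flatten_params
from .params import (
    MicrodosimetryParams,
    ModelParameters,
    NonTargetedParams,
    PharmacologyParams,
    SPECIFIC_ENERGY_COEF,
    TargetedParams,
)

__all__ = [
    "SurvivalObservation",
    "FitConfig",
    "FitResult",
    "FREE_PARAM_NAMES",
    "A_PLUS_C_PRIOR_RANGE",
    "default_bounds",
    "negative_log_likelihood",
    "fit_parameters",
    "adjusted_r_squared",
    "posterior_sample",
]

#: canonical ordering of the 11 free parameters
FREE_PARAM_NAMES: tuple[str, ...] = (
    "s_p_min",
    "ed50",
    "r_p",
    "alpha0",
    "beta0",
    "a_plus_c",
    "alpha_b",
    "beta_b",
    "delta_min",
    "delta_max",
    "r_delta",
)

#: literature interval for the sublethal-damage repair rate (per hour)
A_PLUS_C_PRIOR_RANGE: tuple[float, float] = (2.18, 2.23)

_PHARM_NAMES = {"s_p_min", "ed50", "r_p"}
_CONC_NAMES = _PHARM_NAMES | {"delta_min", "delta_max", "r_delta"}
_DOSE_NAMES = {"alpha0", "beta0", "a_plus_c", "alpha_b", "beta_b", "delta_min", "delta_max", "r_delta"}

_SIGMA2_FLOOR = 1e-24  # keeps the profiled likelihood finite on noise-free data


class SurvivalObservation(BaseModel):
    """One clonogenic survival measurement: absorbed dose (Gy), delivery
    dose rate (Gy/h), drug concentration (uM), surviving fraction in
    (0, 1], and optionally its standard error and replicate count."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    dose: float
    dose_rate: float = 60.0
    concentration: float = 0.0
    surviving_fraction: float
    std_error: float | None = None
    n_replicates: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "SurvivalObservation":
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose}")
        if self.dose_rate <= 0:
            raise ValueError(f"dose_rate must be positive, got {self.dose_rate}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be non-negative, got {self.concentration}")
        if not (0.0 < self.surviving_fraction <= 1.0):
            raise ValueError(
                f"surviving_fraction must be in (0, 1], got {self.surviving_fraction}"
            )
        if self.std_error is not None and self.std_error <= 0:
            raise ValueError(f"std_error must be positive, got {self.std_error}")
        return self


def default_bounds(reference: ModelParameters) -> dict[str, tuple[float, float]]:
    """Box constraints centred on a reference parameter set: a factor of 3
    either side of each value, except ``a_plus_c`` which is pinned to its
    literature prior interval."""
    ref = flatten_params(reference)
    bounds = {}
    for name in FREE_PARAM_NAMES:
        if name == "a_plus_c":
            bounds[name] = A_PLUS_C_PRIOR_RANGE
        else:
            v = ref[name]
            bounds[name] = (v / 3.0, min(v * 3.0, 1.0) if name == "s_p_min" else v * 3.0)
    return bounds


class FitConfig(BaseModel):
    """Fit configuration: restart count, RNG seed, parameter box, fixed
    parameters, error model and the F convention for the data's exposures."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n_starts: int = 20
    seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None
    fixed: dict[str, float] = {}
    error_model: str = "auto"  # auto | reported | profiled | fixed
    sigma: float | None = None  # common sigma when error_model == "fixed"
    f_mode: str = "protracted"  # protracted (T = D/rate per point) | acute (F = 1)
    a_plus_c_range: tuple[float, float] = A_PLUS_C_PRIOR_RANGE

    @model_validator(mode="after")
    def _check(self) -> "FitConfig":
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.error_model not in {"auto", "reported", "profiled", "fixed"}:
            raise ValueError(f"unknown error_model {self.error_model!r}")
        if self.error_model == "fixed" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("error_model='fixed' requires a positive sigma")
        if self.f_mode not in {"protracted", "acute"}:
            raise ValueError(f"unknown f_mode {self.f_mode!r}")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if name not in FREE_PARAM_NAMES:
                    raise ValueError(f"bounds given for unknown parameter {name!r}")
                if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                    raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
        lo, hi = self.a_plus_c_range
        if not lo < hi:
            raise ValueError("a_plus_c_range must have lo < hi")
        return self

    @classmethod
    def for_reference(cls, reference: ModelParameters, **kwargs) -> "FitConfig":
        """Config with bounds centred on ``reference`` and ``s_p_max`` /
        ``gamma`` fixed at the reference values (the 11-free-parameter
        setup)."""
        fixed = {"s_p_max": reference.pharmacology.s_p_max, "gamma": reference.gamma}
        fixed.update(kwargs.pop("fixed", {}))
        return cls(bounds=default_bounds(reference), fixed=fixed, **kwargs)


@dataclass
class FitResult:
    """Point estimates with curvature-based uncertainties and fit quality."""

    params: ModelParameters
    std_errors: dict[str, float]
    log_likelihood: float
    r_squared: float
    n_obs: int
    m_params: int
    converged: bool
    free_names: tuple[str, ...]
    restart_objectives: list[float] = field(default_factory=list)
    best_restart: int = 0
    bounds_hit: dict[str, bool] = field(default_factory=dict)

    @property
    def estimates(self) -> dict[str, float]:
        return flatten_params(self.params)


# ----------------------------------------------------------------------
# likelihood machinery

def _data_arrays(data: list[SurvivalObservation], f_mode: str = "protracted"):
    dose = np.array([o.dose for o in data], dtype=float)
    conc = np.array([o.concentration for o in data], dtype=float)
    if f_mode == "acute":
        duration = np.zeros_like(dose)
    else:
        duration = dose / np.array([o.dose_rate for o in data], dtype=float)
    ln_sf = np.log(np.array([o.surviving_fraction for o in data], dtype=float))
    ses = [o.std_error for o in data]
    if all(s is not None for s in ses) and data:
        sigma_ln = np.array(
            [s / o.surviving_fraction for s, o in zip(ses, data)], dtype=float
        )
    else:
        sigma_ln = None
    return dose, duration, conc, ln_sf, sigma_ln


def _nll_from_resid(resid: np.ndarray, mode: str, sigma_ln, sigma: float | None) -> float:
    n = resid.size
    if mode == "reported":
        return float(np.sum(resid**2 / (2.0 * sigma_ln**2) + np.log(sigma_ln)))
    if mode == "fixed":
        return float(np.sum(resid**2) / (2.0 * sigma**2) + n * math.log(sigma))
    # profiled common sigma: sigma2_hat = mean(resid^2)
    sigma2 = max(float(np.mean(resid**2)), _SIGMA2_FLOOR)
    return 0.5 * n * (1.0 + math.log(sigma2))


def _resolve_error_mode(mode: str, sigma_ln) -> str:
    if mode == "auto":
        return "reported" if sigma_ln is not None else "profiled"
    if mode == "reported" and sigma_ln is None:
        raise ValueError("error_model='reported' but some observations lack std_error")
    return mode


def negative_log_likelihood(
    params: ModelParameters,
    data: list[SurvivalObservation],
    error_model: str = "auto",
    sigma: float | None = None,
    f_mode: str = "protracted",
) -> float:
    """Negative Gaussian log-likelihood on ln(surviving fraction), up to
    the additive ``n ln sqrt(2 pi)`` constant.  Invariant under reordering
    of observations and additive over independent datasets (at fixed
    sigma)."""
    if not data:
        raise ValueError("no observations")
    dose, duration, conc, ln_sf, sigma_ln = _data_arrays(data, f_mode)
    theta = flatten_params(params)
    ln_sp, te, nte = _log_survival_parts(theta, dose, duration, conc)
    resid = ln_sf - (ln_sp - te - nte)
    mode = _resolve_error_mode(error_model, sigma_ln)
    return _nll_from_resid(resid, mode, sigma_ln, sigma)


def adjusted_r_squared(observed, calculated, m_params: int) -> float:
    """Determination coefficient adjusted for model size, on the linear
    survival scale:
    ``1 - [sum (exp_i - cal_i)^2 / (n-m-1)] / [sum (exp_i - <exp>)^2 / (n-1)]``.
    Equals the classical ``1 - (1 - R2)(n-1)/(n-m-1)``."""
    obs = np.asarray(observed, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if obs.size == 0 or obs.shape != cal.shape:
        raise ValueError("observed and calculated must be equal-length non-empty")
    n = obs.size
    if n - m_params - 1 <= 0:
        raise ValueError(f"need n > m + 1, got n={n}, m={m_params}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed survival has zero variance")
    ss_res = float(np.sum((obs - cal) ** 2))
    return 1.0 - (ss_res / (n - m_params - 1)) / (ss_tot / (n - 1))


# ----------------------------------------------------------------------
# fitting

def _theta_full(free_vec, free_names, fixed) -> dict[str, float]:
    theta = dict(fixed)
    theta.update(zip(free_names, free_vec))
    return theta


def _params_from_theta(theta: dict[str, float]) -> ModelParameters:
    # invert the spherical-domain conversion so gamma round-trips
    y_d = theta["gamma"] / SPECIFIC_ENERGY_COEF
    return ModelParameters(
        pharmacology=PharmacologyParams(
            s_p_min=theta["s_p_min"], s_p_max=theta["s_p_max"],
            ed50=theta["ed50"], r_p=theta["r_p"],
        ),
        microdosimetry=MicrodosimetryParams(y_d=y_d, gamma=theta["gamma"]),
        targeted=TargetedParams(
            alpha0=theta["alpha0"], beta0=theta["beta0"], a_plus_c=theta["a_plus_c"]
        ),
        non_targeted=NonTargetedParams(
            alpha_b=theta["alpha_b"], beta_b=theta["beta_b"],
            delta_min=theta["delta_min"], delta_max=theta["delta_max"],
            r_delta=theta["r_delta"],
        ),
    )


def _check_design(data, free_names):
    doses = {o.dose for o in data}
    concs = {o.concentration for o in data}
    free = set(free_names)
    if free & _CONC_NAMES and len(concs) < 2:
        raise IdentifiabilityError(
            "concentration-dependent parameters are free but the design has a single concentration"
        )
    if free & _DOSE_NAMES and len(doses) < 2:
        raise IdentifiabilityError(
            "dose-dependent parameters are free but the design has a single dose level"
        )


def fit_parameters(data: list[SurvivalObservation], config: FitConfig) -> FitResult:
    """Estimate the free parameters by seeded Latin-hypercube multi-start
    maximum likelihood.

    Each restart runs a bounded trust-region least-squares refinement from
    one hypercube sample of the parameter box (scaled by the box widths so
    all parameters are searched on a comparable scale).  Uncertainties are
    the square roots of the diagonal of the inverse numerical Hessian of
    the negative log-likelihood at the optimum.
    """
    fixed = {"s_p_max": 1.0}
    fixed.update(config.fixed)
    if "gamma" not in fixed:
        raise ValueError("config.fixed must supply 'gamma' (it is never a free parameter)")
    free_names = tuple(n for n in FREE_PARAM_NAMES if n not in fixed)
    m = len(free_names)
    if len(data) < m + 2:
        raise IdentifiabilityError(f"need at least {m + 2} observations, got {len(data)}")
    _check_design(data, free_names)

    if config.bounds is not None:
        bounds_map = dict(config.bounds)
    else:
        from .io import ht1080_table1  # reference box when none supplied

        bounds_map = default_bounds(ht1080_table1())
    bounds_map["a_plus_c"] = config.a_plus_c_range
    missing = [n for n in free_names if n not in bounds_map]
    if missing:
        raise ValueError(f"no bounds for free parameters: {missing}")
    lo = np.array([bounds_map[n][0] for n in free_names])
    hi = np.array([bounds_map[n][1] for n in free_names])

    dose, duration, conc, ln_sf, sigma_ln = _data_arrays(data, config.f_mode)
    mode = _resolve_error_mode(config.error_model, sigma_ln)

    # In every error mode the MLE is a weighted least-squares problem on
    # log-survival residuals (the profiled likelihood is monotone in the
    # residual sum of squares), so each restart is refined with a bounded
    # trust-region least-squares solve and ranked by its exact NLL.
    def residuals(theta_vec: np.ndarray) -> np.ndarray:
        theta = _theta_full(theta_vec, free_names, fixed)
        ln_sp, te, nte = _log_survival_parts(theta, dose, duration, conc)
        resid = ln_sf - (ln_sp - te - nte)
        if mode == "reported":
            return resid / sigma_ln
        if mode == "fixed":
            return resid / config.sigma
        return resid

    def nll_of(theta_vec: np.ndarray) -> float:
        theta = _theta_full(theta_vec, free_names, fixed)
        ln_sp, te, nte = _log_survival_parts(theta, dose, duration, conc)
        resid = ln_sf - (ln_sp - te - nte)
        return _nll_from_resid(resid, mode, sigma_ln, config.sigma)

    sampler = qmc.LatinHypercube(d=m, seed=int(config.seed) % (2**31))
    starts = sampler.random(config.n_starts)

    best = None
    objectives: list[float] = []
    for i, u0 in enumerate(starts):
        try:
            res = optimize.least_squares(
                residuals,
                lo + u0 * (hi - lo),
                bounds=(lo, hi),
                method="trf",
                x_scale=hi - lo,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
            fval = nll_of(res.x)
        except Exception:
            objectives.append(math.inf)
            continue
        objectives.append(fval)
        if best is None or fval < best[1]:
            best = (i, fval, np.clip(res.x, lo, hi), bool(res.success))
    if best is None or not math.isfinite(best[1]):
        raise ConvergenceError("all optimizer restarts failed")

    best_i, best_f, theta_hat_vec, success = best
    theta_hat = _theta_full(theta_hat_vec, free_names, fixed)
    params = _params_from_theta(theta_hat)

    # curvature-based standard errors on the raw parameter scale
    std_errors = _curvature_std_errors(
        theta_hat_vec, free_names, fixed, dose, duration, conc, ln_sf,
        sigma_ln, mode, config.sigma,
    )

    ln_sp, te, nte = _log_survival_parts(theta_hat, dose, duration, conc)
    sf_cal = np.exp(ln_sp - te - nte)
    sf_obs = np.exp(ln_sf)
    try:
        r2 = adjusted_r_squared(sf_obs, sf_cal, m)
    except ValueError:
        r2 = math.nan

    tol = 1e-9 * (hi - lo)
    bounds_hit = {
        n: bool(theta_hat_vec[j] <= lo[j] + tol[j] or theta_hat_vec[j] >= hi[j] - tol[j])
        for j, n in enumerate(free_names)
    }
    return FitResult(
        params=params,
        std_errors=std_errors,
        log_likelihood=-best_f,
        r_squared=r2,
        n_obs=len(data),
        m_params=m,
        converged=success,
        free_names=free_names,
        restart_objectives=objectives,
        best_restart=best_i,
        bounds_hit=bounds_hit,
    )


def _curvature_std_errors(
    theta_vec, free_names, fixed, dose, duration, conc, ln_sf, sigma_ln, mode, sigma
) -> dict[str, float]:
    m = len(theta_vec)

    def f(v: np.ndarray) -> float:
        theta = _theta_full(v, free_names, fixed)
        ln_sp, te, nte = _log_survival_parts(theta, dose, duration, conc)
        resid = ln_sf - (ln_sp - te - nte)
        return _nll_from_resid(resid, mode, sigma_ln, sigma)

    h = np.maximum(1e-7, 1e-4 * np.abs(theta_vec))
    hess = np.empty((m, m))
    f0 = f(theta_vec)
    for i in range(m):
        for j in range(i, m):
            vpp = theta_vec.copy(); vpp[i] += h[i]; vpp[j] += h[j]
            vpm = theta_vec.copy(); vpm[i] += h[i]; vpm[j] -= h[j]
            vmp = theta_vec.copy(); vmp[i] -= h[i]; vmp[j] += h[j]
            vmm = theta_vec.copy(); vmm[i] -= h[i]; vmm[j] -= h[j]
            if i == j:
                hess[i, i] = (f(vpp) - 2.0 * f0 + f(vmm)) / (4.0 * h[i] ** 2)
            else:
                hess[i, j] = hess[j, i] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (
                    4.0 * h[i] * h[j]
                )
    out: dict[str, float] = {}
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        for name, v in zip(free_names, diag):
            out[name] = math.sqrt(v) if v > 0 else math.nan
    except np.linalg.LinAlgError:
        out = {name: math.nan for name in free_names}
    return out


def posterior_sample(
    data: list[SurvivalObservation],
    config: FitConfig,
    n_samples: int = 2000,
    n_burn: int = 500,
    start: ModelParameters | None = None,
    proposal_scale: float = 0.02,
) -> pd.DataFrame:
    """Optional uncertainty mode: random-walk Metropolis over the bounded
    box with a flat prior, targeting the same likelihood as
    :func:`fit_parameters`.  Returns one row per retained draw with the
    free parameters as columns plus ``nll``.  Not used by the default
    fitting path."""
    fixed = {"s_p_max": 1.0}
    fixed.update(config.fixed)
    if "gamma" not in fixed:
        raise ValueError("config.fixed must supply 'gamma'")
    free_names = tuple(n for n in FREE_PARAM_NAMES if n not in fixed)
    m = len(free_names)
    bounds_map = dict(config.bounds or {})
    bounds_map.setdefault("a_plus_c", config.a_plus_c_range)
    lo = np.array([bounds_map[n][0] for n in free_names])
    hi = np.array([bounds_map[n][1] for n in free_names])
    dose, duration, conc, ln_sf, sigma_ln = _data_arrays(data, config.f_mode)
    mode = _resolve_error_mode(config.error_model, sigma_ln)

    def nll_u(u: np.ndarray) -> float:
        theta = _theta_full(lo + u * (hi - lo), free_names, fixed)
        if theta["delta_min"] > theta["delta_max"]:
            return math.inf
        ln_sp, te, nte = _log_survival_parts(theta, dose, duration, conc)
        return _nll_from_resid(ln_sf - (ln_sp - te - nte), mode, sigma_ln, config.sigma)

    rng = np.random.default_rng(config.seed)
    if start is not None:
        th = np.array([flatten_params(start)[n] for n in free_names])
        u = np.clip((th - lo) / (hi - lo), 0.0, 1.0)
    else:
        u = np.full(m, 0.5)
    cur = nll_u(u)
    rows = []
    for it in range(n_samples + n_burn):
        prop = u + proposal_scale * rng.standard_normal(m)
        # reflect at the unit box
        prop = np.abs(prop)
        prop = np.where(prop > 1.0, 2.0 - prop, prop)
        cand = nll_u(prop)
        if cand < cur or rng.random() < math.exp(min(0.0, cur - cand)):
            u, cur = prop, cand
        if it >= n_burn:
            theta = lo + u * (hi - lo)
            rows.append({**dict(zip(free_names, theta)), "nll": cur})
    return pd.DataFrame(rows)
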