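"""Single-exposure survival model.

The overall surviving fraction after one irradiation at drug concentration
``c`` factorizes as ``S = S_P(c) * S_T(D) * S_NT(D, c)``:

* ``S_P`` is a four-parameter log-logistic in concentration,
* ``-ln S_T = (alpha0 + gamma*beta0) D + F beta0 D^2`` with ``F`` the
  Lea-Catcheside protraction factor for first-order sublethal-damage
  repair at rate ``a + c`` during a delivery of duration ``T``,
* ``-ln S_NT = delta(c) * (1 - p) * p`` where
  ``p = exp(-(alpha_b + gamma*beta_b) D - beta_b D^2)`` is the probability
  that no cell-killing signal was activated, and the lesion ceiling
  ``delta`` rises log-logistically with concentration.

All arithmetic is done on the log scale; the private ``_*`` helpers are
plain-``numpy`` kernels shared with the fitting module, and accept scalars
or arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import (
    Exposure,
    ModelParameters,
    NonTargetedParams,
    PharmacologyParams,
    SPECIFIC_ENERGY_COEF,
    TargetedParams,
)

__all__ = [
    "gamma_from_lineal_energy",
    "lea_catcheside_factor",
    "pharmacological_survival",
    "delta_of_concentration",
    "targeted_log_survival",
    "nontargeted_log_survival",
    "combined_survival",
    "log_combined_survival",
    "survival_components",
    "predict_table",
]


# ----------------------------------------------------------------------
# raw numpy kernels (scalars or arrays; no validation)

def _log_logistic_down(c, lo, hi, ed50, r):
    """Decreasing sigmoid: hi at c=0, lo as c -> inf, midpoint at ed50."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        # (c/ed50)^r via exp/log keeps c=0 exact (ratio -> 0)
        ratio = np.where(c > 0, np.exp(r * np.log(np.maximum(c, 1e-300) / ed50)), 0.0)
    return lo + (hi - lo) / (1.0 + ratio)


def _delta(c, delta_min, delta_max, ed50, r_delta):
    """Increasing sigmoid: delta_min at c=0, delta_max as c -> inf."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(
            c > 0, np.exp(-r_delta * np.log(np.maximum(c, 1e-300) / ed50)), np.inf
        )
    return delta_min + (delta_max - delta_min) / (1.0 + ratio)


def _lea_catcheside(a_plus_c, duration):
    x = np.asarray(a_plus_c * np.asarray(duration, dtype=float), dtype=float)
    small = x < 1e-6
    xs = np.where(small, 1.0, x)  # dummy to avoid 0/0
    exact = 2.0 * (xs + np.expm1(-xs)) / xs**2
    series = 1.0 - x / 3.0 + x**2 / 12.0
    return np.where(small, series, exact)


def _targeted_lesions(dose, duration, alpha0, beta0, a_plus_c, gamma):
    dose = np.asarray(dose, dtype=float)
    f = _lea_catcheside(a_plus_c, duration)
    return (alpha0 + gamma * beta0) * dose + f * beta0 * dose**2


def _nontargeted_lesions(dose, delta, alpha_b, beta_b, gamma):
    dose = np.asarray(dose, dtype=float)
    e = (alpha_b + gamma * beta_b) * dose + beta_b * dose**2
    p = np.exp(-e)
    return delta * -np.expm1(-e) * p


def _log_survival_parts(theta, dose, duration, conc):
    """(ln S_P, targeted lesions, non-targeted lesions) for a flat parameter dict."""
    sp = _log_logistic_down(conc, theta["s_p_min"], theta["s_p_max"], theta["ed50"], theta["r_p"])
    te = _targeted_lesions(
        dose, duration, theta["alpha0"], theta["beta0"], theta["a_plus_c"], theta["gamma"]
    )
    dl = _delta(conc, theta["delta_min"], theta["delta_max"], theta["ed50"], theta["r_delta"])
    nte = _nontargeted_lesions(dose, dl, theta["alpha_b"], theta["beta_b"], theta["gamma"])
    return np.log(sp), te, nte


def flatten_params(params: ModelParameters) -> dict[str, float]:
    """Flat name -> value mapping used by the numpy kernels and the fitter."""
    return {
        "s_p_min": params.pharmacology.s_p_min,
        "s_p_max": params.pharmacology.s_p_max,
        "ed50": params.pharmacology.ed50,
        "r_p": params.pharmacology.r_p,
        "alpha0": params.targeted.alpha0,
        "beta0": params.targeted.beta0,
        "a_plus_c": params.targeted.a_plus_c,
        "alpha_b": params.non_targeted.alpha_b,
        "beta_b": params.non_targeted.beta_b,
        "delta_min": params.non_targeted.delta_min,
        "delta_max": params.non_targeted.delta_max,
        "r_delta": params.non_targeted.r_delta,
        "gamma": params.gamma,
    }


# ----------------------------------------------------------------------
# public typed operations

def gamma_from_lineal_energy(y_d: float, domain_diameter: float = 1.0) -> float:
    """Mean specific energy per event (Gy) for a unit-density spherical
    domain, from the dose-mean lineal energy ``y_d`` (keV/um) and the
    domain diameter (um): ``z = 4 y_d / (rho pi d^2)`` ~ 0.204 y_d / d^2.
    """
    if y_d <= 0:
        raise ValueError(f"y_d must be positive, got {y_d}")
    if domain_diameter <= 0:
        raise ValueError(f"domain_diameter must be positive, got {domain_diameter}")
    return SPECIFIC_ENERGY_COEF * y_d / domain_diameter**2


def lea_catcheside_factor(a_plus_c: float, duration):
    """Dose-protraction factor F in (0, 1]:
    ``F = 2[(a+c)T + exp(-(a+c)T) - 1] / ((a+c)T)^2``, with the acute
    limit F = 1 at T = 0.  Accepts array durations."""
    if a_plus_c <= 0:
        raise ValueError(f"a_plus_c must be positive, got {a_plus_c}")
    duration = np.asarray(duration, dtype=float)
    if np.any(duration < 0):
        raise ValueError("duration must be non-negative")
    out = _lea_catcheside(a_plus_c, duration)
    return float(out) if out.ndim == 0 else out


def pharmacological_survival(concentration, p: PharmacologyParams):
    """Drug-only surviving fraction S_P at the given concentration (uM)."""
    concentration = np.asarray(concentration, dtype=float)
    if np.any(concentration < 0):
        raise ValueError("concentration must be non-negative")
    out = _log_logistic_down(concentration, p.s_p_min, p.s_p_max, p.ed50, p.r_p)
    return float(out) if out.ndim == 0 else out


def delta_of_concentration(concentration, nt: NonTargetedParams, ed50: float):
    """Bystander lesion ceiling delta (lesions/nucleus) at the given drug
    concentration; delta_min at 0 uM, rising to delta_max."""
    concentration = np.asarray(concentration, dtype=float)
    if np.any(concentration < 0):
        raise ValueError("concentration must be non-negative")
    out = _delta(concentration, nt.delta_min, nt.delta_max, ed50, nt.r_delta)
    return float(out) if out.ndim == 0 else out


def targeted_log_survival(exposure: Exposure, t: TargetedParams, gamma: float) -> float:
    """Expected lethal lesions from DNA-targeted damage, -ln S_T >= 0."""
    return float(
        _targeted_lesions(
            exposure.dose, exposure.duration, t.alpha0, t.beta0, t.a_plus_c, gamma
        )
    )


def nontargeted_log_survival(dose: float, delta: float, nt: NonTargetedParams, gamma: float) -> float:
    """Expected lethal lesions from non-targeted signalling, -ln S_NT.

    Bounded above by delta/4, attained where the no-activation
    probability p(D) equals 1/2."""
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    return float(_nontargeted_lesions(dose, delta, nt.alpha_b, nt.beta_b, gamma))


def log_combined_survival(exposure: Exposure, params: ModelParameters) -> float:
    """ln S for a single exposure; the factorization
    ln S = ln S_P - (-ln S_T) - (-ln S_NT) is exact."""
    delta = delta_of_concentration(
        exposure.concentration, params.non_targeted, params.ed50
    )
    return (
        float(np.log(pharmacological_survival(exposure.concentration, params.pharmacology)))
        - targeted_log_survival(exposure, params.targeted, params.gamma)
        - nontargeted_log_survival(exposure.dose, delta, params.non_targeted, params.gamma)
    )


def combined_survival(exposure: Exposure, params: ModelParameters) -> float:
    """Overall surviving fraction S = S_P x S_T x S_NT, in (0, 1]."""
    return float(np.exp(log_combined_survival(exposure, params)))


def survival_components(exposure: Exposure, params: ModelParameters) -> dict[str, float]:
    """The three survival factors and their product for one exposure."""
    s_p = pharmacological_survival(exposure.concentration, params.pharmacology)
    te = targeted_log_survival(exposure, params.targeted, params.gamma)
    delta = delta_of_concentration(exposure.concentration, params.non_targeted, params.ed50)
    nte = nontargeted_log_survival(exposure.dose, delta, params.non_targeted, params.gamma)
    return {
        "s_p": float(s_p),
        "s_t": float(np.exp(-te)),
        "s_nt": float(np.exp(-nte)),
        "survival": float(s_p * np.exp(-te - nte)),
    }


def predict_table(
    params: ModelParameters,
    doses,
    concentrations,
    dose_rate: float = 60.0,
    acute: bool = False,
) -> pd.DataFrame:
    """Survival predictions on the grid doses x concentrations.

    Returns a DataFrame with columns ``dose_gy, concentration_um, s_p,
    s_t, s_nt, survival`` (the writer dialect of the prediction CSV).
    """
    rows = []
    for c in np.atleast_1d(np.asarray(concentrations, dtype=float)):
        for d in np.atleast_1d(np.asarray(doses, dtype=float)):
            exp_ = Exposure(dose=float(d), dose_rate=dose_rate, concentration=float(c), acute=acute)
            comp = survival_components(exp_, params)
            rows.append({"dose_gy": float(d), "concentration_um": float(c), **comp})
    return pd.DataFrame(rows)
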