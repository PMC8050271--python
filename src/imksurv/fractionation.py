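"""Fractionated regimens: course survival and isoeffect total doses.

Lethal lesions accumulate linearly over identical daily fractions (24 h
apart, complete sublethal-damage repair in between, no proliferation):
the course log-kill is ``n`` times the single-fraction value of
``-ln(S_T S_NT)`` at dose-per-fraction ``d``.  Drug survival ``S_P`` is a
growth-arrest effect of the continuous drug exposure and is applied once
per course, not per fraction.

Because the course log-survival is exactly linear in the fraction number
``n``, the isoeffect fraction count for a target survival level has a
closed form; the solver uses it directly (no iteration needed) and the
returned dose satisfies the inverse relation to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .exceptions import UnreachableTargetError
from .model import (
    delta_of_concentration,
    nontargeted_log_survival,
    pharmacological_survival,
    targeted_log_survival,
)
from .params import Exposure, ModelParameters

__all__ = [
    "FractionationScheme",
    "IsoeffectQuery",
    "IsoeffectResult",
    "per_fraction_log_survival",
    "course_log_survival",
    "course_survival",
    "isoeffect_total_dose",
    "regimen_curve",
]


class FractionationScheme(BaseModel):
    """A course of ``n_fractions`` identical fractions of
    ``dose_per_fraction`` Gy, ``interval`` hours apart, delivered at
    ``dose_rate`` Gy/h under a constant drug ``concentration`` (uM).
    ``n_fractions`` may be non-integer (isoeffect solving).  ``acute=True``
    evaluates each fraction in the zero-duration limit (F = 1)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    dose_per_fraction: float
    n_fractions: float
    interval: float = 24.0
    concentration: float = 0.0
    dose_rate: float = 60.0
    acute: bool = False

    @model_validator(mode="after")
    def _check(self) -> "FractionationScheme":
        if self.dose_per_fraction <= 0:
            raise ValueError(f"dose_per_fraction must be positive, got {self.dose_per_fraction}")
        if self.n_fractions < 0:
            raise ValueError(f"n_fractions must be non-negative, got {self.n_fractions}")
        if self.interval <= 0:
            raise ValueError(f"interval must be positive, got {self.interval}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be non-negative, got {self.concentration}")
        if self.dose_rate <= 0:
            raise ValueError(f"dose_rate must be positive, got {self.dose_rate}")
        return self


class IsoeffectQuery(BaseModel):
    """Target survival level to reach with a given dose per fraction and
    drug concentration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    target_survival: float
    dose_per_fraction: float
    concentration: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "IsoeffectQuery":
        if not (0.0 < self.target_survival < 1.0):
            raise ValueError(
                f"target_survival must be in (0, 1), got {self.target_survival}"
            )
        if self.dose_per_fraction <= 0:
            raise ValueError(f"dose_per_fraction must be positive, got {self.dose_per_fraction}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be non-negative, got {self.concentration}")
        return self


@dataclass(frozen=True)
class IsoeffectResult:
    """Isoeffect solution: real-valued fraction count and its total dose,
    plus the next-integer course."""

    total_dose: float
    n_fractions: float
    n_fractions_ceil: int
    total_dose_ceil: float
    dose_per_fraction: float
    concentration: float
    per_fraction_lesions: float
    drug_survival: float


def per_fraction_log_survival(
    dose_per_fraction: float,
    concentration: float,
    params: ModelParameters,
    dose_rate: float = 60.0,
    acute: bool = False,
) -> float:
    """Lethal lesions per fraction, -ln(S_T * S_NT) at dose d; the delta
    ceiling is held at its value for the course concentration."""
    exposure = Exposure(
        dose=dose_per_fraction,
        dose_rate=dose_rate,
        concentration=concentration,
        acute=acute,
    )
    te = targeted_log_survival(exposure, params.targeted, params.gamma)
    delta = delta_of_concentration(concentration, params.non_targeted, params.ed50)
    nte = nontargeted_log_survival(dose_per_fraction, delta, params.non_targeted, params.gamma)
    return te + nte


def course_log_survival(scheme: FractionationScheme, params: ModelParameters) -> float:
    """Total lethal lesions over the course, n x per-fraction value
    (identical fractions, no inter-fraction carry-over, no proliferation)."""
    lam = per_fraction_log_survival(
        scheme.dose_per_fraction,
        scheme.concentration,
        params,
        dose_rate=scheme.dose_rate,
        acute=scheme.acute,
    )
    return scheme.n_fractions * lam


def course_survival(scheme: FractionationScheme, params: ModelParameters) -> float:
    """Overall course survival S_P(c) x exp(-course lesions); the drug
    factor enters once per course."""
    s_p = pharmacological_survival(scheme.concentration, params.pharmacology)
    return float(np.exp(math.log(s_p) - course_log_survival(scheme, params)))


def isoeffect_total_dose(
    query: IsoeffectQuery,
    params: ModelParameters,
    dose_rate: float = 60.0,
    acute: bool = False,
) -> IsoeffectResult:
    """Total dose (Gy) at the queried dose per fraction that reaches the
    target survival level.

    Raises :class:`UnreachableTargetError` when the target is at or above
    the drug-only survival (no radiation needed / target unreachable by
    this query), and :class:`~imksurv.exceptions.ConvergenceError` never:
    linearity of the course log-kill in n makes the solve closed-form.
    """
    s_p = pharmacological_survival(query.concentration, params.pharmacology)
    if query.target_survival >= s_p:
        raise UnreachableTargetError(
            f"target survival {query.target_survival} is not below the drug-only "
            f"survival {s_p:.6g} at {query.concentration} uM; no positive dose is required"
        )
    lam = per_fraction_log_survival(
        query.dose_per_fraction, query.concentration, params, dose_rate=dose_rate, acute=acute
    )
    if lam <= 0:
        raise UnreachableTargetError(
            "per-fraction lethal-lesion yield is zero; the target cannot be reached by adding fractions"
        )
    n_star = (math.log(s_p) - math.log(query.target_survival)) / lam
    n_ceil = math.ceil(n_star - 1e-12)
    return IsoeffectResult(
        total_dose=n_star * query.dose_per_fraction,
        n_fractions=n_star,
        n_fractions_ceil=n_ceil,
        total_dose_ceil=n_ceil * query.dose_per_fraction,
        dose_per_fraction=query.dose_per_fraction,
        concentration=query.concentration,
        per_fraction_lesions=lam,
        drug_survival=s_p,
    )


def regimen_curve(
    dose_per_fraction: float,
    max_fractions: int,
    concentrations,
    params: ModelParameters,
    dose_rate: float = 60.0,
    acute: bool = False,
) -> pd.DataFrame:
    """Course survival versus total dose for n = 0..max_fractions at each
    concentration (one sigmoid-free decay curve per drug level)."""
    rows = []
    for c in np.atleast_1d(np.asarray(concentrations, dtype=float)):
        for n in range(int(max_fractions) + 1):
            scheme = FractionationScheme(
                dose_per_fraction=dose_per_fraction,
                n_fractions=float(n),
                concentration=float(c),
                dose_rate=dose_rate,
                acute=acute,
            )
            rows.append(
                {
                    "concentration_um": float(c),
                    "n_fractions": n,
                    "total_dose_gy": n * dose_per_fraction,
                    "survival": course_survival(scheme, params),
                }
            )
    return pd.DataFrame(rows)
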