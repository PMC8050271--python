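"""Parameter containers for the integrated cell-survival model.

The model multiplies three independent survival factors:

* ``S_P`` — pharmacological survival under the radiosensitizing drug
  (four-parameter log-logistic in concentration);
* ``S_T`` — survival against DNA-targeted radiation damage
  (microdosimetric-kinetic linear-quadratic form with a dose-protraction
  correction);
* ``S_NT`` — survival against non-targeted (intercellular-signalling /
  bystander) damage, whose ceiling ``delta`` rises with drug concentration
  through a log-logistic sharing its midpoint ``ed50`` with the
  pharmacology term.

All containers are immutable pydantic models so that invariants are checked
once, at construction.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "PharmacologyParams",
    "MicrodosimetryParams",
    "TargetedParams",
    "NonTargetedParams",
    "ModelParameters",
    "Exposure",
]

#: conversion from keV/um lineal energy to Gy specific energy for a
#: unit-density 1-um sphere: z = 4 y / (rho pi d^2) with unit bookkeeping.
SPECIFIC_ENERGY_COEF = 4.0 * 1.602176634e-1 / math.pi  # ~0.20397


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class PharmacologyParams(_Frozen):
    """Log-logistic drug-only survival: minimum, maximum, midpoint, hillslope."""

    s_p_min: float
    s_p_max: float = 1.0
    ed50: float
    r_p: float

    @model_validator(mode="after")
    def _check(self) -> "PharmacologyParams":
        if not (0.0 <= self.s_p_min < self.s_p_max <= 1.0):
            raise ValueError(
                f"require 0 <= s_p_min < s_p_max <= 1, got {self.s_p_min}, {self.s_p_max}"
            )
        if self.ed50 <= 0:
            raise ValueError(f"ed50 must be positive, got {self.ed50}")
        if self.r_p <= 0:
            raise ValueError(f"r_p must be positive, got {self.r_p}")
        return self


class MicrodosimetryParams(_Frozen):
    """Radiation-quality inputs: dose-mean lineal energy and the derived
    mean specific energy per event ``gamma`` for the sensitive domain.

    ``gamma`` defaults to the spherical-domain conversion but may be
    overridden with a tabulated value.
    """

    y_d: float
    domain_diameter: float = 1.0
    gamma: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "MicrodosimetryParams":
        if self.y_d <= 0:
            raise ValueError(f"y_d must be positive, got {self.y_d}")
        if self.domain_diameter <= 0:
            raise ValueError(f"domain_diameter must be positive, got {self.domain_diameter}")
        if self.gamma is None:
            object.__setattr__(
                self,
                "gamma",
                SPECIFIC_ENERGY_COEF * self.y_d / self.domain_diameter**2,
            )
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        return self


class TargetedParams(_Frozen):
    """Linear-quadratic coefficients for DNA-targeted kill plus the
    first-order sublethal-damage repair rate (per hour)."""

    alpha0: float
    beta0: float
    a_plus_c: float

    @model_validator(mode="after")
    def _check(self) -> "TargetedParams":
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be non-negative, got {self.alpha0}")
        if self.beta0 < 0:
            raise ValueError(f"beta0 must be non-negative, got {self.beta0}")
        if self.a_plus_c <= 0:
            raise ValueError(f"a_plus_c must be positive, got {self.a_plus_c}")
        return self


class NonTargetedParams(_Frozen):
    """Bystander-signal activation coefficients and the lesion ceiling
    ``delta`` expressed as a log-logistic range in drug concentration."""

    alpha_b: float
    beta_b: float
    delta_min: float
    delta_max: float
    r_delta: float

    @model_validator(mode="after")
    def _check(self) -> "NonTargetedParams":
        if self.alpha_b < 0:
            raise ValueError(f"alpha_b must be non-negative, got {self.alpha_b}")
        if self.beta_b < 0:
            raise ValueError(f"beta_b must be non-negative, got {self.beta_b}")
        if not (0.0 <= self.delta_min <= self.delta_max):
            raise ValueError(
                f"require 0 <= delta_min <= delta_max, got {self.delta_min}, {self.delta_max}"
            )
        if self.r_delta <= 0:
            raise ValueError(f"r_delta must be positive, got {self.r_delta}")
        return self


class ModelParameters(_Frozen):
    """The full parameter set.  The pharmacology midpoint ``ed50`` is shared
    with the ``delta``-vs-concentration curve by construction: the
    non-targeted sigmoid always reads it from ``pharmacology.ed50``."""

    pharmacology: PharmacologyParams
    microdosimetry: MicrodosimetryParams
    targeted: TargetedParams
    non_targeted: NonTargetedParams

    @property
    def gamma(self) -> float:
        return self.microdosimetry.gamma

    @property
    def ed50(self) -> float:
        return self.pharmacology.ed50


class Exposure(_Frozen):
    """A single irradiation event at a fixed drug concentration.

    ``duration`` is hours of beam-on time; when omitted it is derived as
    ``dose / dose_rate``.  ``acute=True`` forces the zero-duration limit
    (protraction factor F = 1) regardless of dose rate.
    """

    dose: float
    dose_rate: float = 60.0  # Gy/h, i.e. 1 Gy/min
    duration: float | None = None
    concentration: float = 0.0
    acute: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Exposure":
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose}")
        if self.dose_rate <= 0:
            raise ValueError(f"dose_rate must be positive, got {self.dose_rate}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be non-negative, got {self.concentration}")
        if self.acute:
            object.__setattr__(self, "duration", 0.0)
        elif self.duration is None:
            object.__setattr__(self, "duration", self.dose / self.dose_rate)
        else:
            if self.duration < 0:
                raise ValueError(f"duration must be non-negative, got {self.duration}")
            if not math.isclose(
                self.dose, self.dose_rate * self.duration, rel_tol=1e-6, abs_tol=1e-9
            ):
                raise ValueError(
                    "dose, dose_rate and duration are inconsistent: "
                    f"{self.dose} Gy != {self.dose_rate} Gy/h x {self.duration} h"
                )
        return self
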