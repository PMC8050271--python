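"""Synthetic clonogenic-survival datasets.

The generator reproduces the three-part experimental design the model is
fitted to — a drug-only concentration curve, radiation dose-response
curves at three drug levels, and a fixed-dose concentration series — and
perturbs model-predicted surviving fractions with multiplicative
lognormal noise, the natural error structure for a ratio statistic
spanning decades.

The packaged design yields exactly 37 observations.  The published study
states only that total and the identities of the three sub-experiments,
not the per-part point counts; the partition used here (12 + 12 + 13,
single replicates) is a reconstruction and is flagged as such in
:func:`published_design`.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .fitting import SurvivalObservation
from .model import combined_survival
from .params import Exposure, ModelParameters

__all__ = [
    "ExperimentalDesign",
    "NoiseModel",
    "generate_survival_dataset",
    "published_design",
]


class ExperimentalDesign(BaseModel):
    """Three-part clonogenic design.

    * ``concentration_curve``: drug levels (uM) assayed with no radiation;
    * ``dose_response_doses`` x ``dose_response_concentrations``: full
      radiation dose-response grid;
    * ``constant_dose`` Gy x ``constant_dose_concentrations``: fixed-dose
      drug series.

    ``replicates`` repeats every condition; ``dose_rate`` (Gy/h) applies
    to all irradiations.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    concentration_curve: tuple[float, ...]
    dose_response_doses: tuple[float, ...]
    dose_response_concentrations: tuple[float, ...]
    constant_dose: float
    constant_dose_concentrations: tuple[float, ...]
    replicates: int = 1
    dose_rate: float = 60.0

    @model_validator(mode="after")
    def _check(self) -> "ExperimentalDesign":
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dose_rate <= 0:
            raise ValueError("dose_rate must be positive")
        if self.constant_dose < 0:
            raise ValueError("constant_dose must be non-negative")
        return self

    def conditions(self) -> list[tuple[float, float]]:
        """Ordered (dose Gy, concentration uM) pairs, replicates expanded."""
        base: list[tuple[float, float]] = []
        base += [(0.0, c) for c in self.concentration_curve]
        base += [
            (d, c)
            for c in self.dose_response_concentrations
            for d in self.dose_response_doses
        ]
        base += [(self.constant_dose, c) for c in self.constant_dose_concentrations]
        return [cond for cond in base for _ in range(self.replicates)]

    @property
    def n_observations(self) -> int:
        return len(self.conditions())


class NoiseModel(BaseModel):
    """Multiplicative lognormal noise on the surviving fraction with the
    given coefficient of variation; mean-corrected so the expected noisy
    SF equals the model SF."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: str = "lognormal"
    cv: float = 0.1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "NoiseModel":
        if self.kind != "lognormal":
            raise ValueError(f"unsupported noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        return self


def published_design() -> ExperimentalDesign:
    """The 37-observation design behind the published fit.

    The source reports only the three sub-experiments — (i) survival vs
    drug concentration over 0-500 uM, (ii) dose response at 0/2/4/10 Gy
    for 0/80/100 uM, (iii) survival at 4 Gy across 20-200 uM — and the
    37-point total.  The per-part concentration grids here are a
    SYNTHETIC reconstruction (12 + 12 + 13 single-replicate conditions)
    chosen to span the stated ranges; only the 37-row total and the
    stated dose/concentration anchors are constrained by the source.
    """
    return ExperimentalDesign(
        concentration_curve=(0, 10, 20, 50, 80, 90, 100, 120, 150, 200, 300, 500),
        dose_response_doses=(0, 2, 4, 10),
        dose_response_concentrations=(0, 80, 100),
        constant_dose=4.0,
        constant_dose_concentrations=(
            10, 20, 40, 60, 80, 90, 100, 120, 150, 200, 300, 400, 500,
        ),
        replicates=1,
        dose_rate=60.0,
    )


def generate_survival_dataset(
    true_params: ModelParameters,
    design: ExperimentalDesign,
    noise: NoiseModel,
) -> list[SurvivalObservation]:
    """Simulate one clonogenic dataset from the model.

    Each condition gets an independent RNG sub-stream keyed by
    (seed, condition index), so datasets are reproducible and conditions
    stay independent under design edits that preserve ordering prefixes.
    With ``cv = 0`` the model predictions pass through exactly.  Noisy
    values are clipped into (0, 1]; reported ``std_error`` is cv x SF.
    """
    sigma = float(np.sqrt(np.log1p(noise.cv**2)))
    out: list[SurvivalObservation] = []
    for i, (dose, conc) in enumerate(design.conditions()):
        exposure = Exposure(dose=dose, dose_rate=design.dose_rate, concentration=conc)
        sf = combined_survival(exposure, true_params)
        if noise.cv > 0:
            rng = np.random.default_rng([noise.seed, i])
            sf = sf * float(np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))
        sf = float(min(max(sf, 1e-12), 1.0))
        out.append(
            SurvivalObservation(
                dose=dose,
                dose_rate=design.dose_rate,
                concentration=conc,
                surviving_fraction=sf,
                std_error=noise.cv * sf if noise.cv > 0 else None,
                n_replicates=design.replicates,
            )
        )
    return out
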