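"""Readers and writers: survival tables (CSV) and parameter files (YAML/JSON).

Survival CSV dialect (no domain standard exists for clonogenic tables):

====================  =========================================
column                meaning
====================  =========================================
dose_gy               absorbed dose, Gy (required)
conc_um               drug concentration, uM (required)
sf                    surviving fraction in (0, 1] (required)
dose_rate_gy_per_min  delivery dose rate, Gy/min (optional; default 1.0)
sf_se                 standard error of sf (optional)
n_rep                 replicate count (optional)
====================  =========================================

Parameter files are flat YAML/JSON mappings with the field names of the
parameter containers; an optional ``std_errors`` mapping is ignored on
read into :class:`~imksurv.params.ModelParameters`.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigError, DataValidationError
from .fitting import SurvivalObservation
from .model import flatten_params
from .params import (
    MicrodosimetryParams,
    ModelParameters,
    NonTargetedParams,
    PharmacologyParams,
    TargetedParams,
)

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "read_params",
    "write_params",
    "ht1080_table1",
    "ht1080_table1_std_errors",
]

_REQUIRED_COLS = ("dose_gy", "conc_um", "sf")
_PARAM_FIELDS = (
    "s_p_min", "s_p_max", "ed50", "r_p",
    "y_d", "gamma",
    "alpha0", "beta0", "a_plus_c",
    "alpha_b", "beta_b", "delta_min", "delta_max", "r_delta",
)


def read_survival_csv(path: str | Path) -> list[SurvivalObservation]:
    """Load and validate a survival table; error messages name the
    offending CSV row (1-based, excluding the header).  The optional
    dose-rate column is given in Gy/min and converted to Gy/h."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required column(s) {missing}")
    out: list[SurvivalObservation] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        try:
            rate_min = row.get("dose_rate_gy_per_min")
            rate = 60.0 * float(rate_min) if pd.notna(rate_min) else 60.0
            se = row.get("sf_se")
            nrep = row.get("n_rep")
            out.append(
                SurvivalObservation(
                    dose=float(row["dose_gy"]),
                    dose_rate=rate,
                    concentration=float(row["conc_um"]),
                    surviving_fraction=float(row["sf"]),
                    std_error=float(se) if pd.notna(se) else None,
                    n_replicates=int(nrep) if pd.notna(nrep) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise DataValidationError(f"{path}: row {rowno}: {exc}") from exc
    return out


def write_survival_csv(observations: list[SurvivalObservation], path: str | Path) -> None:
    """Write observations in the CSV dialect read_survival_csv expects."""
    rows = [
        {
            "dose_gy": o.dose,
            "dose_rate_gy_per_min": o.dose_rate / 60.0,
            "conc_um": o.concentration,
            "sf": o.surviving_fraction,
            "sf_se": o.std_error,
            "n_rep": o.n_replicates,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _params_from_mapping(raw: dict, source: str) -> ModelParameters:
    missing = [f for f in _PARAM_FIELDS if f not in raw and f not in ("gamma", "s_p_max")]
    if missing:
        raise ConfigError(f"{source}: missing parameter field(s) {missing}")
    try:
        return ModelParameters(
            pharmacology=PharmacologyParams(
                s_p_min=raw["s_p_min"],
                s_p_max=raw.get("s_p_max", 1.0),
                ed50=raw["ed50"],
                r_p=raw["r_p"],
            ),
            microdosimetry=MicrodosimetryParams(
                y_d=raw["y_d"],
                domain_diameter=raw.get("domain_diameter", 1.0),
                gamma=raw.get("gamma"),
            ),
            targeted=TargetedParams(
                alpha0=raw["alpha0"], beta0=raw["beta0"], a_plus_c=raw["a_plus_c"]
            ),
            non_targeted=NonTargetedParams(
                alpha_b=raw["alpha_b"],
                beta_b=raw["beta_b"],
                delta_min=raw["delta_min"],
                delta_max=raw["delta_max"],
                r_delta=raw["r_delta"],
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def read_params(path: str | Path) -> ModelParameters:
    """Read a YAML (default) or JSON parameter file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of parameter fields")
    return _params_from_mapping(raw, str(path))


def write_params(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter file (format chosen by extension); lossless
    round-trip with :func:`read_params`."""
    path = Path(path)
    flat = flatten_params(params)
    flat["y_d"] = params.microdosimetry.y_d
    flat["domain_diameter"] = params.microdosimetry.domain_diameter
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(flat, indent=2))
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=False))


def _fixture_raw() -> dict:
    with resources.files("imksurv.data").joinpath("ht1080_table1.yaml").open() as fh:
        return yaml.safe_load(fh)


def ht1080_table1() -> ModelParameters:
    """The packaged HT1080 parameter set (published fitted means; the
    tabulated microdosimetric gamma is used verbatim for reproducibility)."""
    return _params_from_mapping(_fixture_raw(), "ht1080_table1")


def ht1080_table1_std_errors() -> dict[str, float]:
    """Published fitting errors (s.d.) accompanying the HT1080 means."""
    return dict(_fixture_raw()["std_errors"])
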