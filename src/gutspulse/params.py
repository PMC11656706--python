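"""Parameter containers, variant registry and parameter-sharing maps.

Four GUTS stochastic-death variants are supported.  The full model,
``guts_rna_pulse``, couples uptake, a threshold-activated *nrf2*
transcription pulse, a protein proxy driving metabolization, and a hazard
on the *nrf2* fold-change.  The three comparison variants are standard
one-compartment GUTS-SD reconstructions fitted to progressively smaller
endpoint sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "RnaPulseParams",
    "ErrorParams",
    "ScalingContext",
    "ModelState",
    "VariantSpec",
    "VARIANTS",
    "VARIANT_IDS",
    "get_variant",
    "make_sharing_map",
    "validate_sharing_map",
    "params_to_yaml",
    "params_from_yaml",
]

#: canonical endpoint identifiers used across the package
ENDPOINTS = ("cint", "nrf2", "survival")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class RnaPulseParams(_StrictModel):
    """Natural-scale parameters of the GUTS-RNA-pulse model.

    Units follow the model convention: rate constants in 1/h, thresholds on
    the scale of the state they gate (``z_ci`` on the scaled internal
    concentration, ``z`` on *nrf2* fold-change), ``k_k`` in 1/(fold-change h).
    """

    k_i: float
    k_m: float
    z_ci: float
    v_rt: float
    r_rt: float
    k_rd: float
    k_p: float
    z: float
    k_k: float
    h_b: float

    @model_validator(mode="after")
    def _check_signs(self) -> "RnaPulseParams":
        for name in ("k_i", "k_m", "v_rt", "r_rt", "k_rd", "k_p"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("z_ci", "z", "k_k", "h_b"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        return self

    def to_dict(self) -> Dict[str, float]:
        return {k: float(v) for k, v in self.model_dump().items()}


class ErrorParams(_StrictModel):
    """Log-scale standard deviations of the log-normal observation errors."""

    sigma_cint: float
    sigma_nrf2: float

    @model_validator(mode="after")
    def _check(self) -> "ErrorParams":
        for name in ("sigma_cint", "sigma_nrf2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        return self

    def to_dict(self) -> Dict[str, float]:
        return {k: float(v) for k, v in self.model_dump().items()}


class ScalingContext(_StrictModel):
    """Fixed scaling constants of the model.

    ``C_i_max`` is the maximum internal concentration over all experiments,
    used to scale the activation input; ``R_0`` the baseline RNA fold-change
    (1 by convention, which makes the modeled R identical to measured
    fold-change).
    """

    C_i_max: float
    R_0: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "ScalingContext":
        if not (math.isfinite(self.C_i_max) and self.C_i_max > 0):
            raise ValueError(f"C_i_max must be finite and > 0, got {self.C_i_max!r}")
        if not (math.isfinite(self.R_0) and self.R_0 > 0):
            raise ValueError(f"R_0 must be finite and > 0, got {self.R_0!r}")
        return self


@dataclass
class ModelState:
    """State of the GUTS-RNA-pulse ODE system at one instant."""

    C_i: float
    R: float
    P_star: float
    H: float

    def as_array(self):
        import numpy as np

        return np.array([self.C_i, self.R, self.P_star, self.H], dtype=float)


@dataclass(frozen=True)
class VariantSpec:
    """Registry entry for one GUTS variant."""

    name: str
    parameters: tuple
    error_parameters: tuple
    endpoints: tuple
    #: state-vector layout; hazard integral H is always the last state
    states: tuple
    #: index of the state observed by each endpoint ("survival" maps to H)
    endpoint_state: Mapping[str, int]
    #: parameters that are substance-specific under the default sharing map
    default_specific: frozenset


VARIANTS: Dict[str, VariantSpec] = {
    "guts_reduced": VariantSpec(
        name="guts_reduced",
        parameters=("k_d", "z", "k_k", "h_b"),
        error_parameters=(),
        endpoints=("survival",),
        states=("D", "H"),
        endpoint_state={"survival": 1},
        default_specific=frozenset({"k_d"}),
    ),
    "guts_scaled_damage": VariantSpec(
        name="guts_scaled_damage",
        parameters=("k_i", "k_e", "k_d", "z", "k_k", "h_b"),
        error_parameters=("sigma_cint",),
        endpoints=("cint", "survival"),
        states=("C_i", "D", "H"),
        endpoint_state={"cint": 0, "survival": 2},
        default_specific=frozenset({"k_i", "k_e", "k_d"}),
    ),
    "guts_rna": VariantSpec(
        name="guts_rna",
        parameters=("k_i", "k_e", "k_a", "k_r", "z", "k_k", "h_b"),
        error_parameters=("sigma_cint", "sigma_nrf2"),
        endpoints=("cint", "nrf2", "survival"),
        states=("C_i", "D", "H"),
        endpoint_state={"cint": 0, "nrf2": 1, "survival": 2},
        default_specific=frozenset({"k_i", "k_e", "k_a"}),
    ),
    "guts_rna_pulse": VariantSpec(
        name="guts_rna_pulse",
        parameters=(
            "k_i", "k_m", "z_ci", "v_rt", "r_rt", "k_rd", "k_p", "z", "k_k", "h_b",
        ),
        error_parameters=("sigma_cint", "sigma_nrf2"),
        endpoints=("cint", "nrf2", "survival"),
        states=("C_i", "R", "P_star", "H"),
        endpoint_state={"cint": 0, "nrf2": 1, "survival": 3},
        # uptake, metabolization and the activation threshold stay
        # substance-specific; the RNA-protein and death dynamics are shared
        default_specific=frozenset({"k_i", "k_m", "z_ci"}),
    ),
}

VARIANT_IDS = tuple(VARIANTS)


def get_variant(variant: str) -> VariantSpec:
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        ) from None


def make_sharing_map(variant: str, mode: str = "independent") -> Dict[str, str]:
    """Build a sharing map for ``variant``.

    ``mode="specific"`` marks every deterministic parameter substance-specific
    (the substance-specific model); ``mode="independent"`` applies the default
    sharing set of the variant (the parameter-sharing, substance-independent
    model).  Error sigmas are always shared and are not part of the map.
    """
    spec = get_variant(variant)
    if mode == "specific":
        return {p: "specific" for p in spec.parameters}
    if mode in ("independent", "shared", "default"):
        return {
            p: ("specific" if p in spec.default_specific else "shared")
            for p in spec.parameters
        }
    raise ValueError(f"unknown sharing mode {mode!r}")


def validate_sharing_map(variant: str, sharing: Mapping[str, str]) -> None:
    spec = get_variant(variant)
    missing = set(spec.parameters) - set(sharing)
    extra = set(sharing) - set(spec.parameters)
    if missing:
        raise ValueError(f"sharing map missing registry entries: {sorted(missing)}")
    if extra:
        raise ValueError(f"sharing map has unknown entries: {sorted(extra)}")
    bad = {k: v for k, v in sharing.items() if v not in ("shared", "specific")}
    if bad:
        raise ValueError(f"sharing flags must be 'shared'/'specific', got {bad}")


def params_to_yaml(
    params_by_substance: Mapping[str, Mapping[str, float]],
    error_params: ErrorParams | Mapping[str, float] | None = None,
    path=None,
) -> str:
    """Serialize parameter blocks to YAML; returns the document text."""
    doc: Dict[str, object] = {
        "parameters": {
            sub: {k: float(v) for k, v in block.items()}
            for sub, block in params_by_substance.items()
        }
    }
    if error_params is not None:
        if isinstance(error_params, ErrorParams):
            error_params = error_params.to_dict()
        doc["error"] = {k: float(v) for k, v in error_params.items()}
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def params_from_yaml(source) -> tuple:
    """Inverse of :func:`params_to_yaml`; ``source`` is a path or YAML text."""
    try:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, TypeError):
        doc = yaml.safe_load(source)
    params = {sub: dict(block) for sub, block in doc["parameters"].items()}
    err = doc.get("error")
    error_params = ErrorParams(**err) if err else None
    return params, error_params


def free_parameter_labels(
    variant: str,
    substances: Iterable[str],
    sharing: Mapping[str, str],
    include_error: bool = True,
) -> list:
    """Ordered labels of the free parameters of a (possibly multi-substance) fit.

    Substance-specific parameters are labelled ``name[substance]``; shared and
    error parameters keep their bare name.
    """
    validate_sharing_map(variant, sharing)
    spec = get_variant(variant)
    substances = list(substances)
    labels = []
    for name in spec.parameters:
        if sharing[name] == "specific":
            labels.extend(f"{name}[{sub}]" for sub in substances)
        else:
            labels.append(name)
    if include_error:
        labels.extend(spec.error_parameters)
    return labels
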