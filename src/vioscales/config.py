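"""Generator configuration: the statistical conditions of a simulated cohort.

The packaged default configuration (``data/default_config.yaml``) encodes a
study-scale cohort: five latent violence-situation profiles with fixed mixing
weights, profile-conditional Bernoulli feature frequencies, log-normal age
and consultation-delay distributions, latent 0-6 scale means, additive rater
effects, and a linear scale-to-TIW outcome model.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .cohort import SCALE_COLUMNS, SCALE_MAX, SCALE_MIN, SYMPTOM_CONCEPTS

__all__ = ["ConfigurationError", "GeneratorConfig", "default_config", "load_config"]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class LogNormalParams:
    """Log-normal location/scale, specified by median and quartiles."""

    median: float
    q1: float
    q3: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return (math.log(self.q3) - math.log(self.q1)) / (2.0 * _Z75)


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int
    profiles: list[str]
    profile_mixing: np.ndarray
    feature_probs: dict[str, dict[str, float]]
    symptom_probs: dict[str, dict[str, float]]
    age_params: dict[str, LogNormalParams]
    delay_params: dict[str, LogNormalParams]
    scale_means: dict[str, dict[str, float]]
    n_physicians: int = 10
    caseload_weights: np.ndarray | None = None
    rater_bias_sd: float = 0.3
    rater_noise_sd: float = 0.9
    patient_noise_sd: float = 1.3
    tiw_intercept: float = 0.5
    tiw_noise_sd: float = 1.5
    tiw_coefs: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.1931
    typo_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.profile_mixing = np.asarray(self.profile_mixing, dtype=float)
        if self.caseload_weights is None:
            self.caseload_weights = np.full(self.n_physicians, 1.0 / self.n_physicians)
        else:
            self.caseload_weights = np.asarray(self.caseload_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if len(self.profile_mixing) != len(self.profiles):
            raise ConfigurationError("profile_mixing length must match profiles")
        _check_prob_vector(self.profile_mixing, "profile_mixing")
        if len(self.caseload_weights) != self.n_physicians:
            raise ConfigurationError("caseload_weights length must match n_physicians")
        _check_prob_vector(self.caseload_weights, "caseload_weights")
        for name, sd in [
            ("rater_bias_sd", self.rater_bias_sd),
            ("rater_noise_sd", self.rater_noise_sd),
            ("patient_noise_sd", self.patient_noise_sd),
            ("tiw_noise_sd", self.tiw_noise_sd),
        ]:
            if sd < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {sd}")
        for rate_name in ("missing_rate", "typo_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rate_name} must lie in [0, 1], got {rate}")
        for profile in self.profiles:
            for table_name, table in [
                ("feature_probs", self.feature_probs),
                ("symptom_probs", self.symptom_probs),
            ]:
                if profile not in table:
                    raise ConfigurationError(f"{table_name} missing profile {profile!r}")
                for feat, p in table[profile].items():
                    if not 0.0 <= p <= 1.0:
                        raise ConfigurationError(
                            f"{table_name}[{profile}][{feat}] = {p} outside [0, 1]"
                        )
            if profile not in self.scale_means:
                raise ConfigurationError(f"scale_means missing profile {profile!r}")
            for scale in SCALE_COLUMNS:
                if scale not in self.scale_means[profile]:
                    raise ConfigurationError(f"scale_means[{profile}] missing {scale!r}")
                mean = self.scale_means[profile][scale]
                if not SCALE_MIN <= mean <= SCALE_MAX:
                    raise ConfigurationError(
                        f"scale mean {scale}={mean} outside [{SCALE_MIN}, {SCALE_MAX}]"
                    )
        for scale in self.tiw_coefs:
            if scale not in SCALE_COLUMNS:
                raise ConfigurationError(f"unknown scale in tiw_coefs: {scale!r}")
        # feature sets must agree across profiles so columns line up
        ref = set(self.feature_probs[self.profiles[0]])
        for profile in self.profiles[1:]:
            if set(self.feature_probs[profile]) != ref:
                raise ConfigurationError(f"feature set of profile {profile!r} differs")

    @property
    def binary_features(self) -> list[str]:
        return list(self.feature_probs[self.profiles[0]])

    def with_overrides(self, **kwargs: Any) -> "GeneratorConfig":
        """Return a copy with the given fields replaced (re-validated).

        Changing ``n_physicians`` without passing ``caseload_weights``
        resets the caseloads to uniform.
        """
        if "n_physicians" in kwargs and "caseload_weights" not in kwargs:
            kwargs["caseload_weights"] = None
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "GeneratorConfig":
        raw = dict(raw)
        raw.pop("description", None)
        weights = np.asarray(raw.pop("profile_weights"), dtype=float)
        if weights.sum() <= 0:
            raise ConfigurationError("profile_weights must have positive sum")
        mixing = weights / weights.sum()
        caseload = raw.pop("caseload_weights", None)
        if caseload is not None:
            caseload = np.asarray(caseload, dtype=float)
            if caseload.sum() <= 0:
                raise ConfigurationError("caseload_weights must have positive sum")
            caseload = caseload / caseload.sum()
        tiw = raw.pop("tiw_model", {})
        symptoms = raw.pop("symptom_probs")
        for profile, table in symptoms.items():
            unknown = set(table) - set(SYMPTOM_CONCEPTS)
            if unknown:
                raise ConfigurationError(f"unknown symptom concepts in {profile}: {unknown}")
        return cls(
            n_patients=int(raw.pop("n_patients")),
            profiles=list(raw.pop("profiles")),
            profile_mixing=mixing,
            feature_probs=raw.pop("feature_probs"),
            symptom_probs=symptoms,
            age_params={p: LogNormalParams(**v) for p, v in raw.pop("age_params").items()},
            delay_params={p: LogNormalParams(**v) for p, v in raw.pop("delay_params").items()},
            scale_means=raw.pop("scale_means"),
            n_physicians=int(raw.pop("n_physicians", 10)),
            caseload_weights=caseload,
            tiw_intercept=float(tiw.get("intercept", 0.0)),
            tiw_noise_sd=float(tiw.get("noise_sd", 0.0)),
            tiw_coefs=dict(tiw.get("coefs", {})),
            **raw,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_patients": self.n_patients,
            "profiles": list(self.profiles),
            "profile_weights": self.profile_mixing.tolist(),
            "n_physicians": self.n_physicians,
            "caseload_weights": self.caseload_weights.tolist(),
            "rater_bias_sd": self.rater_bias_sd,
            "rater_noise_sd": self.rater_noise_sd,
            "patient_noise_sd": self.patient_noise_sd,
            "missing_rate": self.missing_rate,
            "typo_rate": self.typo_rate,
            "seed": self.seed,
            "tiw_model": {
                "intercept": self.tiw_intercept,
                "noise_sd": self.tiw_noise_sd,
                "coefs": dict(self.tiw_coefs),
            },
            "age_params": {p: vars(v) for p, v in self.age_params.items()},
            "delay_params": {p: vars(v) for p, v in self.delay_params.items()},
            "scale_means": self.scale_means,
            "symptom_probs": self.symptom_probs,
            "feature_probs": self.feature_probs,
        }


def _check_prob_vector(vec: np.ndarray, name: str) -> None:
    if np.any(vec < 0):
        raise ConfigurationError(f"{name} has negative entries")
    if abs(float(vec.sum()) - 1.0) > 1e-12:
        raise ConfigurationError(f"{name} must sum to 1, got {vec.sum()!r}")


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return GeneratorConfig.from_dict(raw)


def default_config(**overrides: Any) -> GeneratorConfig:
    """The packaged study-scale default configuration.

    Keyword overrides replace top-level fields, e.g.
    ``default_config(n_patients=500, seed=7)``.
    """
    ref = importlib.resources.files("vioscales.data") / "default_config.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    cfg = GeneratorConfig.from_dict(raw)
    return cfg.with_overrides(**overrides) if overrides else cfg
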