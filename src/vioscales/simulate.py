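"""Synthetic cohort generation.

The generator emulates the record structure of a forensic consultation
registry for individuals exposed to violence: each patient carries a latent
violence-situation profile that drives binary circumstance features, age and
consultation delay, symptom mentions, the nine 0-6 Likert scale scores and
the TIW outcome.

Scale scores follow an additive latent-continuum model::

    score = clamp(round(mean[profile, scale]
                        + bias[physician]       # constant within physician
                        + severity[patient]     # shared across the 9 scales
                        + noise[patient, scale]), 0, 6)

so interrater disagreement has a systematic (bias) and an idiosyncratic
(noise) component that the concordance stage is designed to detect.  TIW is
``max(0, round(intercept + sum coef * score + noise))``.

All randomness flows from ``config.seed`` through a single
``numpy.random.Generator``; draws happen in a fixed documented order, so a
given configuration yields a byte-identical cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    NUMERIC_FEATURES,
    SCALE_COLUMNS,
    SCALE_MAX,
    SCALE_MIN,
    SYMPTOM_CONCEPTS,
)
from .config import ConfigurationError, GeneratorConfig
from .mining import Lexicon, normalize_text

__all__ = ["generate_cohort", "render_certificates", "apply_missingness"]

_MIN_AGE = 10.0


def _truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                         size: int, lower: float) -> np.ndarray:
    """Log-normal draws resampled until all exceed ``lower``."""
    out = rng.lognormal(mu, sigma, size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
    return np.maximum(out, lower)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full synthetic cohort from ``config``.

    Returns a :class:`~vioscales.cohort.Cohort` whose ``feature_spec``
    covers the clustering variables (binary circumstance features plus age
    and consultation delay).  Scale scores and TIW are complete; apply
    :func:`apply_missingness` afterwards to blank scale fields.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    profiles = np.asarray(config.profiles)

    # Draw order is part of the contract: profile, physician, physician bias,
    # binary features, symptoms, age, delay, patient severity, scale noise,
    # TIW noise.
    profile_idx = rng.choice(len(profiles), size=n, p=config.profile_mixing)
    physician = rng.choice(config.n_physicians, size=n, p=config.caseload_weights)
    physician_bias = rng.normal(0.0, config.rater_bias_sd, config.n_physicians)

    data: dict[str, np.ndarray] = {
        "patient_id": np.arange(n),
        "physician_id": physician,
        "true_profile": profiles[profile_idx],
    }

    for feat in config.binary_features:
        p = np.array([config.feature_probs[pr][feat] for pr in profiles])[profile_idx]
        data[feat] = (rng.random(n) < p).astype(int)

    for concept in SYMPTOM_CONCEPTS:
        p = np.array([config.symptom_probs[pr][concept] for pr in profiles])[profile_idx]
        data[f"symptom_{concept}"] = (rng.random(n) < p).astype(int)

    age = np.empty(n)
    delay = np.empty(n)
    for i, pr in enumerate(profiles):
        mask = profile_idx == i
        ap, dp = config.age_params[pr], config.delay_params[pr]
        age[mask] = _truncated_lognormal(rng, ap.mu, ap.sigma, int(mask.sum()), _MIN_AGE)
        delay[mask] = rng.lognormal(dp.mu, dp.sigma, int(mask.sum()))
    data["age"] = np.round(age, 1)
    data["delay_hours"] = np.round(delay, 1)

    severity = rng.normal(0.0, config.patient_noise_sd, n)
    scale_values: dict[str, np.ndarray] = {}
    for scale in SCALE_COLUMNS:
        mean = np.array([config.scale_means[pr][scale] for pr in profiles])[profile_idx]
        latent = mean + physician_bias[physician] + severity
        latent = latent + rng.normal(0.0, config.rater_noise_sd, n)
        scale_values[scale] = np.clip(np.round(latent), SCALE_MIN, SCALE_MAX).astype(int)
        data[scale] = scale_values[scale]

    tiw = np.full(n, config.tiw_intercept, dtype=float)
    for scale, coef in config.tiw_coefs.items():
        tiw += coef * scale_values[scale]
    tiw += rng.normal(0.0, config.tiw_noise_sd, n)
    data["tiw_days"] = np.maximum(0, np.round(tiw)).astype(int)

    data["second_evaluation"] = np.zeros(n, dtype=int)
    data["intentional"] = np.ones(n, dtype=int)

    df = pd.DataFrame(data)
    for col in SCALE_COLUMNS + ["tiw_days"]:
        df[col] = df[col].astype("Int64")
    df["certificate_text"] = pd.Series([pd.NA] * n, dtype="string")

    feature_spec = {feat: "binary" for feat in config.binary_features}
    for feat in NUMERIC_FEATURES:
        feature_spec[feat] = "numeric"
    return Cohort(df, feature_spec)


def _mutate_token(term: str, rng: np.random.Generator) -> str:
    """One random character edit (substitution, deletion or insertion).

    Space characters are never touched so multi-word terms keep their token
    count; the result is always at Levenshtein distance exactly 1.
    """
    letters = "abcdefghijklmnopqrstuvwxyz"
    op = rng.integers(3)
    positions = [i for i, ch in enumerate(term) if ch != " "]
    if op == 0:  # substitute
        i = positions[rng.integers(len(positions))]
        repl = letters[rng.integers(26)]
        while repl == term[i]:
            repl = letters[rng.integers(26)]
        return term[:i] + repl + term[i + 1:]
    if op == 1 and len(positions) > 1:  # delete
        i = positions[rng.integers(len(positions))]
        return term[:i] + term[i + 1:]
    i = int(rng.integers(len(term) + 1))  # insert
    return term[:i] + letters[rng.integers(26)] + term[i:]


_OPENING = "Patient examine ce jour a la suite de faits de violence volontaire declares."
_SYMPTOM_SENTENCES = {
    "sleep_disorder": "Le patient decrit {term} depuis les faits.",
    "loss_of_appetite": "Il est rapporte une {term}.",
    "stress_symptoms": "Le patient presente des signes de {term}.",
    "pain": "Le patient signale une {term} persistante.",
    "fear": "Le patient exprime de la {term} au decours des faits.",
}
_CLOSING = "Examen clinique complet realise, conclusions remises au patient."


def render_certificates(cohort: Cohort, lexicon: Lexicon, typo_rate: float,
                        seed: int) -> Cohort:
    """Fill ``certificate_text`` from a standardized sentence template.

    For each symptom flag set on a record, one lexicon term for that concept
    is embedded in a sentence; with probability ``typo_rate`` the term
    receives one random character edit.  Records without a flag never
    contain that concept's terms.  Terms of at least five characters are
    preferred for embedding so that a single typo stays within the matcher's
    edit-distance tolerance.
    """
    if not 0.0 <= typo_rate <= 1.0:
        raise ConfigurationError(f"typo_rate must lie in [0, 1], got {typo_rate}")
    for concept in SYMPTOM_CONCEPTS:
        if not lexicon.terms(concept):
            raise ConfigurationError(f"lexicon concept {concept!r} has no terms")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    texts: list[str] = []
    for _, row in out.df.iterrows():
        sentences = [_OPENING]
        for concept in SYMPTOM_CONCEPTS:
            if not row[f"symptom_{concept}"]:
                continue
            terms = lexicon.terms(concept)
            robust = [t for t in terms if len(normalize_text(t)) >= 5]
            pool = robust or terms
            term = normalize_text(pool[rng.integers(len(pool))])
            if rng.random() < typo_rate:
                term = _mutate_token(term, rng)
            sentences.append(_SYMPTOM_SENTENCES[concept].format(term=term))
        sentences.append(_CLOSING)
        texts.append(" ".join(sentences))
    out.df["certificate_text"] = pd.Series(texts, dtype="string")
    return out


def apply_missingness(cohort: Cohort, missing_rate: float, seed: int) -> Cohort:
    """Blank scale fields completely at random at the record level.

    A record is affected with probability ``missing_rate``; an affected
    record loses a random nonempty subset of its nine scale scores (one
    guaranteed, each further scale independently with probability 0.25).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError(f"missing_rate must lie in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    affected = rng.random(n) < missing_rate
    n_scales = len(SCALE_COLUMNS)
    first = rng.integers(n_scales, size=n)
    extra = rng.random((n, n_scales)) < 0.25
    for j, scale in enumerate(SCALE_COLUMNS):
        blank = affected & ((first == j) | extra[:, j])
        col = out.df[scale].copy()
        col[blank] = pd.NA
        out.df[scale] = col
    return out
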