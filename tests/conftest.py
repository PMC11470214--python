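import numpy as np
import pytest

from vioscales import Cohort, default_config, generate_cohort


def sharpen_config(cfg, hi: float = 0.9, lo: float = 0.08, quiet_raters: bool = False):
    """Make the latent profiles well separated: push every profile-conditional
    feature frequency toward `hi`/`lo` depending on which side of 0.5 it
    sits, optionally shrinking the rater-effect noise."""
    fp = {
        pr: {f: (hi if p >= 0.5 else lo) for f, p in tbl.items()}
        for pr, tbl in cfg.feature_probs.items()
    }
    overrides = {"feature_probs": fp}
    if quiet_raters:
        overrides.update(rater_bias_sd=0.05, rater_noise_sd=0.1, patient_noise_sd=0.1)
    return cfg.with_overrides(**overrides)


def zero_noise_config(n_patients: int = 200, seed: int = 0, **kw):
    """All rater/patient noise off: scores are exactly round(profile mean)."""
    return default_config(
        n_patients=n_patients,
        seed=seed,
        rater_bias_sd=0.0,
        rater_noise_sd=0.0,
        patient_noise_sd=0.0,
        tiw_noise_sd=0.0,
        missing_rate=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def study_cohort() -> Cohort:
    """One study-scale cohort (n=4180) under the default conditions."""
    return generate_cohort(default_config(seed=2024, missing_rate=0.0))


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A small default-condition cohort for fast structural tests."""
    return generate_cohort(default_config(n_patients=400, seed=42, missing_rate=0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
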