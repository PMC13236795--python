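import numpy as np
import pytest

from stepinit import GenerativeParams, synthesize_trial
from stepinit.events import extract_outcomes
from stepinit.kinematics import reduce_record
from stepinit.simulate import LatentOutcome


@pytest.fixture(scope="session")
def zero_params() -> GenerativeParams:
    return GenerativeParams().zero_noise()


@pytest.fixture(scope="session")
def noisy_params() -> GenerativeParams:
    return GenerativeParams()


@pytest.fixture(scope="session")
def base_latent() -> LatentOutcome:
    return LatentOutcome(
        reaction_time_ms=637.0,
        initial_posture_cm=-44.0,
        apa_duration_ms=250.0,
        apa_amplitude_cm=-3.97,
        v_peak_m_s=0.563,
        t_v_ms=948.0,
    )


@pytest.fixture(scope="session")
def clean_record(zero_params, base_latent):
    return synthesize_trial(base_latent, 70.0, zero_params, seed=0, meta={"trial_type": "go"})


@pytest.fixture(scope="session")
def clean_kinematics(clean_record):
    return reduce_record(clean_record)


@pytest.fixture(scope="session")
def clean_outcomes(zero_params, base_latent):
    rec = synthesize_trial(base_latent, 70.0, zero_params, seed=0, meta={"trial_type": "go"})
    kin = reduce_record(rec)
    return extract_outcomes(kin)


def roundtrip_errors(latent: LatentOutcome, params: GenerativeParams, mass: float = 70.0, seed: int = 0):
    """Extracted-minus-latent errors for one synthesized trial."""
    rec = synthesize_trial(latent, mass, params, seed=seed)
    row, _ = extract_outcomes(reduce_record(rec))
    return {
        "rt_ms": row.reaction_time_ms - latent.reaction_time_ms,
        "posture_cm": row.initial_posture_cm - latent.initial_posture_cm,
        "duration_ms": row.apa_duration_ms - latent.apa_duration_ms,
        "amplitude_cm": row.apa_amplitude_cm - latent.apa_amplitude_cm,
        "v_m_s": row.v_peak_m_s - latent.v_peak_m_s,
        "tv_ms": row.t_v_ms - latent.t_v_ms,
    }


def random_latent(rng: np.random.Generator) -> LatentOutcome:
    """Latents spanning the generator's physiological parameter box."""
    rt = rng.uniform(250.0, 900.0)
    return LatentOutcome(
        reaction_time_ms=rt,
        initial_posture_cm=rng.uniform(-50.0, -38.0),
        apa_duration_ms=rng.uniform(150.0, 400.0),
        apa_amplitude_cm=rng.uniform(-7.0, -2.0),
        v_peak_m_s=rng.uniform(0.3, 0.8),
        t_v_ms=rt + rng.uniform(250.0, 500.0),
    )
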