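"""Shared fixtures: small synthetic scenes analysed once per session."""


import pytest

from pvsflow import SceneConfig, analyze_stack, simulate
from pvsflow.pipeline import PipelineParams


@pytest.fixture(scope="session")
def steady_scene():
    """Steady Poiseuille scene at the fast-flow regime (V0 = 50 μm/s)."""
    cfg = SceneConfig(
        image_size=(256, 256), duration=12.0, centerline_speed=50.0,
        cardiac_amplitude=0.0, respiratory_amplitude=0.0,
        n_particles=80, stagnant_fraction=0.0, rng_seed=11,
    )
    stack, truth = simulate(cfg)
    result = analyze_stack(stack, params=PipelineParams(), heart_rate_hint=5.0)
    return cfg, truth, result


@pytest.fixture(scope="session")
def sinusoidal_scene():
    """Downstream velocity U + A·sin(ωt) with U = 15, A = 25 μm/s.

    The oscillation rides on the respiratory modulation channel at a slow
    0.5 Hz so the differentiation kernel leaves the sinusoid essentially
    unattenuated.
    """
    u, a = 15.0, 25.0
    cfg = SceneConfig(
        image_size=(224, 224), duration=20.0, centerline_speed=u,
        cardiac_amplitude=0.0, respiratory_amplitude=a / u,
        resp_rate=0.5, heart_rate=5.0,
        n_particles=70, stagnant_fraction=0.0, rng_seed=7,
    )
    stack, truth = simulate(cfg)
    result = analyze_stack(stack, params=PipelineParams(), heart_rate_hint=5.0)
    return cfg, truth, result


def _cardiac_scene(seed: int):
    cfg = SceneConfig(
        image_size=(224, 224), duration=15.0, centerline_speed=30.0,
        cardiac_amplitude=0.02, cardiac_lag=0.05,
        respiratory_amplitude=0.0, heart_rate=5.0, heart_jitter=0.02,
        n_particles=60, stagnant_fraction=0.0, rng_seed=seed,
    )
    stack, truth = simulate(cfg, seed=seed)
    result = analyze_stack(
        stack, truth.ecg, truth.respiration, params=PipelineParams(),
        heart_rate_hint=5.0, resp_rate_hint=1.7,
    )
    return cfg, truth, result


@pytest.fixture(scope="session")
def cardiac_scenes():
    """Cardiac-locked pulsatile scenes (lag 0.05 s), three seeds."""
    return [_cardiac_scene(seed) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def stagnant_scene():
    """Scene with 20% stagnant adhered particles, dynamic masking."""
    cfg = SceneConfig(
        image_size=(224, 224), duration=10.0, centerline_speed=30.0,
        n_particles=30, stagnant_fraction=0.2, rng_seed=5,
    )
    stack, truth = simulate(cfg)
    result = analyze_stack(stack, params=PipelineParams(), heart_rate_hint=5.0)
    return cfg, truth, result
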