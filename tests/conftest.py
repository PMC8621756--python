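"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from memdyn import simgen
from memdyn.core import NoiseModel


def make_brownian_tracks(
    rng: np.random.Generator,
    n_tracks: int,
    n_frames: int,
    step_sigma_um: float,
    localization_sd_um: float = 0.0,
) -> np.ndarray:
    """Pure Brownian position arrays, shape (n_tracks, n_frames, 2) in μm."""
    steps = rng.normal(0.0, step_sigma_um, size=(n_tracks, n_frames - 1, 2))
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if localization_sd_um > 0:
        pos = pos + rng.normal(0.0, localization_sd_um, size=pos.shape)
    return pos


@pytest.fixture(scope="session")
def small_movie():
    """A 30-particle, 20-frame movie with 20 nm localization jitter."""
    spec = simgen.TirfSimSpec(
        n_particles=30,
        n_frames=20,
        field_size_px=(100, 100),
        localization_jitter_um=0.02,
        seed=101,
    )
    movie, truth = simgen.simulate_tirf_movie(spec)
    return spec, movie, truth


@pytest.fixture(scope="session")
def cell_image_46():
    spec = simgen.CellImageSimSpec(n_puncta=46, seed=7)
    return simgen.simulate_cell_image(spec)


@pytest.fixture(scope="session")
def noiseless_lambda():
    spec = simgen.SpectralSimSpec(noise_model=NoiseModel("none"), seed=5)
    return spec, *simgen.simulate_lambda_stack(spec)
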