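"""Shared fixtures: synthetic movies rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from larvascape import tracking
from larvascape.synthlarva import SimulationConfig, run_simulation, truth_to_seeds


def truth_tracks(truth) -> list:
    """Pseudo-tracks carrying the exact ground-truth positions."""
    n_t = truth.times.size
    out = []
    for i, row in truth.cells.iterrows():
        out.append(
            tracking.CellTrack(
                cell_id=row["cell_id"],
                positions=truth.positions[i].copy(),
                confidence=np.full(n_t, tracking.CONF_AUTO, dtype=object),
                valid_start=0,
                valid_end=n_t - 1,
                time=truth.times,
                cell_type=row["cell_type"],
                segment=str(row["segment"]),
                side=row["side"],
            )
        )
    return out


@pytest.fixture(scope="session")
def crawl_noisy():
    """One full peristaltic wave at SNR 10 (red peak 100, read noise sd 10)."""
    cfg = SimulationConfig(mode="crawl", duration=6.0, noise_sd=10.0, seed=11)
    truth, movie = run_simulation(cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def crawl_noisy_tracks(crawl_noisy):
    _, truth, movie = crawl_noisy
    return tracking.track_movie(movie, truth_to_seeds(truth))


@pytest.fixture(scope="session")
def crawl_clean_modulated():
    """Noise-free crawl render with 10% common intensity modulation."""
    cfg = SimulationConfig(
        mode="crawl", duration=6.0, noise_sd=0.0,
        intensity_modulation_amplitude=0.1, seed=11,
    )
    truth, movie = run_simulation(cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def crawl_clean_unmodulated():
    cfg = SimulationConfig(
        mode="crawl", duration=6.0, noise_sd=0.0,
        intensity_modulation_amplitude=0.0, seed=11,
    )
    truth, movie = run_simulation(cfg)
    return cfg, truth, movie


@pytest.fixture(scope="session")
def explore_noisy():
    """Exploration movie (turning + retraction) at SNR 10."""
    cfg = SimulationConfig(mode="explore", duration=10.0, noise_sd=10.0, seed=3)
    truth, movie = run_simulation(cfg)
    return cfg, truth, movie
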