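"""Shared fixtures: small, fast simulation setups used across test modules."""

import numpy as np
import pytest

from mtnuc import (
    MicrotubuleTrack,
    NucleationKinetics,
    RenderSettings,
    SimulationConfig,
)

WT_KINETICS = NucleationKinetics(k=24.5, n_max=300.0)
BUFFER_KINETICS = NucleationKinetics(k=1.2, n_max=300.0)


@pytest.fixture
def wt_kinetics() -> NucleationKinetics:
    """Wildtype-activator condition: fast saturating nucleation."""
    return WT_KINETICS


@pytest.fixture
def buffer_kinetics() -> NucleationKinetics:
    """Buffer-control condition: slow nucleation."""
    return BUFFER_KINETICS


@pytest.fixture
def noise_free_render() -> RenderSettings:
    return RenderSettings(noise_model="none")


@pytest.fixture
def sparse_config() -> SimulationConfig:
    """A few well-separated microtubules on a mid-sized plane; fast growth
    so newborn tracks become visible within a frame or two."""
    return SimulationConfig(
        kinetics=NucleationKinetics(k=2.0, n_max=4.0),
        duration=160.0,
        plane_size=(120, 120),
        pixel_size=0.16,
        growth_speed=9.0,
        seed=3,
    )


def axis_line(track: MicrotubuleTrack, t_end: float, config: SimulationConfig,
              margin_px: float = 5.0) -> list[tuple[float, float]]:
    """A kymograph line along a track's axis with a margin at both ends,
    clamped to the plane (mimics drawing the line along the microtubule)."""
    minus, plus = track.endpoints_px(t_end, config)
    d = plus - minus
    norm = float(np.hypot(*d))
    u = d / norm if norm else np.array([1.0, 0.0])
    a = minus - u * margin_px
    b = plus + u * margin_px
    w, h = config.plane_size
    clamp = lambda p: (min(max(p[0], 0.0), w - 1.0), min(max(p[1], 0.0), h - 1.0))
    return [clamp(a), clamp(b)]
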