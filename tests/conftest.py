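import numpy as np
import pytest

from hallgait.config import ChirpConfig, default_config
from hallgait.cube import RadarCube
from hallgait.simulate import BeamPattern, Scatterer, synthesize_cube


@pytest.fixture(scope="session")
def cfg() -> ChirpConfig:
    return default_config()


@pytest.fixture(scope="session")
def small_cfg() -> ChirpConfig:
    """Tiny profile for brute-force (O(N^2)) oracle comparisons."""
    return ChirpConfig(adc_samples=8, chirps_per_frame=4, frame_period=0.01)


def make_static_scatterer(range_m: float, azimuth_deg: float = 0.0,
                          amplitude: float = 1.0,
                          label: str = "static") -> Scatterer:
    return Scatterer(
        range_trajectory=lambda t, _r=range_m: np.full_like(
            np.asarray(t, dtype=float), _r),
        azimuth_trajectory=lambda t, _a=azimuth_deg: np.full_like(
            np.asarray(t, dtype=float), _a),
        amplitude=amplitude, label=label)


def make_moving_scatterer(r0: float, speed: float,
                          azimuth_deg: float = 0.0,
                          amplitude: float = 1.0,
                          label: str = "torso") -> Scatterer:
    return Scatterer(
        range_trajectory=lambda t: r0 + speed * np.asarray(t, dtype=float),
        azimuth_trajectory=lambda t, _a=azimuth_deg: np.full_like(
            np.asarray(t, dtype=float), _a),
        amplitude=amplitude, label=label)


def make_static_cube(cfg: ChirpConfig, range_m: float, n_frames: int = 2,
                     snr_db=None, seed: int = 0,
                     beam: BeamPattern | None = None) -> RadarCube:
    beam = beam or BeamPattern.no_lens()
    return synthesize_cube([make_static_scatterer(range_m, label="torso")],
                           cfg, beam, snr_db,
                           duration=n_frames * cfg.frame_period,
                           rng_seed=seed)
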