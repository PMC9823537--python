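"""Raw-ADC radar data cube container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ChirpConfig


@dataclass
class RadarCube:
    """Complex raw ADC samples shaped ``[frames, chirps, samples]``.

    ``data`` is stored as little-endian complex64; the associated
    :class:`~hallgait.config.ChirpConfig` travels with the samples.
    """

    data: np.ndarray
    config: ChirpConfig

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D [frames, chirps, samples]")
        if data.shape[1] != self.config.chirps_per_frame:
            raise ValueError(
                f"cube has {data.shape[1]} chirps/frame, config says "
                f"{self.config.chirps_per_frame}")
        if data.shape[2] != self.config.adc_samples:
            raise ValueError(
                f"cube has {data.shape[2]} samples/chirp, config says "
                f"{self.config.adc_samples}")
        self.data = np.ascontiguousarray(data, dtype=np.complex64)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration [s]."""
        return self.n_frames * self.config.frame_period

    def frame_times(self) -> np.ndarray:
        """Nominal time of each frame [s]: frame start + half chirp burst."""
        burst = self.config.chirps_per_frame * self.config.chirp_interval
        return (np.arange(self.n_frames) * self.config.frame_period
                + 0.5 * burst)
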