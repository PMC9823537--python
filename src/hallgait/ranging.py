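"""Fast-time range processing and max-bin torso tracking.

The torso of a walking subject dominates the reflected energy, so with a
well-aimed narrow beam its position per frame is simply the argmax of the
range-magnitude profile (above a minimum range that excludes TX leakage).
A slow-time mean subtraction removes static clutter before the argmax, and
a median filter plus velocity gating cleans the resulting track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal

from .config import max_unambiguous_velocity, range_axis
from .cube import RadarCube


@dataclass
class RangeProfile:
    """Per-frame range magnitude profile."""

    frame_index: int
    magnitudes: np.ndarray   # linear scale, >= 0, length n_fft
    range_axis: np.ndarray   # metres per bin

    def __post_init__(self) -> None:
        if len(self.magnitudes) != len(self.range_axis):
            raise ValueError("magnitudes and range_axis length mismatch")


@dataclass
class RangeTrack:
    """Torso range per frame at frame rate."""

    times: np.ndarray        # [s], strictly increasing
    torso_range: np.ndarray  # [m]
    torso_bin: np.ndarray    # int bin index, -1 where invalid
    valid: np.ndarray        # bool per frame
    n_fft: int
    frame_period: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("track times must be strictly increasing")
        n = len(self.times)
        if not (len(self.torso_range) == len(self.torso_bin)
                == len(self.valid) == n):
            raise ValueError("track arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)


_WINDOW_ALIASES = {"rectangular": "boxcar", "rect": "boxcar", "none": "boxcar"}


def range_fft(cube: RadarCube, window: str = "hann",
              n_fft: int | None = None) -> np.ndarray:
    """Windowed fast-time FFT per chirp -> complex bins [frames, chirps, n_fft].

    Bin 0 corresponds to zero range.  ``n_fft`` >= adc_samples (zero padding
    refines the bin spacing without changing physical resolution).
    """
    cfg = cube.config
    if n_fft is None:
        n_fft = cfg.adc_samples
    if n_fft < cfg.adc_samples:
        raise ValueError("n_fft must be >= adc_samples")
    name = _WINDOW_ALIASES.get(window, window)
    try:
        w = scipy.signal.get_window(name, cfg.adc_samples, fftbins=True)
    except ValueError as exc:
        raise ValueError(f"unknown window name: {window!r}") from exc
    x = cube.data * w.astype(np.float32)
    return scipy.fft.fft(x, n=n_fft, axis=-1)


def clutter_filter(bins: np.ndarray, mode: str = "slow_time_mean") -> np.ndarray:
    """Remove zero-Doppler content from range bins.

    ``slow_time_mean`` subtracts, per range bin, the complex mean across
    the chirps of each frame (the slow-time segment processed at a time),
    cancelling returns that are static over the segment; ``none`` is a
    pass-through.  A walking torso moves many wavelengths per frame, so its
    return is preserved.
    """
    if mode == "none":
        return bins
    if mode != "slow_time_mean":
        raise ValueError(f"unknown clutter filter mode: {mode!r}")
    if bins.shape[0] * bins.shape[1] < 2:
        raise ValueError("clutter filter needs at least 2 chirps")
    mean = bins.mean(axis=1, keepdims=True)
    return bins - mean


def frame_profile(bins: np.ndarray, frame: int, cube: RadarCube) -> RangeProfile:
    """Noncoherent accumulation (mean magnitude over chirps) for one frame."""
    if not 0 <= frame < bins.shape[0]:
        raise IndexError(f"frame {frame} out of bounds")
    mags = np.abs(bins[frame]).mean(axis=0)
    axis = range_axis(cube.config, bins.shape[-1])
    return RangeProfile(frame_index=frame, magnitudes=mags, range_axis=axis)


def all_profiles(bins: np.ndarray) -> np.ndarray:
    """Mean magnitude over chirps for every frame -> [frames, n_fft]."""
    return np.abs(bins).mean(axis=1)


def torso_bin(profile: RangeProfile, min_range: float = 0.3) -> int | None:
    """Index of the maximum range bin at/beyond ``min_range``.

    Ties break toward the smaller bin.  Returns ``None`` (invalid frame)
    when the admissible profile carries no energy.
    """
    mask = profile.range_axis >= min_range
    if not np.any(mask):
        return None
    mags = np.where(mask, profile.magnitudes, -np.inf)
    best = int(np.argmax(mags))
    if profile.magnitudes[best] <= 0:
        return None
    return best


def build_track(cube: RadarCube, window: str = "hann",
                n_fft: int | None = None,
                clutter_mode: str = "slow_time_mean",
                min_range: float = 0.3,
                min_peak_ratio: float = 5.0) -> RangeTrack:
    """Raw max-bin track: FFT, clutter filter, per-frame argmax.

    A frame is valid only when its peak magnitude exceeds
    ``min_peak_ratio`` times the frame's median profile level (noise
    floor); frames where the subject is fully static (removed by the
    clutter filter) fail this test and are flagged for interpolation.
    """
    cfg = cube.config
    if n_fft is None:
        n_fft = cfg.adc_samples
    bins = clutter_filter(range_fft(cube, window=window, n_fft=n_fft),
                          mode=clutter_mode)
    profiles = all_profiles(bins)
    axis = range_axis(cfg, n_fft)
    mask = axis >= min_range
    masked = np.where(mask[None, :], profiles, -np.inf)
    bins_idx = np.argmax(masked, axis=1)
    peak_mag = profiles[np.arange(len(bins_idx)), bins_idx]
    floor = np.median(profiles, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(floor > 0, peak_mag / floor, np.inf)
    valid = (np.isfinite(masked.max(axis=1)) & (peak_mag > 0)
             & (ratio > min_peak_ratio))
    torso_range = np.where(valid, axis[bins_idx], np.nan)
    return RangeTrack(times=cube.frame_times(),
                      torso_range=torso_range,
                      torso_bin=np.where(valid, bins_idx, -1),
                      valid=valid, n_fft=n_fft,
                      frame_period=cfg.frame_period)


def track_smooth(track: RangeTrack, max_speed: float | None = None,
                 median_window: int = 3) -> RangeTrack:
    """Median-filter the track and gate physically impossible jumps.

    Frames whose implied speed from the previous valid frame exceeds
    ``max_speed`` are marked invalid; invalid frames are linearly
    interpolated from their neighbours.
    """
    if len(track) < 3:
        raise ValueError("track_smooth needs at least 3 frames")
    if max_speed is None or max_speed <= 0:
        raise ValueError("max_speed must be a positive velocity bound")

    times = track.times
    r = track.torso_range.astype(float).copy()
    valid = track.valid.copy()

    # fill invalid frames before filtering
    if not valid.any():
        raise ValueError("track has no valid frames")
    r[~valid] = np.interp(times[~valid], times[valid], r[valid])

    if median_window > 1:
        r = scipy.signal.medfilt(r, kernel_size=median_window)

    # velocity gating against the last accepted frame
    gated = valid.copy()
    last = 0
    gated[0] = True
    for i in range(1, len(r)):
        speed = abs(r[i] - r[last]) / (times[i] - times[last])
        if speed > max_speed:
            gated[i] = False
        else:
            last = i
    if gated.sum() >= 2:
        r[~gated] = np.interp(times[~gated], times[gated], r[gated])

    return RangeTrack(times=times, torso_range=r,
                      torso_bin=track.torso_bin.copy(),
                      valid=valid & gated, n_fft=track.n_fft,
                      frame_period=track.frame_period)


def extract_track(cube: RadarCube, window: str = "hann",
                  n_fft: int | None = None,
                  clutter_mode: str = "slow_time_mean",
                  min_range: float = 0.3,
                  max_speed: float | None = None,
                  median_window: int = 3,
                  min_peak_ratio: float = 5.0) -> RangeTrack:
    """Full range-processing stage: raw max-bin track, then smoothing."""
    if max_speed is None:
        max_speed = max_unambiguous_velocity(cube.config)
    raw = build_track(cube, window=window, n_fft=n_fft,
                      clutter_mode=clutter_mode, min_range=min_range,
                      min_peak_ratio=min_peak_ratio)
    return track_smooth(raw, max_speed=max_speed,
                        median_window=median_window)
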