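"""End-to-end cube -> gait report pipeline with one parameter bundle."""

from __future__ import annotations

from dataclasses import dataclass

from .cube import RadarCube
from .gait import (GaitReport, Segmentation, StepEvents, VelocitySeries,
                   build_report, detect_steps, segment_passes, torso_velocity)
from .ranging import RangeTrack, extract_track


@dataclass(frozen=True)
class PipelineParams:
    """Tunables of the processing chain (defaults match the experiments).

    ``n_fft_factor`` zero-pads the fast-time FFT to refine the range grid
    used for tracking (physical resolution is unchanged).
    """

    window: str = "hann"
    n_fft_factor: int = 4
    clutter_mode: str = "slow_time_mean"
    min_range: float = 0.3
    min_peak_ratio: float = 5.0
    median_window: int = 3
    max_speed: float | None = None        # None -> max unambiguous velocity
    smooth_window: int = 5
    min_turn_duration: float = 0.5
    stop_threshold: float = 0.08
    min_step_interval: float = 0.3
    min_prominence: float = 0.2


@dataclass
class GaitResult:
    track: RangeTrack
    velocity: VelocitySeries
    segmentation: Segmentation
    events: StepEvents
    report: GaitReport


def run_pipeline(cube: RadarCube,
                 params: PipelineParams | None = None) -> GaitResult:
    """Run range processing and gait extraction on a raw cube."""
    p = params or PipelineParams()
    n_fft = p.n_fft_factor * cube.config.adc_samples
    track = extract_track(cube, window=p.window, n_fft=n_fft,
                          clutter_mode=p.clutter_mode, min_range=p.min_range,
                          max_speed=p.max_speed,
                          median_window=p.median_window,
                          min_peak_ratio=p.min_peak_ratio)
    velocity = torso_velocity(track, smooth_window=p.smooth_window)
    seg = segment_passes(velocity, min_turn_duration=p.min_turn_duration,
                         stop_threshold=p.stop_threshold)
    events = detect_steps(velocity, seg,
                          min_step_interval=p.min_step_interval,
                          min_prominence=p.min_prominence)
    report = build_report(track, velocity, seg, events)
    return GaitResult(track=track, velocity=velocity, segmentation=seg,
                      events=events, report=report)
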