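"""Per-cycle spatiotemporal gait parameters from a torso range track.

The torso alternately speeds up and slows down over each stance/swing
cycle, so the absolute torso velocity carries one local maximum per step.
The pipeline: differentiate the smoothed range track, split it into
walking passes and turns, peak-detect |v| within passes, read step points
off the range track at the peak instants, and difference successive step
points into step lengths.  Turn time counts toward the average walking
speed but is excluded from every other parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .config import wavelength
from .cube import RadarCube
from .ranging import RangeTrack, range_fft
from .simulate import GaitGroundTruth


@dataclass
class VelocitySeries:
    """Signed torso radial velocity at frame rate (away-positive)."""

    times: np.ndarray
    velocity: np.ndarray
    abs_velocity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.velocity):
            raise ValueError("times and velocity length mismatch")
        self.abs_velocity = np.abs(self.velocity)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class Segment:
    start: int            # frame index, inclusive
    stop: int             # frame index, exclusive
    kind: str             # "pass" | "turn"
    sign: int             # walk direction, 0 for turns
    pass_id: int          # -1 for turns


@dataclass
class Segmentation:
    """Partition of the recording into passes and turns."""

    segments: list
    labels: np.ndarray    # per-frame pass id, -1 for turn frames

    @property
    def passes(self) -> list:
        return [s for s in self.segments if s.kind == "pass"]

    @property
    def turns(self) -> list:
        return [s for s in self.segments if s.kind == "turn"]

    @property
    def interior_turns(self) -> list:
        """Turns strictly between two passes."""
        passes = self.passes
        if not passes:
            return []
        lo, hi = passes[0].start, passes[-1].stop
        return [s for s in self.turns if s.start >= lo and s.stop <= hi]


@dataclass
class StepEvents:
    """Detected step instants (|v| peaks) within passes."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    pass_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class GaitReport:
    """Summary and per-step spatiotemporal gait parameters."""

    avg_speed: float              # [m/s], turns included
    step_count: int
    cadence: float                # steps/min over pass time only
    step_times: np.ndarray        # [s] per step, NaN on last step of a pass
    step_points: np.ndarray       # [m] torso range at each step instant
    step_lengths: np.ndarray      # [m] per step, NaN on last step of a pass
    stride_lengths: np.ndarray    # [m]
    pass_ids: np.ndarray
    peak_times: np.ndarray        # [s] absolute step instants
    per_pass: list = field(default_factory=list)

    @property
    def mean_step_length(self) -> float:
        finite = self.step_lengths[np.isfinite(self.step_lengths)]
        return float(np.mean(finite)) if finite.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(self.step_count),
            "pass_id": self.pass_ids,
            "step_time_s": self.step_times,
            "step_point_m": self.step_points,
            "step_length_m": self.step_lengths,
        })

    def summary_dict(self) -> dict:
        return {
            "avg_speed_mps": float(self.avg_speed),
            "step_count": int(self.step_count),
            "cadence_spm": float(self.cadence),
            "mean_step_length_m": (None if np.isnan(self.mean_step_length)
                                   else float(self.mean_step_length)),
            "stride_lengths_m": [float(x) for x in self.stride_lengths],
            "per_pass": self.per_pass,
        }


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def torso_velocity(track: RangeTrack, smooth_window: int = 5,
                   polyorder: int = 2) -> VelocitySeries:
    """Smoothed derivative of the torso range (local quadratic fit)."""
    n = len(track)
    if n < 3 or track.valid.sum() < 3:
        raise ValueError("need at least 3 valid frames to differentiate")
    window = min(smooth_window, n if n % 2 == 1 else n - 1)
    window = max(window, polyorder + 1 + (polyorder % 2))
    if window % 2 == 0:
        window += 1
    dt = track.frame_period
    v = scipy.signal.savgol_filter(track.torso_range, window_length=window,
                                   polyorder=polyorder, deriv=1, delta=dt,
                                   mode="interp")
    return VelocitySeries(times=track.times, velocity=v)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_passes(v: VelocitySeries, min_turn_duration: float = 0.5,
                   stop_threshold: float = 0.08,
                   min_pass_duration: float = 0.3) -> Segmentation:
    """Label every frame as part of a walking pass or a turn.

    Contiguous runs of consistent velocity sign above ``stop_threshold``
    are passes; low-speed or sign-change gaps longer than
    ``min_turn_duration`` are turns, shorter gaps between same-sign runs
    are absorbed into the surrounding pass.
    """
    n = len(v.times)
    dt = v.dt
    moving = v.abs_velocity > stop_threshold
    sign = np.sign(v.velocity).astype(int)

    # raw runs of moving frames with constant sign
    runs = []
    i = 0
    while i < n:
        if moving[i]:
            j = i
            while j < n and moving[j] and sign[j] == sign[i]:
                j += 1
            runs.append([i, j, sign[i]])
            i = j
        else:
            i += 1

    min_pass_frames = max(1, int(round(min_pass_duration / dt)))
    runs = [r for r in runs if r[1] - r[0] >= min_pass_frames]
    if not runs:
        raise ValueError("no walking pass found")

    # merge same-sign runs separated by short gaps
    merged = [runs[0]]
    gap_frames = int(round(min_turn_duration / dt))
    for run in runs[1:]:
        prev = merged[-1]
        if run[2] == prev[2] and run[0] - prev[1] < gap_frames:
            prev[1] = run[1]
        else:
            merged.append(run)

    labels = np.full(n, -1, dtype=int)
    segments: list[Segment] = []
    cursor = 0
    for pid, (start, stop, s) in enumerate(merged):
        if start > cursor:
            segments.append(Segment(cursor, start, "turn", 0, -1))
        segments.append(Segment(start, stop, "pass", int(s), pid))
        labels[start:stop] = pid
        cursor = stop
    if cursor < n:
        segments.append(Segment(cursor, n, "turn", 0, -1))
    return Segmentation(segments=segments, labels=labels)


# ---------------------------------------------------------------------------
# step detection and geometry
# ---------------------------------------------------------------------------

def detect_steps(v: VelocitySeries, seg: Segmentation,
                 min_step_interval: float = 0.3,
                 min_prominence: float = 0.2) -> StepEvents:
    """Peak detection on |v| within passes.

    Peaks must be at least ``min_step_interval`` apart (cadence cap around
    200 steps/min) with prominence at least ``min_prominence`` times the
    pass median |v|, measured over a window of about one gait cycle so a
    flat plateau cannot borrow prominence from the distant pass edges.  An
    empty result is legitimate (e.g. constant speed).
    """
    dt = v.dt
    distance = max(1, int(round(min_step_interval / dt)))
    wlen = max(2 * distance + 1, int(round(4.0 * min_step_interval / dt)))
    idx_all, pid_all = [], []
    for s in seg.passes:
        x = v.abs_velocity[s.start:s.stop]
        if len(x) < 3:
            continue
        prom = min_prominence * float(np.median(x))
        peaks, _ = scipy.signal.find_peaks(x, distance=distance,
                                           prominence=max(prom, 1e-12),
                                           wlen=wlen)
        idx_all.extend(int(p) + s.start for p in peaks)
        pid_all.extend([s.pass_id] * len(peaks))
    idx = np.asarray(idx_all, dtype=int)
    return StepEvents(peak_times=v.times[idx],
                      peak_indices=idx,
                      pass_ids=np.asarray(pid_all, dtype=int))


@dataclass
class StepGeometry:
    step_points: np.ndarray     # [m], one per detected step
    step_lengths: np.ndarray    # [m], NaN on the last step of each pass
    stride_lengths: np.ndarray  # [m], sum of successive step lengths


def step_geometry(track: RangeTrack, events: StepEvents) -> StepGeometry:
    """Step points from the range track; lengths from successive points.

    ``step_length(i) = |step_point(i+1) - step_point(i)|`` within a pass;
    a stride is the sum of two successive step lengths.  Steps are never
    paired across passes.
    """
    if len(events) and (events.peak_times[0] < track.times[0] - 1e-9
                        or events.peak_times[-1] > track.times[-1] + 1e-9):
        raise ValueError("step event outside the track time span")
    points = np.interp(events.peak_times, track.times, track.torso_range)
    lengths = np.full(len(events), np.nan)
    strides = []
    for pid in np.unique(events.pass_ids):
        sel = np.flatnonzero(events.pass_ids == pid)
        if len(sel) < 2:
            continue
        diffs = np.abs(np.diff(points[sel]))
        lengths[sel[:-1]] = diffs
        strides.extend(diffs[:-1] + diffs[1:])
    return StepGeometry(step_points=points, step_lengths=lengths,
                        stride_lengths=np.asarray(strides, dtype=float))


# ---------------------------------------------------------------------------
# summary parameters
# ---------------------------------------------------------------------------

def average_speed(track: RangeTrack, seg: Segmentation) -> float:
    """Total traversed path over total elapsed time, turns included.

    Sums |range change| over passes and divides by the time from the start
    of the first pass to the end of the last one.
    """
    passes = seg.passes
    if not passes:
        return 0.0
    dist = sum(abs(track.torso_range[s.stop - 1] - track.torso_range[s.start])
               for s in passes)
    elapsed = track.times[passes[-1].stop - 1] - track.times[passes[0].start]
    return float(dist / elapsed) if elapsed > 0 else 0.0


def build_report(track: RangeTrack, v: VelocitySeries, seg: Segmentation,
                 events: StepEvents) -> GaitReport:
    """Assemble the full gait report from the pipeline stages."""
    geometry = step_geometry(track, events)
    n = len(events)

    step_times = np.full(n, np.nan)
    pass_time = 0.0
    per_pass = []
    for s in seg.passes:
        sel = np.flatnonzero(events.pass_ids == s.pass_id)
        if len(sel) >= 2:
            step_times[sel[:-1]] = np.diff(events.peak_times[sel])
        duration = float(track.times[s.stop - 1] - track.times[s.start])
        pass_time += duration
        per_pass.append({
            "pass_id": int(s.pass_id),
            "direction": "away" if s.sign > 0 else "toward",
            "n_steps": int(len(sel)),
            "duration_s": duration,
            "distance_m": float(abs(track.torso_range[s.stop - 1]
                                    - track.torso_range[s.start])),
        })

    cadence = (n / pass_time * 60.0) if pass_time > 0 else 0.0
    return GaitReport(
        avg_speed=average_speed(track, seg),
        step_count=n,
        cadence=float(cadence),
        step_times=step_times,
        step_points=geometry.step_points,
        step_lengths=geometry.step_lengths,
        stride_lengths=geometry.stride_lengths,
        pass_ids=events.pass_ids.copy(),
        peak_times=events.peak_times.copy(),
        per_pass=per_pass,
    )


def compare_to_truth(report: GaitReport, truth: GaitGroundTruth) -> dict:
    """Error metrics of a report against simulation ground truth."""
    true_lengths = []
    for pid in np.unique(truth.true_pass_ids):
        pts = truth.true_step_points[truth.true_pass_ids == pid]
        true_lengths.extend(np.abs(np.diff(pts)))
    true_mean_len = float(np.mean(true_lengths)) if true_lengths else float("nan")
    return {
        "speed_error_mps": float(report.avg_speed - truth.true_avg_speed),
        "step_count_error": int(report.step_count - truth.true_step_count),
        "step_length_error_m": float(report.mean_step_length - true_mean_len),
        "estimated_speed_mps": float(report.avg_speed),
        "true_speed_mps": float(truth.true_avg_speed),
        "estimated_step_count": int(report.step_count),
        "true_step_count": int(truth.true_step_count),
        "mean_step_length_m": float(report.mean_step_length),
        "true_mean_step_length_m": true_mean_len,
    }


# ---------------------------------------------------------------------------
# diagnostic micro-Doppler view
# ---------------------------------------------------------------------------

def micro_doppler_spectrogram(cube: RadarCube, track: RangeTrack,
                              stft_window: int | None = None,
                              fft_window: str = "hann"):
    """Slow-time spectrum at the torso bin per frame -> (times, v_axis, map).

    A visual cross-check only; velocities map through the Doppler relation
    ``v = f_d * lambda / 2`` (away-positive).  Not used by the parameter
    extraction path.
    """
    cfg = cube.config
    n_chirps = cfg.chirps_per_frame
    if stft_window is None:
        stft_window = n_chirps
    if stft_window > n_chirps:
        raise ValueError("stft_window exceeds chirps per frame")
    bins = range_fft(cube, window=fft_window, n_fft=track.n_fft)
    lam = wavelength(cfg)
    w = scipy.signal.get_window("hann", stft_window, fftbins=True)
    n_frames = cube.n_frames
    out = np.zeros((n_frames, stft_window))
    for f in range(n_frames):
        b = track.torso_bin[f]
        if b < 0:
            continue
        x = bins[f, :stft_window, b] * w
        out[f] = np.abs(np.fft.fftshift(np.fft.fft(x)))
    f_d = np.fft.fftshift(np.fft.fftfreq(stft_window, d=cfg.chirp_interval))
    v_axis = f_d * lam / 2.0
    return track.times, v_axis, out
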