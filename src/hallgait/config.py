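"""FMCW chirp/frame configuration and derived radar quantities.

The default configuration mirrors a 77 GHz automotive-style radar profile:
60 MHz/us slope, 64 ADC samples at 2.2 Msps, 256 chirps per frame, 250 us
idle time.  Complex (I/Q) baseband sampling is assumed throughout, so the
unambiguous beat bandwidth equals the ADC sample rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

#: Speed of light in vacuum [m/s], exact by SI definition.
C = 299_792_458.0


@dataclass(frozen=True)
class ChirpConfig:
    """Timing and sampling parameters of one FMCW chirp/frame profile.

    All values are in base SI units (Hz, s, samples).

    Attributes
    ----------
    start_frequency : float
        Frequency at which each ramp starts [Hz].
    slope : float
        Ramp slope [Hz/s].
    idle_time : float
        Gap between the end of one ramp and the start of the next [s].
    tx_start_time : float
        Time within the chirp at which the transmitter turns on [s].
    adc_start_time : float
        Time within the ramp at which ADC sampling starts [s].
    adc_samples : int
        Number of complex samples acquired per chirp.
    adc_sample_rate : float
        Complex sample rate [samples/s].
    ramp_end_time : float
        Duration of the frequency ramp [s].
    chirps_per_frame : int
        Number of chirps grouped into one frame.
    frame_period : float
        Frame repetition period [s].  Not part of the chirp profile itself;
        defaults to 100 ms (>= the 256 x 310 us minimum).
    """

    start_frequency: float = 77.0e9
    slope: float = 60.0e12          # 60 MHz/us
    idle_time: float = 250.0e-6
    tx_start_time: float = 98.0e-6
    adc_start_time: float = 10.0e-6
    adc_samples: int = 64
    adc_sample_rate: float = 2.2e6  # 2200 Ksps
    ramp_end_time: float = 60.0e-6
    chirps_per_frame: int = 256
    frame_period: float = 0.1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.start_frequency <= 0:
            raise ValueError("start_frequency must be > 0")
        if self.adc_sample_rate <= 0:
            raise ValueError("adc_sample_rate must be > 0")
        for name in ("idle_time", "tx_start_time", "adc_start_time",
                     "ramp_end_time", "frame_period"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.adc_samples < 2:
            raise ValueError("adc_samples must be >= 2")
        if self.chirps_per_frame < 2:
            raise ValueError("chirps_per_frame must be >= 2")
        adc_window = self.adc_samples / self.adc_sample_rate
        if self.adc_start_time + adc_window > self.ramp_end_time + 1e-12:
            raise ValueError(
                "ADC window does not fit the ramp: "
                f"{self.adc_start_time + adc_window:.3e} s > "
                f"{self.ramp_end_time:.3e} s")
        if self.frame_period < self.chirps_per_frame * self.chirp_interval - 1e-12:
            raise ValueError(
                "frame_period shorter than the chirp burst: "
                f"{self.frame_period:.4e} s < "
                f"{self.chirps_per_frame * self.chirp_interval:.4e} s")

    # -- derived quantities -------------------------------------------------

    @property
    def chirp_interval(self) -> float:
        """Chirp-to-chirp interval (idle time + ramp duration) [s]."""
        return self.idle_time + self.ramp_end_time

    @property
    def adc_window(self) -> float:
        """Duration of the sampled portion of the ramp [s]."""
        return self.adc_samples / self.adc_sample_rate

    @property
    def frame_rate(self) -> float:
        """Frames per second [Hz]."""
        return 1.0 / self.frame_period


def default_config() -> ChirpConfig:
    """Return the reference chirp configuration used by all experiments."""
    return ChirpConfig()


def sweep_bandwidth(cfg: ChirpConfig) -> float:
    """Full-ramp sweep bandwidth slope x ramp_end_time [Hz].

    This is the max-minus-min frequency of the whole ramp (3600 MHz for the
    default profile).  The bandwidth actually sampled by the ADC is smaller;
    see :func:`sampled_bandwidth`.
    """
    return cfg.slope * cfg.ramp_end_time


def sampled_bandwidth(cfg: ChirpConfig) -> float:
    """Bandwidth swept during the ADC window [Hz]; sets range resolution."""
    return cfg.slope * cfg.adc_window


def range_resolution(cfg: ChirpConfig) -> float:
    """Physical range resolution c / (2 x sampled bandwidth) [m]."""
    return C / (2.0 * sampled_bandwidth(cfg))


def range_bin_spacing(cfg: ChirpConfig, n_fft: int | None = None) -> float:
    """Range spacing of one FFT output bin [m]."""
    if n_fft is None:
        n_fft = cfg.adc_samples
    if n_fft < cfg.adc_samples:
        raise ValueError("n_fft must be >= adc_samples")
    return (cfg.adc_sample_rate / n_fft) * C / (2.0 * cfg.slope)


def range_axis(cfg: ChirpConfig, n_fft: int | None = None) -> np.ndarray:
    """Range of each fast-time FFT bin [m], bin 0 at zero range.

    Bin ``k`` maps to ``k * (adc_sample_rate / n_fft) * c / (2 * slope)``.
    """
    spacing = range_bin_spacing(cfg, n_fft)
    if n_fft is None:
        n_fft = cfg.adc_samples
    return np.arange(n_fft) * spacing


def max_beat_range(cfg: ChirpConfig) -> float:
    """Maximum unambiguous range for complex sampling [m].

    The largest beat frequency representable is the complex sample rate,
    which maps to ``adc_sample_rate * c / (2 * slope)``.
    """
    return cfg.adc_sample_rate * C / (2.0 * cfg.slope)


def wavelength(cfg: ChirpConfig, convention: str = "sweep_center") -> float:
    """Carrier wavelength [m].

    Parameters
    ----------
    convention : {"sweep_center", "sampled_center", "start"}
        ``sweep_center`` (default) uses the centre of the full ramp,
        ``sampled_center`` the centre of the ADC-sampled portion and
        ``start`` the ramp start frequency.
    """
    if convention == "sweep_center":
        f = cfg.start_frequency + 0.5 * sweep_bandwidth(cfg)
    elif convention == "sampled_center":
        f = (cfg.start_frequency
             + cfg.slope * (cfg.adc_start_time + 0.5 * cfg.adc_window))
    elif convention == "start":
        f = cfg.start_frequency
    else:
        raise ValueError(f"unknown wavelength convention: {convention!r}")
    return C / f


def chirp_interval(cfg: ChirpConfig) -> float:
    """Chirp-to-chirp interval [s]."""
    return cfg.chirp_interval


def max_unambiguous_velocity(cfg: ChirpConfig,
                             wavelength_m: float | None = None) -> float:
    """Maximum unambiguous radial velocity lambda / (4 x interval) [m/s]."""
    lam = wavelength(cfg) if wavelength_m is None else wavelength_m
    return lam / (4.0 * cfg.chirp_interval)


def velocity_resolution(cfg: ChirpConfig,
                        wavelength_m: float | None = None) -> float:
    """Velocity resolution lambda / (2 x chirps x interval) [m/s]."""
    lam = wavelength(cfg) if wavelength_m is None else wavelength_m
    return lam / (2.0 * cfg.chirps_per_frame * cfg.chirp_interval)


# -- flat, unit-suffixed serialisation -------------------------------------

_UNIT_FIELDS = {
    "start_frequency_ghz": ("start_frequency", 1e9),
    "slope_mhz_per_us": ("slope", 1e12),
    "idle_time_us": ("idle_time", 1e-6),
    "tx_start_time_us": ("tx_start_time", 1e-6),
    "adc_start_time_us": ("adc_start_time", 1e-6),
    "adc_samples": ("adc_samples", 1),
    "adc_sample_rate_ksps": ("adc_sample_rate", 1e3),
    "ramp_end_time_us": ("ramp_end_time", 1e-6),
    "chirps_per_frame": ("chirps_per_frame", 1),
    "frame_period_ms": ("frame_period", 1e-3),
}


def config_to_dict(cfg: ChirpConfig) -> dict:
    """Serialise to a flat dict with unit-suffixed keys."""
    raw = asdict(cfg)
    out = {}
    for key, (field, scale) in _UNIT_FIELDS.items():
        value = raw[field] / scale if scale != 1 else raw[field]
        out[key] = value
    return out


def config_from_dict(d: dict) -> ChirpConfig:
    """Inverse of :func:`config_to_dict`; unknown keys are rejected."""
    kwargs = {}
    for key, value in d.items():
        if key not in _UNIT_FIELDS:
            raise ValueError(f"unknown configuration key: {key!r}")
        field, scale = _UNIT_FIELDS[key]
        if scale == 1:
            kwargs[field] = int(value)
        else:
            kwargs[field] = float(value) * scale
    return ChirpConfig(**kwargs)
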