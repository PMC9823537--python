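"""File formats: cube container, raw I/Q dialect, configs, reports.

Cube container layout (little-endian throughout)::

    bytes 0..7    magic  b"HGCUBE01"
    bytes 8..11   uint32 header length L
    bytes 12..12+L-1   UTF-8 JSON header: dims, encoding, chirp config
    remainder     frames x chirps x samples complex64 (I then Q)

The raw dialect is a bare int16 interleaved I/Q stream (LSB-first) with a
YAML sidecar carrying the chirp config, dims and scale — the kind of file
a capture card produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .config import ChirpConfig, config_from_dict, config_to_dict
from .cube import RadarCube
from .gait import GaitReport
from .simulate import GaitGroundTruth

MAGIC = b"HGCUBE01"
ENCODING = "complex64-le"


class CubeFormatError(IOError):
    """Base class for cube container errors."""


class MagicError(CubeFormatError):
    """The file does not start with the container magic."""


class TruncatedCubeError(CubeFormatError):
    """The payload is shorter than the header-declared dimensions."""


class DimensionMismatchError(CubeFormatError):
    """Header dimensions are invalid or disagree with the payload size."""


# -- container --------------------------------------------------------------

def write_cube(cube: RadarCube, path) -> None:
    header = {
        "dims": list(cube.data.shape),
        "encoding": ENCODING,
        "config": config_to_dict(cube.config),
    }
    blob = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(np.array(len(blob), dtype="<u4").tobytes())
        fh.write(blob)
        fh.write(np.ascontiguousarray(cube.data, dtype="<c8").tobytes())


def read_cube(path) -> RadarCube:
    raw = Path(path).read_bytes()
    if len(raw) < len(MAGIC) + 4 or raw[:len(MAGIC)] != MAGIC:
        raise MagicError(f"{path}: not a cube container (bad magic)")
    hlen = int(np.frombuffer(raw[8:12], dtype="<u4")[0])
    if len(raw) < 12 + hlen:
        raise TruncatedCubeError(f"{path}: truncated header")
    header = json.loads(raw[12:12 + hlen].decode("utf-8"))
    dims = header.get("dims")
    if (not isinstance(dims, list) or len(dims) != 3
            or any(int(d) <= 0 for d in dims)):
        raise DimensionMismatchError(f"{path}: invalid dims {dims!r}")
    frames, chirps, samples = (int(d) for d in dims)
    expected = frames * chirps * samples * 8
    payload = raw[12 + hlen:]
    if len(payload) < expected:
        raise TruncatedCubeError(
            f"{path}: payload {len(payload)} B < expected {expected} B")
    if len(payload) > expected:
        raise DimensionMismatchError(
            f"{path}: payload {len(payload)} B != expected {expected} B")
    data = np.frombuffer(payload, dtype="<c8").reshape(frames, chirps, samples)
    cfg = config_from_dict(header["config"])
    return RadarCube(data=data.copy(), config=cfg)


# -- raw int16 I/Q dialect --------------------------------------------------

def write_raw_iq(cube: RadarCube, path, sidecar_path, scale: float = 1.0) -> None:
    """Write int16 interleaved I/Q plus a YAML sidecar.

    ``scale`` multiplies samples before rounding to int16; pick it so the
    data uses the int16 range (values are clipped).
    """
    data = cube.data.ravel()
    scaled = np.empty(data.size * 2, dtype="<i2")
    scaled[0::2] = np.clip(np.round(data.real * scale), -32768, 32767)
    scaled[1::2] = np.clip(np.round(data.imag * scale), -32768, 32767)
    with open(path, "wb") as fh:
        fh.write(scaled.tobytes())
    sidecar = {
        "dims": [int(d) for d in cube.data.shape],
        "scale": float(scale),
        "config": config_to_dict(cube.config),
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_raw_iq(path, sidecar_path) -> RadarCube:
    with open(sidecar_path, "r", encoding="utf-8") as fh:
        sidecar = yaml.safe_load(fh)
    raw = Path(path).read_bytes()
    if len(raw) % 4:
        raise CubeFormatError(
            f"{path}: stream length {len(raw)} not divisible by 4 bytes "
            "per complex sample")
    frames, chirps, samples = (int(d) for d in sidecar["dims"])
    stream = np.frombuffer(raw, dtype="<i2").astype(np.float32)
    n = frames * chirps * samples
    if stream.size != 2 * n:
        raise DimensionMismatchError(
            f"{path}: {stream.size // 2} samples, sidecar dims imply {n}")
    data = (stream[0::2] + 1j * stream[1::2]) / float(sidecar["scale"])
    cfg = config_from_dict(sidecar["config"])
    return RadarCube(data=data.reshape(frames, chirps, samples), config=cfg)


# -- configs ----------------------------------------------------------------

def write_config(cfg: ChirpConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def read_config(path) -> ChirpConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


# -- reports and ground truth ----------------------------------------------

def write_report(report: GaitReport, csv_path, json_path) -> None:
    """Per-step CSV plus a JSON summary (no timestamps: reproducible)."""
    report.to_frame().to_csv(csv_path, index=False, float_format="%.6f")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report.summary_dict()), fh, indent=2,
                  sort_keys=True)
        fh.write("\n")


def read_report_summary(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_truth(truth: GaitGroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> GaitGroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        return GaitGroundTruth.from_dict(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
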