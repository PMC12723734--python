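"""Movie data model and TIFF I/O.

A movie is a 3-D stack (frames x rows x cols) of non-negative intensities,
either raw camera counts or photon counts, together with the acquisition
metadata (pixel size at the object plane, frame time) that every downstream
stage needs.

Coordinate convention: pixel indices are 0-based; the physical center of
pixel (r, c) lies at ((r + 0.5) * pixel_size_nm, (c + 0.5) * pixel_size_nm).
All localizations and site positions are expressed in nm in this frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "Movie",
    "AcquisitionConfig",
    "read_movie",
    "write_movie",
    "to_photons",
    "split_segments",
    "read_mask",
]


@dataclass
class AcquisitionConfig:
    """Camera/acquisition metadata for one imaging regime.

    ``photon_conversion_gain`` is in camera counts per photoelectron and
    ``camera_offset`` in counts; both are user-supplied for standard-mode
    data and irrelevant (gain 1, offset 0) for photon-number-resolved data.
    """

    exposure_ms: float
    pixel_size_nm: float
    n_frames: int
    photon_conversion_gain: float = 1.0
    camera_offset: float = 0.0
    read_noise_e: float = 0.0
    fov_px: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.photon_conversion_gain <= 0:
            raise ValueError("photon_conversion_gain must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.exposure_ms <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("exposure_ms and pixel_size_nm must be > 0")

    @property
    def duration_ms(self) -> float:
        return self.exposure_ms * self.n_frames

    def to_dict(self) -> dict:
        return {
            "exposure_ms": self.exposure_ms,
            "pixel_size_nm": self.pixel_size_nm,
            "n_frames": self.n_frames,
            "photon_conversion_gain": self.photon_conversion_gain,
            "camera_offset": self.camera_offset,
            "read_noise_e": self.read_noise_e,
            "fov_px": list(self.fov_px),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "fov_px" in d:
            d["fov_px"] = tuple(d["fov_px"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionConfig":
        """Load from a YAML or JSON sidecar."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class Movie:
    """Intensity time series I(t; x, y) with acquisition metadata.

    ``data`` is stored as floating point even for photon-resolved stacks so
    that cumulant arithmetic cannot overflow integer types.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_time_ms: float
    is_photons: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        # float32 keeps 36k-frame stacks small; float64 input is respected
        self.data = arr if arr.dtype == np.float64 else arr.astype(np.float32)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frames, rows, cols)")
        if self.data.shape[0] < 2:
            raise ValueError("at least 2 frames required for temporal analysis")
        if self.pixel_size_nm <= 0 or self.frame_time_ms <= 0:
            raise ValueError("pixel_size_nm and frame_time_ms must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("movie intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def fov_nm(self) -> tuple[float, float]:
        """(height, width) of the field of view in nm."""
        return (
            self.data.shape[1] * self.pixel_size_nm,
            self.data.shape[2] * self.pixel_size_nm,
        )

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_time_ms

    def temporal_average(self) -> np.ndarray:
        """Diffraction-limited temporal average image."""
        return self.data.mean(axis=0)


def read_movie(path: str | Path, meta: AcquisitionConfig) -> Movie:
    """Read a multi-frame grayscale TIFF and attach acquisition metadata.

    Intensities are passed through unchanged; use :func:`to_photons` to
    convert standard-mode camera counts.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise IOError(f"could not read TIFF movie {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        raise ValueError(f"{path}: at least 2 frames required, got a single frame")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D grayscale stack, got shape {data.shape}")
    if data.shape[0] < 2:
        raise ValueError(f"{path}: at least 2 frames required, got {data.shape[0]}")
    is_photons = meta.photon_conversion_gain == 1.0 and meta.camera_offset == 0.0
    return Movie(
        data=data.astype(np.float32),
        pixel_size_nm=meta.pixel_size_nm,
        frame_time_ms=meta.exposure_ms,
        is_photons=is_photons,
    )


def write_movie(movie: Movie, path: str | Path, dtype: str = "float32") -> Path:
    """Write a movie as a multi-frame grayscale TIFF (uint16 or float32)."""
    path = Path(path)
    if dtype not in ("uint16", "float32"):
        raise ValueError("dtype must be 'uint16' or 'float32'")
    data = movie.data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def to_photons(movie: Movie, gain: float, offset: float = 0.0) -> Movie:
    """Convert camera counts to photons: max(0, (counts - offset) / gain)."""
    if movie.is_photons:
        raise ValueError("movie is already in photons")
    if gain <= 0:
        raise ValueError("gain must be > 0")
    data = np.maximum(0.0, (movie.data.astype(np.float64) - offset) / gain)
    return Movie(
        data=data.astype(np.float32),
        pixel_size_nm=movie.pixel_size_nm,
        frame_time_ms=movie.frame_time_ms,
        is_photons=True,
    )


def split_segments(movie: Movie, n_segments: int) -> list[Movie]:
    """Split a movie into contiguous equal-length temporal segments.

    When the frame count is not divisible the trailing remainder frames are
    dropped (floor division), which keeps per-segment statistics identical.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > movie.n_frames:
        raise ValueError(
            f"n_segments ({n_segments}) exceeds frame count ({movie.n_frames})"
        )
    seg_len = movie.n_frames // n_segments
    if seg_len < 2:
        raise ValueError("segments must contain at least 2 frames")
    return [
        replace(movie, data=movie.data[i * seg_len : (i + 1) * seg_len])
        for i in range(n_segments)
    ]


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a single-frame 8-bit TIFF mask (0 = background) as boolean."""
    mask = np.asarray(tifffile.imread(path))
    if mask.ndim != 2:
        raise ValueError("mask must be a single 2-D frame")
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match frame shape {shape}")
    return mask > 0
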