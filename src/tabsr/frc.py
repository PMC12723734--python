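"""Fourier ring correlation (FRC) resolution estimation.

Localizations are randomly halved into two statistically independent
subsets; each half is rendered as a raw 5 nm 2-D histogram (no smoothing
kernel, which would bias the correlation), and the normalized correlation
between the two Fourier transforms is computed over concentric rings of
spatial frequency:

    FRC(r_i) = Re sum_{r in r_i} F1(r) F2*(r)
               / sqrt( sum |F1|^2 * sum |F2|^2 ).

The effective image resolution is the inverse of the frequency where the
curve first drops below the fixed 1/7 threshold (located by linear
interpolation between neighboring rings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paint import LocalizationTable, histogram_image

__all__ = [
    "FRCCurve",
    "split_localizations",
    "frc_curve",
    "resolution_from_frc",
    "frc_resolution",
    "FRC_THRESHOLD",
]

logger = logging.getLogger(__name__)

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCCurve:
    """Ring-wise correlation vs spatial frequency (cycles/nm)."""

    spatial_freq_per_nm: np.ndarray
    frc: np.ndarray
    ring_width_per_nm: float
    resolution_nm: float | None = None

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"freq_per_nm": self.spatial_freq_per_nm, "frc": self.frc}
        ).to_csv(path, index=False)


def split_localizations(
    table: LocalizationTable, seed: int | np.random.Generator = 0
) -> tuple[LocalizationTable, LocalizationTable]:
    """Assign each localization independently to one of two half-data sets
    with probability 1/2 (disjoint and exhaustive; seeded)."""
    if len(table) < 2:
        raise ValueError("need at least 2 localizations to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pick = rng.random(len(table)) < 0.5
    make = lambda sel: LocalizationTable(
        table.df[sel].reset_index(drop=True), table.pixel_size_nm, table.frame_time_ms
    )
    return make(pick), make(~pick)


def frc_curve(img1: np.ndarray, img2: np.ndarray, bin_nm: float = 5.0) -> FRCCurve:
    """Ring-wise normalized cross-spectrum of two equal-shape square images.

    Ring width is one discrete frequency step, 1 / (N * bin_nm). Rings in
    which either image has no power are undefined (NaN). The real part of
    the complex numerator is taken (standard FRC convention).
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must have equal shape")
    if img1.ndim != 2 or img1.shape[0] != img1.shape[1]:
        raise ValueError("images must be square 2-D arrays")
    n = img1.shape[0]
    f1 = np.fft.fft2(img1)
    f2 = np.fft.fft2(img2)
    ix = np.fft.fftfreq(n, d=1.0 / n)  # integer frequency index
    ring = np.round(np.sqrt(ix[:, None] ** 2 + ix[None, :] ** 2)).astype(int)
    n_rings = n // 2 + 1
    sel = ring < n_rings
    ring_flat = ring[sel]
    num = np.bincount(ring_flat, weights=(f1 * np.conj(f2)).real[sel], minlength=n_rings)
    p1 = np.bincount(ring_flat, weights=(np.abs(f1) ** 2)[sel], minlength=n_rings)
    p2 = np.bincount(ring_flat, weights=(np.abs(f2) ** 2)[sel], minlength=n_rings)
    with np.errstate(divide="ignore", invalid="ignore"):
        frc = num / np.sqrt(p1 * p2)
    undefined = (p1 == 0) | (p2 == 0)
    if undefined.any():
        logger.info("%d rings with zero power flagged undefined", int(undefined.sum()))
        frc[undefined] = np.nan
    df = 1.0 / (n * bin_nm)
    freqs = np.arange(n_rings) * df
    return FRCCurve(spatial_freq_per_nm=freqs, frc=frc, ring_width_per_nm=df)


def resolution_from_frc(curve: FRCCurve, threshold: float = FRC_THRESHOLD) -> float | None:
    """Resolution (nm) = 1 / frequency of the first crossing below threshold.

    The crossing is located by linear interpolation of the FRC between the
    last ring above and the first ring below the threshold. Returns None
    (with a log message) if the curve never crosses.
    """
    freqs = curve.spatial_freq_per_nm
    frc = curve.frc
    defined = np.isfinite(frc)
    below = np.nonzero(defined & (frc < threshold))[0]
    # ignore the r = 0 ring itself as a "crossing"
    below = below[below > 0]
    if below.size == 0:
        logger.warning("FRC never crosses %.4f; resolution undefined", threshold)
        return None
    i = below[0]
    # previous defined ring above the threshold
    j_candidates = np.nonzero(defined[:i])[0]
    if j_candidates.size == 0:
        return float(1.0 / freqs[i])
    j = j_candidates[-1]
    f_lo, f_hi = freqs[j], freqs[i]
    v_lo, v_hi = frc[j], frc[i]
    if v_lo == v_hi:
        f_cross = f_hi
    else:
        f_cross = f_lo + (f_hi - f_lo) * (v_lo - threshold) / (v_lo - v_hi)
    return float(1.0 / f_cross)


def frc_resolution(
    table: LocalizationTable,
    fov_nm: tuple[float, float],
    bin_nm: float = 5.0,
    threshold: float = FRC_THRESHOLD,
    seed: int | np.random.Generator = 0,
) -> tuple[float | None, FRCCurve]:
    """End-to-end FRC: split localizations, histogram both halves, correlate.

    Returns (resolution_nm or None, curve)."""
    half1, half2 = split_localizations(table, seed)
    img1 = histogram_image(half1, fov_nm, bin_nm)
    img2 = histogram_image(half2, fov_nm, bin_nm)
    curve = frc_curve(img1, img2, bin_nm)
    res = resolution_from_frc(curve, threshold)
    curve.resolution_nm = res
    return res, curve
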