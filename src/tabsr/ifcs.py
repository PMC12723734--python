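"""Pixel-wise imaging fluorescence correlation spectroscopy (iFCS).

For every camera pixel the normalized temporal autocorrelation

    G(tau; x, y) = < dI(t) dI(t+tau) >_t / < I(t) >_t^2

is computed per movie segment, averaged across segments (uncertainty =
standard error of the mean per lag), and fit by weighted least squares with
a two-component binding model

    G(tau) = G0 (1 - ff + ff e^{-tau/tau_fast})
                (1 - fs + fs e^{-tau/tau_slow}) + Ginf

whose relaxation times reflect dye residence on the fibril (and possibly
photophysical blinking, which this analysis cannot distinguish). A
one-component model is the ff = 1, fs = 0 reduction. Models are compared by
reduced chi-squared, and per-pixel results are assembled into spatial
parameter maps gated by ACF signal-to-noise (amplitude over the scatter of
the last five lags; pixels with SNR <= 10 are masked).

The autocorrelation numerator is computed by the SOFI module's cumulant
routines, making the shared-computation identity between the two stages
exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import sofi
from .movie import Movie, split_segments

__all__ = [
    "ACFRecord",
    "ACFStack",
    "FitResult",
    "ParameterMaps",
    "make_lag_grid",
    "pixel_acf",
    "average_segments",
    "segmented_acf",
    "estimate_snr",
    "acf_model",
    "fit_acf",
    "fit_all_pixels",
    "build_maps",
]

logger = logging.getLogger(__name__)

SNR_GATE_DEFAULT = 10.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class ACFRecord:
    """Segment-averaged autocorrelation for a single pixel."""

    pixel: tuple[int, int]
    lags_ms: np.ndarray
    G: np.ndarray
    sem: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.diff(self.lags_ms) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not (len(self.lags_ms) == len(self.G) == len(self.sem)):
            raise ValueError("lags, G and sem must have equal length")


@dataclass
class ACFStack:
    """Segment-averaged ACFs for every pixel of a movie."""

    lags_ms: np.ndarray          # (n_lags,)
    G: np.ndarray                # (n_lags, rows, cols), NaN where undefined
    sem: np.ndarray              # (n_lags, rows, cols)
    n_segments: int
    valid: np.ndarray            # (rows, cols) bool; False for zero-mean traces
    frame_time_ms: float
    pixel_size_nm: float

    def record(self, row: int, col: int) -> ACFRecord:
        return ACFRecord(
            pixel=(row, col),
            lags_ms=self.lags_ms,
            G=self.G[:, row, col],
            sem=self.sem[:, row, col],
            n_segments=self.n_segments,
        )


@dataclass
class FitResult:
    """Binding-model fit for one pixel's ACF. tau_fast <= tau_slow always
    (components are relabeled after the fit if needed)."""

    G0: float
    tau_fast_ms: float
    tau_slow_ms: float
    f_fast: float
    f_slow: float
    G_inf: float
    reduced_chi2: float
    snr: float
    converged: bool
    model: str = "two_component"
    message: str = ""

    def __post_init__(self) -> None:
        if self.tau_fast_ms > self.tau_slow_ms:
            self.tau_fast_ms, self.tau_slow_ms = self.tau_slow_ms, self.tau_fast_ms
            self.f_fast, self.f_slow = self.f_slow, self.f_fast

    @property
    def fast_weight_fraction(self) -> float:
        """Fraction of bound molecules on the shorter relaxation time,
        f_fast / (f_fast + f_slow)."""
        denom = self.f_fast + self.f_slow
        return float(self.f_fast / denom) if denom > 0 else np.nan


@dataclass
class ParameterMaps:
    """Per-pixel rasters of fitted parameters; gated pixels are NaN with
    ``valid`` False (never silently zero)."""

    tau_fast_ms: np.ndarray
    tau_slow_ms: np.ndarray
    fast_weight_fraction: np.ndarray
    G0: np.ndarray
    snr: np.ndarray
    valid: np.ndarray


# ---------------------------------------------------------------------------
# autocorrelation


def make_lag_grid(
    n_frames: int,
    max_lag: int | None = None,
    points_per_decade: int = 16,
    linear_until: int = 16,
) -> np.ndarray:
    """Quasi-logarithmic integer lag grid: every lag up to ``linear_until``,
    then ~16 per decade up to ``max_lag`` (default n_frames // 4)."""
    if max_lag is None:
        max_lag = max(2, n_frames // 4)
    max_lag = min(max_lag, n_frames - 1)
    lin = np.arange(1, min(linear_until, max_lag) + 1)
    if max_lag <= linear_until:
        return lin
    n_log = int(np.ceil(np.log10(max_lag / linear_until) * points_per_decade))
    log = np.unique(
        np.round(
            linear_until * (max_lag / linear_until) ** (np.arange(1, n_log + 1) / n_log)
        ).astype(int)
    )
    return np.unique(np.concatenate([lin, log]))


def pixel_acf(
    segment: Movie, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized per-pixel autocorrelation of one segment.

    Returns (lags_ms, G, valid) where G has shape (n_lags, rows, cols).
    The numerator is the SOFI second-order cumulant (shared computation);
    the denominator is the squared temporal mean. Pixels with zero mean
    have undefined G and are flagged invalid (NaN).
    """
    lags = np.asarray(lags, dtype=int)
    if lags.max() >= segment.n_frames:
        raise ValueError("max lag must be < segment frame count")
    cov = sofi.lagged_covariance(segment.data, lags)
    mean_img = segment.data.mean(axis=0, dtype=np.float64)
    valid = mean_img > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = cov / mean_img**2
    g[:, ~valid] = np.nan
    return lags * segment.frame_time_ms, g, valid


def average_segments(
    per_segment_G: list[np.ndarray],
    lags_ms: np.ndarray,
    frame_time_ms: float,
    pixel_size_nm: float,
) -> ACFStack:
    """Mean and SEM across segments at each lag, per pixel."""
    if len(per_segment_G) < 1:
        raise ValueError("need at least one segment")
    stack = np.stack(per_segment_G)  # (n_seg, n_lags, rows, cols)
    n_seg = stack.shape[0]
    mean = stack.mean(axis=0)
    if n_seg >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n_seg)
    else:
        logger.warning("single segment: SEM undefined, flagged as NaN")
        sem = np.full_like(mean, np.nan)
    valid = np.all(np.isfinite(mean), axis=0)
    return ACFStack(
        lags_ms=np.asarray(lags_ms, dtype=float),
        G=mean,
        sem=sem,
        n_segments=n_seg,
        valid=valid,
        frame_time_ms=frame_time_ms,
        pixel_size_nm=pixel_size_nm,
    )


def segmented_acf(
    movie: Movie,
    n_segments: int = 6,
    lags: np.ndarray | None = None,
) -> ACFStack:
    """Segment-averaged ACF of a full movie (the standard iFCS pipeline:
    split into segments, correlate each, average with SEM)."""
    segments = split_segments(movie, n_segments)
    seg_len = segments[0].n_frames
    if lags is None:
        lags = make_lag_grid(seg_len)
    per_seg = []
    lags_ms = None
    for seg in segments:
        lags_ms, g, _ = pixel_acf(seg, lags)
        per_seg.append(g)
    return average_segments(per_seg, lags_ms, movie.frame_time_ms, movie.pixel_size_nm)


# ---------------------------------------------------------------------------
# SNR and model fitting


def estimate_snr(acf: ACFRecord, n_amplitude_lags: int = 3, n_tail_lags: int = 5) -> float:
    """ACF amplitude / std of the last five lags.

    Amplitude is the mean of G over the first ``n_amplitude_lags`` nonzero
    lags of the averaged curve (a pre-fit quantity, so gating can precede
    fitting). A zero tail std yields +inf.
    """
    if len(acf.G) < n_amplitude_lags + n_tail_lags:
        raise ValueError("need at least amplitude + tail lags for SNR")
    amplitude = float(np.mean(acf.G[:n_amplitude_lags]))
    tail_std = float(np.std(acf.G[-n_tail_lags:]))
    if amplitude <= 0:
        return 0.0
    if tail_std == 0:
        logger.info("pixel %s: zero tail std, SNR = inf", acf.pixel)
        return np.inf
    return amplitude / tail_std


def acf_model(
    lags_ms: np.ndarray,
    G0: float,
    tau_fast_ms: float,
    tau_slow_ms: float,
    f_fast: float,
    f_slow: float,
    G_inf: float,
) -> np.ndarray:
    """Product-form two-component binding model."""
    t = np.asarray(lags_ms, dtype=float)
    fast = 1.0 - f_fast + f_fast * np.exp(-t / tau_fast_ms)
    slow = 1.0 - f_slow + f_slow * np.exp(-t / tau_slow_ms)
    return G0 * fast * slow + G_inf


def _initial_taus(lags_ms: np.ndarray, g: np.ndarray, amplitude: float) -> tuple[float, float]:
    """Heuristic time constants from the 70% / 30% amplitude crossings."""

    def crossing(level: float, default: float) -> float:
        below = np.nonzero(g < level * amplitude)[0]
        return float(lags_ms[below[0]]) if below.size else default

    tau_f = crossing(0.7, lags_ms[len(lags_ms) // 4])
    tau_s = crossing(0.3, lags_ms[-1] / 2)
    if tau_s <= tau_f:
        tau_s = 10.0 * tau_f
    return tau_f, tau_s


def fit_acf(
    acf: ACFRecord,
    model: str = "two_component",
    sem_floor_frac: float = 1e-6,
    max_nfev: int = 2000,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Weighted least-squares fit of the binding model to one pixel's ACF.

    Weights are 1/SEM^2 with SEM floored at ``sem_floor_frac`` x max|G| to
    avoid infinite weights; reduced chi2 = sum(weighted resid^2)/(n - p).
    Bounds: tau in [frame time, span of lags], fractions in [0, 1]. On
    non-convergence up to ``n_restarts`` jittered restarts are attempted.
    """
    lags = acf.lags_ms
    g = acf.G
    ok = np.isfinite(g)
    n_params = 6 if model == "two_component" else 3
    if ok.sum() < n_params + 2:
        return _failed_fit(acf, model, "too few finite lags")
    lags, g = lags[ok], g[ok]
    sem = acf.sem[ok]
    if not np.all(np.isfinite(sem)):
        sem = np.full_like(g, max(np.std(g), 1e-12))  # unweighted fallback
    floor = sem_floor_frac * max(np.max(np.abs(g)), 1e-300)
    sem = np.maximum(sem, floor)

    snr = estimate_snr(acf) if len(acf.G) >= 8 else np.nan
    amplitude = float(np.mean(g[:3]))
    tau_f0, tau_s0 = _initial_taus(lags, g, amplitude)
    tau_lo, tau_hi = acf.lags_ms[0], float(lags[-1]) * 4

    if model == "two_component":
        def resid(p):
            return (acf_model(lags, p[0], p[1], p[2], p[3], p[4], p[5]) - g) / sem

        x0 = np.array([max(amplitude, 1e-6), tau_f0, tau_s0, 0.5, 0.5, 0.0])
        lo = np.array([0.0, tau_lo, tau_lo, 0.0, 0.0, -np.inf])
        hi = np.array([np.inf, tau_hi, tau_hi, 1.0, 1.0, np.inf])
    elif model == "one_component":
        def resid(p):
            return (p[0] * np.exp(-lags / p[1]) + p[2] - g) / sem

        x0 = np.array([max(amplitude, 1e-6), np.sqrt(tau_f0 * tau_s0), 0.0])
        lo = np.array([0.0, tau_lo, -np.inf])
        hi = np.array([np.inf, tau_hi, np.inf])
    else:
        raise ValueError("model must be 'one_component' or 'two_component'")

    rng = rng or np.random.default_rng(0)
    best = None
    start = np.clip(x0, lo, np.minimum(hi, 1e300))
    for attempt in range(n_restarts + 1):
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - numerical edge
            sol = None
            message = str(exc)
        else:
            message = sol.message
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.success:
                break
        # jittered restart
        jitter = rng.uniform(0.5, 2.0, size=x0.size)
        start = np.clip(x0 * jitter, lo, np.minimum(hi, 1e300))

    if best is None:
        return _failed_fit(acf, model, message, snr=snr)
    p = best.x
    dof = max(1, len(g) - n_params)
    red_chi2 = float(2 * best.cost / dof)  # cost = 0.5 * sum(resid^2)
    # a relaxation time pinned at a bound is unidentifiable, not a fit
    tau_idx = (1, 2) if model == "two_component" else (1,)
    taus_free = all(
        p[i] > tau_lo * 1.01 and p[i] < tau_hi * 0.99 for i in tau_idx
    )
    success = bool(best.success) and taus_free
    if model == "two_component":
        return FitResult(
            G0=float(p[0]), tau_fast_ms=float(p[1]), tau_slow_ms=float(p[2]),
            f_fast=float(p[3]), f_slow=float(p[4]), G_inf=float(p[5]),
            reduced_chi2=red_chi2, snr=float(snr), converged=success,
            model=model, message=best.message,
        )
    return FitResult(
        G0=float(p[0]), tau_fast_ms=float(p[1]), tau_slow_ms=float(p[1]),
        f_fast=1.0, f_slow=0.0, G_inf=float(p[2]),
        reduced_chi2=red_chi2, snr=float(snr), converged=success,
        model=model, message=best.message,
    )


def _failed_fit(acf: ACFRecord, model: str, message: str, snr: float = np.nan) -> FitResult:
    return FitResult(
        G0=np.nan, tau_fast_ms=np.nan, tau_slow_ms=np.nan, f_fast=np.nan,
        f_slow=np.nan, G_inf=np.nan, reduced_chi2=np.nan,
        snr=float(snr), converged=False, model=model, message=message,
    )


def fit_all_pixels(
    stack: ACFStack,
    model: str = "two_component",
    snr_gate: float = SNR_GATE_DEFAULT,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit every SNR-gated pixel; returns a tidy per-pixel table.

    Gating is strict (SNR > gate): the gate is applied before fitting, so
    pixels below it are never fit. An optional boolean mask restricts the
    pixels considered (e.g. a cell/ROI mask).
    """
    rows, cols = stack.G.shape[1:]
    records = []
    rng = np.random.default_rng(12345)
    for r in range(rows):
        for c in range(cols):
            if mask is not None and not mask[r, c]:
                continue
            if not stack.valid[r, c]:
                continue
            rec = stack.record(r, c)
            snr = estimate_snr(rec)
            if not snr > snr_gate:
                continue
            fit = fit_acf(rec, model=model, rng=rng)
            records.append(
                {
                    "row": r, "col": c, "snr": snr,
                    "G0": fit.G0, "tau_fast_ms": fit.tau_fast_ms,
                    "tau_slow_ms": fit.tau_slow_ms, "f_fast": fit.f_fast,
                    "f_slow": fit.f_slow, "G_inf": fit.G_inf,
                    "fast_weight_fraction": fit.fast_weight_fraction,
                    "reduced_chi2": fit.reduced_chi2,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(records)


def build_maps(
    fits: pd.DataFrame,
    shape: tuple[int, int],
    snr_gate: float = SNR_GATE_DEFAULT,
) -> ParameterMaps:
    """Assemble spatial maps from per-pixel fits.

    Pixels absent from the table, below the SNR gate, or whose fit failed
    to converge are invalid: NaN values and ``valid`` False.
    """
    maps = {
        name: np.full(shape, np.nan)
        for name in ("tau_fast_ms", "tau_slow_ms", "fast_weight_fraction", "G0", "snr")
    }
    valid = np.zeros(shape, dtype=bool)
    for rec in fits.itertuples():
        r, c = int(rec.row), int(rec.col)
        maps["snr"][r, c] = rec.snr
        if not (rec.snr > snr_gate and rec.converged):
            continue
        maps["tau_fast_ms"][r, c] = rec.tau_fast_ms
        maps["tau_slow_ms"][r, c] = rec.tau_slow_ms
        maps["fast_weight_fraction"][r, c] = rec.fast_weight_fraction
        maps["G0"][r, c] = rec.G0
        valid[r, c] = True
    return ParameterMaps(
        tau_fast_ms=maps["tau_fast_ms"],
        tau_slow_ms=maps["tau_slow_ms"],
        fast_weight_fraction=maps["fast_weight_fraction"],
        G0=maps["G0"],
        snr=maps["snr"],
        valid=valid,
    )
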