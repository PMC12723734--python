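"""Single-molecule localization of transient binding events (PAINT).

Each movie frame is filtered with a Laplacian-of-Gaussian (sigma = 1.5 px),
candidates are local maxima above three standard deviations of the filtered
frame, and each candidate sub-image is fit with a 2-D Gaussian PSF to give
a subpixel position and photon count. Localizations accumulate into a
density map (5 nm histogram bins convolved with a sigma = 25 nm Gaussian
kernel). Consecutive-frame detections of the same molecule are linked
(nearest neighbor, no gap closing) into apparent "on"-time runs, whose
histogram is fit by one- or two-exponential decays to estimate apparent
binding times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import ndimage
from scipy.optimize import least_squares

from .movie import Movie

__all__ = [
    "Localization",
    "LocalizationTable",
    "OnTimeDistribution",
    "log_filter",
    "detect_candidates",
    "fit_gaussian2d",
    "localize_movie",
    "filter_localizations",
    "reconstruct",
    "link_on_times",
    "fit_on_time_decay",
    "measure_profile_width",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("frame", "x_nm", "y_nm", "photons", "sigma_nm", "residual")


@dataclass
class Localization:
    frame: int
    x_nm: float
    y_nm: float
    photons: float
    psf_sigma_fit_nm: float
    fit_ok: bool
    residual_norm: float


@dataclass
class LocalizationTable:
    """Per-molecule records, sorted by frame, plus source metadata."""

    df: pd.DataFrame
    pixel_size_nm: float
    frame_time_ms: float

    def __post_init__(self) -> None:
        self.df = self.df.sort_values("frame", kind="stable", ignore_index=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        out = self.df.rename(columns={"psf_sigma_fit_nm": "sigma_nm", "residual_norm": "residual"})
        out[list(CSV_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_nm: float, frame_time_ms: float) -> "LocalizationTable":
        df = pd.read_csv(path).rename(
            columns={"sigma_nm": "psf_sigma_fit_nm", "residual": "residual_norm"}
        )
        df["fit_ok"] = True
        return cls(df, pixel_size_nm, frame_time_ms)


@dataclass
class OnTimeDistribution:
    """Histogram of consecutive-frame on-run lengths k = 1, 2, ..."""

    counts: np.ndarray  # counts[k-1] = number of runs of length k
    frame_time_ms: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def run_lengths(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    def mean_frames(self) -> float:
        n = self.counts.sum()
        return float((self.run_lengths * self.counts).sum() / n) if n else np.nan


# ---------------------------------------------------------------------------
# detection


def log_filter(frame: np.ndarray, sigma_px: float = 1.5) -> np.ndarray:
    """Negated Laplacian-of-Gaussian response: bright spots -> positive peaks."""
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    # mean subtraction cancels the truncated kernel's constant-offset residue
    return -ndimage.gaussian_laplace(frame - frame.mean(), sigma_px)


def detect_candidates(
    filtered: np.ndarray,
    k: float = 3.0,
    dedup_radius_px: float = 3.0,
) -> np.ndarray:
    """Local maxima of the filtered frame above k x std(filtered frame).

    The std is taken over the whole filtered frame, signal pixels included
    (mild threshold inflation in dense frames is accepted). 8-connected
    local maxima within ``dedup_radius_px`` of a brighter maximum are
    suppressed: one emitter, one candidate. Returns (n, 2) int array of
    (row, col).
    """
    thr = k * filtered.std()
    is_max = (filtered == ndimage.maximum_filter(filtered, size=3)) & (filtered > thr)
    coords = np.argwhere(is_max)
    if len(coords) < 2:
        return coords
    values = filtered[coords[:, 0], coords[:, 1]]
    order = np.argsort(values)[::-1]
    coords = coords[order]
    keep: list[int] = []
    for i, (r, c) in enumerate(coords):
        if all((r - coords[j, 0]) ** 2 + (c - coords[j, 1]) ** 2 > dedup_radius_px**2 for j in keep):
            keep.append(i)
    return coords[keep]


# ---------------------------------------------------------------------------
# 2-D Gaussian fitting


def _gauss2d_resid(p, rr, cc, z):
    amp, r0, c0, sig, off = p
    model = off + amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sig**2))
    return (model - z).ravel()


def fit_gaussian2d(
    subimage: np.ndarray,
    init: dict | None = None,
    pixel_size_nm: float = 92.0,
    frame: int = 0,
    origin_px: tuple[int, int] = (0, 0),
    sigma_bounds_px: tuple[float, float] = (0.4, 5.0),
) -> Localization:
    """Nonlinear least-squares 2-D Gaussian fit of a candidate sub-image.

    Fits amplitude, center, width and a constant offset; the photon count is
    the integrated volume 2*pi*amp*sigma^2. ``origin_px`` locates the
    sub-image's (0, 0) pixel in the full frame so positions come back in
    absolute nm. ``fit_ok`` is False on non-convergence, a center outside
    the window, or a width at/outside the bounds (degenerate fits such as a
    flat sub-image land there).
    """
    z = np.asarray(subimage, dtype=np.float64)
    nr, nc = z.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    init = init or {}
    off0 = float(np.percentile(z, 20))
    amp0 = float(init.get("amplitude", max(z.max() - off0, 1e-9)))
    r0 = float(init.get("row", (nr - 1) / 2))
    c0 = float(init.get("col", (nc - 1) / 2))
    sig0 = float(init.get("sigma_px", max(1.0, nr / 6)))
    p0 = [amp0, r0, c0, sig0, off0]
    lo = [0.0, -1.0, -1.0, sigma_bounds_px[0], -np.inf]
    hi = [np.inf, nr, nc, sigma_bounds_px[1], np.inf]

    bad = Localization(frame, np.nan, np.nan, np.nan, np.nan, False, np.nan)
    if z.max() - z.min() <= 0:
        return bad
    try:
        sol = least_squares(
            _gauss2d_resid, p0, args=(rr, cc, z), bounds=(lo, hi), max_nfev=400
        )
    except Exception:
        return bad
    amp, rf, cf, sig, off = sol.x
    ok = (
        sol.success
        and 0 <= rf <= nr - 1
        and 0 <= cf <= nc - 1
        and sigma_bounds_px[0] * 1.001 < sig < sigma_bounds_px[1] * 0.999
        and amp > 0
    )
    resid_rms = float(np.sqrt(np.mean(sol.fun**2)))
    scale = max(amp, 1e-12)
    return Localization(
        frame=frame,
        x_nm=(origin_px[1] + cf + 0.5) * pixel_size_nm,
        y_nm=(origin_px[0] + rf + 0.5) * pixel_size_nm,
        photons=float(2 * np.pi * amp * sig**2),
        psf_sigma_fit_nm=float(sig * pixel_size_nm),
        fit_ok=bool(ok),
        residual_norm=resid_rms / scale,
    )


def localize_movie(
    movie: Movie,
    log_sigma_px: float = 1.5,
    threshold_k: float = 3.0,
    psf_sigma_px: float = 1.3,
    keep_failed: bool = False,
) -> LocalizationTable:
    """Frame-by-frame detection + subpixel localization.

    Fit windows have side 2*ceil(3*psf_sigma_px) + 1; candidates whose
    window would be clipped by the frame edge are discarded (counted in the
    log). Failed fits are dropped unless ``keep_failed``.
    """
    half = int(np.ceil(3 * psf_sigma_px))
    n_rows, n_cols = movie.shape[1:]
    records = []
    n_edge = n_fail = 0
    for t in range(movie.n_frames):
        frame = movie.data[t]
        filt = log_filter(frame, log_sigma_px)
        for r, c in detect_candidates(filt, threshold_k, dedup_radius_px=2 * log_sigma_px):
            if not (half <= r < n_rows - half and half <= c < n_cols - half):
                n_edge += 1
                continue
            sub = frame[r - half : r + half + 1, c - half : c + half + 1]
            loc = fit_gaussian2d(
                sub,
                init={"sigma_px": psf_sigma_px},
                pixel_size_nm=movie.pixel_size_nm,
                frame=t,
                origin_px=(r - half, c - half),
            )
            if loc.fit_ok or keep_failed:
                records.append(vars(loc))
            else:
                n_fail += 1
    logger.info(
        "localized %d molecules (%d edge-clipped, %d failed fits discarded)",
        len(records), n_edge, n_fail,
    )
    cols = ["frame", "x_nm", "y_nm", "photons", "psf_sigma_fit_nm", "fit_ok", "residual_norm"]
    df = pd.DataFrame(records, columns=cols)
    return LocalizationTable(df, movie.pixel_size_nm, movie.frame_time_ms)


def filter_localizations(
    table: LocalizationTable,
    sigma_bounds_nm: tuple[float, float] = (40.0, 250.0),
    min_photons: float = 0.0,
    max_residual: float = np.inf,
) -> LocalizationTable:
    """Quality filter: PSF-width window, minimum photons, maximum residual."""
    df = table.df
    keep = (
        df["psf_sigma_fit_nm"].between(*sigma_bounds_nm)
        & (df["photons"] >= min_photons)
        & (df["residual_norm"] <= max_residual)
        & df["fit_ok"]
    )
    logger.info("filter_localizations: kept %d / %d", int(keep.sum()), len(df))
    return LocalizationTable(df[keep].reset_index(drop=True), table.pixel_size_nm, table.frame_time_ms)


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct(
    table: LocalizationTable,
    fov_nm: tuple[float, float],
    bin_nm: float = 5.0,
    kernel_sigma_nm: float = 25.0,
) -> tuple[np.ndarray, float]:
    """Super-resolved density map: 2-D histogram blurred by a Gaussian.

    Returns (image, bin_nm); image rows follow y, columns follow x, and its
    total mass equals the localization count (up to kernel truncation at
    the FOV edge). Empty tables are an error.
    """
    if len(table) == 0:
        raise ValueError("cannot reconstruct from an empty localization table")
    h_nm, w_nm = fov_nm
    n_rows = int(np.ceil(h_nm / bin_nm))
    n_cols = int(np.ceil(w_nm / bin_nm))
    hist, _, _ = np.histogram2d(
        table.df["y_nm"], table.df["x_nm"],
        bins=(n_rows, n_cols), range=((0, n_rows * bin_nm), (0, n_cols * bin_nm)),
    )
    image = ndimage.gaussian_filter(hist, kernel_sigma_nm / bin_nm, mode="constant")
    return image, bin_nm


def histogram_image(
    table: LocalizationTable, fov_nm: tuple[float, float], bin_nm: float = 5.0
) -> np.ndarray:
    """Raw (unsmoothed) localization histogram, e.g. for ring correlation."""
    h_nm, w_nm = fov_nm
    n = int(np.ceil(max(h_nm, w_nm) / bin_nm))  # square grid
    hist, _, _ = np.histogram2d(
        table.df["y_nm"], table.df["x_nm"],
        bins=(n, n), range=((0, n * bin_nm), (0, n * bin_nm)),
    )
    return hist


# ---------------------------------------------------------------------------
# on-time analysis


def link_on_times(table: LocalizationTable, radius_nm: float = 92.0) -> OnTimeDistribution:
    """Greedy nearest-neighbor linking across consecutive frames.

    A molecule localized within ``radius_nm`` of a previous-frame
    localization continues that run; gaps are never closed, so a single
    missed frame splits a binding event into two runs (matching how
    apparent on-times are measured in practice). Run lengths in frames are
    histogrammed.
    """
    df = table.df
    run_lengths: list[int] = []
    active_xy = np.zeros((0, 2))
    active_len: list[int] = []
    prev_frame = None
    for frame, group in df.groupby("frame", sort=True):
        xy = group[["x_nm", "y_nm"]].to_numpy()
        if prev_frame is None or frame != prev_frame + 1 or len(active_xy) == 0:
            run_lengths.extend(active_len)
            active_xy, active_len = xy, [1] * len(xy)
        else:
            d2 = ((xy[:, None, :] - active_xy[None, :, :]) ** 2).sum(-1)
            pairs = sorted(
                ((d2[i, j], i, j) for i in range(len(xy)) for j in range(len(active_xy))
                 if d2[i, j] <= radius_nm**2)
            )
            used_i, used_j = set(), set()
            match = {}
            for _, i, j in pairs:
                if i not in used_i and j not in used_j:
                    match[i] = j
                    used_i.add(i)
                    used_j.add(j)
            new_xy, new_len = [], []
            for i in range(len(xy)):
                new_xy.append(xy[i])
                new_len.append(active_len[match[i]] + 1 if i in match else 1)
            run_lengths.extend(active_len[j] for j in range(len(active_xy)) if j not in used_j)
            active_xy = np.array(new_xy)
            active_len = new_len
        prev_frame = frame
    run_lengths.extend(active_len)
    if not run_lengths:
        return OnTimeDistribution(np.zeros(0, dtype=int), table.frame_time_ms)
    counts = np.bincount(run_lengths)[1:]
    return OnTimeDistribution(counts, table.frame_time_ms)


def _exp_decay(k, amplitude, tau_ms, frame_time_ms):
    return amplitude * np.exp(-k * frame_time_ms / tau_ms)


def fit_on_time_decay(
    dist: OnTimeDistribution,
    n_components: int = 2,
    exclude_first_bin: bool = False,
) -> dict:
    """Weighted LS fit of run-length counts with exponential decays.

    Model: counts(k) ~ sum_i A_i exp(-k dt / tau_i), Poisson weights
    (sigma_k = sqrt(max(counts_k, 1))). Returns tau values (ms, sorted
    ascending), amplitudes, and reduced chi2. The k = 1 bin mixes sub-frame
    events; it can optionally be excluded.
    """
    k = dist.run_lengths.astype(float)
    counts = dist.counts.astype(float)
    if exclude_first_bin:
        k, counts = k[1:], counts[1:]
    occupied = counts > 0
    min_bins = 5 if n_components == 2 else 3
    if occupied.sum() < min_bins:
        raise ValueError(
            f"need >= {min_bins} occupied bins for a {n_components}-component fit, "
            f"got {int(occupied.sum())}"
        )
    k, counts = k[occupied], counts[occupied]
    weights = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    dt = dist.frame_time_ms

    if n_components == 1:
        model = Model(_exp_decay, independent_vars=["k"])
        params = model.make_params(amplitude=counts[0] * np.e, tau_ms=dt, frame_time_ms=dt)
    else:
        model = Model(_exp_decay, prefix="fast_", independent_vars=["k"]) + Model(
            _exp_decay, prefix="slow_", independent_vars=["k"]
        )
        params = model.make_params(
            fast_amplitude=counts[0] * np.e, fast_tau_ms=dt * 0.5,
            slow_amplitude=counts[0] / 10, slow_tau_ms=dt * 3,
            fast_frame_time_ms=dt, slow_frame_time_ms=dt,
        )
    for name, par in params.items():
        if name.endswith("frame_time_ms"):
            par.vary = False
        elif name.endswith("tau_ms"):
            par.min = dt * 1e-3
            par.max = dt * len(dist.counts) * 100
        elif name.endswith("amplitude"):
            par.min = 0
    result = model.fit(counts, params, k=k, weights=weights)
    if not result.success:
        raise RuntimeError(f"on-time decay fit did not converge: {result.message}")
    if n_components == 1:
        taus = [result.params["tau_ms"].value]
        amps = [result.params["amplitude"].value]
    else:
        taus = [result.params["fast_tau_ms"].value, result.params["slow_tau_ms"].value]
        amps = [result.params["fast_amplitude"].value, result.params["slow_amplitude"].value]
        if taus[0] > taus[1]:
            taus, amps = taus[::-1], amps[::-1]
    return {
        "tau_ms": taus,
        "amplitudes": amps,
        "reduced_chi2": float(result.redchi),
        "n_components": n_components,
        "lmfit_result": result,
    }


# ---------------------------------------------------------------------------
# fibril width measurement


def _gauss1d(x, amplitude, center, sigma, offset):
    return offset + amplitude * np.exp(-((x - center) ** 2) / (2 * sigma**2))


def measure_profile_width(
    image: np.ndarray,
    line_nm: tuple[tuple[float, float], tuple[float, float]],
    half_width_px: int,
    pixel_size_nm: float,
    n_samples: int = 50,
) -> float:
    """Apparent width (Gaussian sigma, nm) of a linear structure.

    Samples intensity profiles perpendicular to the line at ``n_samples``
    points along it, averages them, and fits a 1-D Gaussian plus constant
    offset. ``line_nm`` gives the two endpoints ((x0, y0), (x1, y1)) in nm.
    """
    (x0, y0), (x1, y1) = line_nm
    p0 = np.array([x0, y0]) / pixel_size_nm - 0.5
    p1 = np.array([x1, y1]) / pixel_size_nm - 0.5
    direction = p1 - p0
    length = np.linalg.norm(direction)
    if length == 0:
        raise ValueError("line endpoints coincide")
    direction = direction / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(-half_width_px, half_width_px + 1, dtype=float)
    along = np.linspace(0, length, n_samples)
    # sample grid: (profile position, along-line position)
    pts = (
        p0[None, None, :]
        + along[None, :, None] * direction[None, None, :]
        + offsets[:, None, None] * normal[None, None, :]
    )
    # map_coordinates wants (row=y, col=x)
    samples = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [pts[..., 1], pts[..., 0]], order=1, mode="nearest"
    )
    profile = samples.mean(axis=1)
    if profile.max() - profile.min() <= 0:
        raise ValueError("flat profile: no structure to measure")
    x_nm = offsets * pixel_size_nm
    model = Model(_gauss1d)
    params = model.make_params(
        amplitude=profile.max() - profile.min(),
        center=x_nm[np.argmax(profile)],
        sigma=half_width_px * pixel_size_nm / 4,
        offset=profile.min(),
    )
    params["sigma"].min = pixel_size_nm / 10
    params["amplitude"].min = 0
    result = model.fit(profile, params, x=x_nm)
    if not result.success:
        raise RuntimeError(f"profile fit did not converge: {result.message}")
    return float(result.params["sigma"].value)
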