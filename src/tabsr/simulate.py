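"""Synthetic fluorescence movies of transient dye binding to fibrils.

Emulates fluorogenic-dye imaging of amyloid fibrils: a dye is dark in
solution and bright while bound to a fibril, so each binding event is a
localized burst of fluorescence. Fibril backbones are worm-like polylines
carrying discrete binding sites; each site receives Poisson-distributed
binding events whose dwell times follow a two-component exponential mixture
(a fast and a slow residence mode). Image formation uses an integrated 2-D
Gaussian PSF, Poisson shot noise on signal plus uniform background, and
optional Gaussian read noise.

Two acquisition regimes are provided as presets:

* ``paint_sofi_acquisition`` — 30 ms frames, 92 nm pixels, 10,000 frames,
  ~690 photons per molecule per frame (single-molecule regime).
* ``ifcs_acquisition`` — 2.5 ms frames, 46 nm pixels, 36,000 frames split
  into six 15 s segments for autocorrelation analysis; per-frame brightness
  scales with exposure (690 * 2.5/30 = 57.5 photons/frame).

Everything is driven by one master seed; geometry, kinetics and optics draw
from independently spawned sub-streams, so a GroundTruth plus its seed fully
determines the movie.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .movie import AcquisitionConfig, Movie

__all__ = [
    "FibrilField",
    "KineticsModel",
    "EventList",
    "OpticsCameraModel",
    "GroundTruth",
    "generate_fibril_field",
    "simulate_binding_events",
    "render_movie",
    "simulate_scenario",
    "expected_acf",
    "simulate_blinking_emitter",
    "paint_sofi_acquisition",
    "ifcs_acquisition",
    "default_kinetics",
    "default_optics",
]

SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FibrilField:
    """Fibril backbones and the discrete dye-binding sites along them."""

    segments: list[np.ndarray]  # each (n_i, 2) polyline vertices in nm (x, y)
    site_density_per_nm: float
    sites: np.ndarray  # (n_sites, 2) positions in nm
    fov_nm: tuple[float, float]  # (height, width)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def total_length_nm(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(seg, axis=0), axis=1).sum() for seg in self.segments)
        )


@dataclass
class KineticsModel:
    """Two-mode transient binding kinetics.

    ``f_fast`` is the probability that an individual binding event draws its
    dwell from the fast exponential. Note this event-count weight differs
    from the ACF's bound-fraction weight, which is residence-time weighted:
    f_fast_acf = f*tau_fast / (f*tau_fast + (1-f)*tau_slow).
    """

    arrival_rate_per_site_per_s: float
    tau_fast_ms: float
    tau_slow_ms: float
    f_fast: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_fast <= 1.0):
            raise ValueError("f_fast must be in [0, 1]")
        if self.tau_fast_ms >= self.tau_slow_ms:
            raise ValueError("tau_fast_ms must be < tau_slow_ms")
        if self.arrival_rate_per_site_per_s < 0:
            raise ValueError("arrival rate must be >= 0")

    @property
    def mean_dwell_ms(self) -> float:
        return self.f_fast * self.tau_fast_ms + (1 - self.f_fast) * self.tau_slow_ms

    @property
    def dwell_weighted_f_fast(self) -> float:
        """ACF (residence-time) weight of the fast component."""
        wf = self.f_fast * self.tau_fast_ms
        ws = (1 - self.f_fast) * self.tau_slow_ms
        return wf / (wf + ws)

    def mean_occupancy(self) -> float:
        """Mean number of bound molecules per site (M/G/inf)."""
        return self.arrival_rate_per_site_per_s * self.mean_dwell_ms / 1000.0


@dataclass
class EventList:
    """Binding events sorted by start time."""

    events: pd.DataFrame  # columns: site, x_nm, y_nm, t_on_ms, dwell_ms, photons_per_frame_mean

    COLUMNS = ("site", "x_nm", "y_nm", "t_on_ms", "dwell_ms", "photons_per_frame_mean")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        if len(self.events) and (self.events["dwell_ms"] <= 0).any():
            raise ValueError("dwell_ms must be > 0")
        self.events = self.events.sort_values("t_on_ms", ignore_index=True)

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventList":
        return cls(pd.read_csv(path))

    @classmethod
    def empty(cls) -> "EventList":
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cls.COLUMNS}))


@dataclass
class OpticsCameraModel:
    """PSF and camera parameters for image formation."""

    psf_sigma_nm: float = 120.0
    mean_photons_per_frame: float = 690.0
    brightness_cv: float = 0.55  # broad log-normal brightness spread (SD/mean)
    background_photons_per_pixel_per_frame: float = 2.0
    read_noise_e: float = 0.0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")


@dataclass
class GroundTruth:
    """Everything needed to reproduce a simulated movie and score recovery."""

    field: FibrilField | None
    kinetics: KineticsModel | None
    events: EventList
    optics: OpticsCameraModel
    acquisition: AcquisitionConfig
    seed: int

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(directory / "events.csv")
        meta = {
            "seed": self.seed,
            "optics": vars(self.optics),
            "acquisition": self.acquisition.to_dict(),
        }
        if self.kinetics is not None:
            meta["kinetics"] = vars(self.kinetics)
        if self.field is not None:
            meta["field"] = {
                "site_density_per_nm": self.field.site_density_per_nm,
                "fov_nm": list(self.field.fov_nm),
                "n_sites": self.field.n_sites,
            }
        (directory / "ground_truth.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# acquisition presets


def paint_sofi_acquisition(n_frames: int = 10_000, fov_px: tuple[int, int] = (64, 64)) -> AcquisitionConfig:
    """30 ms / 92 nm single-molecule (PAINT + SOFI) regime."""
    return AcquisitionConfig(exposure_ms=30.0, pixel_size_nm=92.0, n_frames=n_frames, fov_px=fov_px)


def ifcs_acquisition(n_frames: int = 36_000, fov_px: tuple[int, int] = (64, 64)) -> AcquisitionConfig:
    """2.5 ms / 46 nm high-temporal-resolution (iFCS + SOFI) regime."""
    return AcquisitionConfig(exposure_ms=2.5, pixel_size_nm=46.0, n_frames=n_frames, fov_px=fov_px)


def default_kinetics(
    arrival_rate_per_site_per_s: float = 1.1,
    tau_fast_ms: float = 23.0,
    tau_slow_ms: float = 482.0,
    f_fast: float = 0.95,
) -> KineticsModel:
    """Two-mode dwell kinetics with fast/slow residence times of 23/482 ms.

    The event-probability 0.95 puts comparable residence-time weight on both
    modes (dwell-weighted fast fraction ~= 0.49), so an autocorrelation
    analysis sees two components of similar amplitude.
    """
    return KineticsModel(arrival_rate_per_site_per_s, tau_fast_ms, tau_slow_ms, f_fast)


def default_optics(acq: AcquisitionConfig, **overrides) -> OpticsCameraModel:
    """Optics scaled to the acquisition: photon emission rate fixed at
    690 photons per 30 ms, background ~2 photons/px per 30 ms."""
    scale = acq.exposure_ms / 30.0
    params = dict(
        psf_sigma_nm=120.0,
        mean_photons_per_frame=690.0 * scale,
        brightness_cv=0.55,
        background_photons_per_pixel_per_frame=2.0 * scale,
        read_noise_e=0.0,
    )
    params.update(overrides)
    return OpticsCameraModel(**params)


# ---------------------------------------------------------------------------
# geometry


def generate_fibril_field(
    fov_nm: tuple[float, float],
    n_fibrils: int,
    persistence_nm: float = 2000.0,
    site_density_per_nm: float = 0.05,
    seed: int | np.random.Generator = 0,
    step_nm: float = 50.0,
    margin_frac: float = 0.1,
) -> FibrilField:
    """Lay down worm-like fibril backbones and sample binding sites.

    Backbones are discrete worm-like chains: heading angle diffuses with
    variance step/persistence per step, truncated at the FOV. Site counts
    are Poisson with mean (backbone length x density); site positions are
    uniform along arc length.
    """
    if fov_nm[0] <= 0 or fov_nm[1] <= 0:
        raise ValueError("FOV dimensions must be positive")
    if n_fibrils < 0:
        raise ValueError("n_fibrils must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = fov_nm
    segments: list[np.ndarray] = []
    for _ in range(n_fibrils):
        # start inside an interior margin, random heading, grow to FOV edge
        start = np.array(
            [rng.uniform(margin_frac * w, (1 - margin_frac) * w),
             rng.uniform(margin_frac * h, (1 - margin_frac) * h)]
        )
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.3, 0.9) * min(h, w)
        n_steps = max(2, int(round(length / step_nm)))
        pts = [start]
        for _ in range(n_steps):
            theta += rng.normal(0.0, np.sqrt(step_nm / persistence_nm))
            nxt = pts[-1] + step_nm * np.array([np.cos(theta), np.sin(theta)])
            if not (0 <= nxt[0] <= w and 0 <= nxt[1] <= h):
                break
            pts.append(nxt)
        if len(pts) >= 2:
            segments.append(np.array(pts))

    sites = []
    for seg in segments:
        deltas = np.diff(seg, axis=0)
        seglens = np.linalg.norm(deltas, axis=1)
        total = seglens.sum()
        n_sites = rng.poisson(total * site_density_per_nm)
        if n_sites == 0:
            continue
        arc = rng.uniform(0, total, n_sites)
        cum = np.concatenate([[0.0], np.cumsum(seglens)])
        idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seglens) - 1)
        frac = (arc - cum[idx]) / seglens[idx]
        sites.append(seg[idx] + frac[:, None] * deltas[idx])
    sites_arr = np.concatenate(sites, axis=0) if sites else np.zeros((0, 2))
    return FibrilField(
        segments=segments,
        site_density_per_nm=site_density_per_nm,
        sites=sites_arr,
        fov_nm=tuple(fov_nm),
    )


# ---------------------------------------------------------------------------
# kinetics


def simulate_binding_events(
    field: FibrilField,
    kinetics: KineticsModel,
    duration_ms: float,
    seed: int | np.random.Generator = 0,
    mean_photons_per_frame: float = 690.0,
    brightness_cv: float = 0.0,
) -> EventList:
    """Sample Poisson arrivals and mixture-exponential dwells per site.

    Each site receives arrivals at the stated rate; each event's dwell is
    exponential with mean tau_fast (probability f_fast) or tau_slow.
    Per-event mean brightness is log-normal with the given CV. Events at
    different sites may overlap freely (no excluded volume).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if field.n_sites == 0 or kinetics.arrival_rate_per_site_per_s == 0:
        return EventList.empty()

    rate_per_ms = kinetics.arrival_rate_per_site_per_s / 1000.0
    n_per_site = rng.poisson(rate_per_ms * duration_ms, size=field.n_sites)
    total = int(n_per_site.sum())
    if total == 0:
        return EventList.empty()
    site_idx = np.repeat(np.arange(field.n_sites), n_per_site)
    t_on = rng.uniform(0.0, duration_ms, total)
    fast = rng.random(total) < kinetics.f_fast
    dwell = np.where(
        fast,
        rng.exponential(kinetics.tau_fast_ms, total),
        rng.exponential(kinetics.tau_slow_ms, total),
    )
    if brightness_cv > 0:
        sigma = np.sqrt(np.log(1.0 + brightness_cv**2))
        mu = np.log(mean_photons_per_frame) - 0.5 * sigma**2
        brightness = rng.lognormal(mu, sigma, total)
    else:
        brightness = np.full(total, float(mean_photons_per_frame))
    events = pd.DataFrame(
        {
            "site": site_idx,
            "x_nm": field.sites[site_idx, 0],
            "y_nm": field.sites[site_idx, 1],
            "t_on_ms": t_on,
            "dwell_ms": dwell,
            "photons_per_frame_mean": brightness,
        }
    )
    return EventList(events)


# ---------------------------------------------------------------------------
# image formation


def integrated_gaussian_psf(
    x0_nm: float,
    y0_nm: float,
    sigma_nm: float,
    pixel_size_nm: float,
    rows: slice,
    cols: slice,
) -> np.ndarray:
    """Photon fraction per pixel for a unit-flux emitter at (x0, y0).

    Integrates the 2-D Gaussian over each pixel area (error-function form);
    x maps to columns, y to rows.
    """
    r = np.arange(rows.start, rows.stop)
    c = np.arange(cols.start, cols.stop)
    # pixel edges in nm
    ex = (np.concatenate([c, [cols.stop]]) * pixel_size_nm - x0_nm) / (SQRT2 * sigma_nm)
    ey = (np.concatenate([r, [rows.stop]]) * pixel_size_nm - y0_nm) / (SQRT2 * sigma_nm)
    fx = 0.5 * np.diff(erf(ex))
    fy = 0.5 * np.diff(erf(ey))
    return np.outer(fy, fx)


def render_movie(
    events: EventList,
    optics: OpticsCameraModel,
    acq: AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    psf_cutoff_sigmas: float = 5.0,
) -> Movie:
    """Render binding events into a photon-count movie.

    Each event contributes an integrated-Gaussian spot scaled by its
    brightness and by its fractional temporal overlap with each frame.
    With ``noise`` enabled, Poisson shot noise is applied to signal plus
    uniform background, then Gaussian read noise is added and the result
    clamped at zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_rows, n_cols = acq.fov_px
    px = acq.pixel_size_nm
    sigma_px = optics.psf_sigma_nm / px
    if sigma_px < 0.25:
        import warnings

        warnings.warn(
            f"PSF sigma ({optics.psf_sigma_nm} nm) is below 0.25 pixel; "
            "the PSF is undersampled",
            stacklevel=2,
        )
    dt = acq.exposure_ms
    n_frames = acq.n_frames
    signal = np.zeros((n_frames, n_rows, n_cols), dtype=np.float32)
    halo = int(np.ceil(psf_cutoff_sigmas * sigma_px))

    ev = events.events
    for x0, y0, t_on, dwell, bright in zip(
        ev["x_nm"].to_numpy(),
        ev["y_nm"].to_numpy(),
        ev["t_on_ms"].to_numpy(),
        ev["dwell_ms"].to_numpy(),
        ev["photons_per_frame_mean"].to_numpy(),
    ):
        f0 = max(0, int(np.floor(t_on / dt)))
        f1 = min(n_frames - 1, int(np.ceil((t_on + dwell) / dt)) - 1)
        if f1 < f0:
            continue
        frames = np.arange(f0, f1 + 1)
        overlap = (
            np.minimum((frames + 1) * dt, t_on + dwell) - np.maximum(frames * dt, t_on)
        ) / dt
        overlap = np.clip(overlap, 0.0, 1.0)
        cc = int(round(x0 / px - 0.5))
        rc = int(round(y0 / px - 0.5))
        rows = slice(max(0, rc - halo), min(n_rows, rc + halo + 1))
        cols = slice(max(0, cc - halo), min(n_cols, cc + halo + 1))
        if rows.start >= rows.stop or cols.start >= cols.stop:
            continue
        patch = integrated_gaussian_psf(x0, y0, optics.psf_sigma_nm, px, rows, cols)
        signal[f0 : f1 + 1, rows, cols] += (
            (bright * overlap)[:, None, None] * patch[None]
        ).astype(np.float32)

    if noise:
        bg = optics.background_photons_per_pixel_per_frame
        # chunk over frames to bound peak memory on long stacks
        chunk = max(1, int(2e7 // (n_rows * n_cols)))
        for i in range(0, n_frames, chunk):
            lam = signal[i : i + chunk].astype(np.float64) + bg
            block = rng.poisson(lam).astype(np.float32)
            if optics.read_noise_e > 0:
                block += rng.normal(0.0, optics.read_noise_e, block.shape).astype(
                    np.float32
                )
            signal[i : i + chunk] = np.maximum(block, 0.0)

    return Movie(
        data=signal,
        pixel_size_nm=px,
        frame_time_ms=dt,
        is_photons=True,
    )


def simulate_scenario(
    acq: AcquisitionConfig,
    kinetics: KineticsModel | None = None,
    optics: OpticsCameraModel | None = None,
    n_fibrils: int = 8,
    site_density_per_nm: float = 0.05,
    seed: int = 0,
    noise: bool = True,
) -> tuple[Movie, GroundTruth]:
    """End-to-end simulation: geometry -> events -> movie, fully seeded.

    The master seed spawns independent sub-streams for geometry, kinetics
    and optics so each stage is reproducible in isolation.
    """
    kinetics = kinetics or default_kinetics()
    optics = optics if optics is not None else default_optics(acq)
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_kin, rng_opt = (np.random.default_rng(s) for s in ss.spawn(3))
    fov_nm = (acq.fov_px[0] * acq.pixel_size_nm, acq.fov_px[1] * acq.pixel_size_nm)
    field = generate_fibril_field(
        fov_nm, n_fibrils, site_density_per_nm=site_density_per_nm, seed=rng_geom
    )
    events = simulate_binding_events(
        field,
        kinetics,
        duration_ms=acq.duration_ms,
        seed=rng_kin,
        mean_photons_per_frame=optics.mean_photons_per_frame,
        brightness_cv=optics.brightness_cv,
    )
    movie = render_movie(events, optics, acq, seed=rng_opt, noise=noise)
    truth = GroundTruth(
        field=field,
        kinetics=kinetics,
        events=events,
        optics=optics,
        acquisition=acq,
        seed=seed,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# reference ACF and the blinking-emitter scenario


def expected_acf(
    kinetics: KineticsModel,
    mean_occupancy: float,
    lags_ms: np.ndarray,
    G_inf: float = 0.0,
) -> np.ndarray:
    """Reference two-component autocorrelation for recovery tests.

    Product-form binding model with residence-time-weighted fractions
    ff = f tau_f / (f tau_f + (1-f) tau_s), fs = 1 - ff (the ACF weights
    each bound state by its residence time, not by how many events it
    contributes) and amplitude G0 = (1 - occ)/occ. The product of the two
    bracketed relaxation factors has a constant term (1-ff)(1-fs); that
    constant is folded into the offset so the curve obeys the standard
    limits G(0) = G0 + G_inf and G(inf) = G_inf, and reduces exactly to
    G0 exp(-tau/tau_fast) + G_inf when the slow fraction vanishes.
    """
    if not (0.0 < mean_occupancy < 1.0):
        raise ValueError("mean_occupancy must be in (0, 1)")
    lags_ms = np.asarray(lags_ms, dtype=float)
    ff = kinetics.dwell_weighted_f_fast
    fs = 1.0 - ff
    g0 = (1.0 - mean_occupancy) / mean_occupancy
    fast = 1.0 - ff + ff * np.exp(-lags_ms / kinetics.tau_fast_ms)
    slow = 1.0 - fs + fs * np.exp(-lags_ms / kinetics.tau_slow_ms)
    baseline = (1.0 - ff) * (1.0 - fs)
    return g0 * (fast * slow - baseline) / (1.0 - baseline) + G_inf


def simulate_blinking_emitter(
    n_frames: int = 5000,
    fov_px: tuple[int, int] = (64, 64),
    pixel_size_nm: float = 92.0,
    position_px: tuple[float, float] = (31.7, 32.4),
    p_on: float = 0.3,
    mean_on_frames: float = 3.0,
    psf_sigma_px: float = 1.3,
    photons_per_frame: float = 1000.0,
    background: float = 0.0,
    seed: int = 0,
    noise: bool = True,
) -> tuple[Movie, np.ndarray]:
    """One stationary emitter blinking as a two-state telegraph process.

    The on/off Markov chain has stationary on-probability ``p_on`` and mean
    on-dwell ``mean_on_frames`` frames. Returns the movie and the boolean
    on-state trace. This is the canonical scenario for measuring the
    sqrt(2) PSF narrowing of a second-order fluctuation image.
    """
    rng = np.random.default_rng(seed)
    p_off_given_on = 1.0 / mean_on_frames
    # stationary: p_on = p_on_given_off*(1-p_on_on... solve for switch-on rate
    p_on_given_off = p_off_given_on * p_on / (1.0 - p_on)
    if not (0 < p_on_given_off < 1):
        raise ValueError("inconsistent telegraph parameters")
    state = np.empty(n_frames, dtype=bool)
    state[0] = rng.random() < p_on
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        if state[t - 1]:
            state[t] = u[t] >= p_off_given_on
        else:
            state[t] = u[t] < p_on_given_off
    r0, c0 = position_px
    x0 = (c0 + 0.5) * pixel_size_nm
    y0 = (r0 + 0.5) * pixel_size_nm
    n_rows, n_cols = fov_px
    patch = integrated_gaussian_psf(
        x0, y0, psf_sigma_px * pixel_size_nm, pixel_size_nm,
        slice(0, n_rows), slice(0, n_cols),
    )
    lam = state[:, None, None] * (photons_per_frame * patch)[None] + background
    data = rng.poisson(lam).astype(np.float32) if noise else lam.astype(np.float32)
    movie = Movie(
        data=data, pixel_size_nm=pixel_size_nm, frame_time_ms=30.0, is_photons=True
    )
    return movie, state
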