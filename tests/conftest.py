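import numpy as np
import pytest

from tabsr import simulate
from tabsr.movie import Movie


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_movie(data, pixel_size_nm=92.0, frame_time_ms=30.0):
    return Movie(
        data=np.asarray(data, dtype=np.float64),
        pixel_size_nm=pixel_size_nm,
        frame_time_ms=frame_time_ms,
    )


@pytest.fixture(scope="session")
def blinking_movie():
    """Single telegraph-blinking emitter, the canonical SOFI scenario."""
    movie, state = simulate.simulate_blinking_emitter(n_frames=5000, seed=7)
    return movie, state


def isolated_site_movie(
    rate_per_s,
    seed=7,
    n_frames=30_000,
    fov_px=40,
    spacing_px=8,
    psf_sigma_nm=60.0,
    photons_per_frame=57.5,
    kinetics_kwargs=None,
):
    """Grid of isolated binding sites, noise- and background-free.

    Averaging the per-site-pixel ACFs gives a clean estimate of the binding
    autocorrelation for comparison against the analytic two-component model.
    """
    acq = simulate.ifcs_acquisition(n_frames=n_frames, fov_px=(fov_px, fov_px))
    px = acq.pixel_size_nm
    centers = [
        (r, c)
        for r in range(spacing_px // 2, fov_px, spacing_px)
        for c in range(spacing_px // 2, fov_px, spacing_px)
    ]
    sites = np.array([[(c + 0.5) * px, (r + 0.5) * px] for r, c in centers])
    field = simulate.FibrilField(
        segments=[], site_density_per_nm=0.0, sites=sites, fov_nm=(fov_px * px, fov_px * px)
    )
    kin = simulate.default_kinetics(
        arrival_rate_per_site_per_s=rate_per_s, **(kinetics_kwargs or {})
    )
    events = simulate.simulate_binding_events(
        field, kin, acq.duration_ms, seed=seed, mean_photons_per_frame=photons_per_frame
    )
    optics = simulate.OpticsCameraModel(
        psf_sigma_nm=psf_sigma_nm, background_photons_per_pixel_per_frame=0.0
    )
    movie = simulate.render_movie(events, optics, acq, seed=seed, noise=False)
    return movie, kin, centers
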