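import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tabsr import paint, simulate
from tabsr.movie import AcquisitionConfig
from tabsr.simulate import integrated_gaussian_psf

PX = 92.0


def loc_table(rows, pixel_size_nm=PX, frame_time_ms=30.0):
    """LocalizationTable from (frame, x_nm, y_nm) triples."""
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
    df["photons"] = 500.0
    df["psf_sigma_fit_nm"] = 120.0
    df["fit_ok"] = True
    df["residual_norm"] = 0.01
    return paint.LocalizationTable(df, pixel_size_nm, frame_time_ms)


def spot_frame(x0_nm, y0_nm, photons=1000.0, shape=(32, 32), sigma_nm=1.3 * PX):
    return photons * integrated_gaussian_psf(
        x0_nm, y0_nm, sigma_nm, PX, slice(0, shape[0]), slice(0, shape[1])
    )


class TestLoGFilter:
    def test_constant_frame_gives_zero_response(self):
        out = paint.log_filter(np.full((16, 16), 5.0), 1.5)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_bright_spot_peaks_at_center(self):
        frame = spot_frame((12 + 0.5) * PX, (9 + 0.5) * PX)
        out = paint.log_filter(frame, 1.5)
        assert np.unravel_index(out.argmax(), out.shape) == (9, 12)

    def test_linearity(self):
        a = spot_frame((8 + 0.5) * PX, (8 + 0.5) * PX)
        b = spot_frame((24 + 0.5) * PX, (22 + 0.5) * PX)
        fa, fb = paint.log_filter(a, 1.5), paint.log_filter(b, 1.5)
        np.testing.assert_allclose(paint.log_filter(a + b, 1.5), fa + fb, atol=1e-9)


class TestDetectCandidates:
    def test_all_zero_frame_gives_no_candidates(self):
        assert len(paint.detect_candidates(np.zeros((16, 16)))) == 0

    def test_single_bright_spot_one_candidate(self, rng):
        noise = rng.normal(0, 1.0, (32, 32))
        frame = noise + spot_frame((15 + 0.5) * PX, (11 + 0.5) * PX, photons=2000.0) / 10
        # peak ~ 20x noise sigma after filtering
        filtered = paint.log_filter(frame, 1.5)
        cands = paint.detect_candidates(filtered, 3.0)
        assert len(cands) == 1
        assert tuple(cands[0]) == (11, 15)

    def test_noise_false_positive_rate_stable_across_seeds(self):
        """The 3-sigma local-maxima rule has a small, seed-stable
        false-positive rate on pure Gaussian noise (Monte-Carlo oracle,
        500 frames per seed)."""
        rates = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            n_cand = sum(
                len(paint.detect_candidates(paint.log_filter(rng.normal(0, 1, (32, 32)), 1.5)))
                for _ in range(500)
            )
            rates.append(n_cand / 500)
        # Poisson-consistent between independent seed sets
        tot = sum(rates) * 500 / 2
        assert abs(rates[0] - rates[1]) < 6 * np.sqrt(max(tot, 1)) / 500
        assert rates[0] < 5  # far below one candidate per 200 pixels

    def test_deduplication_keeps_brighter(self):
        filtered = np.zeros((16, 16))
        filtered[8, 8] = 10.0
        filtered[8, 9] = 8.0
        filtered[2, 2] = 9.0
        cands = paint.detect_candidates(filtered, 3.0, dedup_radius_px=3.0)
        assert {tuple(c) for c in cands} == {(8, 8), (2, 2)}


class TestFitGaussian2D:
    def test_noise_free_subpixel_recovery(self):
        """A spot 17 nm off a pixel center is recovered to < 1 nm."""
        x0 = (15 + 0.5) * PX + 17.0
        y0 = (15 + 0.5) * PX - 6.0
        frame = spot_frame(x0, y0)
        sub = frame[11:20, 11:20]
        loc = paint.fit_gaussian2d(sub, init={"sigma_px": 1.3}, pixel_size_nm=PX,
                                   origin_px=(11, 11))
        assert loc.fit_ok
        assert abs(loc.x_nm - x0) < 1.0
        assert abs(loc.y_nm - y0) < 1.0

    def test_localization_precision_near_information_bound(self):
        """Monte-Carlo RMSE at 690 photons over 2 background photons/px is
        within a factor 1.5 of the pixelation+background-corrected
        sigma/sqrt(N) bound."""
        rng = np.random.default_rng(0)
        x0 = (7 + 0.35 + 0.5) * PX
        y0 = (7 + 0.22 + 0.5) * PX
        patch = integrated_gaussian_psf(x0, y0, 1.3 * PX, PX, slice(0, 15), slice(0, 15))
        errs = []
        for _ in range(200):
            z = rng.poisson(690 * patch + 2.0)
            loc = paint.fit_gaussian2d(z, init={"sigma_px": 1.3}, pixel_size_nm=PX)
            if loc.fit_ok:
                errs.append((loc.x_nm - x0, loc.y_nm - y0))
        errs = np.asarray(errs)
        assert len(errs) > 180
        rmse = np.sqrt((errs**2).mean())
        sa2 = (1.3 * PX) ** 2 + PX**2 / 12  # pixelation-corrected width
        bound = np.sqrt(sa2 / 690 * (16 / 9 + 8 * np.pi * sa2 * 2.0 / (690 * PX**2)))
        assert bound / 1.5 < rmse < bound * 1.5

    def test_flat_subimage_fails(self):
        loc = paint.fit_gaussian2d(np.full((9, 9), 3.0))
        assert not loc.fit_ok


class TestLocalizeMovie:
    def test_noise_free_emitters_recovered_below_2nm(self):
        """Detection + localization on noise-free frames has < 2 nm error."""
        acq = AcquisitionConfig(exposure_ms=30.0, pixel_size_nm=PX, n_frames=8, fov_px=(32, 32))
        rng = np.random.default_rng(1)
        optics = simulate.OpticsCameraModel(
            psf_sigma_nm=1.3 * PX, background_photons_per_pixel_per_frame=0.0
        )
        for _ in range(5):
            x0 = (rng.uniform(10, 20) + 0.5) * PX
            y0 = (rng.uniform(10, 20) + 0.5) * PX
            ev = simulate.EventList(pd.DataFrame({
                "site": [0], "x_nm": [x0], "y_nm": [y0], "t_on_ms": [0.0],
                "dwell_ms": [acq.duration_ms], "photons_per_frame_mean": [1000.0],
            }))
            movie = simulate.render_movie(ev, optics, acq, noise=False)
            table = paint.localize_movie(movie)
            assert len(table) == 8
            err = np.hypot(table.df.x_nm - x0, table.df.y_nm - y0)
            assert err.max() < 2.0

    def test_detected_photons_and_stationarity_on_sparse_scenario(self):
        """On a sparse transient-binding movie the filtered mean photon
        count per molecule per frame matches the configured brightness
        within 10%, and the localization rate is stationary (no trend at
        alpha = 0.05)."""
        acq = simulate.paint_sofi_acquisition(n_frames=400, fov_px=(48, 48))
        kin = simulate.KineticsModel(0.02, 100.0, 300.0, f_fast=0.3)
        optics = simulate.default_optics(acq, brightness_cv=0.0)
        movie, _ = simulate.simulate_scenario(
            acq, kinetics=kin, optics=optics, seed=21, n_fibrils=4
        )
        table = paint.localize_movie(movie)
        filt = paint.filter_localizations(
            table, sigma_bounds_nm=(60.0, 200.0), min_photons=200.0
        )
        mean_photons = filt.df.photons.mean()
        assert abs(mean_photons - 690.0) / 690.0 < 0.10
        counts = filt.df.groupby("frame").size().reindex(range(400), fill_value=0)
        res = stats.linregress(np.arange(400), counts.to_numpy())
        assert res.pvalue > 0.05


class TestFilterLocalizations:
    def test_all_pass_is_identity(self):
        t = loc_table([(0, 100.0, 100.0), (1, 200.0, 200.0)])
        out = paint.filter_localizations(t, sigma_bounds_nm=(0.0, 1e6))
        assert len(out) == 2

    def test_width_outlier_removed(self):
        t = loc_table([(0, 100.0, 100.0)])
        t.df.loc[0, "psf_sigma_fit_nm"] = 3 * 120.0
        out = paint.filter_localizations(t)  # default bounds (40, 250) nm
        assert len(out) == 0

    def test_empty_table(self):
        t = loc_table([])
        assert len(paint.filter_localizations(t)) == 0


class TestReconstruct:
    FOV = (2000.0, 2000.0)

    def test_single_localization_mass_and_width(self):
        t = loc_table([(0, 1000.0, 1000.0)])
        img, bin_nm = paint.reconstruct(t, self.FOV)
        assert abs(img.sum() - 1.0) < 1e-3
        # second moment of the kernel ~ 25 nm
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        x_nm = (xx + 0.5) * bin_nm
        var = (img * (x_nm - 1000.0) ** 2).sum() / img.sum()
        assert abs(np.sqrt(var) - np.sqrt(25.0**2 + bin_nm**2 / 12)) < 1.0

    def test_two_coincident_localizations_double_the_image(self):
        one = paint.reconstruct(loc_table([(0, 1000.0, 1000.0)]), self.FOV)[0]
        two = paint.reconstruct(
            loc_table([(0, 1000.0, 1000.0), (1, 1000.0, 1000.0)]), self.FOV
        )[0]
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_line_of_localizations_has_expected_cross_section(self):
        n = 2000
        xs = np.linspace(500.0, 2500.0, n)
        t = loc_table([(i, xs[i], 1500.0) for i in range(n)], frame_time_ms=30.0)
        img, bin_nm = paint.reconstruct(t, (3000.0, 3000.0))
        assert abs(img.sum() - n) / n < 0.005
        width = paint.measure_profile_width(
            img, ((700.0, 1500.0), (2300.0, 1500.0)), half_width_px=30, pixel_size_nm=bin_nm
        )
        expected = np.sqrt(25.0**2 + bin_nm**2 / 12)
        assert abs(width - expected) / expected < 0.05

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            paint.reconstruct(loc_table([]), self.FOV)


class TestLinkOnTimes:
    def test_continuous_run(self):
        t = loc_table([(f, 1000.0, 1000.0) for f in range(5, 10)])
        d = paint.link_on_times(t, radius_nm=PX)
        assert d.counts[4] == 1 and d.counts.sum() == 1

    def test_gap_splits_run(self):
        t = loc_table([(f, 1000.0, 1000.0) for f in (5, 6, 8, 9)])
        d = paint.link_on_times(t, radius_nm=PX)
        assert d.counts[1] == 2 and d.counts.sum() == 2

    def test_distant_molecules_not_linked(self):
        t = loc_table([(0, 500.0, 500.0), (1, 2000.0, 2000.0)])
        d = paint.link_on_times(t, radius_nm=PX)
        assert d.counts[0] == 2

    def test_run_length_mean_matches_sampling_oracle(self):
        """Sequential single molecules with exponential dwells (mean 5
        frames, starts frame-aligned): expected run length is
        1/(1 - e^(-1/5)) ~= 5.52 frames."""
        rng = np.random.default_rng(3)
        rows, f = [], 0
        ks = []
        for _ in range(4000):
            k = int(np.ceil(rng.exponential(5.0)))
            ks.append(k)
            x, y = rng.uniform(500, 5000, 2)
            rows.extend((f + j, x, y) for j in range(k))
            f += k + 2
        d = paint.link_on_times(loc_table(rows), radius_nm=PX)
        oracle = 1.0 / (1.0 - np.exp(-1.0 / 5.0))
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(d.mean_frames() - oracle) < 3 * se + abs(np.mean(ks) - oracle)


class TestOnTimeDecay:
    def test_single_exponential_recovery(self):
        """Apparent on-times from a 17 ms dwell at 30 ms frames: fitted
        decay time within 15%."""
        rng = np.random.default_rng(4)
        k = np.ceil(rng.exponential(17.0, 10_000) / 30.0).astype(int)
        dist = paint.OnTimeDistribution(np.bincount(k)[1:], 30.0)
        fit = paint.fit_on_time_decay(dist, n_components=1)
        assert abs(fit["tau_ms"][0] - 17.0) / 17.0 < 0.15

    def test_two_component_mixture_prefers_biexponential(self):
        """17/77 ms dwell mixture at 30 ms frames, n = 50,000: the
        two-component fit recovers both times and beats the
        single-component fit on reduced chi2."""
        rng = np.random.default_rng(1)
        n = 50_000
        fast = rng.random(n) < 0.7
        d = np.where(fast, rng.exponential(17.0, n), rng.exponential(77.0, n))
        k = np.ceil(d / 30.0).astype(int)
        dist = paint.OnTimeDistribution(np.bincount(k)[1:], 30.0)
        f1 = paint.fit_on_time_decay(dist, n_components=1)
        f2 = paint.fit_on_time_decay(dist, n_components=2)
        assert f2["reduced_chi2"] < f1["reduced_chi2"]
        assert f1["reduced_chi2"] > 10  # monoexponential clearly inadequate
        assert abs(f2["tau_ms"][0] - 17.0) / 17.0 < 0.25
        assert abs(f2["tau_ms"][1] - 77.0) / 77.0 < 0.25

    def test_single_bin_is_an_error(self):
        dist = paint.OnTimeDistribution(np.array([100]), 30.0)
        with pytest.raises(ValueError, match="occupied bins"):
            paint.fit_on_time_decay(dist, n_components=2)


class TestProfileWidth:
    @pytest.mark.parametrize("sigma_nm", [113.0, 136.0])
    def test_rendered_ridge_width_recovered(self, sigma_nm):
        """Gaussian ridge of known width on a 20 nm grid: recovered sigma
        within 5%."""
        grid = 20.0
        yy = np.arange(200)[:, None] * np.ones((1, 200))
        center_nm = 100.3 * grid
        img = np.exp(-(((yy + 0.5) * grid - center_nm) ** 2) / (2 * sigma_nm**2))
        width = paint.measure_profile_width(
            img,
            ((20 * grid, center_nm), (180 * grid, center_nm)),
            half_width_px=25,
            pixel_size_nm=grid,
        )
        assert abs(width - sigma_nm) / sigma_nm < 0.05

    def test_flat_image_is_an_error(self):
        with pytest.raises(ValueError, match="flat"):
            paint.measure_profile_width(
                np.ones((50, 50)), ((100.0, 500.0), (900.0, 500.0)), 10, 20.0
            )


class TestTableIO:
    def test_csv_roundtrip(self, tmp_path):
        t = loc_table([(3, 100.0, 200.0), (1, 50.0, 60.0)])
        t.to_csv(tmp_path / "loc.csv")
        back = paint.LocalizationTable.from_csv(tmp_path / "loc.csv", PX, 30.0)
        assert list(back.df.frame) == [1, 3]  # sorted by frame
        np.testing.assert_allclose(
            back.df[["x_nm", "y_nm"]].to_numpy(), [[50.0, 60.0], [100.0, 200.0]]
        )
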