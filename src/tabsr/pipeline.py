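"""End-to-end orchestration: simulate -> PAINT / SOFI / iFCS / FRC.

A :class:`PipelineConfig` (YAML-serializable) plus a master seed fully
determines a run. ``run_pipeline`` writes all stage artifacts and a
machine-readable manifest into a run directory; ``validate_run`` re-checks
the core invariants (SOFI/iFCS numerator identity, reconstruction mass
conservation, artifact presence) on a completed run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import frc as frc_mod
from . import ifcs, paint, simulate, sofi
from .movie import AcquisitionConfig, Movie, read_movie, write_movie

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_run"]

DEFAULT_STAGE_PARAMS = {
    "log_sigma_px": 1.5,
    "threshold_k": 3.0,
    "psf_sigma_px": 1.3,
    "bin_nm": 5.0,
    "kernel_sigma_nm": 25.0,
    "n_segments": 6,
    "snr_gate": 10.0,
    "frc_threshold": 1.0 / 7.0,
    "sofi_mode": "first_lag",
    "link_radius_nm": 92.0,
}


@dataclass
class PipelineConfig:
    """Scenario + stage toggles + stage parameters + master seed."""

    scenario: dict = field(default_factory=lambda: {"regime": "paint_sofi", "n_frames": 4000, "fov_px": [64, 64]})
    movie_path: str | None = None  # analyse an existing TIFF instead of simulating
    run_paint: bool = True
    run_sofi: bool = True
    run_ifcs: bool = True
    run_frc: bool = True
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_STAGE_PARAMS)
        merged.update(self.params)
        self.params = merged

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_movie(config: PipelineConfig) -> tuple[Movie, simulate.GroundTruth | None]:
    sc = dict(config.scenario)
    if config.movie_path is not None:
        meta = AcquisitionConfig.from_dict(sc["acquisition"]) if "acquisition" in sc else AcquisitionConfig(
            exposure_ms=30.0, pixel_size_nm=92.0, n_frames=2
        )
        return read_movie(config.movie_path, meta), None
    regime = sc.pop("regime", "paint_sofi")
    fov_px = tuple(sc.pop("fov_px", (64, 64)))
    n_frames = sc.pop("n_frames", 4000)
    if regime == "paint_sofi":
        acq = simulate.paint_sofi_acquisition(n_frames=n_frames, fov_px=fov_px)
    elif regime == "ifcs":
        acq = simulate.ifcs_acquisition(n_frames=n_frames, fov_px=fov_px)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    movie, truth = simulate.simulate_scenario(acq, seed=config.seed, **sc)
    return movie, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage_info: dict[str, dict] = {}

    t0 = time.perf_counter()
    movie, truth = _build_movie(config)
    write_movie(movie, outdir / "movie.tif")
    if truth is not None:
        truth.save(outdir / "ground_truth")
    timings["simulate_or_load"] = time.perf_counter() - t0
    p = config.params
    table = None

    if config.run_paint:
        t0 = time.perf_counter()
        table = paint.localize_movie(
            movie,
            log_sigma_px=p["log_sigma_px"],
            threshold_k=p["threshold_k"],
            psf_sigma_px=p["psf_sigma_px"],
        )
        table.to_csv(outdir / "localizations.csv")
        if len(table):
            image, _ = paint.reconstruct(
                table, movie.fov_nm, bin_nm=p["bin_nm"], kernel_sigma_nm=p["kernel_sigma_nm"]
            )
            tifffile.imwrite(outdir / "paint.tif", image.astype(np.float32))
            dist = paint.link_on_times(table, radius_nm=p["link_radius_nm"])
            np.savetxt(outdir / "on_time_counts.csv", dist.counts, fmt="%d", header="count_per_run_length")
        stage_info["paint"] = {"n_localizations": int(len(table))}
        timings["paint"] = time.perf_counter() - t0

    if config.run_sofi:
        t0 = time.perf_counter()
        img = sofi.sofi_image(movie, mode=p["sofi_mode"])
        tifffile.imwrite(outdir / "sofi.tif", img.rendered.astype(np.float32))
        np.save(outdir / "sofi_raw.npy", img.values)
        stage_info["sofi"] = {"taus_used": img.taus_used}
        timings["sofi"] = time.perf_counter() - t0

    if config.run_ifcs:
        t0 = time.perf_counter()
        n_seg = int(p["n_segments"])
        n_seg = min(n_seg, movie.n_frames // 2)
        stack = ifcs.segmented_acf(movie, n_segments=n_seg)
        fits = ifcs.fit_all_pixels(stack, snr_gate=p["snr_gate"])
        fits.to_csv(outdir / "acf_fits.csv", index=False)
        maps = ifcs.build_maps(fits, stack.G.shape[1:], snr_gate=p["snr_gate"])
        tifffile.imwrite(
            outdir / "parameter_maps.tif",
            np.stack(
                [maps.tau_fast_ms, maps.tau_slow_ms, maps.fast_weight_fraction, maps.G0]
            ).astype(np.float32),
            photometric="minisblack",
        )
        stage_info["ifcs"] = {
            "n_segments": n_seg,
            "n_fit": int(len(fits)),
            "n_valid": int(maps.valid.sum()),
            "sem_defined": n_seg >= 2,
        }
        timings["ifcs"] = time.perf_counter() - t0

    if config.run_frc and config.run_paint and table is not None and len(table) >= 2:
        t0 = time.perf_counter()
        res, curve = frc_mod.frc_resolution(
            table, movie.fov_nm, bin_nm=p["bin_nm"],
            threshold=p["frc_threshold"], seed=config.seed,
        )
        curve.to_csv(outdir / "frc_curve.csv")
        stage_info["frc"] = {"resolution_nm": res}
        timings["frc"] = time.perf_counter() - t0

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": timings,
        "stages": stage_info,
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _versions() -> dict:
    import numpy, pandas, scipy, tifffile as tf

    from . import __version__

    return {
        "tabsr": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "tifffile": tf.__version__,
    }


def validate_run(rundir: str | Path) -> dict:
    """Re-check core invariants on a completed run directory.

    Returns {check name: "pass" | "fail" | "skipped"}; raises if required
    artifacts are missing.
    """
    rundir = Path(rundir)
    manifest_path = rundir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    config = PipelineConfig(**manifest["config"])
    report: dict[str, str] = {}

    movie_path = rundir / "movie.tif"
    if not movie_path.exists():
        raise FileNotFoundError(f"missing movie artifact: {movie_path}")
    acq_meta = AcquisitionConfig(
        exposure_ms=30.0 if config.scenario.get("regime", "paint_sofi") == "paint_sofi" else 2.5,
        pixel_size_nm=92.0 if config.scenario.get("regime", "paint_sofi") == "paint_sofi" else 46.0,
        n_frames=2,
    )
    movie = read_movie(movie_path, acq_meta)

    if (rundir / "sofi_raw.npy").exists():
        raw = np.load(rundir / "sofi_raw.npy")
        taus = manifest["stages"]["sofi"]["taus_used"]
        expected = sofi.lagged_covariance(movie.data, np.array(taus)).sum(axis=0)
        same = np.allclose(raw, expected, rtol=1e-6, atol=1e-9)
        report["sofi_ifcs_numerator_identity"] = "pass" if same else "fail"
    else:
        report["sofi_ifcs_numerator_identity"] = "skipped"

    loc_path = rundir / "localizations.csv"
    if loc_path.exists() and (rundir / "paint.tif").exists():
        table = paint.LocalizationTable.from_csv(
            loc_path, movie.pixel_size_nm, movie.frame_time_ms
        )
        if len(table):
            image = np.asarray(tifffile.imread(rundir / "paint.tif"), dtype=float)
            mass_ok = abs(image.sum() - len(table)) <= max(0.01 * len(table), 0.5)
            report["reconstruction_mass_conservation"] = "pass" if mass_ok else "fail"
        else:
            report["reconstruction_mass_conservation"] = "skipped"
    else:
        report["reconstruction_mass_conservation"] = "skipped"

    ifcs_info = manifest["stages"].get("ifcs")
    if ifcs_info is not None:
        report["ifcs_sem"] = "pass" if ifcs_info.get("sem_defined") else "skipped"
    else:
        report["ifcs_sem"] = "skipped"

    return report
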