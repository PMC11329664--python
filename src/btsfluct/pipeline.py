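"""End-to-end pipeline: simulate-or-load -> preprocess -> correlate -> fit ->
quality -> BTS, driven by a flat key-value configuration.

Every stochastic stage receives an explicit seed derived from the config;
outputs are written as plain-text interchange files together with a run
manifest (config hash, seeds, package versions) so runs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .bts import build_histogram, default_edges, pool_records
from .carpet import ScanConfig, SimBox, Species
from .correlate import carpet_traces, correlate_carpet
from .fcsfit import calibration_from_fwhm, fit_carpet_curves
from .io import (
    read_carpet,
    write_carpet,
    write_curves,
    write_fit_table,
    write_histogram,
)
from .quality import snr
from .simulate import simulate_free, simulate_mixture

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    Either ``input_path`` (load a carpet) or the simulation block
    (diffusion/brightness/particles) must be provided.  Units are stated in
    the field names; durations are seconds internally and milliseconds at
    the BTS boundary.
    """

    out_dir: str = "bts_run"
    seed: int = 1
    # acquisition / simulation geometry
    n_pixels: int = 50
    pixel_spacing_nm: float = 100.0
    dwell_time_us: float = 4.0
    line_frequency_hz: float = 2000.0
    duration_s: float = 30.0
    psf_fwhm_nm: float = 240.0
    box_width_um: float = 5.0
    box_height_um: float = 8.0
    # simulation (ignored when input_path is set)
    input_path: Optional[str] = None
    diffusion_um2_s: float = 1.0
    brightness_khz: float = 25.0
    n_particles: int = 100
    oligomer_order: Optional[int] = None
    oligomer_fraction: float = 0.0
    n_repeats: int = 1
    # preprocessing / correlation
    crop_seconds: float = 10.0
    bleach_window_s: Optional[float] = None
    spatial_first_pixel: Optional[int] = None
    spatial_n_keep: Optional[int] = None
    scheme: str = "multi_tau"
    # fitting
    model_id: str = "diff2d"
    fit_max_lag_s: float = 10.0
    # BTS histogram
    bins: int = 50

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value JSON configuration file."""
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full pipeline and write all stage outputs.

    Returns a result bundle: the pooled record table, histogram, quality
    summary and the paths of everything written.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scan = ScanConfig(
        n_pixels=cfg.n_pixels,
        pixel_spacing_nm=cfg.pixel_spacing_nm,
        dwell_time_us=cfg.dwell_time_us,
        line_frequency_hz=cfg.line_frequency_hz,
        n_lines=int(round(cfg.duration_s * cfg.line_frequency_hz)),
        psf_fwhm_nm=cfg.psf_fwhm_nm,
    )
    box = SimBox(cfg.box_width_um, cfg.box_height_um)
    calibration = calibration_from_fwhm(cfg.psf_fwhm_nm)

    # ---- stage 1: simulate or load -----------------------------------
    carpets = []
    if cfg.input_path is not None:
        if not Path(cfg.input_path).exists():
            raise FileNotFoundError(f"input carpet {cfg.input_path} not found")
        logger.info("stage simulate/load: reading %s", cfg.input_path)
        carpets.append(("input", read_carpet(cfg.input_path)))
    else:
        seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_repeats)
        for r, s in enumerate(seeds):
            s = int(s % (2**31))
            monomer = Species(cfg.diffusion_um2_s, cfg.brightness_khz, cfg.n_particles)
            logger.info("stage simulate: repeat %d (seed %d)", r, s)
            if cfg.oligomer_order is None:
                carpet = simulate_free(scan, box, monomer, seed=s)
            else:
                carpet = simulate_mixture(
                    scan, box, monomer, cfg.oligomer_order, cfg.oligomer_fraction,
                    seed=s,
                )
            carpets.append((f"sim{r}", carpet))
            write_carpet(carpet, out / f"carpet_{r}.tif")

    # ---- stages 2-4: preprocess, correlate, fit, quality --------------
    spatial = None
    if cfg.spatial_first_pixel is not None and cfg.spatial_n_keep is not None:
        spatial = (cfg.spatial_first_pixel, cfg.spatial_n_keep)
    tables: List[pd.DataFrame] = []
    snr_values: List[float] = []
    for mid, carpet in carpets:
        logger.info("stage correlate: %s", mid)
        curves = correlate_carpet(
            carpet,
            crop_seconds=cfg.crop_seconds,
            spatial_window=spatial,
            bleach_window_s=cfg.bleach_window_s,
            scheme=cfg.scheme,
        )
        write_curves(curves, out / f"curves_{mid}.csv")
        logger.info("stage fit: %s (%d curves)", mid, len(curves))
        table = fit_carpet_curves(
            curves,
            dwell_time_s=scan.dwell_time_s,
            model_id=cfg.model_id,
            fit_max_lag_s=cfg.fit_max_lag_s,
            calibration=calibration,
            measurement_id=mid,
        )
        tables.append(table)
        from .correlate import crop_initial  # quality on the cropped carpet

        cropped = crop_initial(carpet, cfg.crop_seconds) if cfg.crop_seconds else carpet
        for trace in carpet_traces(cropped)[:: max(1, cropped.n_pixels // 10)]:
            if np.any(trace.counts):
                try:
                    snr_values.append(snr(trace))
                except ValueError:
                    pass

    fits = pd.concat(tables, ignore_index=True)
    write_fit_table(fits, out / "fits.csv")

    # ---- stage 5: BTS histogram ---------------------------------------
    records = pool_records(tables)
    xy = records[["ln_tau", "cpm_hz"]].to_numpy()
    edges = default_edges(xy, bins=cfg.bins)
    hist = build_histogram(records, *edges)
    write_histogram(hist, out / "bts_hist.csv")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_records": int(len(records)),
        "median_tau_d_ms": float(records["tau_d_ms"].median()),
        "median_cpm_khz": float(records["cpm_hz"].median() / 1e3),
        "median_snr": float(np.median(snr_values)) if snr_values else None,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "records": records,
        "histogram": hist,
        "fit_table": fits,
        "manifest": manifest,
        "out_dir": str(out),
    }
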