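"""Plain-text / TIFF readers and writers for the pipeline interchange files.

Carpets travel as 2D TIFF (lines x pixels, 16-bit unsigned) or CSV matrices
with a JSON sidecar holding the acquisition metadata (dwell time, line
frequency, pixel spacing, PSF) and, for simulated data, the ground-truth
manifest.  Correlation curves and fit tables are long-format CSV with units
in the column names, so every stage can be run, inspected and replaced
independently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .bts import BTSHistogram
from .carpet import PhotonCarpet, ScanConfig
from .correlate import CorrelationCurve

__all__ = [
    "write_carpet",
    "read_carpet",
    "write_curves",
    "read_curves",
    "write_fit_table",
    "read_fit_table",
    "write_histogram",
    "read_histogram",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _scan_to_meta(scan: ScanConfig) -> Dict:
    return {
        "n_pixels": scan.n_pixels,
        "pixel_spacing_nm": scan.pixel_spacing_nm,
        "dwell_time_us": scan.dwell_time_us,
        "line_frequency_hz": scan.line_frequency_hz,
        "n_lines": scan.n_lines,
        "psf_fwhm_nm": scan.psf_fwhm_nm,
    }


def write_carpet(carpet: PhotonCarpet, path: Union[str, Path]) -> Path:
    """Write a carpet as TIFF (.tif/.tiff, uint16) or CSV, plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        counts = carpet.counts
        if counts.max() > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed the uint16 range of the TIFF format")
        tifffile.imwrite(path, counts.astype(np.uint16))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, carpet.counts, fmt="%.10g", delimiter=",")
    else:
        raise ValueError(f"unsupported carpet format {path.suffix!r}")
    meta = {
        "scan": _scan_to_meta(carpet.scan_config),
        "pixel_indices": carpet.pixel_indices.tolist(),
        "ground_truth": carpet.ground_truth,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows: List[List[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            vals = []
            for j, cell in enumerate(line.split(",")):
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: "
                        f"{cell!r}"
                    ) from exc
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    return np.asarray(rows)


def read_carpet(
    path: Union[str, Path], metadata: Optional[Union[str, Path, Dict]] = None
) -> PhotonCarpet:
    """Read a carpet from TIFF or CSV.

    ``metadata`` may be a dict or a path to a JSON file with a ``scan``
    section; it defaults to the sidecar written by :func:`write_carpet`.
    If the matrix arrives transposed relative to the declared pixel count it
    is transposed back (with a logged notice).  Non-integer values are
    accepted as real intensities with a notice.
    """
    path = Path(path)
    if metadata is None:
        metadata = _sidecar_path(path)
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    scan_meta = metadata["scan"] if "scan" in metadata else metadata

    if path.suffix.lower() in (".tif", ".tiff"):
        counts = np.asarray(tifffile.imread(path))
    elif path.suffix.lower() == ".csv":
        counts = _read_csv_matrix(path)
    else:
        raise ValueError(f"unsupported carpet format {path.suffix!r}")
    if counts.ndim != 2:
        raise ValueError(f"{path}: expected a 2D matrix, got shape {counts.shape}")
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative intensity values")

    n_pixels = int(scan_meta["n_pixels"])
    if counts.shape[1] != n_pixels and counts.shape[0] == n_pixels:
        logger.info("read_carpet: transposing %s to match %d pixels", path, n_pixels)
        counts = counts.T
    if not np.issubdtype(counts.dtype, np.integer):
        if np.allclose(counts, np.round(counts)):
            counts = np.round(counts).astype(np.int64)
        else:
            logger.info("read_carpet: %s holds non-integer intensities", path)

    scan = ScanConfig(
        n_pixels=n_pixels,
        pixel_spacing_nm=float(scan_meta["pixel_spacing_nm"]),
        dwell_time_us=float(scan_meta["dwell_time_us"]),
        line_frequency_hz=float(scan_meta["line_frequency_hz"]),
        n_lines=counts.shape[0],
        psf_fwhm_nm=float(scan_meta["psf_fwhm_nm"]),
    )
    pix = metadata.get("pixel_indices") if isinstance(metadata, dict) else None
    return PhotonCarpet(
        counts,
        scan,
        ground_truth=metadata.get("ground_truth"),
        pixel_indices=np.asarray(pix) if pix is not None else None,
    )


def write_curves(curves: Sequence[CorrelationCurve], path: Union[str, Path]) -> Path:
    """Write correlation curves as long-format CSV (pixel, lag_s, g)."""
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "pixel": c.pixel_index,
                "lag_s": c.lag_times_s,
                "g": c.g,
                "mean_intensity": c.mean_intensity,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_curves(path: Union[str, Path]) -> List[CorrelationCurve]:
    df = pd.read_csv(path)
    curves = []
    for pix, grp in df.groupby("pixel", sort=True):
        curves.append(
            CorrelationCurve(
                lag_times_s=grp["lag_s"].to_numpy(),
                g=grp["g"].to_numpy(),
                pixel_index=int(pix),
                mean_intensity=float(grp["mean_intensity"].iloc[0]),
            )
        )
    return curves


def write_fit_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_fit_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_histogram(hist: BTSHistogram, path: Union[str, Path]) -> Path:
    """Histogram density as a CSV matrix plus a JSON edge sidecar."""
    path = Path(path)
    np.savetxt(path, hist.density, delimiter=",")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "x_edges_ln_tau_ms": hist.x_edges.tolist(),
                "y_edges_cpm_hz": hist.y_edges.tolist(),
            }
        )
    )
    return path


def read_histogram(path: Union[str, Path]) -> BTSHistogram:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    x_edges = np.asarray(meta["x_edges_ln_tau_ms"])
    y_edges = np.asarray(meta["y_edges_cpm_hz"])
    density = np.loadtxt(path, delimiter=",").reshape(
        x_edges.size - 1, y_edges.size - 1
    )
    return BTSHistogram(x_edges, y_edges, density)
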