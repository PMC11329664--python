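"""Containers for scanning-FCS acquisitions.

A scanning-FCS (sFCS) measurement repeatedly scans the same line of pixels,
producing a "carpet": an integer photon-count matrix of shape
``(n_lines, n_pixels)``.  Each column is the intensity fluctuation trace of
one pixel, sampled once per line period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ScanConfig", "SimBox", "Species", "PhotonCarpet", "fwhm_to_waist"]

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


def fwhm_to_waist(fwhm: float) -> float:
    """Convert a Gaussian PSF full width at half maximum to the 1/e^2 radius.

    omega = FWHM / sqrt(2 ln 2).  This is the single PSF convention used
    package-wide: the detection profile is W(r) = exp(-2 r^2 / omega^2).
    """
    if fwhm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm}")
    return fwhm / _SQRT_2LN2


@dataclass(frozen=True)
class ScanConfig:
    """Line-scan acquisition geometry and timing.

    Parameters
    ----------
    n_pixels : int
        Number of pixels along the scanned line.
    pixel_spacing_nm : float
        Centre-to-centre pixel distance in nm.
    dwell_time_us : float
        Pixel dwell time in microseconds.
    line_frequency_hz : float
        Line repetition rate in Hz; the line period is 1/line_frequency_hz
        and must accommodate ``n_pixels * dwell_time`` (the remainder is the
        retrace gap).
    n_lines : int
        Number of scanned lines; acquisition duration = n_lines / line_frequency.
    psf_fwhm_nm : float
        Full width at half maximum of the 2D Gaussian detection spot, in nm.
    """

    n_pixels: int = 50
    pixel_spacing_nm: float = 100.0
    dwell_time_us: float = 4.0
    line_frequency_hz: float = 2000.0
    n_lines: int = 60_000
    psf_fwhm_nm: float = 240.0

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.dwell_time_us <= 0 or self.line_frequency_hz <= 0:
            raise ValueError("dwell time and line frequency must be positive")
        if self.psf_fwhm_nm <= 0:
            raise ValueError("psf_fwhm_nm must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.n_pixels * self.dwell_time_us * 1e-6 > self.line_period_s + 1e-15:
            raise ValueError(
                "active scan time n_pixels*dwell exceeds the line period "
                f"({self.n_pixels * self.dwell_time_us * 1e-6:.3g} s > "
                f"{self.line_period_s:.3g} s)"
            )

    @property
    def dwell_time_s(self) -> float:
        return self.dwell_time_us * 1e-6

    @property
    def line_period_s(self) -> float:
        return 1.0 / self.line_frequency_hz

    @property
    def retrace_gap_s(self) -> float:
        """Idle time between the last pixel of one line and the first of the next."""
        return self.line_period_s - (self.n_pixels - 1) * self.dwell_time_s

    @property
    def duration_s(self) -> float:
        return self.n_lines / self.line_frequency_hz

    @property
    def psf_waist_um(self) -> float:
        """1/e^2 radius omega in micrometres."""
        return fwhm_to_waist(self.psf_fwhm_nm) * 1e-3


@dataclass(frozen=True)
class SimBox:
    """Periodic 2D simulation box (membrane plane), dimensions in micrometres."""

    width_um: float = 5.0
    height_um: float = 8.0
    boundary_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("box dimensions must be positive")
        if self.boundary_mode != "periodic":
            raise ValueError("only periodic boundaries are supported")

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


@dataclass(frozen=True)
class Species:
    """A diffusing fluorescent species.

    ``brightness_khz`` is the peak detected count rate (kHz) of one particle
    sitting at the PSF centre; off-centre emission is attenuated by the
    Gaussian detection profile.
    """

    diffusion_um2_s: float
    brightness_khz: float
    n_particles: int
    oligomer_order: int = 1

    def __post_init__(self) -> None:
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.brightness_khz < 0:
            raise ValueError("brightness must be >= 0")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.oligomer_order < 1:
            raise ValueError("oligomer_order must be >= 1")


@dataclass
class PhotonCarpet:
    """An sFCS photon-count matrix with its acquisition metadata.

    ``counts`` has shape ``(n_lines, n_pixels)``; row l, column p is the
    number of photons detected in the dwell of pixel p during line l.
    ``pixel_indices`` keeps the original pixel coordinates through spatial
    cropping.  ``ground_truth`` carries the simulation manifest (species,
    box, seed) when the carpet is simulated.
    """

    counts: np.ndarray
    scan_config: ScanConfig
    ground_truth: Optional[dict] = None
    pixel_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D (lines x pixels) matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != self.scan_config.n_pixels:
            raise ValueError(
                f"counts has {self.counts.shape[1]} pixels but scan_config "
                f"declares {self.scan_config.n_pixels}"
            )
        if self.counts.shape[0] != self.scan_config.n_lines:
            raise ValueError(
                f"counts has {self.counts.shape[0]} lines but scan_config "
                f"declares {self.scan_config.n_lines}"
            )
        if self.pixel_indices is None:
            self.pixel_indices = np.arange(self.counts.shape[1])
        else:
            self.pixel_indices = np.asarray(self.pixel_indices)
            if self.pixel_indices.shape != (self.counts.shape[1],):
                raise ValueError("pixel_indices must match the number of columns")

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_lines / self.scan_config.line_frequency_hz
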