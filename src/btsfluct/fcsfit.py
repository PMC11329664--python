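"""FCS model functions, nonlinear curve fitting, calibration and brightness.

The correlation curve of freely diffusing molecules sampled by a Gaussian
spot is fitted to

    G(tau) = G(0) * G_D(tau) * G_T(tau) + offset

with a diffusion term G_D (2D membrane diffusion ``(1+tau/tau_D)^-1`` or 3D
solution diffusion with an axial aspect-ratio factor) and an optional triplet
photophysics term G_T.  The fitted transit time tau_D converts to a diffusion
coefficient through the spot calibration D = omega^2 / (4 tau_D), and the
molecular brightness (counts per molecule) is the mean intensity times the
correlation amplitude, cpm = <I> * G(0) / dwell.

Fitting follows a statsmodels-like surface: :class:`FCSDiffusionModel` is
constructed from a :class:`~btsfluct.correlate.CorrelationCurve`, and
``fit()`` returns an :class:`FCSFitResult` with estimates, standard errors,
residuals and a ``summary()`` table.  :func:`fit_curve` is the functional
shorthand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .carpet import fwhm_to_waist
from .correlate import CorrelationCurve, IntensityTrace

__all__ = [
    "model_diff2d",
    "model_diff3d",
    "FCSDiffusionModel",
    "FCSFitResult",
    "fit_curve",
    "CalibrationResult",
    "calibrate_omega_from_dye",
    "calibration_from_fwhm",
    "transit_time_from_d",
    "transit_time_from_omega",
    "d_from_transit_time",
    "brightness_cpm",
    "particle_density",
    "moment_brightness",
    "fit_carpet_curves",
]


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def model_diff2d(tau, g0: float, tau_d: float, offset: float = 0.0):
    """2D free-diffusion correlation: g0/(1+tau/tau_d) + offset."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    tau = np.asarray(tau, dtype=float)
    return g0 / (1.0 + tau / tau_d) + offset


def model_diff3d(
    tau,
    g0: float,
    tau_d: float,
    aspect_ratio: float,
    offset: float = 0.0,
    triplet_fraction: float = 0.0,
    triplet_time: float = 5e-6,
):
    """3D free-diffusion correlation with optional triplet term.

    g0 * (1+tau/tau_d)^-1 * (1+tau/(AR^2 tau_d))^-1/2
       * [1 + T/(1-T) * exp(-tau/tau_T)] + offset
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    if not 0.0 <= triplet_fraction < 1.0:
        raise ValueError("triplet_fraction must lie in [0, 1)")
    tau = np.asarray(tau, dtype=float)
    diff = (1.0 + tau / tau_d) ** -1 * (
        1.0 + tau / (aspect_ratio**2 * tau_d)
    ) ** -0.5
    trip = 1.0
    if triplet_fraction > 0.0:
        trip = 1.0 + triplet_fraction / (1.0 - triplet_fraction) * np.exp(
            -tau / triplet_time
        )
    return g0 * diff * trip + offset


_MODEL_IDS = ("diff2d", "diff3d", "diff3d_triplet")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FCSFitResult:
    """Result of fitting an FCS model to one correlation curve."""

    model_id: str
    params: Dict[str, float]
    stderr: Dict[str, Optional[float]]
    converged: bool
    residuals: np.ndarray
    lag_times_s: np.ndarray
    fit_range_s: tuple
    pixel_index: int
    mean_intensity: float

    @property
    def g0(self) -> float:
        return self.params["g0"]

    @property
    def tau_d_s(self) -> float:
        return self.params["tau_d"]

    @property
    def tau_d_ms(self) -> float:
        return self.params["tau_d"] * 1e3

    @property
    def offset(self) -> float:
        return self.params["offset"]

    def predict(self, tau) -> np.ndarray:
        """Evaluate the fitted model on a lag grid (seconds)."""
        p = self.params
        if self.model_id == "diff2d":
            return model_diff2d(tau, p["g0"], p["tau_d"], p["offset"])
        return model_diff3d(
            tau,
            p["g0"],
            p["tau_d"],
            p.get("aspect_ratio", 1.0),
            p["offset"],
            p.get("triplet_fraction", 0.0),
            p.get("triplet_time", 5e-6),
        )

    def summary(self) -> str:
        lines = [
            f"FCS fit ({self.model_id}), pixel {self.pixel_index}",
            f"  converged: {self.converged}",
            f"  fit range: {self.fit_range_s[0]:.3g} .. {self.fit_range_s[1]:.3g} s"
            f" ({self.residuals.size} lags)",
        ]
        for name, value in self.params.items():
            err = self.stderr.get(name)
            err_s = f" +/- {err:.3g}" if err is not None and np.isfinite(err) else ""
            lines.append(f"  {name:>16s} = {value:.6g}{err_s}")
        return "\n".join(lines)


class FCSDiffusionModel:
    """Nonlinear least-squares FCS model bound to one correlation curve.

    Parameters
    ----------
    curve : CorrelationCurve
    model_id : {"diff2d", "diff3d", "diff3d_triplet"}
    fixed : mapping of parameter name -> value to hold fixed
        (e.g. ``{"offset": 0.0}``; the triplet time defaults to 5 us fixed).
    fit_max_lag_s : float
        Upper lag bound of the fit window (default 10 s); the lower bound is
        the first measured lag.
    """

    def __init__(
        self,
        curve: CorrelationCurve,
        model_id: str = "diff2d",
        fixed: Optional[Dict[str, float]] = None,
        fit_max_lag_s: float = 10.0,
    ) -> None:
        if model_id not in _MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        self.curve = curve
        self.model_id = model_id
        self.fixed = dict(fixed or {})
        self.fit_max_lag_s = fit_max_lag_s

        mask = curve.lag_times_s <= fit_max_lag_s
        self.tau = curve.lag_times_s[mask]
        self.g = curve.g[mask]
        finite = np.isfinite(self.g)
        self.tau, self.g = self.tau[finite], self.g[finite]
        if self.tau.size < 5:
            raise ValueError("need at least 5 finite lags inside the fit range")

    # -- initial guesses -------------------------------------------------
    def _guesses(self) -> Dict[str, float]:
        g0_init = float(np.mean(self.g[:3]))
        # offset guess: mean over the last decade of lags
        last_decade = self.tau >= self.tau[-1] / 10.0
        offset_init = float(np.mean(self.g[last_decade]))
        half = offset_init + max(g0_init - offset_init, 1e-12) / 2.0
        below = np.nonzero(self.g < half)[0]
        tau_d_init = float(self.tau[below[0]]) if below.size else float(self.tau[-1])
        return {"g0": g0_init, "tau_d": tau_d_init, "offset": offset_init}

    def _build_params(self) -> lmfit.Parameters:
        init = self._guesses()
        p = lmfit.Parameters()
        p.add("g0", value=max(init["g0"], 1e-8), min=1e-10)
        p.add("tau_d", value=max(init["tau_d"], 1e-9), min=1e-9)
        p.add("offset", value=init["offset"])
        if self.model_id in ("diff3d", "diff3d_triplet"):
            p.add("aspect_ratio", value=5.0, min=1.0, max=10.0)
        if self.model_id == "diff3d_triplet":
            p.add("triplet_fraction", value=0.1, min=0.0, max=0.99)
            p.add("triplet_time", value=5e-6, vary=False)
        for name, value in self.fixed.items():
            if name not in p:
                raise ValueError(f"cannot fix unknown parameter {name!r}")
            p[name].set(value=value, vary=False)
        return p

    def _eval(self, p: lmfit.Parameters) -> np.ndarray:
        v = p.valuesdict()
        if self.model_id == "diff2d":
            return model_diff2d(self.tau, v["g0"], v["tau_d"], v["offset"])
        return model_diff3d(
            self.tau,
            v["g0"],
            v["tau_d"],
            v.get("aspect_ratio", 1.0),
            v["offset"],
            v.get("triplet_fraction", 0.0),
            v.get("triplet_time", 5e-6),
        )

    def fit(self) -> FCSFitResult:
        """Unweighted least-squares fit; bound-hitting flags non-convergence."""
        params = self._build_params()
        minimizer = lmfit.Minimizer(
            lambda p: self._eval(p) - self.g, params
        )
        out = minimizer.minimize(method="least_squares", xtol=1e-10, ftol=1e-10)
        values = {k: float(v.value) for k, v in out.params.items()}
        stderr = {
            k: (float(v.stderr) if v.stderr is not None else None)
            for k, v in out.params.items()
        }
        converged = bool(out.success) and not _at_bounds(out.params)
        residuals = self.g - self._eval(out.params)
        return FCSFitResult(
            model_id=self.model_id,
            params=values,
            stderr=stderr,
            converged=converged,
            residuals=residuals,
            lag_times_s=self.tau.copy(),
            fit_range_s=(float(self.tau[0]), float(self.tau[-1])),
            pixel_index=self.curve.pixel_index,
            mean_intensity=self.curve.mean_intensity,
        )


def _at_bounds(params: lmfit.Parameters, atol_frac: float = 1e-6) -> bool:
    """True if any free parameter ended up pinned at a bound."""
    for par in params.values():
        if not par.vary:
            continue
        lo, hi = par.min, par.max
        if np.isfinite(lo) and np.isfinite(hi):
            span = hi - lo
        else:
            span = max(abs(par.value), 1.0)
        if np.isfinite(lo) and par.value - lo <= atol_frac * span:
            return True
        if np.isfinite(hi) and hi - par.value <= atol_frac * span:
            return True
    return False


def fit_curve(
    curve: CorrelationCurve,
    model_id: str = "diff2d",
    fixed: Optional[Dict[str, float]] = None,
    fit_max_lag_s: float = 10.0,
) -> FCSFitResult:
    """Fit one correlation curve (functional shorthand for FCSDiffusionModel)."""
    return FCSDiffusionModel(curve, model_id, fixed, fit_max_lag_s).fit()


# ---------------------------------------------------------------------------
# calibration and derived quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    """Observation-spot calibration: 1/e^2 radius and spot area."""

    omega_um: float
    source: str = "fwhm"

    def __post_init__(self) -> None:
        if self.omega_um <= 0:
            raise ValueError("omega must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.omega_um**2


def calibrate_omega_from_dye(
    tau_d_measured_s: float, d_reference_um2_s: float
) -> CalibrationResult:
    """Spot radius from a reference dye of known diffusion coefficient.

    omega = sqrt(4 * D_ref * tau_D); the spot area is pi * omega^2.
    """
    if tau_d_measured_s <= 0 or d_reference_um2_s <= 0:
        raise ValueError("transit time and reference D must be positive")
    omega = math.sqrt(4.0 * d_reference_um2_s * tau_d_measured_s)
    return CalibrationResult(omega_um=omega, source="reference_dye")


def calibration_from_fwhm(psf_fwhm_nm: float) -> CalibrationResult:
    """Spot calibration directly from a known PSF FWHM (nm)."""
    return CalibrationResult(omega_um=fwhm_to_waist(psf_fwhm_nm) * 1e-3, source="fwhm")


def transit_time_from_omega(omega_um: float, d_um2_s: float) -> float:
    """Transit time (s) of a species with diffusion coefficient D through a
    spot of 1/e^2 radius omega: tau_D = omega^2 / (4 D)."""
    if omega_um <= 0 or d_um2_s <= 0:
        raise ValueError("omega and D must be positive")
    return omega_um**2 / (4.0 * d_um2_s)


def transit_time_from_d(d_um2_s: float, psf_fwhm_nm: float) -> float:
    """Expected transit time in milliseconds for diffusion coefficient D
    (um^2/s) through a Gaussian spot of the given FWHM (nm)."""
    omega = fwhm_to_waist(psf_fwhm_nm) * 1e-3
    return transit_time_from_omega(omega, d_um2_s) * 1e3


def d_from_transit_time(tau_d_ms: float, psf_fwhm_nm: float) -> float:
    """Diffusion coefficient (um^2/s) from a transit time in ms: D = omega^2/(4 tau_D)."""
    if tau_d_ms <= 0:
        raise ValueError("transit time must be positive")
    omega = fwhm_to_waist(psf_fwhm_nm) * 1e-3
    return omega**2 / (4.0 * tau_d_ms * 1e-3)


def brightness_cpm(mean_intensity: float, g0: float, dwell_time_s: float) -> float:
    """Molecular brightness (counts per molecule, Hz).

    cpm = mean intensity (counts per dwell) * G(0) / dwell time.  Note that
    for a 2D Gaussian spot this equals half the peak count rate of a single
    particle at the spot centre.
    """
    if dwell_time_s <= 0:
        raise ValueError("dwell time must be positive")
    return mean_intensity * g0 / dwell_time_s


def particle_density(g0: float, calibration: CalibrationResult) -> float:
    """Particles per um^2 from the correlation amplitude: N = 1/G(0),
    density = N / (pi omega^2)."""
    if g0 <= 0:
        raise ValueError("g0 must be positive")
    return (1.0 / g0) / calibration.area_um2


def moment_brightness(trace: IntensityTrace, dwell_time_s: float) -> float:
    """Moment-based (number-and-brightness) estimator, Hz.

    epsilon = (var - mean) / mean counts per dwell, divided by the dwell
    time.  Secondary estimator: needs no correlation but is sensitive to the
    detector calibration.
    """
    if dwell_time_s <= 0:
        raise ValueError("dwell time must be positive")
    x = trace.counts.astype(float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero-mean trace")
    var = x.var()
    return (var - mean) / mean / dwell_time_s


# ---------------------------------------------------------------------------
# carpet-level fit table
# ---------------------------------------------------------------------------

def fit_carpet_curves(
    curves: Sequence[CorrelationCurve],
    dwell_time_s: float,
    model_id: str = "diff2d",
    fixed: Optional[Dict[str, float]] = None,
    fit_max_lag_s: float = 10.0,
    calibration: Optional[CalibrationResult] = None,
    measurement_id: str = "",
) -> pd.DataFrame:
    """Fit every curve and assemble the interchange fit table.

    Columns: measurement_id, pixel, model, g0, tau_d_ms, offset, cpm_hz,
    density_um2 (NaN without a calibration), converged, nrmsd.
    """
    from .quality import nrmsd as _nrmsd

    rows = []
    for curve in curves:
        try:
            res = fit_curve(curve, model_id, fixed, fit_max_lag_s)
        except ValueError:
            continue
        dens = (
            particle_density(res.g0, calibration)
            if (calibration is not None and res.g0 > 0)
            else np.nan
        )
        rows.append(
            {
                "measurement_id": measurement_id,
                "pixel": curve.pixel_index,
                "model": model_id,
                "g0": res.g0,
                "tau_d_ms": res.tau_d_ms,
                "offset": res.offset,
                "cpm_hz": brightness_cpm(res.mean_intensity, res.g0, dwell_time_s),
                "density_um2": dens,
                "converged": res.converged,
                "nrmsd": _nrmsd(curve, res) if res.g0 > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
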