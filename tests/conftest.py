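"""Shared fixtures: small simulated carpets reused across test modules."""

import numpy as np
import pytest

from btsfluct import ScanConfig, SimBox, Species, simulate_free


@pytest.fixture(scope="session")
def default_box():
    return SimBox()


@pytest.fixture(scope="session")
def short_scan():
    """10 s acquisition at the default geometry (50 px, 240 nm FWHM, 2000 Hz)."""
    return ScanConfig(n_lines=20_000)


@pytest.fixture(scope="session")
def sim_carpet(short_scan, default_box):
    """One 10 s free-diffusion carpet: D = 1 um^2/s, 25 kHz peak, 100 particles."""
    return simulate_free(
        short_scan, default_box, Species(1.0, 25.0, 100), seed=7
    )


@pytest.fixture(scope="session")
def study_scale_tables(default_box):
    """Fit tables from three pooled 30 s free-diffusion measurements
    (D = 1 um^2/s, 25 kHz peak brightness, 100 particles): one condition at
    the study's acquisition scale."""
    from btsfluct import correlate_carpet, fit_carpet_curves

    scan = ScanConfig(n_lines=60_000)
    frames = []
    for rep in range(3):
        carpet = simulate_free(
            scan, default_box, Species(1.0, 25.0, 100), seed=60 + rep
        )
        curves = correlate_carpet(carpet, crop_seconds=10.0)
        frames.append(
            fit_carpet_curves(
                curves, dwell_time_s=scan.dwell_time_s, measurement_id=str(rep)
            )
        )
    return frames


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
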