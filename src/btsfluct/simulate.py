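"""Brownian-dynamics photon-count simulator for scanning FCS.

Point particles perform free 2D Brownian motion in a periodic box and are
sampled by a confocal spot scanned along a fixed line of pixels.  At the
sampling instant of pixel p (line l) the expected count in one dwell is

    mu = dwell * sum_j B_j * exp(-2 d_j^2 / omega^2)

with B_j the particle's peak count rate, d_j its (minimal-image) distance to
the pixel centre and omega the 1/e^2 PSF radius.  Detected counts are Poisson
draws with that mean, which yields realistic photon-counting shot noise.

Because Brownian motion is Markovian, particle positions are propagated with
exact Gaussian increments directly between consecutive sampling instants
(per-axis variance 2*D*dt, dt the dwell within a line and dwell+retrace gap
across line boundaries); this is distributionally identical to stepping at a
finer clock.  Particles keep diffusing during the retrace gap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .carpet import PhotonCarpet, ScanConfig, SimBox, Species

__all__ = [
    "simulate_free",
    "simulate_mixture",
    "simulate_species",
    "OLIGOMER_D_FACTORS",
]

# Diffusion slow-down of oligomers relative to the monomer: dimers, trimers
# and tetramers diffuse at 0.7x, 0.5x and 0.25x the monomer coefficient;
# brightness increases linearly with the oligomeric state.
OLIGOMER_D_FACTORS = {2: 0.7, 3: 0.5, 4: 0.25}

_LINES_PER_CHUNK = 1024


def _pixel_centres_x(scan: ScanConfig, box: SimBox) -> np.ndarray:
    """Pixel centres along x (um), centred on the box width."""
    spacing = scan.pixel_spacing_nm * 1e-3
    offsets = (np.arange(scan.n_pixels) - (scan.n_pixels - 1) / 2.0) * spacing
    return box.width_um / 2.0 + offsets


def simulate_species(
    scan: ScanConfig,
    box: SimBox,
    species: Sequence[Species],
    seed: int,
) -> PhotonCarpet:
    """Simulate an sFCS carpet for an arbitrary list of species.

    One root :class:`numpy.random.SeedSequence` spawns three independent
    streams (initial positions, Brownian displacements, photon shot noise),
    so identical ``(scan, box, species, seed)`` give bit-identical carpets.
    """
    species = list(species)
    if not species:
        raise ValueError("at least one species is required")
    root = np.random.SeedSequence(seed)
    ss_init, ss_move, ss_photon = root.spawn(3)
    rng_init = np.random.Generator(np.random.PCG64(ss_init))
    rng_move = np.random.Generator(np.random.PCG64(ss_move))
    rng_photon = np.random.Generator(np.random.PCG64(ss_photon))

    n_total = int(sum(s.n_particles for s in species))
    d_coeffs = np.concatenate(
        [np.full(s.n_particles, s.diffusion_um2_s) for s in species]
    )
    brightness_hz = np.concatenate(
        [np.full(s.n_particles, s.brightness_khz * 1e3) for s in species]
    )

    n_pix, n_lines = scan.n_pixels, scan.n_lines
    dwell = scan.dwell_time_s
    omega = scan.psf_waist_um
    w, h = box.width_um, box.height_um
    px_x = _pixel_centres_x(scan, box)
    line_y = h / 2.0

    counts = np.empty((n_lines, n_pix), dtype=np.int64)

    if n_total == 0:
        counts[:] = 0
        return PhotonCarpet(
            counts, scan, ground_truth=_manifest(species, box, seed)
        )

    pos = rng_init.uniform(0.0, [w, h], size=(n_total, 2))

    # time gaps between consecutive sampling instants within one line block:
    # dwell between pixels, dwell + retrace across the line boundary
    dt_line = np.full(n_pix, dwell)
    dt_line[0] = scan.retrace_gap_s + dwell  # first pixel follows previous line
    sqrt2dt = np.sqrt(2.0 * dt_line)

    # single-precision kernel: position round-off (~1e-4 um over a chunk) is
    # negligible against the 0.2 um PSF radius, and halves memory bandwidth
    sqrt_d = np.sqrt(d_coeffs).astype(np.float32)
    bright32 = brightness_hz.astype(np.float32)
    inv_psf = np.float32(-2.0 / (omega * omega))
    w32, h32 = np.float32(w), np.float32(h)

    for start in range(0, n_lines, _LINES_PER_CHUNK):
        stop = min(start + _LINES_PER_CHUNK, n_lines)
        n_chunk = stop - start
        t_chunk = n_chunk * n_pix

        # per-instant x pixel centre for this chunk
        chunk_px = np.tile(px_x, n_chunk).astype(np.float32)

        # x and y displacement streams, contiguous (t_chunk, n_total) each
        steps = rng_move.standard_normal((2, t_chunk, n_total), dtype=np.float32)
        scale = (
            np.tile(sqrt2dt, n_chunk).astype(np.float32)[:, None] * sqrt_d[None, :]
        )
        steps *= scale[None, :, :]
        if start == 0:
            # first ever sample: particles observed at their initial positions
            steps[:, 0, :] = 0.0
        np.cumsum(steps, axis=1, out=steps)
        dx, dy = steps[0], steps[1]
        dx += pos[:, 0].astype(np.float32)[None, :]
        dy += pos[:, 1].astype(np.float32)[None, :]
        pos = np.stack([dx[-1], dy[-1]], axis=1).astype(np.float64)

        dx -= chunk_px[:, None]
        dy -= np.float32(line_y)
        # minimal-image distance under periodic boundaries (in place)
        tmp = np.empty_like(dx)
        np.multiply(dx, np.float32(1.0 / w), out=tmp)
        np.rint(tmp, out=tmp)
        tmp *= w32
        dx -= tmp
        np.multiply(dy, np.float32(1.0 / h), out=tmp)
        np.rint(tmp, out=tmp)
        tmp *= h32
        dy -= tmp
        dx *= dx
        dy *= dy
        dx += dy
        dx *= inv_psf
        rate = np.exp(dx, out=dx)
        mu = dwell * (rate @ bright32).astype(np.float64)
        counts[start:stop] = rng_photon.poisson(mu).reshape(n_chunk, n_pix)
        # keep carried positions wrapped to avoid float blow-up on long runs
        pos[:, 0] %= w
        pos[:, 1] %= h

    return PhotonCarpet(counts, scan, ground_truth=_manifest(species, box, seed))


def _manifest(species: Sequence[Species], box: SimBox, seed: int) -> dict:
    return {
        "seed": int(seed),
        "box": {"width_um": box.width_um, "height_um": box.height_um},
        "species": [
            {
                "diffusion_um2_s": s.diffusion_um2_s,
                "brightness_khz": s.brightness_khz,
                "n_particles": s.n_particles,
                "oligomer_order": s.oligomer_order,
            }
            for s in species
        ],
    }


def simulate_free(
    scan: ScanConfig, box: SimBox, species: Species, seed: int
) -> PhotonCarpet:
    """Simulate free diffusion of a single species."""
    return simulate_species(scan, box, [species], seed)


def simulate_mixture(
    scan: ScanConfig,
    box: SimBox,
    monomer: Species,
    oligomer_order: int,
    oligomer_fraction: float,
    seed: int,
) -> PhotonCarpet:
    """Simulate a monomer/oligomer mixture at a given oligomer fraction.

    The total particle number is kept constant: a fraction of the monomers is
    replaced by oligomers of the requested order, which diffuse slower by the
    order-specific factor (0.7 / 0.5 / 0.25 for dimer / trimer / tetramer)
    and are brighter by the order (linear brightness scaling).
    """
    if oligomer_order not in OLIGOMER_D_FACTORS:
        raise ValueError(
            f"oligomer_order must be one of {sorted(OLIGOMER_D_FACTORS)}, "
            f"got {oligomer_order}"
        )
    if not 0.0 <= oligomer_fraction <= 1.0:
        raise ValueError("oligomer_fraction must lie in [0, 1]")

    n_total = monomer.n_particles
    n_oligo = int(round(oligomer_fraction * n_total))
    n_mono = n_total - n_oligo
    factor = OLIGOMER_D_FACTORS[oligomer_order]

    species = [
        Species(
            diffusion_um2_s=monomer.diffusion_um2_s,
            brightness_khz=monomer.brightness_khz,
            n_particles=n_mono,
            oligomer_order=1,
        ),
        Species(
            diffusion_um2_s=monomer.diffusion_um2_s * factor,
            brightness_khz=monomer.brightness_khz * oligomer_order,
            n_particles=n_oligo,
            oligomer_order=oligomer_order,
        ),
    ]
    return simulate_species(scan, box, species, seed)
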