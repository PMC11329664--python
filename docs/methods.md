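# Methods

`btsfluct` implements brightness-transit statistics (BTS) for scanning
fluorescence correlation spectroscopy (sFCS): a simulation and analysis
pipeline that quantifies membrane diffusion (transit times) and
oligomerisation (molecular brightness) from line-scan photon-count data,
compares conditions at the histogram level, and classifies the diffusion
mode of pooled transit-time distributions.  This note records the models,
the numerical choices, and what the synthetic data do and do not emulate.

## Simulation model

Point particles perform free 2D Brownian motion in a periodic box
(default 5 × 8 µm², emulating a supported lipid bilayer patch) and are
observed by a Gaussian confocal spot scanned along a fixed line of pixels.
The detection profile is W(r) = exp(−2r²/ω²) with ω = FWHM/√(2 ln 2); the
default FWHM is 240 nm, so ω ≈ 204 nm.  At the sampling instant of pixel
*p* in line *l* the expected photon count in one dwell is

    μ(l, p) = δ · Σ_j B_j · exp(−2 d_j² / ω²),

where δ is the pixel dwell time (default 4 µs), B_j the particle's **peak**
count rate (the rate a particle would produce sitting exactly at the spot
centre) and d_j the minimal-image distance from particle *j* to the pixel
centre.  Detected counts are Poisson draws with mean μ, which produces
photon-counting shot noise with the correct rate dependence.

Brownian motion is Markovian, so positions are advanced by exact Gaussian
increments (per-axis variance 2DΔt) directly between consecutive sampling
instants: Δt = δ between pixels of one line and δ + retrace gap across line
boundaries.  Particles keep diffusing during the retrace.  Stepping at a
finer internal clock would change nothing distributionally, so no separate
fine-stepping mode exists.  Default scan: 50 pixels at 100 nm spacing,
2000 Hz line rate, 30 s acquisition, 100 particles at 25 kHz peak
brightness — one "measurement" yielding 50 pixel traces.

Oligomer mixtures replace a fraction *f* of the monomers by oligomers of
order 2, 3 or 4, keeping the total particle number constant; oligomers are
slower by the factors 0.7, 0.5 and 0.25 respectively and brighter linearly
with their order.

Randomness: one root `SeedSequence(seed)` spawns three independent streams
(initial positions, displacements, shot noise); identical inputs give
bit-identical carpets.  The propagation kernel runs in single precision
(position round-off ≈ 10⁻⁴ µm over a processing chunk, four orders of
magnitude below ω); counts and all analysis are double precision.

## Correlation estimator

Each pixel column is a photon-count time series at the line period
(0.5 ms at 2000 Hz).  The fluctuation autocorrelation is estimated with
segment-local (symmetric) normalisation,

    G(k) = ⟨I_t I_{t+k}⟩ / (μ_L μ_R) − 1,

with μ_L, μ_R the means of the leading/trailing overlap segments, which
removes first-order drift bias.  G → 0 at uncorrelated lags; any residual
baseline is absorbed by the fitted offset.

Lag grids: `linear` evaluates every integer lag (used as the brute-force
oracle in tests); `multi_tau` is the classic software correlator — 16 lags
in the first octave on the raw trace, then repeated binning-by-2 with lags
9–16 of each binned level.  The two schemes agree exactly (to 1e-12) on the
unbinned first octave; binned levels trade a triangular-average bias of
order (bin/lag)² ≤ 1/81 for a large variance reduction, without which
per-pixel fitting is impractical.

Curves are cut at a maximum lag of **one quarter of the trace length**.
Beyond that the mean-subtracted estimator acquires a shape-distorting
negative bias of order τ/T: fitting a 20 s trace out to lag 10 s biases
recovered diffusion coefficients upward by ~6% at D = 0.1 µm²/s, out to
5 s by ~3%.  T/4 also matches the ratio used for the experimental analysis
convention this package follows (10 s fit maximum on 38–50 s traces).

Preprocessing order is fixed: temporal crop (default: first 10 s removed,
discarding immobile/settling contributions) → optional spatial crop
(records keep original pixel coordinates) → optional photobleaching
correction → autocorrelation.  Bleach correction partitions the trace into
windows (default 16 s) and rescales each multiplicatively to the global
mean; windows with zero mean are left unscaled with a warning.

## FCS model fitting

Curves are fitted by unweighted least squares to
G(τ) = G(0)·G_D(τ)·G_T(τ) + offset, with

* `diff2d` (membrane diffusion): G_D = (1 + τ/τ_D)⁻¹ — exact for a 2D
  Gaussian spot and free 2D diffusion;
* `diff3d`: an additional axial factor (1 + τ/(AR²τ_D))^(−1/2) with aspect
  ratio AR ∈ [1, 10], for solution calibration measurements;
* `diff3d_triplet`: times a triplet photophysics factor
  1 + T/(1−T)·exp(−τ/τ_T), with τ_T fixed at 5 µs by default.

The offset is free for sFCS fits (it absorbs the finite-trace baseline of
the fluctuation estimator) and may be fixed for calibration fits.  Initial
guesses: G(0) from the first three lags, τ_D from the half-decay lag,
offset from the last decade of lags.  A fit is flagged non-converged if
the solver fails or any free parameter lands on a bound (rather than
silently clipping); non-converged fits are excluded from pooling.
`FCSDiffusionModel.fit()` returns an `FCSFitResult` with estimates,
standard errors from the local curvature, residuals and `summary()`.

Calibration and derived quantities:

* D = ω²/(4τ_D); ω either from a reference dye of known D (ω = √(4D·τ_D))
  or directly from the PSF FWHM.  Spot area A = πω².
* Molecular brightness cpm = ⟨I⟩·G(0)/δ (counts s⁻¹ per molecule).  For a
  2D Gaussian spot this equals exactly **half the peak rate** of one
  particle (∫W²/∫W = 1/2), so simulations at 25 kHz peak brightness yield
  ≈12.5 kHz cpm; only relative changes matter for oligomerisation calls.
* Particle density = 1/(G(0)·πω²), taking the spot area as πω² exactly
  (no effective-area correction factor); the simulator round-trip recovers
  the box density within the PSF-sampling bias (tested at 20%).
* A moment (number-and-brightness) estimator ε = (var−mean)/mean/δ is
  provided as a secondary, correlation-free brightness measure.

## Quality metrics

* nRMSD = √(Σ residuals²)/G(0)_fit over the fitted lag range — the summed
  (not averaged) form; `per_lag=True` gives the mean-normalised variant for
  comparisons across different lag grids.
* Chunked SNR: the trace is split into equal chunks (default 3), each
  correlated; SNR = mean over the first 9 lags of G_full/√var, where var is
  the sample variance (ddof = 1) across chunk curves.  Zero variance at any
  lag returns NaN with a warning.  Chunk length is a parameter because
  usable trace lengths vary between acquisitions.

## BTS histograms and the permutation test

Each converged fit contributes one record (ln(τ_D/1 ms), cpm).  Records
pool across pixels and measurements — spatial information is deliberately
discarded — into a pdf-normalised 2D histogram on fixed edges (default
50 × 50 bins spanning the pooled range); conditions being compared must
share identical edges.

Histogram distance: BD = −ln Σ√(p·q) on bin masses; 0 iff identical,
disjoint support returns a finite sentinel (10⁶) standing in for +∞.
Empty bins contribute nothing (no pseudo-counts).

Significance is a permutation test with the estimator
p = (#{BD_null > BD_data} + 1)/(n_it + 1), so p ∈ [1/(n_it+1), 1].  The
null draws come from permuting the pooled records and splitting them into
two disjoint groups.  By default the groups keep the **original sample
sizes** ("matched"): BD is strongly sample-size dependent (sparser
histograms have systematically larger BD), so null draws must share the
sampling noise of the observed statistic.  A literal subsampled null
(groups of 10–20% of each sample) is available via
`null_scheme="subsampled"`; at desk-scale record counts its sparseness
inflation makes it so conservative it cannot detect even a 60% brightness
shift, and once subsample histograms stop overlapping the capped-infinity
ties degrade the p-value — it exists for comparison, not analysis.
Measured with the matched default: type-I error ≈ nominal (2/40 at
α = 0.05 under the null) and p = 10⁻³ for dimer fractions of 0.1 and 0.5
against pure monomer at 250 records per condition.

## Diffusion-mode model selection

Pooled transit times (ms) are fitted by maximum likelihood under three
candidate distributions: lognormal (free diffusion), double lognormal
(hindered/trapped diffusion: a second slower population) and Gaussian (a
control against blind log-transformation).  Lognormal and Gaussian MLEs
are closed-form moments; the double lognormal is maximised numerically on
the log scale (L-BFGS-B, bounded: weight in (0.01, 0.99), means within the
data span ± 1, scales in [10⁻³σ̂, 10σ̂]) with deterministic seeded
multi-starts.  One start is always the degenerate equal-component solution
at the single-lognormal optimum, which guarantees the nesting inequality
logL(double) ≥ logL(single) up to optimiser tolerance; components are
reported with μ₁ < μ₂.  The log-Jacobian −Σ ln x is included so that
likelihoods of log-scale and natural-scale models are comparable.

Models are ranked by BIC = k ln n − 2 logL (k = 2, 5, 2) and summarised by
relative likelihoods RL = exp((BIC_min − BIC)/2); the best model has
RL = 1 exactly, with BIC ties broken toward fewer parameters.  RL = 1 for
the lognormal is the free-diffusion call.  Classification needs
study-scale pooling: per-pixel transit-time estimates from short, noisy
acquisitions are genuinely heavy-tailed (heterogeneous per-pixel
precision), and a single 10 s carpet of 50 records can legitimately prefer
the mixture; three pooled 30 s measurements classify cleanly.

## Problem sizes and what the tests show

Simulated study conditions follow the acquisition geometry above; the
quantitative benchmark simulates D ∈ {0.1, 1, 5} µm²/s at 25 kHz peak
brightness, 10 measurements × 50 pixels (500 curves) per condition for the
acceptance script and 4 measurements per condition in the test suite.
Per-curve transit-time estimates scatter 20–30% at this photon budget;
the quantitative claim is about the ensemble (median-over-curves) recovery
per condition, whose median error across the D grid is the headline
number.  D = 5 µm²/s sits at the sampling boundary (transit ≈ 4 line
periods at 2000 Hz) and retains a percent-scale systematic plus a few
percent of seed-to-seed scatter in its condition-level estimate.

The synthetic data emulate photon-counting shot noise, diffusion through a
scanned Gaussian spot, finite-trace estimator bias and monomer/oligomer
brightness mixtures.  They do not emulate detector afterpulsing or dead
time, triplet blinking, photobleaching, axial (3D) diffusion, membrane
undulations, stage drift or sample heterogeneity — so passing tests
validate the estimators and statistics, not robustness to every
experimental artefact; the bleach-correction and spatial-cropping steps
exist precisely for such artefacts in real data.

## Known limitations

* Brightness is defined as the peak count rate; the measured cpm is half
  of it for the 2D Gaussian spot.  Comparisons between conditions are
  unaffected; absolute brightness calibration against other conventions
  needs the factor 2.
* The mixture fraction of monomers vs oligomers is not identifiable from
  BTS alone (amplitude-weighted brightness); the statistics detect the
  presence of oligomers, not their stoichiometric fraction.
* Very fast diffusion (transit ≲ 4 line periods) is at the temporal
  resolution limit; very slow diffusion (transit approaching the trace
  length) is at the statistical limit.  Both recover with larger error,
  matching the boundary behaviour expected of sFCS.
* Particle density uses N = 1/G(0) and A = πω² without an effective-area
  factor; densities carry the PSF-weighted sampling bias (≤ ~20% in the
  tested regime).
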