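# Methods

`dopafilm` reconstructs, as tested code, the analysis chain used for planar
dopamine-sensitive film imaging: a fluorescence movie of a chemi-sensitive
2D surface is converted to ΔF/F₀, segmented into release hotspots,
and reduced to per-site kinetic, quantal and biophysical statistics. A
synthetic movie generator with exactly known ground truth closes the loop:
every stage is validated by recovering quantities that were planted in the
simulation.

## Forward model (simcore)

The simulated world is a flat sensing film under a monolayer of neurites.

**Release.** Vesicular events occur at fixed sites. Evoked events follow
optical stimulus trains (default 5 pulses at 25 Hz, per-pulse release
probability 0.8); spontaneous events are an independent Poisson process per
site (0.29 s⁻¹ for the sodium-channel-blockade scenario, 0.16 s⁻¹ for
pre-drug spontaneous activity). Each event releases an integer number of
quanta (1–3, categorical) whose sizes are lognormal with mean `Q_quantum`
(default 1.5×10⁴ nM·µm², chosen so one quantum produces a few-percent ΔF/F
response, the scale of measured quantal transients) and CV 0.25.

**Diffusion and clearance.** Free dopamine follows the 2D free-space
Green's function C(r,t) = Q/(4πDt)·exp(−r²/4Dt), damped by first-order
clearance exp(−k_up·t) that stands in for transporter (DAT) activity.
Default D = 110 µm²/s (1.1×10⁻⁶ cm²/s, the measured mean). Cellular presets
use k_up = 25 s⁻¹, i.e. a confinement length √(D/k) ≈ 2 µm — strong local
clearance at DAT-rich release sites; the reuptake-blockade scenario divides
k_up by 4. Events carry a finite initial extent `sigma_release_um`,
implemented exactly as a time offset τ → τ + σ_rel²/(2D) in the Green's
function. This width is *not* cosmetic: a true point source seen by an
integrating sensor produces a scale-free logarithmic footprint whose
Gaussian-fit FWHM is set by estimator scales rather than physics; the
finite fusion-cloud width restores a real, tunable length scale. The preset
width (≈0.54 µm) is calibrated once, by bisection on the noiseless
single-quantum forward model, so the planted hotspot FWHM equals the
measured dendritic value of 3.2 µm. The wider evoked axonal footprint is an
emergent consequence of multi-pulse release and is not separately planted.

**Sensor.** The film is a two-state reversible binding surface,
dS/dt = k_on·C·(1−S) − k_off·S with k_on = k_off/Kd; Kd = 268 nM is the
measured apparent dissociation constant, and k_off = 0.26 s⁻¹ makes the
post-event decay constant ≈ 3.8 s, the measured evoked clearance scale. The
integrator treats C as constant over each substep and applies the exact
exponential update, with the per-substep mean concentration computed as a
*dose integral* (midpoint quadrature, geometrically refined across the
release instant, on pixel-area-averaged erf fields). This makes the bound
map independent of the substep resolution despite the 1/t singularity of
the Green's function — naive endpoint sampling changes planted widths by
tens of percent when the frame rate changes.

**Camera.** Expected counts = baseline·(1 + A_max·S) with baseline 2000
counts and A_max = 1; Poisson shot noise, then Gaussian read noise
(SD 5 counts), clipped at zero. Identical seeds give bit-identical movies;
all randomness derives from `blake2b(seed, stage-name)` sub-seeds.

**Presets.** `evoked_axon` (25 varicosities on three axonal branches, 8
release-competent = 32%, two stimulus trains plus sparse spontaneous
activity), `dendrite` (30 varicosities every 2.5 µm along a 75 µm path,
every third competent → sites planted every 7.5 µm), `ttx`, `spontaneous`,
`ca_free` (no events), `nom` (4× slower clearance), and
`diffusion_fixture` (a single noiseless event with no uptake and a
fast-equilibrating sensor variant, k_off = 50 s⁻¹, so the film tracks
concentration rather than integrating it — see "Diffusivity" below).
Grid sizes are scaled down from the full 180×230 µm field of view so a
simulation runs in seconds; densities and rates are unchanged.

## Baseline (ΔF/F₀)

The raw movie is blurred with a 2D Gaussian (σ = 0.5 px). A leaky
cumulative minimum — m₀ = F₀, m_t = min(F_t, m_{t−1} + η(F_t − m_{t−1})),
η = 0.01/frame — tracks the lower envelope while following slow drift. The
movie is lightly smoothed in time (σ = 3 frames) before the minimum so the
envelope sits near the noise floor rather than its extreme excursions.
The baseline is then the fixed point of

    F0 ← min(minima, (smooth(F0) + λ·minima)/(1 + λ)),

with temporal Gaussian smoothing (σ = 10 frames) and restoring weight
λ = 0.1. The restoring term matters: plain smooth-then-clip is heat flow
under an upper obstacle and, run to convergence, collapses everything to
the global minimum; the anchored iteration is a contraction with a unique
fixed point that is smooth where the minima are smooth and clipped through
sharp notches. F0 is floored at 1 count and dFF = (F_blur − F0)/F0.

Known bias: an envelope baseline sits ~2 noise SD below the mean, so
event-free dFF has a small positive offset (≲1%), and the baseline creeps
upward under multi-second transients (η per frame × duration), shaving a
few percent off recovered amplitudes. Both are quantified in the tests;
neither affects centroids, spacings, or model selection.

## Hotspot segmentation

The dF stack (per-pixel re-zeroed at its temporal median, negatives
clipped) is factorized as X ≈ WH, W ≥ 0 the spatial maps, H ≥ 0 the
loadings, minimizing ‖X − WH‖² + α‖W‖₁ + β·tr(WᵀLW) with L the 4-neighbor
pixel-grid Laplacian (the contiguity penalty; β = 0.1, α = 0 by default).
Multiplicative updates keep the objective non-increasing.

Rank selection (`k="auto"`) grows one component at a time: each new
component is warm-started from the previous solution and matched-filter
seeded from the residual (seed pixel = maximum of the temporally and
spatially smoothed residual energy). Growth stops when the added component
is no longer a detectable signal — its cluster's data trace must clear the
detection SNR floor of 5 — or when the energy gain falls below 10⁻³ of the
total. A reconstruction-error "elbow" was tried first and fails on
realistic movies: the Frobenius error is dominated by the noise floor and
by the DC term that clipping gives zero-mean noise, so the elbow fires at
rank 1 regardless of the number of sources. The clipped-noise DC typically
claims one spatially flat component; a cluster-area filter (> 20% of the
field) removes it.

Clusters are pixels ≥ 0.3 of a map's max. Because strongly time-correlated
sites (shared stimulus trains) can share one component, a multi-blob map is
split into one hotspot per connected blob (≥ 20 px; a map shattering into
more than 12 blobs is background and is dropped). Per-hotspot statistics:
ΔF/F trace = cluster-mean dF over cluster-mean F0; intensity-weighted
centroid on the mean of the five post-peak dF frames (the bound-fraction
footprint decays uniformly after release ends, so averaging buys SNR
without broadening); spatial FWHM from an isotropic Gaussian+offset fit in
a window sized by the radial half-max radius, with the background taken
from a local annulus 10–14 px out (so ambient spillover does not inflate
widths). Duplicates within 1.7 µm, and satellites within 5 µm whose traces
correlate > 0.9 with a stronger neighbor, are merged.

Varicosities are detected in the structural channel as connected regions
≥ 3× the mean intensity along the process mask (area ≥ 4 px), with
intensity-weighted centroids. Hotspots are matched to varicosities by
greedy nearest-neighbor without reuse inside 1.7 µm (the measured
localization bound, < 5 camera pixels). Along-path spacing projects
centroids to polyline arclength (lateral tolerance 3 µm).

## Kinetics

Events are local maxima with prominence ≥ 2% ΔF/F gated at SNR ≥ 5, where
the detection SNR divides peak height above a pre-rise baseline window by
the robust noise floor (median absolute successive difference / √2 ×
1.4826) — usable even when transients pile up. The reported measurement
SNR follows the conventional definition (peak dF over the SD of baseline F
in a pre-event window). Temporal FWHM interpolates the half crossings of
(peak − local baseline). τ_off is a three-parameter fit A·exp(−t/τ) + c
from the peak over min(10× an initial guess, the next event); the offset
term matters — a two-parameter fit is biased when the trace has a plateau.
τ_peak is the time from the maximum of the second difference of the
lightly smoothed trace (σ = 2 frames) to the peak. τ_10/90 is Q(0.9) −
Q(0.1) of the τ_off population with linear-interpolation quantiles.

## Quantal analysis

Peak amplitudes are fitted with 1–4 component 1D Gaussian mixtures by EM
(quantile-spread initialization, 10 restarts, SDs floored at 10⁻³ of the
sample SD) and with a lognormal (exact MLE). AIC = 2p − 2logL with
p = 3k − 1 for a k-mixture and p = 2 for the lognormal; minimum AIC wins,
ties toward fewer parameters. The quantile-quantile table inverts the
mixture CDF by bracketed bisection. The test fixture uses the measured
component means (5.7, 9.6, 15.1 %ΔF/F); the SDs (1.2%) and weights
(0.5/0.35/0.15) are assumptions of the fixture, not measured values.

## Diffusivity and calibration

A point-source footprint has per-axis variance σ²(t) = σ₀² + 2Dt, so D is
half the slope of a line fitted to per-frame isotropic Gaussian variances
about the (fixed) event centroid; σ₀² (instrument width, release-cloud
width, sensor lag) is absorbed in the intercept. The recovery fixture uses
the fast-unbinding sensor variant: with the default slow film (k_off =
0.26 s⁻¹) the bound map is the *time-integral* of the concentration, and
variance regression on it recovers ≈ D/2 — the default presets therefore
report an apparent D only. The fixture movie has no drift, so its dF is
taken against the pre-event mean frame; the envelope baseline would creep
under the transient and bias late-frame widths.

The dose-response calibration fits ΔF/F = A_max·C/(C + Kd) by nonlinear
least squares on log-spaced concentrations; fits whose covariance leaves Kd
effectively unbounded (all points in the linear regime) are flagged
ill-conditioned rather than reported.

## What a green test does and does not establish

The generator emulates quantal point-ish release, 2D diffusion with
first-order clearance, saturable reversible binding, and shot+read noise
on a stationary, spatially uniform film. It does not emulate: 3D tissue
geometry or tortuosity, Michaelis–Menten transporter saturation,
photobleaching (the film does not bleach), film inhomogeneity, motion, or
cross-talk from other fluorophores. Recovery of a planted quantity
therefore validates the estimator chain under the stated physics, not the
biological numbers themselves; the measured values quoted above enter as
fixture parameters, never as assertions about new data.

## Numerical choices

- Seeds: every stochastic stage draws from blake2b(master seed, stage
  name) mod 2³¹; fits with restarts are bit-reproducible under a fixed
  seed.
- NNMF runs in float32 (movies are 10⁷ entries); objectives accumulate in
  float64. Convergence: relative objective change < 10⁻⁴, cap 150
  iterations.
- Baseline iteration: tolerance 10⁻⁴ of the stack max, cap 60 iterations.
- EM: tolerance 10⁻⁸ relative log-likelihood, cap 500 iterations.
- Mixture CDF inversion: Brent bisection to 10⁻¹⁰.
- Degenerate inputs: all-zero stacks give zero components; all-identical
  samples raise a degeneracy error (mixtures) or a flagged σ = 0
  (lognormal); negative diffusivity slopes clip to 0 with a flag.

## Known limitations

- Evoked scenarios with a shared stimulus make site traces nearly
  collinear; sites are then recovered via blob splitting, which can leave
  (unmatched) satellite detections in dense arbors.
- Pipeline amplitudes are biased a few percent low under long transients
  (envelope baseline creep); kinetic *constants* are unaffected.
- The film's own decay constant bounds measurable kinetics: scenario
  differences in τ_off (e.g. minis vs evoked) are not reproduced, because
  one k_off governs all unbinding.
- The quantal stage needs ≥ 20 amplitude samples and skips (with a
  manifest warning) otherwise.
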