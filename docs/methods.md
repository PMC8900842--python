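# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the `trxss` analysis chain for millisecond infrared
temperature-jump (T-jump) time-resolved X-ray solution scattering.

## The measurement being modelled

A sample of protein in aqueous buffer sits in a 1.5 mm quartz capillary.
The detector free-runs at 500 Hz through alternating *laser-off* and
*laser-on* steps of 4 s (2000 frames of 1.9 ms live time each, 100 µs
readout); fresh sample is flushed in between steps, and a scan begins and
ends laser-off.  During an on step, a 1470 nm laser pulse (50 W, 2 ms)
arrives 1 s into the acquisition and heats the water; an optional train of
50 µs secondary pulses at 90 Hz maintains the jump for 3 s.  All timing
arithmetic lives in `trxss.timing`; frame binning is half-open
(an event on a frame boundary belongs to the later frame), frame timestamps
refer to the exposure start, and the secondary-pulse delay Δt2 is measured
from the *start* of the primary pulse (a convention, stated because trigger
diagrams are ambiguous about it).

Two signals ride on the static scattering:

* **solvent heating** — water's wide-angle scattering changes shape with
  temperature, linearly in ΔT over tens of degrees, with isosbestic points
  at q ≈ 1.5 and 2.1 1/Å.  This is both a nuisance (to be subtracted before
  protein analysis) and the internal thermometer;
* **protein response** — a low-q difference signal, negative at the lowest
  q for an expanding particle, whose occupancy α(t) rises as one or two
  exponentials after the jump.

## Synthetic data generator

No public benchmark data exist for this kind of acquisition, so
`trxss.synthetic` generates scans with the statistical structure the
analysis assumes.  Per frame at in-step time t (absolute time T):

    counts ~ Poisson( gain(T) · damage(t) · scale ·
                      [ I_base(q) + on · ( ΔT(t−Δt1)·g·b(q) + α(t−Δt1)·A·p(q) ) ] )

with `scale = (flux/1e12)·(live/1.9 ms)` and:

* `b(q)` — unit-ℓ2-norm water heating shape, constructed as
  −(q−1.5)(q−2.1)·Gaussian(centre 1.8, σ 0.3 1/Å).  Any smooth shape with
  zeros pinned at the isosbestic points serves; the polynomial×envelope
  form puts the zeros there *exactly*, which a difference of two Gaussians
  only does after solving for its coefficients.
* `p(q)` — unit-norm protein difference shape, Guinier(Rg 15 Å) −
  Guinier(Rg 14 Å): the expansion signature, negligible for q > 1 1/Å.
* `I_base(q)` — flat 2000 counts/bin + a broad water peak (3000 counts,
  centre 2.0, σ 0.25 1/Å) + for protein samples a Guinier term
  (1500 counts, Rg 14 Å).  Absolute count levels are synthetic: they are
  set so a 1.9 ms frame at 1e12 photons/s yields the ~2000–5000 counts/bin
  plausible for this geometry, not matched to any measured detector.
* `gain(T)` — sawtooth from 1.00 down to 0.90 over each 600 s injection
  period (top-up refills), phase-randomised per scan.
* `damage(t) = 1 + 0.01·t` — radiation-damage ramp, a function of in-step
  time only, because the sample is replaced between steps.  This is the
  precise reason the frame-matched difference protocol cancels it.
* ΔT profile: held constant for the secondary-train duration when the jump
  is maintained, otherwise decaying with a 200 ms cooling constant
  (consistent with the observation that decay towards the bath begins
  within ~100 ms of the jump).

**Signal amplitudes.** The heating amplitude is g = 12 counts/°C along
`b`, chosen so a *single* 2 ms difference frame at ΔT ≈ 15 °C has a
projection signal-to-noise of ≈ 2 — at the edge of detectability, the
regime the instrument's own characterisation describes.  The protein
amplitude is A = 200 counts along `p` (a ~1.5–2% relative change at the
low-q extremum for a ~40 mg/ml lysozyme-like sample).  A was fixed by a
Fisher-information calculation: with ~55 repeats, 2000-frame steps and this
noise model, the τ estimator's sampling SD evaluates to 0.46 s for
τ = 4.46 s and 0.72 s for τ = 5.26 s — matching the ±0.53 / ±0.71 s
uncertainties reported for those conditions, which we treat as the
instrument's statement of achieved precision.  The defaults for the
benchmark conditions are (ΔT, τ) = (13.1 °C, 4.46 s), (15.8 °C, 5.26 s)
and (12.7 °C, {0.04 s, 0.29 s} with amplitude split 0.4/0.6).

**What the generator does not emulate:** detector point-spread and pixel
masks, capillary-window artefacts near the top wall, buffer-mismatch
features, physically accurate water structure factors, frame-level flux
jitter (the drift is smooth), and kinetics coupled to the instantaneous
temperature (α(t) follows its exponentials regardless of the cooling
history).  Passing tests therefore demonstrate the *estimators*, not
detector physics.

## Normalisation

Frames are normalised to the water scattering via the trapezoid integral
over a window around the q ≈ 1.5 1/Å isosbestic point (default
[1.45, 1.55]; the isosbestic choice makes the window insensitive to the
heating signal itself).  The per-frame scale is `reference / estimate`,
where the estimate of the per-frame window integral is, by default, a
structured model: one gain level per step — split at detected
synchrotron-refill jumps, which stand ~15σ above the photon noise of
successive integrals — multiplied by the scan-wide mean in-step profile
(the damage ramp), fitted with a cubic over laser-off steps only.

This structure matters.  Raw per-frame scales carry the photon noise of an
~11-bin integral and inject a base-spectrum-shaped noise component into
every difference frame; in simulation this doubles the variance of the
fitted τ and, worse, deterministically tilts the leading SVD component of
a pure-solvent scan (the eigenvector perturbation is driven by the noise
covariance, which this component dominates), biasing τ after solvent
subtraction by about −20%.  Plain per-step means fail differently: a
refill jump inside a step is missed, and splitting at the jump and
averaging each segment rescales the damage ramp per segment, breaking its
frame-matched cancellation.  The gain×ramp model removes the gain (jumps
included, estimated by local linear fits across the cut so the ramp is not
aliased into the jump) while leaving the ramp in the data for the protocol
to cancel, and while dividing the *signal* by the same ramp so its time
course is undistorted.  `mode="frame"` and `mode="smooth"` remain
available; noise-free checks of exact cancellation use `"frame"`.

The normalisation reference defaults to the scan's own first off step, and
the reference level is carried in the metadata so that thermometry can put
a scan and a calibration measured at different incident flux on one scale.

## Difference protocol and averaging

For every on step m, frame n of the flanking off steps m−1 and m+1 is
averaged and subtracted from frame n of step m.  This cancels, exactly:
any drift linear in time (the flanking average interpolates to the on
step), and any common function of in-step time (the damage ramp).  The
null control differences *disjoint* successive off-step pairs
(off[2j+1] − off[2j]): the flanking-average rule applied to off steps
telescopes when averaged, collapsing the control's noise level to near
zero and making it useless as an empirical noise floor, so disjoint pairs
are used instead.

`average_repeats` reports the per-(frame, bin) mean and SEM across
repeats.  Adjacent on-series share one flanking off step
(covariance σ²/4 against a per-series variance of 3σ²/2), so the naive SEM
underestimates the standard error of the mean of a full consecutive run by
a factor √(2/1.25) ≈ 1.27; tests that need an exact noise scale either use
disjoint subsets or apply this factor, and users combining consecutive
repeats should too.

## Solvent-heating subtraction

A pure-solvent T-jump difference is rank 1 by construction (c(t)·b(q)), so
the solvent series is truncated to its leading SVD component before the
per-frame scalar fit s(t) = ⟨sample, solvent⟩/⟨solvent, solvent⟩ over the
scale window (default [1.9, 2.1] 1/Å, fitted per frame because ΔT evolves
in time).  Without the truncation the noisy regressor attenuates s(t)
(classical errors-in-variables bias; measured s ≈ 0.1 instead of ≈ 1 at
realistic noise).

## Thermometry

Calibration regresses the normalised static differences bin-wise (through
the origin) on ΔT; the slope curve is the per-degree basis ΔI_heat(q), and
the linearity diagnostic is the r² of amplitude vs ΔT.  Retrieval projects
each difference frame onto the basis over the WAXS fit range (default
[1.45, 2.5] 1/Å; the range used in practice is rarely stated, so it is
configurable), giving ΔT(t) = c(t) in °C directly.  The projection is
unweighted by default (a 1/σ² weighted variant exists); uncertainties
propagate from the per-bin SEM.  Using the same baseline temperature for
calibration and jump is recommended and a mismatch warns rather than
errors.  The spatial ΔT survey map uses bilinear interpolation on the
rectangular (100 µm) grid with an X-ray-footprint box average
(160 × 140 µm).

## Kinetics

The heat-subtracted difference matrix, restricted to the low-q window
(default q ≤ 1 1/Å), is decomposed by thin SVD with frames as rows.  SVD
signs are arbitrary, so they are fixed deterministically: the dominant
extremum of each q-space singular vector within the lowest-q quartile is
made negative (the expansion signature).  The leading time course is
fitted with offset + Σ Aᵢ(1 − exp(−t/τᵢ)), t = 0 at the laser pulse, by
nonlinear least squares with multi-start initialisation (τ starts
logarithmic from the sampling interval to the post-trigger window; 8
starts for one component, coarse-grid pairs for two).  The model is
*causal* — flat at the offset before the pulse — and the fit uses the
whole step including pre-trigger frames: the baseline pins the offset and
shrinks the τ uncertainty by ~25% relative to post-trigger-only fitting.
τ uncertainties come from the fit covariance; a flat trace is returned
with `identifiable=False` and infinite τ uncertainty rather than an error.
Model choice between one and two exponentials uses the corrected Akaike
criterion AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1); ties go to fewer
parameters, and the reported margin should be inspected — a margin near
zero means the data cannot distinguish the models.  A fitted τ is an
observed relaxation time: with modest jumps the transition is
bidirectional and forward and reverse rates contribute jointly.

With the 4 s step and the pulse at 1 s, only 3 s of evolution is observed;
τ beyond ~3 s is increasingly window-limited and its fitted uncertainty
grows accordingly (the recovery checks below use the reported
uncertainties of the benchmark conditions, which already reflect this).

## Heat model

The laser deposition and relaxation are modelled on a 2-D cross-section of
the capillary (transverse x, depth z from the laser-entry wall; cell-centred
grid, default spacing 25 µm):

* **Deposition.** ΔT(x, z) = (1−r)·E·G(x)·µ·e^(−µz)/(ρ·c_p·L) with
  E = power × pulse duration (default 50 W × 2 ms), r = 0.05 reflected,
  µ = 3000 1/m (1470 nm in water), G a transverse Gaussian of 0.9 mm FWHM
  renormalised over the capillary bore (the fiber tip sits against the
  capillary, so essentially all light enters it), and L the out-of-plane
  slab thickness, defaulting to the Gaussian-equivalent width of the spot
  (FWHM·√(2π)/2.355 ≈ 0.96 mm), which preserves the 3-D peak-plane
  amplitude.  Per-cell profiles are integrated exactly (erf differences,
  exponential cell integrals), so the deposited energy equals the
  Beer-Lambert closed form (1−r)·E·(1−e^(−µD)) to machine precision.
* **Relaxation.** Explicit finite-difference diffusion
  (α = 1.43×10⁻⁷ m²/s; ρ = 998 kg/m³, c_p = 4182 J/(kg·K), water at
  20 °C, overridable) with the stability bound dt ≤ h²/4α *enforced*, not
  silently sub-stepped — the explicit scheme was chosen for auditability.
  Boundaries: fixed ΔT = 0 at the capillary wall (quartz + bath as heat
  sink) by default; an insulating mode exists and conserves enthalpy to
  rounding, which the tests verify.  Scheduled secondary pulses re-deposit
  `power × duration` joules instantaneously with the deposition profile.
* **Observation.** `beam_average` takes the area-weighted mean over the
  X-ray footprint, default 160 × 140 µm centred 0.5 mm below the entry
  wall.  At the default configuration this evaluates to ≈ 17.5 °C at
  10 ms — within the expected 0.6–1.4 agreement band of the ~16 °C that
  WAXS thermometry retrieves from a matched synthetic scan.

**Known limitation.** The model has no third dimension and no convection.
Axial heat transport along the capillary is a real loss channel on exactly
the pulse-train timescale (√(2αt) ≈ 0.9 mm at 3 s, comparable to the spot
size), so under the 50 µs/90 Hz maintenance train the 2-D model
*over-maintains*: the beam-averaged jump creeps up to ~1.8× its 10 ms
value by the train end instead of holding flat.  The qualitative contrast
(train maintains, free field decays to the bath within ~1 s) is correct
and tested; the quantitative flatness of a maintained jump is not a claim
this model supports.

## Problem sizes used by the checks

The recovery checks run the full pipeline at the standard scheme (2000
frames/step, 163-bin q grid) with 50 laser-on repeats per condition
(101 steps) — below the 50–60 + interleaved-off protocol of a real
measurement but enough that the τ sampling SD sits well inside the
tolerance bands; the jump-recovery tolerances are the reported
uncertainties of the benchmark conditions, doubled for τ at this reduced
repeat count.  The signal-to-noise scaling check uses 100 repeats, taking
every other series so the groups share no off steps, and checks the
log-log slope of the SEM over 5–50 averaged repeats against −1/2.  The
noise-floor check variance-matches the off-off control to the sample
average (per-element 1.5σ²/N_on vs 2σ²/N_ctrl) and expects the sample's
second singular value within [0.7, 1.4] of the matched control floor —
both quantities estimate the same Marchenko-Pastur-type edge of
same-shaped noise matrices.
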