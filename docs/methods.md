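# Methods

## Exchange model and simulator

The simulator propagates the Bloch–McConnell equations for a star-topology
system: one water pool (f = 1, δ = 0) and N−1 solute pools that exchange
with water only. Pool i is described by T₁, T₂, a fractional proton
concentration f relative to water, an exchange rate k (pool → water, Hz)
and a chemical shift δ (ppm). Detailed balance fixes the reverse rate at
f·k, so exchange conserves total z-magnetization exactly; a unit test
asserts this at machine precision. Magnetization is stacked as
(Mx…, My…, Mz…) and the affine relaxation term is absorbed into an
augmented (3N+1)-dimensional linear system, so propagation over any
piecewise-constant segment is a single matrix exponential and no inversion
of the generator is needed. In the rotating frame the convention is
dMx/dt = −Mx/T₂ + Δω·My with Δω = 2π·γ̄·B₀·(δ_pool − δ_offset) and
ω₁ = 2π·γ̄·B₁ (γ̄ = 42.577 MHz/T).

Saturation is a train of n_p shaped pulses (duration t_p, inter-pulse delay
t_d, free evolution during the delay; a hard-spoil option that zeroes
transverse magnetization between pulses is available but off by default).
Z is the water z-magnetization at the end of the train divided by its
equilibrium value; with the 3 T protocol (t_p = t_d = 100 ms, n_p = 40) the
train is at steady state — doubling n_p changes Z by < 10⁻³.

**Gaussian waveform.** Pulses are discretized into piecewise-constant
segments sampling a Gaussian envelope truncated at ±2σ (σ = t_p/4). Two
numerical points matter here:

- *Segment count.* A piecewise-constant waveform excites a spurious
  sideband at the segment frequency n_segments/t_p. With the conventional
  32 segments and t_p = 100 ms that is 320 Hz ≈ 2.5 ppm at 3 T — in the
  middle of the Z-spectrum, where it appears as a sharp artificial dip at
  ±2.46 ppm (≈ 0.1 in Z) that corrupts the Lorentzian decomposition. The
  default is therefore 128 segments, which moves the sideband to ≈ 10 ppm,
  outside the sampled window. Convergence at the ±1 ppm evaluation offsets
  is much less demanding (32 vs 256 segments differ by < 10⁻⁴ there); the
  window-wide criterion is the binding one.
- *B₁ convention.* The nominal amplitude is the time-average of the
  envelope over t_p ("mean" convention); a "peak" convention is available.
  Mean was retained after checking alternatives against data-driven
  anchors: the peak convention produces direct-saturation lines narrower
  than the lower width bound of the shipped fit table allows, and a
  CW-power-equivalent convention fails the two-pool recovery property
  below.

The whole spectrum is simulated in a handful of vectorized operations: all
(offset, segment-amplitude) generators are exponentiated in one batched
degree-13 Padé scaling-and-squaring call, segment propagators are chained
by batched matrix products, and the n_p-fold train is applied by binary
exponentiation. The batched exponential is validated against
`scipy.linalg.expm`, and the full pipeline against a step-by-step scalar
reference and a high-order ODE integration (relative 10⁻⁶ on randomized
three-pool systems).

**Presets.** `ivd6` is the 3 T intervertebral-disc model: water
(T₁ = 1.306 s, T₂ = 134 ms), GAG hydroxyl (+1 ppm, T₂ = 10 ms, f and k
variable), GAG amide (+3.5 ppm, T₂ = 2 ms, k = 50 Hz, f tied to one third
of the hydroxyl fraction — the 3:1 OH:NH stoichiometry of the disaccharide
unit; the tie is idempotent and re-applied on any parameter change), two
NOE pools (−1.6 ppm and −3.5 ppm) and a semisolid MT pool (−2.3 ppm,
T₂ = 15 µs). All solute T₁ equal the water T₁. `ideal2` is water +
hydroxyl only.

## CEST metrics and the Ω-plot inversion

MTR_asym = Z(−δ) − Z(+δ); MTR_Rex = 1/Z(+δ) − 1/Z(−δ) (flagged NaN when
either Z drops below a 0.05 floor); AREX = R₁·MTR_Rex with R₁ from the
measured (or, in simulation mode, the ground-truth) water T₁. The identity
MTR_Rex = MTR_asym/(Z₊·Z₋) is property-tested. Values at ±δ are taken from
the nearest sampled offset within 0.02 ppm, otherwise by cubic-spline
interpolation — the 64-point acquisition grid under-resolves the curvature
of the spillover dip near ±1 ppm, and linear interpolation there leaves a
measurable bias in MTR_Rex.

For a dilute pool the steady-state exchange contribution is
Rex = f_b·k_ba·α with labeling efficiency α = ω₁²/(ω₁² + Λ²),
Λ² = k_ba(k_ba + R_2b). Pulsed saturation scales this by the duty cycle
DC = t_p/(t_p + t_d), so y = 1/(AREX/DC) against x = 1/ω₁² is a line with
intercept p = 1/(f_b k_ba) and slope q = Λ²/(f_b k_ba); then
k_ba = (−R_2b + √(R_2b² + 4 q/p))/2 and f_b = 1/(p·k_ba). R_2b = 100 Hz is
assumed for GAG hydroxyl protons.

**Form factors for shaped pulses.** With a shaped envelope
ω₁(t) = ω₁·s(t) (⟨s⟩ = 1), the pulse-averaged efficiency expanded to
second order in ω₁²/Λ² gives

    1/⟨α⟩ ≈ c₄/c₂² + Λ²/(c₂·ω₁²),   c₂ = ⟨s²⟩, c₄ = ⟨s⁴⟩,

so the regression uses x = 1/(c₂ω₁²) and an intercept inflated by c₄/c₂²
(for block pulses c₂ = c₄ = 1 and the classical form returns). The moments
are computed from the actual discretized waveform. This pairing of
convention, duty-cycle scaling and form factors is pinned empirically by
the two-pool recovery property: on ideal two-pool simulations over the
physiological box (f_b 0.5–5 ‰ × k_ba 100–500 Hz, 4×4 grid) it recovers
both parameters within ±1 ‰ / ±300 Hz at 15/16 grid points, with nearly
unbiased k̂ at low-to-mid rates; the classical 1/ω₁² form without moments
passes only 13/16. Exchange rates recovered at the fast end of the box and
beyond bias low — an intrinsic property of the linearized inversion at
these saturation powers that the error bounds acknowledge.

Points with non-positive AREX are excluded from the regression rather than
floored (flooring biases the intercept); fewer than three surviving points,
or a non-positive fitted intercept or slope, yields an estimate flagged
inadmissible with NaN parameters — never silently clamped values. On the
six-pool system the raw AREX Ω-plot frequently lands in exactly this
non-physiological regime, which is the failure mode the Lorentzian
correction addresses.

## Lorentzian decomposition and the corrected two-pool spectrum

Each Z-spectrum is fitted as 1 − Σᵢ Aᵢ/(1 + ((δ−cᵢ)/(Wᵢ/2))²) over six
components with per-parameter start values and box constraints (widths are
FWHM in ppm). The shipped table starts water at A = 0.85, W = 2 ppm and
constrains, e.g., the hydroxyl line to A ∈ [0, 0.1], W ∈ [0.5, 2] ppm,
c ∈ [0.6, 1.4] ppm; the MT line is fitted as a Lorentzian of width
8–20 ppm even though the underlying semisolid pool is far broader — the
model is deliberately the operational fitting model, not the physics.
A YAML/JSON schema can override any entry.

The loss is arctangent-based. The default applies arctan per residual:
mean(arctan(rᵢ)²) — zero exactly at a perfect fit and asymptotically the
MSE for small residuals, with the soft-gradient behavior away from zero
that motivates the arctangent. A "literal" variant squares the arctangent
of the *signed mean* residual; it is degenerate (symmetric residuals cancel
to zero loss) and ships only behind a flag, with a unit test documenting
the cancellation. An "arctan-mse" variant is also available.

Optimization uses SLSQP (a sequential-quadratic-programming box-constrained
method) from the tabulated start, tight tolerance (ftol 10⁻¹⁴, ≤ 400
iterations), with optional multistart (N seeded jittered starts within 25 %
of the box; best loss wins; deterministic for a fixed seed). On exact
in-bounds Lorentzian data the fit is residual-free (loss < 10⁻¹⁰).
Optimizer failure returns best-so-far parameters with `converged=False`,
never an exception.

After fitting, centers are snapped to the nominal pool offsets
("re-centering"; the fitted centers are kept as metadata) and the corrected
spectrum Z_corr = 1 − L_water − L_target is evaluated analytically. The
LAREX pipeline runs fit → re-center → synthesize per B₁ level
independently, then feeds MTR_Rex/AREX of the corrected spectra into the
same Ω-plot inversion.

**Known limitation — amplitude leakage into the target line.** The
direct-saturation line of a 50 %-duty-cycle pulse train is not exactly
Lorentzian (the alternation of saturation and recovery fattens its flanks),
and the least-squares decomposition absorbs part of that symmetric misfit
into the hydroxyl line, whose fitted amplitude can sit at its upper bound.
The corrected asymmetry curve therefore *overshoots* the true two-pool
curve at these powers (it removes the dilution by the upfield pools, and
then some). The Ω-plot estimates remain within the study's error bounds at
the reference operating point and the correction decisively beats raw AREX
on mean fraction error, but per-level corrected amplitudes should not be
read as quantitative pool amplitudes. Below f_b ≈ 1 ‰ the decomposition
noise exceeds the hydroxyl signal and LAREX estimates become unreliable
(often flagged inadmissible) — the phantom trend test accordingly uses a
rank statistic rather than per-ROI error bounds.

## Preprocessing

- *Normalization*: division by the 300-ppm reference frame, which is then
  dropped; non-positive references are flagged per voxel, not propagated as
  infinities. The reference frame itself is ~0.5–1 % saturated by the
  semisolid pool, which bounds the agreement between normalized synthetic
  stacks and the simulator's intrinsic Z.
- *WASSR B₀ mapping*: the direct-saturation minimum of a low-power sweep
  (0.2 µT, single 25-ms pulse, 22 offsets over ±1 ppm) located by cubic
  spline on a 0.001-ppm grid; sweep-boundary minima are flagged
  unreliable. Recovery of injected shifts is accurate to ≤ 0.005 ppm.
  Correction resamples each spectrum at (nominal + shift) with edge values
  held; flagged voxels pass through unchanged.
- *Denoising*: scikit-image non-local means (patch radius 1, search radius
  5, strength 0.8·σ̂ with σ̂ estimated from the frame), optional and off in
  spectrum mode.
- *Relaxometry*: IR fit of |S₀(1 − 2e^(−TI/T₁))| with polarity restoration
  by exhaustive sign search over the zero-crossing position (clinical
  magnitude data; the signed model is available), TIs 25–3000 ms; SE fit of
  S₀e^(−TE/T₂) seeded by its log-linear regression, TEs 9.7–194 ms. Both
  are scale-equivariant and recover the disc ground truth (1.306 s /
  134 ms) to four digits from noiseless protocol timings.

## Synthetic data and what passing tests mean

The phantom generator emulates voxelwise six-pool spectra per ROI, a
per-voxel B₀ shift field applied by spectral resampling, the matching WASSR
sweep, and IR/SE relaxometry series, with i.i.d. Gaussian noise on the
normalized signal. It does not model Rician magnitude statistics, B₁
transmit inhomogeneity, motion, partial volume or readout weighting, so
passing tests demonstrate correctness of the estimation chain under the
stated exchange model — not robustness to every acquisition artifact of
in-vivo data. The in-silico accuracy study is noiseless and fully
deterministic; all stochastic elements (phantom noise, multistart jitter)
flow from a single seed.

## Problem sizes

The accuracy grids run at 4×4 over the physiological box in the test suite
and acceptance script (the full-range 6×6 grid is the library default, and
finer grids sit behind the desk-scale guard in `GridSpec`); each cell
simulates 7 B₁ levels × 65 offsets for both pool systems. The worked
single-point example uses the full seven-level protocol. These sizes keep
the complete suite at a few minutes on one CPU while exercising every
pipeline end to end.
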