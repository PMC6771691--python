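# Methods

## Pulse model and units

All internal angular frequencies are rad/s with γ = 267.522 rad s⁻¹ µT⁻¹
(2π·42.576 MHz/T); pulse offsets are entered in Hz and converted at the API
boundary, which removes any 2π ambiguity in the phase integrals. The
Bloch-Siegert phase of a shaped pulse with peak amplitude B₁ₚ and normalized
envelope is, to first order in γB₁/ω_off,

    Φ_BSS = K_BSS · B₁ₚ²,   K_BSS = ∫₀ᵀ (γ B₁ⁿᵒʳᵐ)² / (2 ω_off) dt ,

with a second, offset-sign-*independent* term −K_B0 · B₁ₚ² · Δω_B0
(K_B0 = ∫(γB₁ⁿᵒʳᵐ)²/(2ω_off²)dt) carrying the first-order dependence on the
local field offset. Because K_B0 is even in ω_off, this term cancels exactly
in the ± subtraction — the property that makes BSS mapping insensitive to B0
inhomogeneity to first order. Envelopes are discretized at 500 samples and
integrated by the trapezoid rule (relative quadrature error < 1e-6 for the
smooth shapes used).

The Fermi envelope is 1/(1+exp((|t−T/2|−t₀)/a)), renormalized to peak 1.
Defaults: T = 2 ms, t₀ = 0.75·T/2, a = T/30. These proportions were chosen so
that the 260° flip-angle calibration lands at a peak amplitude of 11.33 µT,
i.e. γB₁/ω_off ≈ 0.24 at the 2 kHz offset — the operating regime of the
mapping sequence this package models. Both (t₀, a) are configurable; results
are reported as functions of the calibrated flip angle, so the dependence on
the exact envelope proportions is second-order.

Flip-angle calibration uses the envelope area: B₁ₚ = α / K_flip with
K_flip = ∫γB₁ⁿᵒʳᵐ dt. A stepwise on-resonance rotation oracle confirms the
calibration to < 0.01%.

**First-order bound.** A brute-force oracle integrates the full Bloch
precession in the frame rotating with the pulse (effective field
(γB₁(t), 0, ω_off), 20 000 Rodrigues steps, no relaxation) and reads the
accrued transverse phase minus the plain ω_off·T precession. At B₁ = 11 µT
and γB₁/ω_off = 0.23 the first-order formula differs from this by 0.7%. Two
effects contribute with the same B₁² scaling: the (γB₁/ω_off)²/4 correction
of the effective-field magnitude, and a non-adiabatic contribution from the
envelope ramps — so the *relative* error does not vanish at weak amplitude,
and the bound is quoted for the operating regime rather than asymptotically.

## Sequence simulation

One voxel is an ensemble of 128 isochromats at uniform fractional positions
in [−0.5, 0.5) (deterministic by construction; doubling the count changes the
reported error curves by < 1e-6 percentage points, because isochromats evolve
independently and the voxel mean is a low-order trigonometric sum in
position). Per TR, in order:

1. excitation: rotation by α (default 15°) about the transverse axis at the
   RF-spoiling azimuth ϕ(n) = ϕ_inc·n(n+1)/2 mod 2π, applied to excitation
   and off-resonance pulse alike;
2. free precession (local Δf) + T₁/T₂ relaxation to echoes 1–2 (exact
   exponential operators; echoes recorded as the demodulated complex mean);
3. balanced crusher pair around the off-resonance pulse: +6π·position before,
   −6π·position after. Pre-existing transverse magnetization is rewound;
   magnetization excited by the pulse itself would see a single lobe and be
   crushed, which is why on-resonance excitation by the pulse is neglected
   entirely (an un-rewound pair would instead dephase the voxel's post-pulse
   echoes to zero, contradicting the sequence's design);
4. composite pulse action: z-rotation by sign·K_BSS·B₁ₚ² − K_B0·B₁ₚ²·Δω_B0
   plus relaxation/precession over the 2 ms duration (the full-rotation model
   lives in the pulse module as the approximation oracle, step above);
5. echoes 3–8; 6π·position end-of-TR spoiler; relaxation to TR end.

Echo times are absolute from excitation ([2.38, 4.68, 11.42, …, 22.92] ms;
the pulse is centered in the echo-2→3 gap). Readout-gradient intra-voxel
dephasing is ignored (echoes at gradient-echo centers, balanced gradients).
Odd/even eddy-current phase is a scanner artifact and is injected only by the
phantom generator, not simulated here.

**Orderings and steady state.** Interleaved runs alternate the offset sign
every TR; 400 dummy TRs precede a 200-TR measurement window, and the ± states
are the complex means over the last 50 TR-pairs. Sequential runs play two
400-TR blocks (200 dummies each) with the RF-spoiling index reset at the
block boundary. Convergence is checked by comparing the ± phase difference of
two successive 50-pair windows (tolerance 1e-4 rad; a failed check is
recorded on the timeline and surfaced as a CLI warning). These window sizes
make every reported error-curve point stable to well below 0.01 percentage
points while keeping a 19-increment sweep at seconds of runtime.

**Estimators on simulated data.** The classic phase is read at the first
post-pulse echo (half the ± phase difference); with zero local off-resonance
the extracted difference is echo-independent, which was verified against
echoes 4–8. The interleaved-vs-sequential error is
100·(B1_int − B1_seq)/B1_seq, with the sequential reference simulated at the
same spoiling increment (its BSS phase is increment-independent, so the
choice is immaterial). The GLM estimate is fitted to the same interleaved
± mean echoes.

## GLM estimator

Design matrix (16 rows = 8 echoes × 2 offsets; rank 6): BSS step (0 before /
±1 after the pulse), TE column (B0), ±1 odd/even, two per-offset intercepts,
and a common post-pulse step. Weighted least squares uses the echo magnitude
as weight, following the acquisition-noise heuristic of down-weighting
low-signal echoes; `weights="mag2"` (variance-optimal for complex Gaussian
noise) and `"uniform"` are available. Zero-magnitude rows keep weight 0
rather than being dropped; voxels whose weighted normal matrix is singular
(effective rank < 6) are flagged invalid and masked. The fitted BSS
coefficient must be positive under the (+, −) stack convention; negative fits
are masked, not clipped. Default spatial mask: echo-1 magnitude above 5% of
the volume's 99th percentile.

Temporal unwrapping follows the multi-echo recipe: wrapped inter-echo
differences are spatially unwrapped (scikit-image's reliability-sorted
algorithm) and cumulatively added to the first echo's phase. Each unwrapped
difference map is re-anchored so the majority of voxels keep their
principal-value step; this assumes most true inter-echo steps lie in
(−π, π], which holds for shimmed B0 fields, and leaves at most a global
2π·integer per offset that the per-offset intercepts absorb. Single-voxel
inputs fall back to per-voxel temporal unwrapping. The two offset stacks are
unwrapped independently — any 2π ambiguity between them is likewise absorbed
by the intercepts.

Phase-to-B1 conversion inverts the quadratic law, B₁ₚ = √(Φ_BSS/K_BSS). For
the classic estimator ΦDiff/2 must lie in [0, π); voxels within 5% of the
wrap boundary are flagged (at the default 260° pulse, a B1 efficiency of
~1.4 would approach it).

## Digital phantoms

`generate_ideal` composes phases exactly from the GLM forward model (BSS
phase from a quadratic-bowl B1 efficiency field spanning 0.7–1.3 of nominal,
a smooth ±100 Hz B0 field, 0.05 rad odd/even phase, per-offset initial phases
0.30/0.10 rad, 0.20 rad common post-pulse phase) with mono-exponential T₂
magnitudes over three default compartments (gel 550/70 ms, white-matter-like
1000/70 ms, fluid-like 1350/100 ms). Noise is complex Gaussian added to the
complex signal, so magnitude-dependent phase variance emerges naturally;
generation is bit-reproducible from the seed. `generate_biased` instead
embeds the pseudo-steady-state complex echoes of the interleaved Bloch
simulation, caching runs on (T₁, T₂, B₁ₚ, ΔB0) rounded to 3 decimals —
phantom specs with piecewise-constant fields per class need one run per
compartment.

What passing tests on these phantoms show — and do not show: the ideal
phantom validates the estimator against its own forward model (exact
recovery, coefficient isolation, noise propagation); the biased phantom
validates that the GLM removes the *simulated* interleave bias. Neither
includes coil sensitivities, k-space sampling/apodization, motion, drift,
chemical shift, diffusion, or slice-profile effects, so agreement here does
not establish in vivo accuracy — only correctness of the estimation given
the modeled signal.

## Numerical choices and limitations

* Exact relaxation/precession operators between events; no sub-TR time
  stepping is needed because all events are instantaneous rotations.
* The composite pulse model omits on-resonance excitation by the
  off-resonance pulse (crushed by design) and keeps only first-order phase;
  the full-rotation oracle bounds the resulting approximation error (< 1%
  in the operating regime).
* An `ideal_spoiling` switch zeroes transverse magnetization at end-of-TR,
  removing all TR-to-TR coherence carry-over; the interleave bias then
  vanishes to machine precision for every spoiling increment, confirming
  carried coherence as the bias mechanism.
* The bias predictions at the phantom settings (4.84% at T₂ = 70 ms, 3.36%
  at T₂ = 50 ms, no RF spoiling) are quoted with a ±0.5 percentage-point
  reproduction tolerance, since steady-state windowing and dummy-cycle
  handling admit small implementation-dependent variation.
* Relative errors are insensitive to the absolute B1 scale but not to the
  per-pulse BSS phase (≈0.5 rad at defaults); sweeps that set `peak_b1`
  directly bypass the flip-angle calibration.
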