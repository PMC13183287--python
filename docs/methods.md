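# Methods

## Model

Each region couples two Jansen-Rit masses, an α-tuned and a γ-tuned one.
For subpopulation s ∈ {α, γ} with constants (A_s, B_s, a_s, b_s), states
x₀ᔆ, x₁ᔆ, x₂ᔆ (PSPs, mV) and their rates y₀ᔆ, y₁ᔆ, y₂ᔆ:

    ẋk = yk
    ẏ0 = A a S(x1ˢ − x2ˢ) − 2a y0 − a² x0
    ẏ1 = A a (p(t) + C2 S(C1 x0ˢ)) + A a · K C Σⱼ Mᵢⱼ ζpyr,j − 2a y1 − a² x1
    ẏ2 = B b C4 S(C3 x0ˢ) − 2b y2 − b² x2

Each mass's internal sigmoids see *its own* states, so the two masses are
independent oscillators sharing the external input p, the long-range
input, and the node's single plastic C₄. The node-level quantities are

    EEG      = (r^α x1^α − (1−r^α) x1^γ) − (r^α x2^α − (1−r^α) x2^γ)
    ζ_pyr    = r^α S(x1^α − x2^α) + (1−r^α) S(x1^γ − x2^γ)
    ζ_inh    = S(C3 · (r^α x0^α − (1−r^α) x0^γ))
    τ Ċ₄     = ζ_inh (ζ_pyr − ρ) ((C₄ − C₄,min)/C)^β

The EEG mixes the two masses' potentials with opposite signs — the
two generators stand for superficial- versus deep-layer dipole
contributions of opposite orientation — whereas firing rates, being
population counts, mix with positive weights. This distinction matters:
the α and γ presets are exact time-rescalings of one another
(A/a and B/b are identical across presets), so their long-time mean
potentials coincide and a signed potential mixture has no DC component at
r^α = 0.5. A homeostatic rule driven by S(of that signed mixture) would
be pinned near S(0) ≈ 0.17 s⁻¹ and could never reach a 2.5 s⁻¹ target;
driving ISP, inter-regional coupling, and the hemodynamics with the rate
mixture restores a controllable operating point at every r^α while
reducing to the classical single-mass model at r^α ∈ {0, 1}. A
`combined_sigmoid_args` switch implements the alternative variant in
which every sigmoid sees the signed combined potentials; it is retained
for comparison, not as the default, because the masses then mirror each
other and the mixture cancels.

The long-range input enters the pyramidal loop like the external input,
i.e. scaled by A·a (each mass's own A·a). Without that scaling the
coupling term is a sub-percent perturbation of the drive and the global
coupling K has no observable effect; with it, the model shows the
expected phenomenology — γ-band dynamics at K = 0 shifting to α/θ by
K = 1 with ISP on, and saturation-driven loss of oscillations and of
envelope correlations at strong K with ISP off. A
`coupling_scaled_by_aa=False` flag restores the unscaled variant.

### Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| A^α, B^α | 3.9, 26.4 | mV | α EPSP/IPSP amplitudes |
| a^α, b^α | 120, 60 | s⁻¹ | α inverse time constants |
| a^γ, b^γ | 660, 330 | s⁻¹ | γ inverse time constants (A^γ = 32.5a/1000 = 21.45, B^γ = 440b/1000 = 145.2) |
| ζmax, r, v_th | 5, 0.56, 6 | s⁻¹, mV⁻¹, mV | sigmoid |
| C; C1..C4 | 135; C, 0.8C, 0.25C, 0.25C | — | local connectivity |
| r^α | 0.5 | — | α-neuron proportion |
| ⟨p⟩, σ_p | 220, 31 | s⁻¹ | external input statistics |
| ρ, τ, β, C₄,min | 2.5, 2, 1, 0 | s⁻¹, s, —, — | ISP |
| Δt, output rate | 1 ms, 200 Hz | | integration / storage |
| transient | 60 s | | discarded before analysis |

C₄,min is not specified by the source material; 0 is used (the soft
bound then reduces to (C₄/C)^β) with a hard clip at C₄,min after each
Euler step guarding finite-step overshoot.

## Integration and noise

Explicit Euler at 1 ms; p_i(t) is redrawn per region and step from
N(⟨p⟩, σ_p²) and held over the step — an input-noise convention without
√dt scaling (an `sde_scaling` flag provides the Wiener-increment
alternative). Initial states are zero with C₄(0) = 0.25C. Traces are
anti-alias filtered (zero-phase 8th-order Butterworth at 0.8 of the
output Nyquist, staged for large factors; maximally flat so in-band
amplitudes and DC are preserved) and decimated to 200 Hz before storage.

A known artifact of the 1 ms explicit Euler step is a bias in fast
oscillation frequencies: the α-only node's deterministic limit cycle at
p = 220 runs at 13.1 Hz (high-accuracy integration), while the 1 ms-Euler
pipeline measures 11.5 Hz on the 0.5 Hz Welch grid; the γ mass
(a = 660 s⁻¹, aΔt ≈ 0.66) is distorted more strongly (its fast cycle:
73.5 Hz exact, ~40 Hz through the protocol pipeline). The 1 ms protocol
is retained as the model's operating definition; slow regimes
(≤ ~3 Hz) are step-robust, which the test suite checks.

## Plasticity and clamping accuracy

The ISP fixed point on an oscillatory attractor sets the ζ_inh-weighted
time average of ζ_pyr to ρ, i.e. ⟨ζ_pyr⟩ = ρ − cov(ζ_inh, ζ_pyr)/⟨ζ_inh⟩.
On a limit cycle the covariance term is positive and the plain time
average undershoots or overshoots ρ by roughly 3–11% depending on the
operating point (verified to be independent of the integration step and
of the integrator). The clamping is therefore asserted in the tests as
monotone tracking of ρ with a 15% band; exact equality would require a
rate estimate decorrelated from the instantaneous inhibitory rate (for
example a slow-averaged ζ_pyr), which is not part of this model.

The 63.2% convergence diagnostic takes the baseline level from the first
2 s and the steady level from the last 10 s of the ROI-averaged C₄ trace
and reports the first crossing of baseline + (1 − 1/e)·(total change).

## Hemodynamics

The Balloon-Windkessel system (τ_s = 0.65, τ_f = 0.41, τ_v = τ_q = 0.98 s,
κ = 0.32, E₀ = 0.4, V₀ = 0.04, k₁ = 2.77, k₂ = 0.2, k₃ = 0.5) is driven
by the node pyramidal rate, integrated with Euler at 10 ms from the
resting point (0, 1, 1, 1), and the BOLD observable is resampled to the
repetition time TR = 2.08 s. The venous outflow term in the
deoxyhemoglobin equation is implemented as q·v^(1/κ)/v — the standard
Balloon form; the flattened one-line rendering of this term in the source
equations is typographically ambiguous. The drive is the combined rate
mixture and is not demeaned or rescaled.

## Observables

Band-pass filtering uses 3rd-order Bessel filters applied zero-phase
(forward-backward); the bands are δ 0.5–4, θ 4–8, α 8–13, β 13–30,
γ 30–40 Hz. Envelopes are Hilbert magnitudes high-passed at 0.5 Hz
(zero-phase 3rd-order Butterworth). Spectra use Welch's method with 2 s
Hann windows, 50% overlap and per-segment mean removal (0.5 Hz
resolution); relative band power divides trapezoidally integrated band
power by the total between 0.5 and 30 Hz. Spectral peak readouts break
ties toward the lower frequency (the 0.5 Hz grid makes narrow ridges
step-like). EEG FC is the Pearson correlation of band-limited envelopes;
BOLD FC band-passes at 0.01–0.08 Hz first. FC diagonals are zeroed
before any comparison so matrix-level fits are not inflated by the
trivial self-correlation.

## Fitting metrics

SSIM is computed globally over the full matrix with the standard
stabilizing constants (k₁ = 0.01, k₂ = 0.03, dynamic range = joint
max − min), not as a sliding-window mean: the global form is
deterministic and well-defined for FC-sized matrices and the windowed
variant is available externally as a cross-check. Spectral fits use the
Clarkson similarity 1 − ½‖x/‖x‖ − y/‖y‖‖ on (θ, α, β) relative-power
vectors; dual EEG+fMRI fitting masks a parameter grid at EEG similarity
≥ 0.85 and maximizes SSIM over the surviving cells, breaking ties by
higher EEG score then lexicographic cell order. An empty mask is an
explicit no-feasible-cell result. Effect sizes use Cohen's D with pooled
SD.

## Bifurcation toolkit

Equilibria are Newton roots of the analytic vector field (residual
< 1e-10; with ISP the extended system appends C₄, whose root condition
forces ζ_pyr = ρ or C₄ = C₄,min). Branches are followed by
pseudo-arclength continuation with an analytic Jacobian, adaptive step,
and stability labels per point; saddle-nodes are refined by solving the
extended fold system (f = 0, Jv = 0, ‖v‖ = 1) and Hopf points by
bisection of the complex-pair real part to 1e-3 in p. Periodic orbits
use single shooting with monodromy matrices from the variational
equations (DOP853, rtol 1e-10); cycle continuation runs pseudo-arclength
in (orbit point, period, p) with coordinates scaled by the orbit
amplitude so arclength steps make comparable progress in every
direction. Folds of cycles are read from the sign change of dp/ds
(a real multiplier passing +1); torus points bisect the modulus-1
crossing of a complex Floquet pair to 1e-2 in p. The trivial multiplier
is reproduced to ~1e-4 and serves as an internal accuracy check.

The non-convergent regime of the ISP node between the saddle-node and
the torus point (persistent switching between state-space regions) is
characterized only by simulation; no attractor continuation is attempted
there.

## Synthetic data

The connectome generator stands in for diffusion-MRI structural
matrices: log-normal weights on a sparse support (default density 0.3,
σ = 0.8), block-modular structure (2 modules per hemisphere boost
within-block weights ×3), hemispheric mirror symmetry with AAL-style
ordering (homotopic pairs on the anti-diagonal), weaker sparse callosal
links, a ring backbone guaranteeing connectedness, and max-1
normalization. Signal fixtures (amplitude-modulated carrier pairs with a
controllable shared-envelope fraction, and Gaussian series with a
prescribed correlation matrix) exercise the envelope-FC and metric
pipelines against constructions with known answers. What the generator
does not emulate: realistic strength distributions of any specific
atlas, distance-dependent weight decay, or inter-subject variability —
so whole-brain tests demonstrate mechanism (direction and ordering of
effects), not atlas-level quantitative reproduction.

## Problem sizes used in tests and the acceptance script

Single-node runs use 180 s (60 s discarded) for spectral readouts and
300 s for plasticity runs analyzed after the measured C₄ convergence
time; noisy mixture readouts average 5 seeds. Whole-brain property runs
use N = 20 (strength–inhibition regressions; 60 s, 10 s discarded,
5 seeds) and N = 10 (τ sweep; 120 s noise-free). Cycle continuations
cover p ∈ [100, 230] (ISP) and [100, 200] (no ISP). These sizes were
chosen as the smallest at which the qualitative claims stabilize across
seeds.

## Known limitations

- The 1 ms Euler frequency bias above (~1.5–2 Hz at α-band rates).
- Homeostatic clamping is exact only in the ζ_inh-weighted sense; plain
  time-averaged rates deviate by the covariance term.
- At this connectome scale, strength–C₄ regression slopes increase with
  K only below the saturation of the coupled sigmoids (K ≲ 0.3 for the
  default generator); beyond it the differentiation compresses.
- No conduction delays, no region-heterogeneous excitability, no
  codim-2 continuation.
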