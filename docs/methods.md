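# Methods

## The two-layer scattering model

A thin, homogeneous top layer of thickness *d* (reduced scattering
μs_top′) rests on a semi-infinite homogeneous substrate (μs_bot′). The
refractive index is the same in both layers, so no internal Fresnel
boundary exists, and only scattering — not absorption — differs between
layers. When such a target is processed with a homogeneous SFDI model, the
retrieved scattering is treated as the mixture

    μs_mod′(⟨fx⟩) = α(d, ⟨fx⟩) μs_top′ + (1 − α) μs_bot′.

The weight α is the fraction of the depth-sensitivity integral contained in
the top layer. For planar illumination and wide-field detection the source
and detector sensitivities at depth z are both proportional to the fluence
φ(z), so the hitting density of the co-located forward–adjoint pair is φ²:

    α(d, fx) = ∫₀^d φ²(z, fx) dz / ∫₀^∞ φ²(z, fx) dz.

α rises monotonically with d (more layer in the integral) and with fx
(modulated fluence decays as exp(−μeff′ z) with
μeff′ = sqrt(μeff² + (2π fx)²), so higher frequencies concentrate φ² near
the surface). Both monotonicities are asserted by tests over the certified
parameter grid below.

The model has three free parameters (d, μs_top′, μs_bot′), all supplied
from independent characterization; no inverse solver for them is included
(that is a separate estimation problem, out of scope here).

## Fluence models

All three models produce φ(z)/P0 as a two-term exponential sum, which makes
∫φ² analytic: φ² = Σᵢⱼ aᵢaⱼ e^(−(kᵢ+kⱼ)z) integrates term by term. The
shared frequency dependence enters only through μeff′(fx), with the
transverse wavenumber kx = 2π fx, ky = 0 (1-D projected sinusoids).

**SDA.** φ = A e^(−μtr z) + C e^(−μeff′ z), μtr = μa + μs′. A is the
particular solution amplitude of the 1-D diffusion equation driven by
the exponentially attenuated source, A = 3(μs′/μtr)/((μeff′/μtr)² − 1); C
follows from the partial-current boundary condition
φ(0) = φ′(0)/(3Rμtr) with R = (1−Reff)/(2(1+Reff)). Tests verify the ODE
residual and the boundary condition directly rather than re-asserting the
printed amplitudes.

**δ-P1 (original SFD form).** The δ-P1 closure splits radiance into a
collimated delta component and a diffuse part with rescaled coefficients
μs* = μs(1−g²), μtr* = μa + μs*, g* = g/(1+g). The AC diffuse fluence is

    φ_AC = C*/(μeff′−μtr*) [e^(−μtr* z) − e^(−μeff′ z)]
         + C*/(μeff′+μtr*) [e^(−μtr* z) − e^(−μeff′ (z+2zb))]

with C* = 3 μtr μs*/(2 μeff′) and extrapolated boundary
zb = (2/(3μtr)) R′, R′ = (1+R1)/(1−R1). We implement it exactly in this
form (no collimated term added), collected into two rates; the collected
and raw forms are compared at machine precision in tests.

**Modified δ-P1.** Driving the δ-P1 governing equation with a sinusoidally
modulated source and closing with conservation of the normal diffuse flux,

    [φd − (2/(3μtr)) R′ dφd/dz]_{z=0} = −(2/μtr) R′ g* μs* q0,

gives φ = (1+A′) e^(−μtr* z) + C′ e^(−μeff′ z), where
A′ = 3μs*(μtr* + g*μa)/(μeff′² − μtr*²),

    C′ = −[A′(1 + (2R′μtr*)/(3μtr)) + (2R′/μtr) g* μs*]
         / (1 + (2R′μeff′)/(3μtr)),

and the leading "1" is the collimated component e^(−μtr* z) itself. The
amplitudes are verified in tests by substituting them back into the
boundary condition (residual < 1e−9 relative at every certified grid
point) and into the governing ODE — the solution must satisfy its own
derivation.

Normalization is per delivered (post-specular) power: specular reflectance
is dropped because reference-phantom calibration cancels source-side
factors.

### Boundary reflection quantities

- Reff(n) uses the standard rational polynomial
  0.0636n + 0.668 + 0.710/n − 1.440/n² (0.5295 at n = 1.4; the fit's
  residual at n = 1 is 0.0016 and is left as-is, documented).
- R1(n), the first moment of the unpolarized Fresnel reflectance for
  internal incidence, is computed by adaptive quadrature of
  2∫₀¹ R_F(μ) μ dμ with the total-internal-reflection breakpoint passed to
  the integrator, and cached per n. A direct integral was preferred over a
  polynomial fit because it is exact at every n (R1(1) = 0 identically) and
  removes any ambiguity about fit provenance; both quantities sit behind
  single swappable functions should a user want alternative conventions.
  R′ = (1+R1)/(1−R1) is implemented as a ratio: as a product it could not
  diverge with index mismatch and would not satisfy the flux boundary
  condition, which the residual test confirms.

### Certified parameter grid and singularities

Positivity of φ on z ∈ [0, 20] mm and the depth-concentration
monotonicities are certified by tests over μa ∈ {0.01, 0.05, 0.1},
μs′ ∈ {0.5, 1, 2, 5} mm⁻¹, g ∈ {0.7, 0.8, 0.9}, fx ∈ {0, 0.1, 0.3, 0.5}
mm⁻¹ at n = 1.4. Outside this box a cheap 41-point positivity scan runs at
call time and raises a warning. The collected amplitudes are singular where
μeff′(fx) crosses μtr (SDA) or μtr* (both δ-P1 forms); within 1e−9 relative
of a crossing a typed `SingularConfigurationError` is raised rather than a
silently perturbed result — callers perturb fx by ~1e−6 mm⁻¹, which moves
far off the pole.

## Partial-volume numerics

The analytic α sums aᵢaⱼ/(kᵢ+kⱼ) pair terms (rates summed before
exponentiation; pairs below 1e−300 dropped). α is invariant under uniform
amplitude rescaling, clipped to [0, 1] only against epsilon-level rounding.
A fluence that is negative anywhere on [0, 20] mm, or whose total φ²
integral is non-positive, raises `InvalidFluenceError` instead of returning
an α with no physical reading. The quadrature oracle truncates the improper
integral at z = 40/min(kᵢ) (tail < 1e−12 of the total for exponential
sums) and agrees with the analytic route to better than 1e−8 on 200 seeded
random sums.

## Processing pipeline

- **Demodulation.** Exactly three phases at 0°/120°/240°;
  M_AC = (√2/3)·sqrt((I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²), exact for noise-free
  sinusoids and independent of the DC offset. fx = 0 frames are averaged
  (planar convention); with patterns synthesized as ½Rd(1+cos φk) both
  conventions give the same ½Rd amplitude scale, so one calibration covers
  the whole grid.
- **Calibration.** Rd = (AC_sample/AC_ref)·Rd_model(ref, fx); out-of-[0,1]
  pixels are clipped with a counted warning; a reference with > 5%
  non-positive pixels is rejected.
- **Forward Rd model.** The closed-form diffusion reflectance
  Rd = 3A·a′/((μeff′/μtr + 1)(μeff′/μtr + 3A)), A = (1−Reff)/(2(1+Reff)),
  a′ = μs′/μtr. This replaces a white-Monte-Carlo lookup: absolute property
  estimates therefore differ slightly from Monte-Carlo-calibrated
  processing, and all pipeline guarantees are stated as self-consistency
  and recovery properties. `RdLookupTable` accepts a long-format CSV
  (mu_a, mu_s_prime, fx, rd) and drops in wherever a forward model is
  accepted, for users with their own tabulated model.
- **Inversion.** Bounded trust-region least squares over
  μa ∈ [1e−4, 1], μs′ ∈ [0.05, 10] mm⁻¹, fixed init (0.01, 1), tolerances
  1e−14; deterministic, order-invariant in the input frequencies;
  boundary-pinned solutions are flagged in the result.
- **Sub-sets.** Contiguous windows of 4 frequencies, stride 1: the
  11-frequency grid yields 8 sub-sets with ⟨fx⟩ from 0.075 to
  0.425 mm⁻¹. Per-sub-set properties feed the fluence used in α, so each
  sub-set carries its own penetration depth, summarized by the convention
  δ = 1/μeff′(⟨fx⟩) (a characteristic-depth convention only; not suitable
  for reproducing any externally reported depth figure).
- **ROI.** Homogeneous targets are summarized by the mean over a centred
  rectangle covering 25% of the image area (configurable).

## Synthetic data: what it emulates and what it does not

The generator reproduces the validation study's *conditions*: five top
layer thicknesses {0.130, 0.269, 0.490, 0.675, 1.149} mm; layer optical
properties per band (458 nm: top 0.0322/3.4319, bottom 0.0215/0.8675;
536 nm: 0.0370/2.9269, 0.0226/0.8322; 626 nm: 0.0427/2.3436,
0.0242/0.7830; μa/μs′ in mm⁻¹), giving scattering contrasts ≈ 4, 3.5, 3;
the 11-frequency grid; three-phase sinusoidal patterns. Anisotropy and
refractive index are not part of that characterization; defaults g = 0.8,
n = 1.4 are the field's conventional silicone/tissue values and are
user-overridable.

Two deliberately synthetic closures stand in for physics the package does
not model:

1. **Homogeneous-equivalent rule.** Real per-sub-set (μa, μs′) on a layered
   target come from a measurement. Lacking a layered radiative-transport
   forward model, the generator closes the loop with a fixed point: iterate
   fluence → α → α-weighted mixing of both μs′ *and* μa until stationary
   (tolerance 1e−8, ≤ 100 iterations; "thickness-weighted" μa mixing uses α
   because α is precisely the thickness-derived weight of this model). The
   resulting series is self-consistent by construction, which is what makes
   exact round-trip tests possible — and is also why those tests say
   nothing about how well any fluence model matches real layered media.
   A user-supplied rule ⟨fx⟩ → (μa, μs′) (e.g. from layered Monte Carlo)
   can replace it.
2. **Pattern stacks.** Images are ideal sinusoids ½·S·Rd(1+cos(2πfx·x+φk))
   with optional multiplicative/additive Gaussian noise under a recorded
   seed (default 1% multiplicative — a testing convention, no instrument
   noise model is claimed). No optical blur, no profilometry error, no
   spatially varying illumination. Default geometry is 64×64 pixels at
   0.4 mm/pixel — the smallest image holding one full period of the lowest
   nonzero frequency (0.05 mm⁻¹ → 50 px) while keeping the highest
   frequency above Nyquist (5 px/period) and every code path fast.

Consequently, passing tests demonstrate internal mathematical correctness
(models solve their equations, analytic integrals match quadrature,
the pipeline inverts its own forward model exactly, generated curves round
-trip) and the qualitative structure reported for the physical experiment
(curves bounded by layer values, ordered by thickness, saturating at high
fx); they do not certify accuracy on instrument data, whose absolute
values depend on the Rd model and acquisition physics outside this
package.

## Problem sizes and determinism

Test and acceptance workloads use 64×64-pixel stacks, the 11-frequency
grid, the 144-point certified grid, 200 random exponential sums and
100-replicate noise studies — sizes chosen so the full suite runs in
seconds on one core while still exercising every code path. Every
stochastic component takes an explicit seed (numpy Generator); reruns with
the same seed are bit-identical, and the CLI echoes its resolved
configuration and a config hash into each run directory.

## Known limitations

- No inverse solver for (μs_top′, μs_bot′, d); the model evaluates, it does
  not fit layer parameters.
- Absorption layering is not modeled (scattering contrast only); measured
  per-sub-set μa is passed through as-is, including any high-frequency
  noise amplification a real instrument would show.
- The closed-form diffusion Rd underlies calibration and inversion;
  sub-diffusive regimes (very high fx, low albedo) inherit its biases
  unless a lookup-table model is plugged in.
- The δ-P1 extrapolated-boundary form is taken exactly as stated, with zb
  inside the final exponential only.
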