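# Methods

## Physical model

`betamag` transports electrons (beta particles) through liquid water in a
uniform static magnetic field with a class-II-style condensed-history
scheme. The project-wide unit system is mm / MeV / tesla / g cm⁻³.

**Energy loss.** The collision stopping power is the Bethe formula with the
Møller closure for free-electron collisions and mean excitation energy
I = 75 eV (the standard reference value for liquid water):

S = K (Z/A) ρ / β² · [ ln( τ²(τ+2) / 2(I/mc²)² ) + F(τ) ],
F(τ) = 1 − β² + [τ²/8 − (2τ+1) ln 2]/(τ+1)².

The density-effect correction is omitted; below ~2.3 MeV in water it is a
sub-percent effect, and its omission biases stopping powers slightly high
(ranges slightly short). Radiative losses are not included in S: at the
Y-90 endpoint they are ~2 % of the total in water, so CSDA ranges computed
here are ~2 % long. The CSDA range is the adaptive quadrature of dT′/S(T′)
from the 10 keV cutoff; the sub-cutoff residual pathlength (a few µm) is
neglected, matching the engine, which deposits residual energy locally.

**Helical stepping.** For uniform **B** the equation of motion has the
closed-form helix solution; each step rotates the perpendicular direction
component by φ = s·(0.29979 B)/p about **B** (the electron's negative
charge fixes the rotation sense) and advances the position along the exact
arc. There is no field-integration error; step lengths are limited by
`max_step_length` (0.1 mm) and by a maximum fractional energy loss per step
(2 %), whichever is shorter.

**Multiple scattering.** After each step the direction is deflected by a
Gaussian polar angle with uniform azimuth. The width follows Highland's
parameterisation θ₀ = 13.6 MeV/(βp)·√(x/X₀)·(1+0.038 ln(x/X₀)), X₀ =
36.08 g cm⁻² for water. Because Highland's logarithmic factor is
calibrated for the *whole* absorber, applying it independently to each
~0.1 mm sub-step underestimates the accumulated width by ~20-30 %; the
kernel therefore draws each step's width from the quadrature difference
θ₀²(X+x) − θ₀²(X) at the current βp, where X is the thickness already
traversed (a test verifies the per-step widths re-sum to the full-path
Highland width). There is no single-scatter (large-angle) tail and no
energy-loss straggling: tracks are somewhat more ballistic than a
full-physics engine's, which shows up as slightly deep stopping points
(mean Y-90 stopping radius ≈ 3.3 mm here vs ≈ 2.5 mm quoted for water)
and slightly over-strong confinement at the highest field.

**Hits.** Each step deposits S(T)·(step) at its endpoint as one "hit";
termination at the 10 keV cutoff deposits the remainder locally, and a
history leaving the 15 mm sphere carries its remaining energy away as
logged escape. Per-history energy balance closes to 1e-6 MeV. These
condensed-step endpoints are a *surrogate* for discrete-interaction
scoring: secondaries (delta rays, bremsstrahlung photons) are not
transported, so the hit cloud lacks the far-reaching photon interaction
points a full engine records. Consequently the confinement this package
measures at high field is an upper bound: at 3 T and 2 MeV it finds a
~63 % volume reduction where the full-physics reference is 53 %, and the
central hit-count enhancement (~6 %) under-represents the reference
(~20 %), because the B-insensitive secondary halo is missing from both
numerator and denominator in different proportions.

**Y-90 source.** Energies are drawn by rejection from the allowed-shape
density N(T) ∝ p·E·(Q−T)²·F(Z,E), Q = 2.28 MeV, with the non-relativistic
Fermi function F = 2πη/(1−e^(−2πη)), η = Zα/β, Z = 40. Y-90's decay is
actually first-forbidden unique; the allowed shape is ~1.5 % hard in the
mean (0.946 vs 0.934 MeV evaluated), inside the ±0.02 MeV comparison band.
Rejection uses a constant envelope 1.05× the gridded density maximum, so
samples follow the analytic shape exactly.

**Randomness.** Every history draws all its numbers (direction, spectrum
energy, scattering angles) from a substream seeded by a SplitMix-style hash
of `(seed, particle_id)`. Results are therefore independent of chunking and
execution order, and bit-reproducible per seed.

## Analysis stages

**Slices and stripes.** Slices are normal to y (0.1 mm thick, centres on
1 mm multiples); within a slice, hits are histogrammed into half-open
0.5 mm stripe bins along x and along z (half-open bins keep counts additive
and gap-free). The "central stripe" used for the hit-enhancement figure is
|x| ≤ 0.25 mm, |y| ≤ 0.05 mm, any z.

**Extents and volume.** The per-axis extent is a percentile of |coordinate|
over hits; the default 99.5 rather than the absolute maximum, because the
max is an extreme-value statistic with poor seed-to-seed stability (the
reference estimator is unspecified; both are exposed). The interaction
volume is the ellipsoid V = (4/3)πabc of the three extents, and confinement
is reported as 100·(1 − V(B)/V(0)) with the 0 T run of the same energy and
seed as reference.

**Film plane.** Dose is accumulated in 0.1 mm pixels on a plane normal to z
at 0 or 2 mm from the source, over a 0.3 mm slab (nominal film
sensitive-layer scale); response is taken proportional to deposited energy —
no dose-response curve, optical-density model, saturation, capillary glass
wall or water/air gaps. Maps are smoothed (Gaussian, 2 px) before
contouring to stabilize the maximum against Monte Carlo noise; smoothing is
disabled in closed-form synthetic tests. Isodose levels default to
{0.9, 0.75, 0.6, 0.45, 0.3, 0.15} of the maximum (six contours); a
diameter is the extent of the thresholded region along the grid line
through the maximum, quantized to whole pixels. At offset 0 the unsaturated
1/r² peak at the source pixel makes *relative* isodose contours collapse to
a few pixels and essentially field-independent — a known fidelity gap to
the physical film; directional conclusions are therefore drawn at the 2 mm
offset, where the outermost contour's perpendicular diameter shrinks
significantly under 1.5 T.

## Synthetic ground truth

The generators mimic the statistical structure the analyses assume —
uniform/Gaussian ellipsoidal point clouds (axis-extent and volume
recovery), separable Gaussian dose maps with optional multiplicative noise
(closed-form isodose diameters), and exact helices (stepper oracle). They
contain no transport physics: a green analysis test establishes the
correctness of the measurement, not the fidelity of the engine.

## Numerical choices and defaults

| parameter | default | rationale |
|---|---|---|
| sphere radius | 15 mm | medium large enough to contain all Y-90 betas |
| cutoff energy | 10 keV | residual range ~2.5 µm, below scoring resolution |
| max step | 0.1 mm | matches slice thickness; extents converge <0.5 % on halving |
| max fractional ΔE/step | 2 % | stopping-power variation per step stays small |
| extent percentile | 99.5 | seed-stable range estimator (see above) |
| histories per cell | 10⁵ (reference used 10⁶) | ratio standard errors ≪ comparison tolerances |
| isodose smoothing | 2 px | stabilizes max; off in closed-form tests |

## Known limitations

- No secondary-particle transport (delta rays, bremsstrahlung photons
  deposit locally): confinement overestimated at high B, central
  enhancement underestimated.
- Gaussian-only small-angle scattering and no straggling: transverse tails
  short, stopping points ~30 % deep in the mean for Y-90.
- Allowed-shape Y-90 spectrum (true decay first-forbidden unique): mean
  ~1.5 % hard.
- Film emulation is geometric only; absolute-dose normalization and film
  chemistry are out of scope, so measured film percentages are compared in
  direction, not magnitude.
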