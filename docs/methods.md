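# Methods

## Model

The globe is an elastic, pre-stressed thin spherical shell (the corneoscleral
envelope, treated as homogeneous) enclosing an incompressible linear
viscoelastic medium (the vitreous humor). The equilibrium state is a uniform
internal pressure p; the shell then carries an isotropic membrane pre-tension
N̊ = (pR/2) P, with P the tangent projector. Small-amplitude motions
∝ e^{ζt}, ζ ∈ ℂ, are superposed on this state; Im ζ is the angular frequency
and −Re ζ the decay rate.

**Interior.** The incremental nominal (Piola) stress of the pressurised
medium is S = p(∇u)ᵀ + Σ with Σ = −qI + 2G(ζ) sym ∇u; the hereditary
(convolution) constitutive law is never evaluated in the time domain — for
exponential motions it reduces exactly to multiplication by the complex
modulus G(ζ), the ζ-weighted Laplace transform of the relaxation function.
For the Kelvin–Voigt vitreous G(ζ) = γ + ζη; γ = 0 gives a Newtonian fluid
and η = 0 an elastic solid. Momentum balance and incompressibility give

    ρ_v ζ² u = −∇q + G(ζ) Δu,   div u = 0,

(the p(∇u)ᵀ term is divergence-free for solenoidal u and drops from the
interior balance, but it does contribute to the traction on the shell). At
harmonic degree ℓ ≥ 1 the bounded general solution has three amplitudes: a
pressure-driven potential mode C1 with q ∝ (r/R)^ℓ, a divergence-free
poloidal shear wave C2 with radial dependence j_ℓ(a r/R), and a toroidal
shear wave C3, where a(ζ) = iRζ√(ρ_v/G(ζ)) is the dimensionless interior
wavenumber. The ℓ = 1 spheroidal amplitudes do not yield admissible modes
and are excluded at type level; the ℓ = 1 toroidal solution rotates every
concentric sphere rigidly and deforms nothing, so it is computed but flagged
undetectable.

**Shell.** With normal and tangential displacement w = n·u and v = Pu, the
linearised balances are

    ρ_s h ẅ  = div_s(P div_s M) − (1/R) P:N + (pR/2) Δ_s w − (p/2) div_s v − n·Sn
    ρ_s h v̈  = P div_s N + (1/R) P div_s M − P S n

with constitutive laws

    N = (pR/2) ∇_s u + h (2μ ε + λ̃ (tr ε) P) + M/R,
    M = (h³/12) (2μ κ + λ̃ (tr κ) P),

ε the in-plane stretch, κ the bending tensor of the mid-surface, and
μ, λ̃ the shear modulus and the plane-stress-corrected Lamé parameter. The
pre-stress block (pR/2)∇_s u of N is taken on the full displacement
w n + v; its normal block n⊗(∇_s w − v/R) regenerates, through div_s,
exactly the two explicit pressure terms of the normal balance — this
consistency fixes all signs. The fluid loading −n·Sn, −PSn uses the full
nominal S, including p(∇u)ᵀ (a flag can disable that term for sensitivity
studies only).

**Harmonic reduction.** All degree-ℓ tensor fields on the sphere are
combinations of four atoms — Y P, the covariant Hessian of Y, the symmetric
covariant gradient of the toroidal harmonic c, and Y times the tangential
rotation ϵ — whose surface divergences reduce to scalar multipliers
(Bochner-type identities; tabulated in `harmonics.surface_operators` and
pinned by a finite-difference oracle in the tests). The shell PDEs thus
become a 2×2 algebraic system in the spheroidal pair (C1, C2) (the interior
no-slip values w, v_b at r = R and the traction are linear in the
amplitudes) and a scalar equation for C3. The azimuthal order m never enters.

**Eigenvalues.** Zeros of det(m_ij) (spheroidal) and m33 (torsional) are
found by damped Newton iteration with finite-difference derivative, seeded by
(i) the exact empty-shell roots (a polynomial eigenproblem solved directly),
(ii) golden-section-refined minima of the normalised characteristic magnitude
along the imaginary axis, and (iii) continuation from neighbouring sweep
points. Completeness inside the window (default 1–5000 Hz × damping
0–10⁴ 1/s) is certified by the argument principle; roots the axis seeds miss
(strongly damped modes) are cornered by winding-guided rectangle bisection.
A count mismatch is a hard failure, not a warning.

## Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| R | mid-surface radius | 11.2e-3 (eye) | m |
| h | wall thickness | 0.5e-3 (eye) | m |
| ρ_s | shell density | 1077 (sclera) | kg/m³ |
| ν | shell Poisson ratio | 0.5 (eye), 0.45 (ball) | – |
| K | ocular rigidity | 0.021 µl⁻¹ = 2.1e7 m⁻³ | 1/m³ |
| p | IOP / inflation pressure | 15 mmHg = 1999.83 Pa | Pa |
| ρ_v | filling density | 1000 (vitreous, per the reported fit) | kg/m³ |
| γ | vitreous shear modulus | 10 | Pa |
| η | vitreous viscosity | 0.39 | Pa·s |

Friedenwald's law is used with the natural logarithm (dp/dV = Kp), giving
compliance C = 1/(Kp) and E = πR⁴Kp/h at ν = 0.5 (4.15 MPa at baseline).
Constant-rigidity mode re-evaluates E at each pressure (material stiffening);
constant-compliance mode freezes E at its 15 mmHg value, isolating geometric
(pre-stress) stiffening. Unit conversions (mmHg → Pa at 133.322, kPa, µl⁻¹ →
m⁻³) happen only at the I/O boundary; everything internal is SI. Presets:
`eye-table1` (values above) and `salimi-ball` (R = 25 mm, h = 4 mm,
E = 4.8 MPa, ν = 0.45, ρ_s = 1200 kg/m³, water filling), the latter matching
a published hammer-excitation experiment on a water-filled rubber ball.

## Numerical choices

- **Complex spherical Bessel functions** via scipy's half-integer-order
  Bessel routines; arguments are canonicalised to the right half plane
  (j_ℓ is entire with parity (−1)^ℓ, and every characteristic quantity is
  even in a, so the square-root branch of a(ζ) cannot matter — asserted by
  parity tests). Accuracy is validated against 50-digit arbitrary-precision
  values to 1e-10 relative.
- **Characteristic assembly** uses u = j_ℓ(a)/a^ℓ and v = j_{ℓ−1}(a)/a^{ℓ−1}
  (entire, even) with a common e^{−|Im a|} scaling. This makes the
  determinant single-valued and analytic in ζ (required by the argument
  principle), regular at a = 0, and overflow-safe when the viscous boundary
  layer is thin (|Im a| in the thousands for water). The scaling factor is
  positive, so zeros, phases and residual ratios are unchanged.
- **Residual scales.** A root is accepted when |f| < 1e-10 × scale, with
  scale = |m11 m22| + |m12 m21| for the determinant and the sum of the
  magnitudes of the inertia, elastic and traction contributions for m33. The
  latter matters: at zeros of j_ℓ(a) every term proportional to the interior
  surface amplitude vanishes and m33 is legitimately tiny without being a
  root; a cruder scale accepts such pseudo-roots.
- **Newton:** relative FD step 1e-6, tolerance 1e-10, max 100 iterations,
  halving line search. Roots are canonicalised to Im ζ ≥ 0 (conjugate-pair
  symmetry is tested) and deduplicated at relative 1e-6.
- **Argument-principle contour:** initial edge sampling density follows the
  total variation of a(ζ) along each edge (the characteristic functions
  inherit e^{±ia} oscillations), refined adaptively where the phase step
  exceeds 1 rad, and the whole count is re-run at doubled density until two
  consecutive densities agree — uniform-stride phase tracking alone can
  alias full 2π wraps. Near-contour zeros trigger an automatic outward
  perturbation of the rectangle.
- **Continuation** across sweeps seeds each point with a linear
  extrapolation of the two previous roots, falling back to the previous root
  and then to a local imaginary-axis search; failed points are emitted as
  explicit NaN rows, never dropped.
- **Classification:** torsional by construction; within the spheroidal
  family a mode is "bending" when the normal share |w|²/(|w|²+|v_b|²) of the
  shell's kinetic energy exceeds ½, else "stretching".
- `modulus_from_relaxation` (generic rheology beyond Kelvin–Voigt) uses
  adaptive quadrature of the Laplace integral, truncated at 50 decay times of
  e^{−ζτ}; non-convergent integrals are rejected explicitly.

## Verification strategy

Four independent oracles pin the hand-derived reduction, since no reference
implementation of the coupled problem exists:

1. **Interior PDE residual** (the central gate): for random admissible
   solutions (ℓ ≤ 4, complex ζ, random amplitudes, Kelvin–Voigt/Newtonian/
   elastic media), ρ_v ζ²u − div S and div u vanish pointwise to < 1e-8
   relative, with div S evaluated by 4th-order Cartesian finite differences.
   This fixes the harmonic normalisation and every factor in the radial
   profiles.
2. **Static inflation:** the assembled normal equation for the uniform mode
   reproduces dp/dR = 4h(μ+λ̃)/R² exactly (bending correction verified to
   vanish as h³), pinning the pre-stress signs.
3. **Classical toroidal limit:** the torsional root converges to
   ω² = μ(ℓ−1)(ℓ+2)/(ρ_s R²) as h/R → 0, p → 0.
4. **Energy-method stiffness:** the empty-shell stiffness matrix recomputed
   from the strain-energy quadratic form (strains evaluated from their tensor
   definitions by finite differences on the sphere, energies by
   Gauss–Legendre quadrature) agrees with the spectral assembly to 1e-6,
   membrane and bending blocks, both families.

The surface traction has two independent routes — closed forms from Bessel
recurrences, and quadrature projection of the finite-difference stress — that
are required to agree to 1e-8.

## Validation against experiment, and a known discrepancy

For the water-filled rubber ball (`salimi-ball` preset) the model's lowest
ℓ=2 mode is 183.6 / 192.1 / 202.6 Hz at 13.7 / 34.5 / 62.0 kPa, against
measured values 187 / 195 / 206 Hz — errors of 1.8 / 1.5 / 1.6%, with the
pressure trend matching the experiment closely. A previously published
semi-analytic analysis of the same configuration reports computed values of
176 / 180 / 187 Hz (5.9–9.2% below the measurements). Our implementation of
the stated shell equations is anchored by the four oracles above, and a scan
over every defensible reading of the typography-sensitive pre-stress terms
(traction with/without the p(∇u)ᵀ transport term, the transpose state of the
(pR/2)∇_s u block, bending on/off, both plane-stress λ̃ conventions) produced
no variant reproducing those published values without contradicting the
stated constitutive law; the difference evidently lies in that analysis'
unpublished algebra. We retain the formulation as stated and note that it
lands closer to the measurements.

Two related remarks. First, the plane-stress Lamé correction is implemented
as λ̃ = 2Eν/(1+ν) as stated with the model; the standard plane-stress value
is Eν/(1−ν²) (which alone reproduces the biaxial modulus E/(1−ν)). The two
coincide at ν = 0.5, so all eye results are unaffected; for the ν = 0.45
ball the choice moves the lowest mode by ~1 Hz. Second, the "empty shell"
reference case carries the pre-stress p but no surface traction; it is not
the ρ_v → 0 limit of the filled model, which retains the p(∇u)ᵀ traction of
a pressurised massless medium (the two differ by <1% at eye conditions).

## What the study conditions do and do not show

The studies run the conditions the model targets: ℓ = 2 (the lowest
observable harmonics), physiological IOP 15 mmHg, IOP sweeps over 2–80 mmHg
(40 log-spaced points by default; 12–15 points in the tests for speed),
rigidity ±50% around 0.021 µl⁻¹, kinematic viscosity 1e-6–1e-3 m²/s at
density 1000 kg/m³. Under constant rigidity E ∝ Kp, so frequency scales as
√(Kp) up to fluid-loading corrections: the log-log IOP slope is 0.502, and
the *relative* sensitivity ∂log f/∂log K is ≈ ½ at every pressure — the
familiar statement that rigidity matters mostly at high IOP refers to the
*absolute* slope ∂f/∂K, which grows like √p; `rigidity_grid` emits both
diagnostics.

Passing tests show internal consistency of the idealised model, not fidelity
to real eyes: the geometry is a perfect sphere with uniform thickness and
isotropic properties; cornea and sclera are not distinguished; the aqueous
chamber, lens and optic nerve are absent; there is no periocular tissue or
exterior fluid loading (radiation damping is therefore absent, and the
computed damping is a vitreous-only lower bound); vitreous rheology is
reduced to a two-parameter Kelvin–Voigt fit. Forced response and transient
excitation are out of scope — the model yields free-vibration spectra only.
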