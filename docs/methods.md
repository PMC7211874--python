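# Methods

This note records the models implemented in myofibrekit, the assumptions
behind them, the defaults and units, and what the synthetic-data pipeline
does and does not establish about real cardiac data.

## Geometry and the transmural coordinate

Meshes are linear tetrahedra with boundary triangles labelled
`lv_endo` / `rv_endo` / `epi` / `base`.  The transmural coordinate ē is the
discrete harmonic function with Dirichlet data 0 on the endocardium and 1
on the epicardium and a natural (zero-flux) condition on the base — the
standard Laplace–Dirichlet construction for rule-based fibre methods.  The
basal boundary condition is a modelling choice (nothing forces zero flux
there); it is the conventional one and keeps ē well defined on truncated
geometries.  Discretization is plain P1 FEM with a direct sparse solve;
on the 7–10 mm spherical shell at 0.7 mm edge length the solution matches
the analytic harmonic (1/R_i − 1/R)/(1/R_i − 1/R_o) to better than 1e-3
in the relative L2 norm.  We quote L2 rather than the nodewise max norm
because the max is set by the few worst-shaped tetrahedra of the jittered
lattice (about 2e-3 at that resolution) and is not representative of the
field.

Local frames are built per element: `r0` is the normalized gradient of ē
(endo→epi by construction), `l0` the prescribed long axis orthogonalized
against `r0`, and `c0 = l0 × r0`.  Elements with a vanishing transmural
gradient (possible in slivers) inherit the nearest valid frame, with a
warning.  The frame construction is the conventional gradient-based one;
on a bi-ventricular geometry it is inherited machinery rather than a
validated anatomical statement.

AHA17 labels: the long-axis extent between the base plane and the deepest
endocardial point is split into equal basal/mid/apical thirds (the
partition fractions are not standardized for idealized geometry; equal
thirds is our choice), with 6/6/4 circumferential sectors counted from a
caller-supplied anterior reference direction; everything apical of the
cavity is the apex cap, segment 17.

## Rule-based fibres

The fibre rotation (helix) angle varies linearly in ē between an
endocardial and an epicardial value, and the fibre lies in the c0–l0 plane
at that angle: f0 = cosθ c0 + sinθ l0.  Positive θ rotates from +c0
towards +l0 (right-handed about r0); only the magnitude convention is
fixed by the usual in-plane projection definition, the sign is ours.  The
sheet is transmural (s0 = r0) with an optional rigid rotation about the
fibre for sensitivity studies (default 0° — sheet-rotation sensitivity is
known to be weak), and n0 = f0 × s0.  In per-segment mode each AHA17
segment uses its own angle pair with *no* smoothing across boundaries; the
packaged angle table (`data/rotation_angles.csv`) carries the per-segment
averages, including segment 4's epicardial 0° outlier, verbatim, plus the
whole-LV pair 40°/−30° used in uniform mode and for the RV.

## Fibre mapping

Given surface displacements (in practice the output of a diffeomorphic
surface registration; here closed-form affine + Gaussian-bump warps), the
interior displacement is the componentwise harmonic extension.  The
per-element deformation gradient F = I + ∇u uses the convention
F_ij = ∂(x_i + u_i)/∂X_j, validated by the exactness of rotations and
affine maps in the tests.  Fibres are pushed forward as F f/|F f| and
transferred to the target mesh by nearest element centroid (k-d tree, with
an exhaustive-search oracle in the tests).  After transfer the fibre is
kept as pushed forward — mapped fibres legitimately leave the c0–l0 plane —
and only the sheet is re-derived transmurally, orthogonalized against the
fibre, with n0 completing the triad.

## Dispersion model and fitting

Fibres are axial (f ≡ −f), so deviation angles live on (−90°, 90°] and are
modelled by the π-periodic von Mises density

    ρ(θ; b) = exp(b cos 2θ) / (π I₀(b)),   b ≥ 0,

normalized to 1 over one π period (b = 0 is the uniform density 1/π; the
normalizing constant is immaterial to both the MLE and the structural
tensor).  In-plane and out-of-plane deviations are assumed independent
and centred at zero, so only the two concentrations are estimated; the
location is fixed rather than fitted.  The MLE solves
I₁(b)/I₀(b) = mean(cos 2θ) by bracketed root finding on [0, b_max]
(default cap 50, flagged when hit — the likelihood degenerates as all
samples coincide).  Fitting uses raw samples; a histogram-weighted variant
(5° bins by default) exists for comparison with binned fits and agrees to
a few percent at realistic sample sizes.

Sampling for synthetic fields inverts the tabulated CDF on a fine grid
(narrowed to ±8σ for large b so resolution tracks the peak); this gives
exact density control with no rejection step, at the cost of a quantization
of order π/4096 — visible only in the b → ∞ limit, where the sampled field
matches the mean field to ~0.1°.

## Generalized structural tensor

With the mean fibre along e₃, sheet along e₁, sheet-normal along e₂ and
M(Θ, Φ) the unit direction at polar angle Θ and azimuth Φ, the tensor is

    H = (1/N) ∫₀^π ∫₀^{2π} ρ_in(Θ; b₁) ρ_op(Φ − π/2; b₂) sinΘ · M⊗M dΦ dΘ,

with N normalizing the weighted integral of 1.  H is symmetric, positive
semi-definite and has unit trace exactly (‖M‖ = 1), and for centred
densities it is diagonal; its entries are the active-tension proportions
n_s = H₁₁, n_n = H₂₂, n_f = H₃₃.  Quadrature is tensor-product
Gauss–Legendre (96 × 192 start, doubled until components move < 1e-6;
an error is raised if that never happens).  N is computed with the same
rule as H rather than from the Bessel closed form, so normalization errors
cancel; the Bessel form is asserted separately in the density tests.  An
independent Monte-Carlo estimator (inverse-CDF sampling of Θ ∝ ρ_in sinΘ
and of the axial Φ density, mean of M⊗M, with per-component standard
errors) serves as the sampling oracle.

At (b₁, b₂) = (1.6153, 1.2144) the converged integral gives
diag(H) = (0.08547, 0.26860, 0.64593) and n_n/n_f = 0.4158.  Note a
structural property that is easy to miss: H₃₃ = E[cos²Θ] does not involve
the azimuthal density at all, so n_f is exactly independent of b₂; the
out-of-plane concentration only redistributes weight between the sheet and
sheet-normal axes.

## Constitutive laws

Passive: reduced Holzapfel–Ogden energy with isochoric invariants of
C̄ = F̄ᵀF̄, F̄ = J^(−1/3)F — an isotropic exponential in Ī₁, tension-only
exponential-quadratic terms in Ī₄f and Ī₄n (switched by max(Ī₄, 1), so
collagen-like fibres bear load only in tension), exponential shear
couplings in Ī₈fs and Ī₈fn, and the volumetric penalty
(1/D)((J²−1)/2 − ln J) with D = 2/K.  The Cauchy stress uses the standard
decoupled form with deviatoric projections of the pushed-forward dyads;
its correctness is pinned by a central-difference derivative of the energy
(relative error < 1e-4 on random states, in practice ~1e-8).  Parameter
sets: the packaged LV row (a = 0.0381 kPa, b = 8.143, a_f = 3.533,
b_f = 51.339, a_n = 1.373, b_n = 4.495, a_fs = 0.929, b_fs = 4.067,
a_fn = 1.771, b_fn = 8.225 kPa-units as applicable) and RV row
(a = 0.485, b = 7.513, a_f = 2.777, b_f = 1.685, a_n = 0.704, b_n = 9.407,
a_fs = 0.121, b_fs = 15.314, a_fn = 1.351, b_fn = 17.235).  All constants
must be positive (convexity); the tables are used verbatim, with an
`a_scale` knob exposing the global stiffness scaling that in-vivo
calibration of ex-vivo fits typically requires (default 1: whether the
table values are pre- or post-scaling is not decidable from the source,
so no hidden factor is applied).  The bulk modulus is not part of the fit;
default K = 1000 kPa (D = 2e-3 kPa⁻¹) — effectively incompressible at
tissue stress scales — and configurable.

Active: time-varying elastance

    T_a(t, l) = (T_max/2) · Ca₀²/(Ca₀² + ECa₅₀(l)²) · (1 − cos ω(t, l)),
    ECa₅₀(l) = Ca₀max / sqrt(exp(B(l − l₀)) − 1),
    ω = π t/t₀ (activation),  π (t − t₀ + t_r)/t_r (relaxation),  0 after,
    t_r = m l + b_t,     l = l_r sqrt(Ī₄f).

Defaults: Ca₀ = Ca₀max = 4.35 µM, B = 4.75 µm⁻¹, l₀ = 1.58 µm,
l_r = 1.85 µm, t₀ = 150 ms (the pump model overrides t₀ = 120 ms to end
ejection at 0.12 s), m = 1048.9 ms µm⁻¹, b_t = −1629 ms, T_max = 180 kPa
(LV) / 135 kPa (RV) — the standard published elastance constants, all
overridable.  The sarcomere-length coupling l = l_r √Ī₄f is the usual
choice; peak tension is non-decreasing in l (length-dependent activation).
The dispersed active Cauchy stress distributes T_a over the deformed,
normalized fibre/sheet/sheet-normal dyads with proportions (n_f, n_s, n_n);
when the proportions come from H they sum to 1 and trace(σ_a) = T_a
exactly.  Cross-fibre sensitivity studies also use unnormalized sets such
as n_f = 1 with n_n = 0.4, in which case the trace exceeds T_a by design.

## Reduced-order pump model

The ventricle is a thick-walled incompressible sphere (reference radii
R_i, R_o) whose deformed state at cavity volume V follows the spherically
symmetric incompressible map r³ = R³ + r_i³ − R_i³, giving the equibiaxial
tangential stretch λ = r/R and F = diag(λ⁻², λ, λ) in the (radial,
tangential, tangential) basis.  The wall stress is evaluated with the full
constitutive stack at Gauss points across the wall (default 5), with the
fibre tangential at its rule-based rotation angle and the sheet radial,
and the cavity pressure is the equilibrium integral
P = ∫ 2(σ_t − σ_r)/r dr (within 10% of the Laplace law in the thin-wall
limit, as tested).  **On a sphere the fibre rotation angle is mechanically
inert** (equibiaxial symmetry), which is precisely why this model is fit
for purpose: it isolates the effect of the dispersion proportions and the
circulation from fibre-geometry interaction, and it cannot and does not
claim to reproduce finite-element ejection fractions, twist, or regional
stress patterns of a real ventricular geometry.

The circulation is a closed loop of fluid cavities: LA → (mitral) → LV →
(aortic) → aorta → systemic bed → RA → (tricuspid) → RV → (pulmonary
valve) → pulmonary artery → pulmonary bed → LA.  Exchanges follow
Δp·A = C_V·ṁ (hydrodynamic coefficient zero), equivalent to linear
resistances; valves are ideal diodes.  The printed viscous coefficients
(C_V = 20, 50, 55, 16, 3600, 300 MPa mm² s/tonne for AV, MV, PV, TV,
systemic, pulmonary) convert to Windkessel resistances through a single
linear factor pinned by the aortic-valve calibration pair
(20.0 → 0.150 mmHg s/ml); the factor is equivalently the physical
conversion 7.5006e6·ρ_blood/A with ρ_blood = 1.055e-9 tonne/mm³ and an
effective exchange area A ≈ 1.055 mm².  The aorta and pulmonary artery are
linear compliances (0.061 and 0.065 ml/mmHg); the atria are ideal pressure
sources at the end-diastolic pressures (8 and 4 mmHg) — the printed tables
leave the atrial compliances unspecified ("whatever keeps end-diastolic
pressure constant"), and an ideal source is that limit.

Integration: cavity volumes (and arterial pressures) are the state, so the
ventricular pressure is an explicit function P(V, t) and no per-step
root-finding is needed; explicit fixed-step Euler at 0.1 ms (results are
unchanged at 0.05 ms to 5 decimal places in EF).  Every flow enters one
cavity and leaves another, so closed-loop volume conservation holds to
round-off by construction and is *reported*, not assumed.  Cycles start at
end diastole — the volume where the passive curve crosses the
end-diastolic pressure, found by bracketed root finding; for an elastic
wall this is equivalent to, and history-independent of, a quasi-static
linear pressure ramp.  Cycle length 1 s; activation onset at t = 0.

Reference radii are a design choice of the synthetic study conditions:
LV 8.05/11.55 mm and RV 6.9/8.9 mm, chosen once so that passive inflation
to the end-diastolic pressures gives end-diastolic volumes of ≈2.87 ml
(LV) and ≈1.96 ml (RV), a physiological neonatal scale; they are not
claimed to match any imaged geometry.

## Synthetic data: what it does and does not emulate

The mesh generator produces truncated thick-walled ellipsoids (apex down,
base plane z = const) from a structured lattice in generalized-radius /
polar-angle / azimuth coordinates, triangulated by a Delaunay pass and
filtered by the centroid's generalized radius.  A small seeded jitter,
applied within each coordinate surface so boundary nodes stay exactly on
their surfaces, breaks the co-spherical degeneracies of a regular lattice;
the result is bit-reproducible for a fixed spec and seed.  This replaces a
literal structured hex/wedge subdivision: it needs no conforming-split
bookkeeping at the poles and cannot produce inverted elements.  The price
is a modestly irregular element quality (the sliver tail visible in the
max-norm Laplace error above).

The dispersed fibre sampler perturbs the rule-based mean field by
independent in-plane and out-of-plane π-periodic von Mises deviations —
exactly the generative model the dispersion-fitting stage assumes.
Passing the round-trip tests (sample → extract → fit → tensor recovers
the generating concentrations and proportions) therefore validates the
estimator chain, *not* the adequacy of the independent-von-Mises model for
real DT-MRI data; real fields also carry spatial correlation, transmural
trends in dispersion, and measurement noise that the generator
deliberately omits.  Likewise the analytic warps (affine + Gaussian bump)
exercise the mapping machinery with exact oracles but are far smoother
than registration-derived displacement fields.

## Numerical choices and degenerate inputs

* Angles are degrees at every interface and radians internally; stresses
  kPa internally with mmHg/ml only at the circulation interfaces
  (1 kPa = 7.5006168 mmHg).
* Fibres parallel to the transmural direction have no in-plane angle; they
  are flagged, excluded from fits, and warned about.
* All-identical angle samples make the concentration likelihood unbounded:
  an error, while near-identical samples hit the configurable cap b_max.
* Tets are re-oriented to positive volume on mesh construction; degenerate
  (flat) simplices from the lattice are dropped before assembly.
* det F ≤ 0 anywhere in a mapped displacement field is a hard error
  listing the offending elements (non-diffeomorphic warp).

## Known limitations

* Dispersion enters the *active* stress only; the passive law is
  dispersion-free (structural-tensor passive coupling with compressed-fibre
  exclusion is a known open problem and out of scope here).
* The reduced-order ventricle cannot express twist, long-axis shortening,
  LV–RV mechanical interaction, or regional stress heterogeneity; its
  ejection fractions are internally consistent but not comparable to
  finite-element or measured values.
* The in-plane/out-of-plane independence assumption (and hence the product
  density in H) is an approximation inherited from the experimental
  literature; pathological tissue in particular may violate it.
* AHA17 longitudinal thirds and sector origins follow fixed conventions on
  idealized geometry and are not registered to anatomical landmarks.
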