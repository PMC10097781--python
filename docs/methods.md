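# Methods

## Scope and model overview

`helixlv` simulates the biomechanics of the fetal left ventricle (LV) as a
function of its myofiber helix-angle architecture.  The wall is an
incompressible, transversely isotropic hyperelastic solid with an added
active fiber tension; the chamber is loaded either by coupling to a
closed-loop 0D model of the fetal circulation or by prescribing the cavity
volume over time (the volume-constrained driver).  Outcome metrics —
stroke work, peak myofiber stress, deformational burden, transmural strain
variance, and global strains — are collected over grids of helix
configurations into maps with interpolated optima.

### Fiber architecture

A helix configuration is the pair (τ̄, τ_diff): the transmural average of
the helix angle and its epicardial-to-endocardial difference.  With the
transmural coordinate e (0 at the epicardium, 1 at the endocardium) the
local helix angle is

    α(e) = τ̄ + (e − ½) τ_diff,

a linear profile whose endpoints are τ̄ ∓ τ_diff/2 at the epi/endocardium.
Positive α rotates the fiber from the circumferential direction toward
apex-to-base, so positive endocardial angles are right-handed.  The
transverse (wall-crossing) fiber angle is fixed at zero: fibers lie in the
wall-tangent plane.

The transmural coordinate is the harmonic (Laplace–Dirichlet) field with
e = 0/1 boundary values — the standard rule-based construction.  Wall
frames follow from its gradient: t = −∇e/|∇e| (endo→epi), l is the
projection of the long axis onto the plane normal to t, and c = l × t.
Within an apex cap (default 2% of the cavity length) where the projection
degenerates, quadrature points inherit the nearest regular frame.

### Passive myocardium

Fung-type transversely isotropic strain energy

    W = C/2 (e^Q − 1),
    Q = b_ff E_ff² + b_xx (E_ss² + E_nn² + E_sn² + E_ns²)
      + b_fx (E_fn² + E_nf² + E_fs² + E_sf²),

with E the Green–Lagrange strain in the fiber/sheet/normal frame.  The
sheet direction is transmural; the law is insensitive to rotations in the
(s, n) plane.  A configurable cap on Q (default 50) fails loudly when a
Newton trial state would overflow the exponential; the solver treats that
as a failed trial and sub-steps.

Defaults (C = 0.876 kPa, b_ff = 18.48, b_xx = 3.58, b_fx = 1.627) are
surrogate values from the Guccione parameter family, shipped clearly
flagged as supplementary-table surrogates; every value is overridable
per run.

### Active tension

Active stress acts along the reference fiber direction,
S_act = P_act f₀ ⊗ f₀, with

    P_act = T0_LV · Ca0² / (Ca0² + ECa50(l)²) · Ct(t, l),

where Ct = (1 − cos ω)/2 rises over [0, t0) and falls over [0, t_r) after
the peak, t_r = m·l + b.  The length-dependent calcium sensitivity uses
the Guccione form ECa50 = Ca0_max / √(exp(B_len (l − l0)) − 1); the
sarcomere length is l = l_ref λ_f with λ_f the fiber stretch and
l_ref = 1.85 µm.  Fetal defaults: t0 = 140.5 ms on a 400 ms cycle;
T0_LV defaults to 40 kPa, inside the reported fetal range 23.9–59.2 kPa,
and `calibrate_t0lv` bisects it against a target peak pressure.  The
relaxation-line parameters (m = 524.5 ms/µm, b = −800 ms) are
cycle-scaled surrogates chosen so that t0 + t_r stays inside the cycle for
physiological sarcomere lengths.

### Finite-element formulation

Total-Lagrangian, quasi-static, two-field mixed formulation: quadratic
(P2) displacements on 10-node tetrahedra and a linear (P1)
hydrostatic-pressure multiplier (Taylor–Hood).  Incompressibility is
enforced by the multiplier and augmented with a volumetric penalty
κ (J − 1) (default κ = 500 kPa), which tightens pointwise J → 1 beyond
what the weak constraint alone achieves on coarse meshes.  The consistent
tangent (passive, active length-dependence, pressure/penalty geometric
terms) is assembled analytically and verified against finite differences
in the suite.

The cavity pressure is the Lagrange multiplier of a cavity-volume
constraint: the cavity volume is the divergence-theorem integral over the
deformed endocardial surface (the basal cap at z = 0 contributes
nothing), and its exact gradient and Hessian with respect to nodal
displacements supply the follower-load vector and load stiffness.  The
bordered Newton system solves displacement, multiplier field, and cavity
pressure together; a backtracking line search plus adaptive load
sub-stepping (with an activation ramp on cold starts) globalizes the
iteration.

Boundary conditions: longitudinal displacement fixed on the base plane
(in-plane free) and a weak epicardial Robin spring (default 0.05 kPa/mm)
standing in for surrounding tissue and removing the residual rigid modes.

### Unloaded state

The zero-pressure reference of a loaded (end-diastolic) geometry is found
by backward displacement: iterate X₀ ← X_meas − u(X₀; EDP) until the
update stalls, then validate by re-inflating (volume round-trip error and
nodal RMS are reported).  In the volume-constrained driver the generated
geometry itself is taken as the unloaded state and assigned to the
waveform instant at one third of the diastolic duration, the low-pressure
point of filling.

### 0D circulation and coupling

The closed fetal loop has elastance chambers (LV, RV, LA, RA), R–C
vascular segments (ascending/descending aorta, pulmonary trunk and bed,
upper body, placenta + lower body, venae cavae), smoothed-diode valves,
and the two fetal shunts: foramen ovale (RA→LA) and ductus arteriosus
(PA→descending aorta).  Parameter values are surrogates in the spirit of
the Pennati fetal model, sized to fetal scales (stroke volume ≈ 1 ml,
systolic LV pressure ≈ 30–45 mmHg at a 400 ms cycle); recalibration is
exposed as global resistance/compliance scale factors (k_R, k_C).  The
stiff ODE system integrates volumes with BDF; total blood volume is
conserved to the integrator tolerance and twelve cycles reach periodic
steady state.

In coupled mode the 0D LV elastance is replaced by the FE chamber: per
macro time step (cycle/steps), the network integrates with the last FE
pressure held, the integrated valve flows set the next LV target volume,
and the FE solve at that volume returns the next pressure — one exchange
per step, no sub-iteration by default.

### Metrics and maps

* Stroke work: shoelace area of the closed (V, p) loop, mmHg·ml → mJ
  (×0.133322); cross-checked against the trapezoidal ∮p dV.
* Peak myofiber stress: temporal peak of the volume-averaged Cauchy
  stress projected on the deformed (normalized) fiber direction.
* Deformational burden: |W̄(ES) − W̄(ED)|, W̄ the volume-averaged passive
  energy density against the unloaded reference.
* Transmural strain variance: unweighted variance of the fiber-direction
  strain (ES vs ED) over quadrature points in a transverse slab at 50% of
  the cavity length (half-width 5% of the cavity length).
* Global strains: volume-averaged strains of material line elements along
  the local longitudinal/circumferential directions, ES against ED; the
  FE-vs-echo error is ER = Δε_long² + Δε_circ².
* Maps: metric values on a (τ̄, τ_diff) grid (default spacing 15° over
  [−90°, 180°]; 3×3 smoke preset), bicubic-spline interpolant (thin-plate
  RBF when nodes are masked), multistart continuous optimization within
  the grid hull with a boundary flag, and SSIM between min–max-normalized
  map pairs (Gaussian 3-node window, standard stabilization constants).

ED/ES are identified as the states of maximum/minimum cavity volume,
robust to waveform phase conventions.  Spatial averages are
volume-weighted (the natural choice; the alternative is a configuration
change away).

### Synthetic inputs

The synthetic-data module emulates everything a patient-specific
analysis would take from echo:

* Volume waveforms: C¹ periodic curves — raised-cosine ejection, biphasic
  (E/A) raised-cosine filling — with exact EDV/ESV and no isovolumetric
  plateaus, matching the temporally smoothed character of motion-tracked
  clinical waveforms.  Fetal defaults: EDV 2.2 ml, ESV 1.2 ml (stroke
  volume ≈ 1 ml), 400 ms cycle; adult: EDV 132 ml, SV 81.8 ml, 800 ms.
* "Image-derived" strains: ground-truth global strains plus i.i.d.
  Gaussian noise, seeded and reproducible — the minimal observation model
  needed to exercise the strain-error machinery.
* Asymmetric fixtures: a volume-preserving shear that leans the apex
  sideways, emulating the straight-septum asymmetry of real fetal LVs.

What these do **not** emulate: speckle/image noise structure, regional
strain heterogeneity, tracking bias, or patient-specific wall-thickness
variation — so passing tests demonstrate the machinery and its
sensitivities, not clinical fidelity on real images.

### Geometry family

Idealized LVs are half-ellipsoid walls (endocardial semi-axes plus a
uniform wall-thickness offset), meshed by a structured
circumferential × longitudinal × transmural grid split into conforming
quadratic tetrahedra (Freudenthal subdivision, apex cells collapsed);
midside nodes are generated in parameter space so boundary faces are
exactly curved.  Printed fetal dimensions: Symmetric 16.00 mm cavity
length × 13.40 mm basal width × 3 mm wall; Regular 18.75 × 15.40 × 3
(asymmetric, leaning apex); Hypertrophic doubles the wall; Long stretches
the length 1.5× and solves its equatorial radius for volume match;
Hemisphere solves r from V = (2/3)πr³; Wide is the Symmetric prolate cut
along an equatorial axis (identical cavity volume by symmetry, and
exactly the 90°-rotated configuration); the adult shape is
85 × 45 × 9 mm.  The five volume-matched fetal shapes agree in cavity
volume to well under the 2% target at production resolution (measured
spread ≈ 0.12%).

The printed Symmetric dimensions give a geometric cavity volume of
≈ 1.50 ml while the fetal waveform EDV is 2.2 ml; the generated geometry
is therefore treated as the reference (unloaded) state and end-diastole
is reached by inflation along the prescribed waveform, never by rescaling
the geometry.

## Numerical choices and problem sizes

* Quadrature: 4-point (degree-2) rule on tet10 for all volume assembly;
  degree-4 Dunavant rule on tri6 surfaces; degree-3 rule for element
  volumes.
* Newton: relative residual 1e−8 (absolute 1e−10), ≤25 iterations,
  backtracking line search, load sub-stepping up to 32 substeps.
* Production meshes honour a 2500-element minimum; the test-suite meshes
  are deliberately coarse (≈160–2400 elements, flagged by
  `enforce_min_elements=False`) so the whole suite runs at desk scale.
  Cycle drivers default to 50 steps/cycle; the suite uses 20.
* Pointwise incompressibility: |J − 1| ≲ 0.5% for passive inflation at
  suite resolutions; at peak active contraction on the coarsest meshes it
  reaches a few percent (the P1 multiplier space limits pointwise
  enforcement), tightening with mesh refinement and with the bulk
  penalty.  The suite asserts the resolution-appropriate bounds.
* Determinism: no stochastic components in the solvers; fixed iteration
  orders; the only seeded randomness is the synthetic strain noise.

## Known limitations

* Constitutive and circulation defaults are documented surrogates from
  the cited model families (Guccione, Pennati); headline patient-specific
  magnitudes are reproduced only in scale, not digit-for-digit.
* The circulation topology is a reduced Pennati-style network (single
  combined placental/lower-body bed, no shunt-closure dynamics).
* Helix profiles are linear and globally uniform; transverse angle is
  zero; no sheetlet sliding; no right ventricle; quasi-static (no
  inertia).
* The coupled driver exchanges once per macro step; strongly mismatched
  FE/0D states can require smaller steps (an error message suggests it).
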