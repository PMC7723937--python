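# Methods

`cartatlas` implements an atlas-based workflow for estimating knee
cartilage mechanics from five anatomical length measurements, together
with the reliability and trajectory statistics used to evaluate such a
workflow. This note records the models, the numerical choices, and what
the synthetic study conditions do and do not demonstrate.

## Template matching and scaling

A subject is characterized by five lengths (mm): the maximum
medial-lateral femoral dimension (ML, the clinical transepicondylar
axis), the maximum anterior-posterior dimensions of the medial and
lateral condyles (AP medial / AP lateral), and the tibiofemoral joint
space widths of both compartments (JSW medial / lateral, interpreted as
combined cartilage thickness). Dimensions are normalized by ML so knees
of different size are compared by shape; the template with minimum RMSE
over the five normalized fields is selected (the ML term is identically
zero, so this equals a four-field RMSE; ties keep library order). The
selected mesh is scaled anisotropically about the centroid of its
tibial contact surface: AP maps to x, ML to y, JSW to z. Because only
the medial compartment is meshed, AP medial and JSW medial govern the x
and z scales by default; a configuration switch (`use_lateral_scaling`)
substitutes the lateral pair. Scaling preserves topology, node sets and
the meniscus-support fraction, and re-normalizes the split-line vectors.

## Gait loading

A generic stance-phase waveform (axial tibiofemoral force in body-weight
units, knee flexion angle; 0-100% stance) is an *input*. The packaged
CSV is a representative two-peaked instrumented-knee profile (peaks near
2.6 and 2.7 BW at ~20% and ~70% stance, flexion from ~5 deg at heel
strike to ~40 deg at toe-off); users may substitute their own. The
medial compartment force is

    F_med(t) = f_bw(t) * m * g * medial_share * (1 - meniscus_fraction)

with `g = 9.81 m/s^2`, `medial_share = 0.5` (half of the joint force
through the medial compartment) and the meniscus-borne share subtracted
because menisci are not meshed. `meniscus_fraction` defaults to the mean
of the atlas library's per-template fractions. Stance maps to time as
100% = 0.6 s (configurable); the default grid is 101 uniform points.

## FRPVE cartilage material

Total stress is the biphasic mixture sum `sigma_t = sigma_nf + sigma_f -
p I`. Default parameters (femoral / tibial): nonfibrillar matrix modulus
E_m 0.215 / 0.106 MPa, initial fibril network modulus E_0 0.92 / 0.18
MPa, strain-dependent fibril modulus E_eps 150 / 23.06 MPa, Poisson
ratio 0.15, fibril damping eta 1062 MPa s, permeability k 6 / 18 x
1e-15 m^4/(N s) (converted to mm^4/(N s) internally), fluid fraction
n_f = 0.8 - 0.15 h_z with normalized depth h_z. With incompressible
constituents the fluid fraction affects the mechanics only through
permeability, which is held constant per tissue, so n_f serves as tissue
description rather than a solver input.

*Non-fibrillar matrix*: compressible neo-Hookean on the stretch
`U = I + eps` (`sigma = mu/J (B - I) + lam ln J / J I`), reducing to
Hooke's law with (E_m, nu_m) at infinitesimal strain. A
`linear_matrix` flag selects the exact linear limit, used for solver
verification against linear poroelasticity benchmarks.

*Fibril network*: two primary directions follow the Benninghoff arcade
(parallel to the split line at the articular surface, rotating
continuously to the surface normal at the bone interface, interpolation
angle `h_z * pi/2`); 13 secondary directions form a fixed quasi-uniform
set (3 cube axes, 4 body diagonals, 6 face diagonals). A primary fibril
is 3x as dense as a secondary one (configurable); per-fibril weights
normalize to one so E_0/E_eps are network-aggregate moduli. Each
direction carries a tension-only uniaxial stress from an equilibrium
spring `sigma_eq = E_0 eps + 0.5 E_eps eps^2` (tangent E_0 + E_eps eps)
in parallel with a Maxwell branch (spring of the same tangent modulus in
series with damper eta):

    d(sigma_v)/dt = E_br(eps) d(eps+)/dt - (E_br(eps)/eta) sigma_v.

Discretization: backward Euler with the branch modulus evaluated at the
*previous* step's strain. The lag keeps the discrete strain-to-stress
map monotone with a non-negative tangent for arbitrarily large
increments (the fully implicit strain-dependent modulus can produce a
negative tangent under strong unloading, which destroys Newton
convergence); it vanishes at constant strain and with step refinement,
so equilibrium and relaxation behavior are exact. The tension clamps are
C1-smoothed over negligible widths (1e-3 MPa on stress, 1e-4 on strain)
so solver tangents stay continuous; outside the blends the law is exact.

## Finite-element solver

A small mixed displacement/pore-pressure solver replaces the original
workflow's commercial FE stage at desk scale: quasistatic biphasic
equations, trilinear hexahedra for both fields (2x2x2 Gauss points),
backward-Euler time stepping, damped Newton iteration on the monolithic
symmetric system (residual force tolerance 1e-6 x reference load,
pressure residual 1e-8 relative, up to 25-40 iterations with
backtracking). Equal-order interpolation is stabilized by a local
pressure-projection term penalizing intra-element pressure fluctuation
(coefficient 0.1/(2 mu)); it vanishes on element-wise constant pressure,
so volume conservation and smooth consolidation profiles are untouched.
Verification: 1-D Terzaghi consolidation (20-element column, time factor
0.3) reproduces the closed-form series within 0.3% relative L2, errors
decrease monotonically under refinement, a sealed column responds
incompressibly (p equals the applied stress, volumetric strain below 1%
of the drained axial strain scale), and the discrete mass balance closes
to 1e-8.

*Contact.* Cartilage-cartilage contact is simplified to the deformable
tibial-side layer against a rigid, impermeable counter-surface (plane,
sphere or ellipsoid - anisotropic scaling turns the atlas sphere into an
ellipsoid). A penetrating contact node feels `penalty * area * depth`
along the surface normal, compression only, with a C1-smoothed ramp at
zero gap (width 1e-3 mm). The pipeline default penalty, 5 MPa/mm, is
deliberately soft: it acts as an elastic foundation representing the
unmeshed femoral cartilage layer (whose undrained stiffness per unit
area is a few MPa/mm), which also spreads contact over a realistic patch
on coarse meshes. If Newton stalls from contact-set chattering, the
active set is frozen after 12 iterations; misclassified nodes then carry
|gap| ~ 1e-4 mm, a force error of order 0.01 N.

*Force-controlled gait.* The counter-surface height is an additional
Newton unknown closed by the constraint "total vertical contact force =
F_med(t)" (1% tolerance). The extra Jacobian column and row assemble to
the same vector, keeping the augmented system symmetric; a stance step
that fails to converge is bisected automatically (up to 8 substeps).
Flexion translates the contact point anteriorly by `0.3 * r_x *
sin(flexion)` - a rolling approximation of counter-surface reorientation
whose vertical component is absorbed by force control.

*Drainage in the gait problem.* The bone interface is sealed; the side
faces are drained; the articular surface is sealed everywhere. At stance
time scales (0.6 s against consolidation times of order 1e3 s) the
distinction between a sealed top and a top drained only outside the
contact patch is negligible, and the fixed Dirichlet set removes a
dependence of the constraint pattern on the contact state. The generic
`solve()` path retains per-step dynamic sealing of flagged contact nodes
for problems where drainage matters.

## Response summarization

At each stance frame the contact region is the set of elements with at
least one flagged contact node. Five parameters are reduced over that
region: maximum principal stress (of total stress), maximum and minimum
principal strain, fibril strain (largest tensile strain over the fibril
directions at each Gauss point) and pore pressure. The average is
area-weighted by element articular-face area over Gauss-point element
means; the peak is the Gauss-point extremum in the physically adverse
direction (maximum for tensile quantities and pore pressure, minimum for
compressive principal strain). Frames with an empty contact region are
recorded as missing and warned about, never interpolated.

## Reliability statistics

ICC(2,1) - two-way random effects, absolute agreement, single
measurement - from the two-way ANOVA mean squares of an n x k
subject-by-trial table, with the McGraw-Wong F-based 95% interval.
Classification uses the Koo-Li cutoffs with boundaries resolved as
[0, 0.5) poor, [0.5, 0.75] moderate, (0.75, 0.9] good, (0.9, 1]
excellent, so that "ICC > 0.75" is exactly good-or-excellent;
`count_reliable` counts strictly above the threshold. A degenerate table
(zero total variance) is reported as ICC 1 with a warning. Note the
well-known small-sample bias of the estimator: at n = 6, k = 3 with a
true variance ratio of 0.9 its expectation is about 0.857; recovery of
the variance-component ratio should therefore be assessed at larger n
(at n = 50 the estimate lands within 0.05 of the ratio).

## Nonparametric 1-D SPM

Paired trajectories are compared by the pointwise paired t statistic on
subject differences, with family-wise inference from the sign-flip
permutation distribution of the field-wide maximum |t|: all 2^n patterns
enumerated for n <= 12 (n = 9 gives 512, exact and deterministic),
seeded Monte-Carlo (default 10 000, identity always included) otherwise.
The threshold is the (1 - alpha) "higher" quantile of max |t|;
supra-threshold clusters are maximal contiguous runs, each with the
max-statistic p of its peak (the fraction of permutations whose global
max |t| reaches the cluster's peak). The minimum achievable p is
2/2^n because the all-flipped pattern mirrors the observed one. All
threshold and peak comparisons use the identity-permutation row of the
same vectorized computation, avoiding epsilon artifacts between
formulas. Zero-variance points map to 0 (zero mean) or signed infinity
sentinels. Empirical calibration at the defaults (n = 9, 101 points,
alpha = 0.05): family-wise type-I error ~ 0.04, and a localized shift of
twice the paired-difference SD on 6 grid points is detected in > 95% of
replicates.

## Synthetic study conditions

The generators are first-class, seeded code; identical inputs give
identical bytes. Dimension distributions reflect adult knees (ML 80 +/-
4 mm, AP medial 53 +/- 4.3, AP lateral 62 +/- 4.6, JSW medial 3.9 +/-
1.0, JSW lateral 5.4 +/- 0.9 mm, body mass 80 +/- 12 kg, with positivity
clips). The atlas library holds 21 templates; meniscus support fractions
are drawn from U(0.3, 0.5). Template geometry is parametric-analytic: a
flat tibial slab taking 2/3 of JSW over a footprint AP-medial long and
0.45 ML wide, under a femoral cap (1/3 of JSW) whose articular sphere
touches the slab at the footprint center. The sphere radius, drawn from
U(130, 180) mm, is the *effective relative-curvature radius* of the
compartment contact - much larger than a condyle radius because the
concave plateau and meniscus make the contact conforming - and doubles
as the rigid counter-surface. Default meshes are 6 x 6 x 3 elements per
layer: coarse enough that nine subjects x 101 stance points run in a few
minutes on one CPU, fine enough for smooth contact-patch growth.

What passing tests show - and do not. The synthetic geometry closes the
loop between generator and morphometry (measured ML/AP/JSW match the
generating parameters within 1%) and exercises every pipeline contract,
but it is not an image-derived knee: there is no condyle asymmetry, no
cartilage thickness gradient, and a single deformable layer stands in
for two. Simulated magnitudes are plausible (peak pore pressures 1.2-1.7
MPa at 500-800 N medial load) but peak local compressive strains are
larger than in high-fidelity two-layer models; with the soft published
matrix moduli on a coarse single layer, deep indentation is needed to
carry peak gait loads, and the small-strain kinematics are stretched at
those local extremes. Conclusions about real knees require real
templates and images; the package's claims are about the method's
correctness, calibration and determinism, which the oracle suite
measures directly.

## Known limitations

- Small-strain kinematics throughout; large local strains under peak
  load are outside the solver's asymptotic regime.
- One deformable layer per compartment; the femoral layer is an elastic
  foundation, not a meshed poroelastic body.
- No depth-dependent permeability or fixed-charge swelling; constant k
  per tissue.
- The fibril branch modulus lag is first-order in the step size; stance
  grids coarser than ~25 points blur the viscous transient.
- Confidence intervals for ICC are F-based approximations; they are
  oracle-tested against an independent implementation, not against
  published intervals (raw measurement tables are not available).
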