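# Methods

This note documents the models, numerical choices, calibrations and known
limitations of `tdcsfield`. Nothing here is an empirical claim beyond what
the test suite and `scripts/acceptance.py` compute.

## Head phantoms

The phantom is a set of concentric spherical shells on a regular voxel
grid: scalp (outer radius 92 mm), compact bone (85 mm), CSF (79 mm) and a
grey-matter core (75 mm) by default, each voxel labelled by the innermost
shell containing its centre. Conductivities are the standard low-frequency
scalar set (S/m): grey matter 0.2, white matter 0.14, blood 0.7, compact
bone 0.008, spongy bone 0.027, CSF 1.8, dura/muscle 0.16, skin/fat 0.08,
eye 1.5, saline sponge 1.6, conductive rubber 0.1. The exterior is excluded
from the system entirely (exact insulating boundary). A sinusoidal radial
perturbation of the grey interface (`amplitude · cos(kφ + phase) · sin²θ`)
emulates gyral variability without breaking shell order.

Electrodes follow the two-compartment model: a 6 mm saline sponge
conforming to the scalp carrying a 1 mm rubber pad, both restricted to a
geodesic square footprint (pad size interpreted as arc length; default
5 × 5 cm). The anode injects +1 mA and the cathode −1 mA, lumped equally
onto the nodes of the rubber voxels. Default montage: anode at the vertex,
cathode 110° away (the contralateral-orbit analogue).

Cohorts draw per-subject shell thicknesses from truncated normals around
the defaults (SDs: scalp 0.8 mm, skull 1.6 mm, CSF 1.0 mm; gyral amplitude
half-normal with SD 0.8 mm; thickness floor max(2 mm, voxel size) so every
phantom stays resolvable). These SDs are the calibration constants that set
the cohort-level field spread: at 3 mm voxels a 27-subject default cohort
gives E_n at the peak-field vertex with mean ≈ 0.32 V/m, SD ≈ 0.10
(coefficient of variation ≈ 0.31) and range ≈ 0.16–0.56 V/m, matching the
spread reported for individualized MRI-based models (0.39 ± 0.12, range
0.20–0.60 V/m) in relative terms. The default CSF shell is 4 mm so the
solver's refinement ladder (4 → 3 → 2 mm voxels) stays within the
"voxel must not exceed the thinnest shell" rule.

## Volume-conductor solver

The quasi-static problem ∇·σ∇φ = 0 with nodal current sources is
discretized with 8-node trilinear hexahedral elements, one per conductive
voxel, per-element constant σ (the element stiffness is σ·h·K̂ with K̂ the
exact 2×2×2-Gauss reference matrix). The operator is symmetric positive
semidefinite with the constant vector as nullspace; the gauge is fixed by
zero mean over active nodes, never by pinning, so the residual stays
meaningful. Exterior nodes receive a decoupled diagonal entry of typical
scale to keep smoothers and coarsening well conditioned.

The solver is a V(2,2) geometric multigrid: damped-Jacobi smoothing
(ω = 0.7), trilinear prolongation built as a Kronecker product of 1-D
interpolations, restriction by its transpose, Galerkin coarse operators
(coefficient coarsening — the irregular domain is never re-voxelized), and
a dense pseudo-inverse at the coarsest level (≤ ~4000 nodes). By default
the V-cycle preconditions conjugate gradients: with the high conductivity
contrasts here (σ ratio up to 225 between CSF and compact bone), plain
Jacobi-smoothed V-cycles converge but slowly, while MG-PCG keeps
grid-size-independent convergence; `accel=None` selects plain V-cycling.
Convergence is declared at Euclidean relative residual ≤ 1e−6 (default).
Systems below 20 000 active nodes go to a sparse direct factorization with
identical contract. Double precision throughout; residual history logged.

The discrete current through any node cut (`fem.cut_current_ma`) conserves
the enclosed injected current to the solver residual. Re-quadrature of the
per-element fields over a box surface (`fields.enclosed_current_ma`) is
first-order accurate only — about 10 % at 2–3 mm voxels — and is provided
as a geometric diagnostic, not a conservation check.

## Field extraction

E = −∇φ is evaluated per element from the trilinear shape-function
gradients at element centres. Cortical maps sample the field at
`vertex + depth · inner_normal` (default depth 1 mm) by trilinear
interpolation of element-centre values; E_abs = |E| and E_n = n̂·E with n̂
the unit inner normal (positive = into the cortex). |E_n| ≤ E_abs is
asserted on every map. For voxel models an alternative `restricted`
sampling mode inverse-distance-weights only interface-free same-tissue
elements within two voxel spacings; it suppresses the discretization noise
that element fields carry next to a conductivity jump at the price of
smoothing over ~2 voxels. Subject-to-template correspondence is the
identity on a shared icosphere (subdivision 3, 642 vertices, by default);
surface registration of real anatomies is out of scope.

## Analytic sphere oracle

For point current sources the concentric-sphere problem has an exact
solution: per degree n, each layer contributes a scaled basis
`a (r/R_outer)^n + b (R_inner/r)^(n+1)` matched by continuity of φ and of
σ∂φ/∂r at interfaces, regularity at the centre, and zero normal current at
the outer boundary; each single source carries a uniform compensating
boundary outflow whose superposition cancels for a zero-sum source pair.
The n = 0 mode is a pure gauge constant below the sources, so evaluation is
restricted to radii beneath the smallest source radius. Default truncation
N = 200 with an explicit tail check (error raised above 1e−8 relative);
the scaled basis keeps the coefficients conditioned at any N. The series
is itself cross-checked against the closed-form image/log solution of the
homogeneous sphere (agreement ~1e−16) and satisfies the interface
conditions to numerical precision.

### Measured solver accuracy

With point sources placed 4 mm under the scalp (the pad-centre analogue)
and the production sampling chain, the relative RMS error of |E| on the
cortical sampling surface against the oracle is 13.1 % at 4 mm, 12.4 % at
3 mm, 9.0 % at 2 mm and 8.9 % at 1.5 mm voxels — monotone but slow. Two
mechanisms set the floor. First, the staircased resistive skull and thin
CSF shells systematically over-transmit current: the deep potential
carries a scale factor of 1.047 at 2 mm (1.028 at 1.5 mm), converging at
roughly O(h^0.7), with skull and CSF interfaces contributing about 2.5 %
each. Second, sampling 1 mm below the grey surface with 2 mm voxels
interpolates across interface-adjacent elements whose fields carry O(1)
local discretization noise. Volume-fraction σ mixing (arithmetic,
harmonic, geometric), variational subcell quadrature, laminate effective
tensors and finite-volume harmonic faces were all evaluated and either
worsen the transmission bias or distort near-interface fields; the sharp
staircase with trilinear elements is kept. Studies needing < 5 % field
accuracy at the cortex should solve at sub-millimetre voxels, which is
exactly what the reference methodology does; the 2 mm default here is a
desk-scale compromise whose error is measured, not hidden.

## PLS region discovery

Vertices are ranked by the cohort mean of E_abs or |E_n|; those at or
above the (100 − r_E)th linear-interpolation percentile are retained
(r_E ladder 1/2/3/10 %), and the predictor matrix holds the per-subject
*signed* E_n values, standardized per column (sample SD, zero-variance
columns dropped with a warning). PLS1 is fitted by NIPALS with X and y
deflation; cumulative R² per component. Q² uses Monte-Carlo repeated
10-fold cross-validation (default 1000 repetitions; fold sizes differ by
at most one; centring and scaling refit inside training folds — the
statistically safe choice where the convention is ambiguous) with the
incremental convention Q²_a = 1 − PRESS_a / RSS_{a−1} (RSS_0 = TSS), which
reproduces the steeply negative higher-component values seen in practice.
A component is predictively significant iff Q² > 1 − 0.95² = 0.0975
(strict). VIP_j = √(p Σ_a SSY_a w²_ja / Σ_a SSY_a); Σ_j VIP²_j = p exactly.
The observation point r0 is the arg-max VIP vertex, ties to the lowest id
(logged), with a stability report across the r_E ladder.

## MEP statistics

The response is the MEP normalized to its session baseline; the overall
excitability change per (subject, session) is the mean of MEP(t)/MEP_base
over the four post-stimulation time points (t0–t30), with missing time
points an error, never imputed. Grubbs screening is the iterative
two-sided test with the t-based critical value.

The mixed model is Gaussian with a per-subject random intercept, fitted by
maximum likelihood (not REML, so LRTs on fixed effects are valid). The
likelihood is profiled over λ = σ²_b/σ²_e, which has a closed form per λ
through the per-group Woodbury identity; the scalar profile is maximized
by a log-grid scan plus bounded refinement, including the λ = 0 boundary
(which reproduces OLS exactly). Fixed-effect designs follow the crossover
structure: intercept, Time (t0 reference), Session (sham = 0), their
interaction, a baseline-amplitude block, and optionally an 8-term
covariate block (field strength or RMT: main effect plus interactions
with Time, Session, Time × Session). The LRT between the base and
covariate models therefore has 8 degrees of freedom. Wald F-tests for
contrasts use the ML covariance with residual-method denominator df
(n − p); Satterthwaite-type df approximations are deliberately not
implemented — at this design's balance they change little, and the
package's inference claims rest on measured type-I calibration (all four
tests within the 99 % binomial band of the 5 % level at 2000 null
replicates) rather than on df formulas. The Wilcoxon signed-rank test
drops zeros, mid-ranks ties, enumerates exactly for n ≤ 25 without ties
and otherwise uses the tie-corrected normal approximation without
continuity correction. The sample-size rule is the Fisher-z inversion
n = ⌈((z_{1−α/2} + z_power)/atanh√R²)² + 3⌉.

## Synthetic MEP cohorts

The generator encodes the structure the analysis assumes. Per-subject
field strengths are truncated-normal (0.39 ± 0.12 V/m on [0.20, 0.60]).
The expected normalized MEP is `1.17 + slope_s · (E_n − m)/m +
baseline_slope · (MEP_base − 0.66) + u_i` with slope −0.72 for real
stimulation, 0 for sham, m the cohort sample mean, and u_i a shared
subject intercept; amplitudes are expectation × baseline × mean-one
lognormal noise per time point (switchable to additive Gaussian for
sensitivity checks). Baselines are lognormal matched to 0.66 ± 0.26 mV,
drawn independently per session; the RMT is generated with correlation
−0.64 to the field strength. The baseline-dependence term (default
−0.5 per mV) reproduces the normalization artefact by which high-baseline
subjects show smaller normalized responses in *both* sessions. Time points
share one expectation (no time trend by default).

Noise calibration (done once, then frozen): the truncated field draw gives
a dose-signal SD of 0.176 on the session-mean normalized MEP, so a subject
intercept SD of 0.13, per-time noise CV of 0.21 and the baseline slope
together yield a between-subject residual SD ≈ 0.22 and hence a
field–response Pearson correlation near −0.63 at n = 27 — the regime the
analysis chain is meant to operate in. Under these defaults, 500-replicate
recovery experiments give a median fitted slope ≈ −0.72 (unbiased), 95 %
CI coverage ≈ 95 %, sham slopes centred on zero, and a negative,
LRT-significant session-by-field interaction in ≈ 99 % of replicates.

What the generator does *not* emulate: real gyral geometry and field
orientation structure (the phantom's E_n pattern is smooth and
anode-centred), intra-subject session-to-session field changes,
non-linearities in the dose–response, and trial-level MEP variability
(only time-point-level noise is drawn). Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
validity of the linear law for real cohorts.

## Pipeline

`run_pipeline` chains phantom cohort → per-subject solve → cortical maps →
MEP synthesis (the response is driven by the extracted E_n at the
peak-mean-field vertex, so region discovery has a ground-truth answer) →
PLS ladder (both field types × r_E 1/2/3/10 % × real and sham responses) →
VIP/r0 → mixed models. One master seed spawns named per-stage substreams;
identical configs give byte-identical serialized bundles (full-precision
CSV/JSON plus a SHA-256 manifest). Default problem sizes in tests and the
acceptance script (27 subjects at 3 mm voxels, 642-vertex template, 500
recovery replicates, 2000 calibration replicates, 200 Monte-Carlo
cross-validation datasets at 50 repetitions) were chosen to keep a full
run in minutes on one CPU while leaving Monte-Carlo error well below the
effects being checked.
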