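# Methods

## Problem setting

The package solves the MCG inverse problem: given the magnetic field
sampled at a planar magnetometer array, estimate the epicardial potential
distribution that produced it. Sources are scalar potentials `s_q(t)` (mV)
attached to unit current dipoles at the nodes of a closed triangulated
ventricular surface, oriented along the outward normals. The forward map is
linear, `B = L s`, with the Biot–Savart lead field

    L(m, q, :) = (μ₀/4π) · (r_m − r'_q)/‖r_m − r'_q‖³ × â_q · unit_scale .

The cross product is taken in exactly this operand order; it is the
negative of the textbook dipole form `â × r / r³`. The sign is a pure
convention — it flips every lead-field entry and every measurement
consistently, so all inverse solutions are unchanged.

### Units

Geometry is in centimetres, sources in millivolts, fields in picotesla.
`μ₀/4π` is kept at its symbolic SI value 1e-7 and a single explicit
constant `unit_scale` (default 1e9, stored with every `LeadField`) converts
the mV·cm⁻² products to pT. The default places a few-mV source at 10–20 cm
in the tens-of-pT range typical of MCG. Volume currents and tissue
conductivities are deliberately outside the model: the forward field is the
primary-current field only, which is also why a spatially uniform potential
over the closed surface is *exactly* magnetically silent (a closed uniform
dipole layer produces no external field). The mean potential level is
therefore unidentifiable from the data; reconstruction quality is carried
by the spatially structured part of the sources.

## Synthetic geometry

Heart surfaces are triaxial ellipsoids (default semi-axes 4 × 3.5 × 5 cm,
the scale of a human ventricular epicardium). Nodes are a Fibonacci lattice
on the unit sphere — rotated by a seeded random rotation so meshes with
different seeds are never index-aligned — scaled onto the ellipsoid and
triangulated through the convex hull of the unit directions. This
guarantees a closed, orientable, genus-0 surface with an exact node count;
an icosahedron-subdivision route was rejected because decimation to an
arbitrary node count cannot make those guarantees. Ellipsoid normals are
analytic; remeshed or imported surfaces use angle-weighted face normals.

`remesh_perturb` recovers the smooth surface underlying a mesh by a
least-squares quadric fit (exact for generated ellipsoids), samples a fresh
lattice at the requested resolution, and can bend the radius by a smooth
low-order spherical-harmonic field bounded by `perturb_scale ×` mean
semi-axis. The default two-model protocol remeshes *without* shape
perturbation: model 2 is the same surface at a different discretization,
which is what breaks the inverse crime.

The detector array is a 9 × 9 planar grid with 3 cm spacing (M = 81),
centred 10 cm above the heart centre along +z. The heart-to-plane distance
is an explicit configuration parameter rather than an anatomical claim.

## Source waveforms

No closed-form epicardial waveform is standard, so each node carries a
parametric action-potential surrogate: resting level → fast depolarization
(cubic smoothstep over `depol_rise`) → plateau → smooth repolarization.
Defaults (resting −0.5 mV, plateau 4.0 mV, depolarization onset 30 ms, rise
10 ms, plateau 70 ms, repolarization 80 ms, T_total 250 ms) put the
mid-ST analysis instant t = 85 ms in the plateau and t = 125 ms in
repolarization, and keep amplitudes in the few-mV range of epicardial
potential maps. Activation spreads from the apex (lowest-z node) with a
delay of `delay_scale` = 8 ms/cm of Euclidean distance, emulating the tens
of milliseconds an activation sequence needs to cross the epicardium. The
delay matters: without it every node sits on the plateau at 85 ms, the
source map is spatially constant, and — by the silent-layer argument above
— the forward field carries no information at all.

Infarction scenarios modify a circular patch (Euclidean distance from a
centre node, default radius 1.5 cm; geodesic distance was rejected as
needless for a patch small relative to surface curvature):

* `st_elevated` multiplies each patch node's deviation from rest by
  `amplitude_factor` (default 0.52, i.e. a 48 % reduction);
* `increased_t` rescales the repolarization duration by
  `repol_shortening_factor` (default 0.6, configurable — only the
  direction, "shortened", is anatomically constrained).

Nodes outside the patch are bit-identical to the normal simulation, a
property the tests check by exhaustive distance scan.

## Noise model

Additive i.i.d. Gaussian noise calibrated to a requested SNR: with signal
power `P_s` the mean squared field over all channels and samples, the noise
standard deviation is `P_n = sqrt(P_s / 10^(SNR/10))`, so the realized
`10·log₁₀(P_s/P_n²)` matches the request in expectation (within 0.01 dB at
81 × 10⁴ samples). The noise-free condition is an explicit sentinel that
bypasses noise injection, not an SNR of ∞ fed to the formula.

## Inverse solvers

All three solvers operate on the component-major flattened design matrix
(3M × Q; all x-rows, then y, then z) and treat time instants as independent
targets, consistent with priors that are i.i.d. across time. A single
eigendecomposition of `AᵀA` per fit is shared across instants and, for the
iterative solvers, across iterations. A configuration switch restricts the
inversion to one Cartesian component (M × Q) for map-style studies.

**Tikhonov.** `(AᵀA + λI)s = Aᵀb` via a Cholesky solve; the λ sweep reuses
one SVD. The residual is `b − Aŝ`: the noise term of the data model is not
observable and cannot be subtracted. The L-curve uses the default
grid (100 linearly spaced λ on [1e-10, 10]; logarithmic spacing optional)
and picks the corner as the maximum signed Menger curvature of the log–log
polyline, ties toward smaller λ. A curve with no appreciable curvature
(e.g. noise-free data) is flagged `distinct=False` rather than silently
trusted.

**Evidence approximation.** Updates use the doubled-precision forms
`α ← γ/(2‖s‖²)`, `β ← (M−γ)/(2‖res‖²)` with `γ = Σ λᵢ/(λᵢ+α)` summed over
the eigenvalues of `βAᵀA` (the summation sign is restored; the per-term
form alone is dimensionless in the wrong way). These carry a factor 2
against the classical MacKay updates; they are exact stationarity
conditions of the evidence when the quadratic exponent is written without
its ½ factors, and since both α and β scale by the same ½ the ratio α/β —
hence the estimate — is identical under either convention. A
`convention="mackay"` switch exposes the classical forms. Hyperparameters
are clipped to [1e-12, 1e15] (noise-free runs legitimately drive β to the
top of this range); five consecutive iterations at a cap flag the run
diverged instead of raising. The stop rule is `max(|Δα|, |Δβ|) < 1e-3`.
Initialization α₀ = β₀ = 1 and all trajectories are recorded. In the 1-D
single-observation toy the evidence is maximal along the whole ridge
`1/α + 1/β = 2`; the tests therefore compare attained evidence values, not
coordinates.

**Variational Bayes.** The model is `B|s,β ~ N(As, β⁻¹I)`,
`s,β|α ~ N(0,(βα)⁻¹I)·Gam(β|a₀,b₀)`, `α ~ Gam(c₀,d₀)`, with mean-field
factorization `q(s,β)q(α)`. Because the prior on `s` scales with β, the
(s, β) block stays jointly conjugate and its optimal factor is the coupled
normal-inverse-gamma

    q(s,β) = N(s | ŝ, β⁻¹Ĉ) Gam(β | â, b̂),
    Ĉ = (E[α]I + AᵀA)⁻¹,  ŝ = ĈAᵀb,
    â = a₀ + M/2,         b̂ = b₀ + ½(‖b − Aŝ‖² + E[α]ŝᵀŝ),
    q(α) = Gam(ĉ, d̂),     ĉ = c₀ + Q/2,  d̂ = d₀ + ½(E[β]ŝᵀŝ + tr Ĉ).

The Gaussian factor absorbs β^{Q/2}, which is why the Gamma shape gains
M/2, not (M+Q)/2; with this shape, b̂ is exactly ELBO-optimal and the
coordinate ascent is provably monotone (the suite checks 100 random
fixtures at 1e-8 absolute tolerance, and with α pinned the fitted q(s,β)
reproduces the exact conjugate posterior measured by 2-D quadrature).
`E[α] = ĉ/d̂` is the effective ridge parameter. Stopping: relative ELBO
change below 0.001 % (1e-5). Defaults a₀ = b₀ = c₀ = d₀ = 1e-6
(broad); the residual inside the ELBO is evaluated directly as `‖b − Aŝ‖`
because the expanded quadratic identity loses ~8 digits to cancellation at
large data scales.

## Evaluation and the two-mesh protocol

Spatial RMSE `sqrt(Σ_q (s_q − ŝ_q)²/Q)` at named instants, temporal RMSE
per node, and Pearson correlation both spatially (per instant) and
temporally (at a focus node near the lesion). Truth and estimate live on
different meshes; the truth is transported onto the estimate's nodes
through a Euclidean nearest-node map (transporting the smooth truth incurs
less mapping error than transporting a noisy estimate; ties break to the
lowest index). Constant series yield a NaN correlation sentinel, reported
as missing rather than coerced to zero.

`run_experiment` wires the full protocol: simulate on model 1, invert
through model 2, sweep SNR (default 6–16 dB plus noise-free), replicate
each noisy condition (default 20 seeds, derived deterministically from the
cell indices), and record per-cell metrics plus hyperparameter summaries
(λ; α, β and α/β; E[α], E[β·sᵀs], final ELBO). Failures are isolated per
cell with a machine-readable reason. Reports serialize to TSV/JSON with a
config hash.

## Problem sizes

The packaged study runs at three scales: `tiny` (24/40 nodes, 3 × 3 grid,
seconds — smoke tests), `small` (60/100 nodes, M = 81, T = 50 — the scale
at which the test suite and the acceptance script replicate the protocol),
and `full` (257/585 nodes, M = 81, T = 250). The solver comparisons
reported by the acceptance script use the `small` scale with 20 noise
replicates at 6 dB; at this scale the 1.5 cm lesion patch contains a single
node (internode spacing ≈ 2 cm), so the ST feature is carried mostly by
the activation wavefront, while at 257 nodes the patch spans ~10 nodes.

## What the generator does and does not emulate

The synthetic data reproduce the *structure* of the study — closed
ventricular surface, normal-dipole sources, activation spread, localized
infarct morphologies, planar MCG sampling, SNR-controlled noise — but not
real electrophysiology: there is no transmembrane-potential model, no
volume conductor, no torso, no respiratory or baseline artefacts, and the
activation sequence is a radial delay field rather than a conduction
simulation. Passing tests therefore demonstrate the correctness and
relative behaviour of the inverse machinery under controlled conditions,
not clinical reconstruction accuracy. Published per-study numbers (L-curve
corner values, absolute RMSE tables, hyperparameter magnitudes) depend on
proprietary anatomical meshes and unseeded noise draws and are not
reproduction targets; the replicated solver *ordering* (VBLR ≤ evidence ≤
Tikhonov in mean spatial RMSE at 6 dB) is.

## Numerical choices and edge cases

* Eigendecompositions clip eigenvalues at 0 (AᵀA is PSD up to roundoff).
* `update_alpha`/`update_beta` cap instead of dividing by zero when the
  solution norm or residual vanishes, with a warning.
* The L-curve corner on fewer than 5 points is refused; log norms are
  floored at 1e-300 before taking logs.
* Lesion patches always contain their centre node; a radius that captures
  only the centre warns but proceeds.
* PLY I/O is ASCII-only and rejects non-triangular faces and malformed
  headers with the offending line number; normals are recomputed (and
  normalized) when absent.
* All generation is deterministic given seeds; noise seeds are derived
  per (scenario, SNR, replicate) cell.

## Known limitations

* Nearest-node transport is first-order; a barycentric interpolation would
  reduce cross-mesh scoring error at coarse resolutions.
* The mean potential level is unobservable (silent uniform layer), so
  absolute-level errors are irreducible for any solver in this forward
  model.
* Per-instant independent inversion ignores temporal smoothness; a
  spatiotemporal prior is out of scope.
* The single scalar α is not sparsity-inducing; per-coefficient relevance
  determination is deliberately excluded.
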