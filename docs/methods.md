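# Methods

`pbrecgi` implements potential-based electrocardiographic imaging (ECGI) on
synthetic torso–heart phantoms: given body-surface potentials Φ_B(t) and a
transfer matrix A for the volume conductor between the epicardium and the
body surface, it estimates the epicardial potentials Φ_H(t) in the forward
relation Φ_B(t) = A·Φ_H(t). Two regularization strategies are implemented —
classical Tikhonov regularization, and a physiology-based strategy that
expresses the solution as a sparse combination of spatial basis vectors
obtained from the SVD of simulated propagating action potentials (APs).
This note records the models, the numerical choices and their rationale,
and what the synthetic phantom does and does not emulate.

## Forward model

**Geometry.** The phantom is a closed spherical epicardium (default radius
40 mm, ≈400 vertices in the benchmark; up to ≈1700 matching clinical mesh
densities) inside a spherical or ellipsoidal torso (default 120 mm,
700–1000 vertices), with 200 body-surface electrodes placed on a
golden-angle spiral (the clinical setups this emulates use 184–216).
Concentric spheres are used deliberately: the Laplace problem in a
spherical annulus with zero outer flux has a closed-form solution, giving
an independent oracle for the numerical transfer matrix. A degree-l surface
harmonic prescribed on the inner sphere appears on the outer sphere
attenuated by (2l+1)·a^(l+1)·b^l / ((l+1)·a^(2l+1) + l·b^(2l+1)).

**Boundary-element transfer matrix.** The region between the surfaces is a
source-free homogeneous conductor with an insulated body surface. Green's
representation theorem is collocated at the surface vertices with
piecewise-constant densities on barycentric dual areas. The singular
double-layer diagonal is fixed by the row-sum identity (the discrete free
term absorbs the solid angle), which makes "constant in → constant out"
exact by construction; consequently every row of A sums to 1 up to solver
rounding, and this is asserted at 1e-3. The singular single-layer diagonal
uses the exact integral over an equal-area flat disk, R_eq/2. With
Dirichlet data on the heart surface the mixed boundary-value problem is
well-posed, so the block system (unknowns: body-surface potentials and the
epicardial normal derivative) is solved directly without deflation.
Accuracy against the analytic oracle is ≈1% relative L2 for degree-1/2
harmonics at the benchmark mesh density and improves monotonically with
refinement. Electrode values are read at the nearest torso vertex,
consistent with the nearest-node pairing used in the evaluation.

**Sensor noise.** Gaussian noise is added per electrode, scaled to a
requested SNR (power ratio of the centered clean signal to the noise, in
dB). The benchmark default is 30 dB, a typical figure for filtered
body-surface maps; a 20–40 dB sensitivity sweep is provided
(`benchmark.snr_sweep`).

## Propagation model

Each mesh vertex carries a single-cell AP model; vertices joined by a
triangulation edge exchange current I = g·(V_j − V_i) with g = ḡ/d², d the
edge length. Conduction is isotropic and homogeneous. A beat is initiated
by a 2-ms current injection at an origin vertex and its 1-ring (single-
vertex stimuli fail to capture on coarse meshes).

**FitzHugh–Nagumo (default).** dv/dt = (v − v³/3 − w + I)/τ_v,
dw/dt = ε(v + β₀ − γw)/τ_w with the classic ε = 0.08, β₀ = 0.7, γ = 0.8 and
separate time constants τ_v = 1.5 ms and τ_w = 25 ms. The split matters on
coarse meshes: the upstroke duration (set by τ_v) must be comparable to the
per-edge conduction delay or wavefronts either fail to capture or cross the
whole surface too fast, while the AP duration (set by τ_w, ≈200 ms here,
canine-like) must exceed the total activation spread so that the surface is
fully activated before recovery begins — the chronological sequence
"activation front → fully activated → recovery wave → fully recovered"
within the 550-sample beat. The dimensionless output is mapped affinely so
the resting state is exactly −80 mV and the nominal spike peak (+2.0 in
model units) is +20 mV; the exact resting offset makes the first SVD
component of any simulated ensemble a near-constant pattern that can be
dropped cleanly.

**Luo–Rudy 1991.** The eight-variable guinea-pig ventricular model (fast
Na⁺, slow inward Ca²⁺, time-dependent/independent K⁺, plateau and
background currents) in native mV/ms units. Gates are advanced by
Rush–Larsen exponential updates (the m-gate time constant is ~6 µs at rest,
far below any practical Euler step); V and Ca_i by forward Euler at 0.02 ms
internal steps. The resting state is computed once by settling plus a root
solve and cached; it is an equilibrium to < 1e-6 and lies at −84.6 mV.

**Integration and calibration.** Output is sampled at dt = 1 ms with
internal substeps (10 for FHN); halving the internal step changes
activation times by at most one sample. ḡ is calibrated by log-space
bisection so the last-minus-first activation time (threshold crossing at
−40 mV) of a paced beat lies in 60–100 ms, a physiological total
ventricular activation time; the spread is monotone decreasing in ḡ over
the bracket.

**Regions and origins.** The sphere is partitioned by a base–apex axis:
top 20% and bottom 10% of the axis coordinate form a basal/apical cap
(no pacing there in the emulated experiments), and the remaining band is
split into two longitudinal sectors standing in for the LV and RV free
walls. Beat origins are sampled pseudo-randomly within a region under a
minimum pairwise spacing (8 mm default, relaxed geometrically with a
warning when infeasible), giving the roughly uniform coverage the method
needs; 25 origins per region by default (a desk-scaled version of the
50 per region used at full scale).

## Basis construction

All simulated beats are concatenated into one matrix (nodes × beats·steps)
and decomposed by thin SVD with singular values in non-increasing order.
For strongly rectangular ensembles (columns ≥ 10× rows) the decomposition
goes through the smaller Gram matrix, accurate for the leading components
that are retained; otherwise LAPACK's thin SVD is used directly. Each
spatial component's sign is fixed so its largest-magnitude entry is
positive, making outputs reproducible across linear-algebra backends.
Components 2–10 (1-based, inclusive) form the default 9-vector basis;
component 1 is the resting-offset pattern and is dropped because
electrograms are reconstructed zero-referenced. Dropping it remains a
configuration choice for cell models without a fixed offset.

## Inverse solvers

Body potentials are re-referenced to zero mean across electrodes per
instant before inversion (a spatially constant potential is unobservable:
A maps constants to constants); a flag disables this.

**Tikhonov.** min ‖AΦ_H − Φ_B‖² + λ‖RΦ_H‖², solved by Cholesky on the
normal equations; λ multiplies the squared seminorm. R is the identity
(order 0), edge differences scaled by 1/length (order 1) or the umbrella
graph Laplacian (order 2); orders 1–2 annihilate constants exactly. λ(t) is
selected per instant on a 40-point log grid spanning [1e-8, 1e2]·σ₁(A)² by
the L-curve criterion. Corner detection: the maximum of the signed
curvature of (log residual, log seminorm) when a distinct corner exists
(curvature is scale-free in log-log coordinates; a genuine corner has
curvature of order one, and 0.2 is used as the floor); when no distinct
corner exists — noise-only instants during electrical quiescence, or
noiseless consistent data — the selector falls back to the minimum-product
(Regińska) point, which degrades gracefully to heavy regularization on
noise and light regularization on consistent data. A naive smallest-λ
fallback at quiet instants produces solutions with norms ~10⁴ larger than
the signal and destroys whole-beat correlations. For order 0 the entire
series is solved through SVD filter factors, identical to the per-instant
path but without per-weight solves.

**Sparse basis reconstruction.** min ‖AU_kβ − Φ_B(t)‖² s.t. ‖β‖₁ ≤ λ(t),
independently per instant. The budget-form problem is solved on the
LARS/lasso homotopy path (piecewise linear in the coefficients, so the
budget solution is an exact interpolation between knots) and polished by
accelerated projected gradient onto the L1 ball, which also resolves
degenerate designs with exactly tied columns where one-at-a-time LARS is
ambiguous (the polished solution is the symmetric optimum). λ(t) is chosen
by K-fold (default 5) cross-validation across electrodes on a log grid of
budgets up to the least-squares L1 norm, minimizing held-out mean squared
error with ties towards the smallest budget; the resampling scheme is this
package's choice — the underlying method description only asks for the
MSE-minimizing parameter.

## Post-processing

Activation is the steepest QRS deflection and recovery the steepest
opposite T-wave deflection, by forward differences with the time assigned
to the earlier sample (temporal criterion), or by the arg-extremum over the
window of ‖DΦ_H(t)‖₂·∂Φ_H/∂t per node (spatiotemporal criterion), where
DΦ_H is the per-triangle linear-interpolation surface gradient averaged
onto vertices by area weights (constants annihilate exactly). The printed
form of the spatiotemporal criterion is read as an arg-min/arg-max over
time — the extremum of the product marks the wavefront passage, and only
this reading yields a time. Nodes whose spatial gradient never exceeds
1e-6 of the global maximum fall back to the temporal criterion, flagged.
The spatiotemporal recovery criterion mirrors activation with the opposite
slope sign; this mirroring is this package's construction.

**Polarity.** On extracellular electrograms activation is a *downslope*;
on AP-like signals (this phantom's ground truth) it is an *upstroke*. All
timing functions take `polarity` ('egm' | 'ap'); the benchmark uses 'ap'
consistently for truth and reconstructions, while 'egm' is the default in
the public API, matching clinical convention.

**Windows.** QRS and T analysis windows are estimated from the RMS over
nodes of the spatially centered potentials: near zero while the surface is
uniformly polarized, elevated during activation and recovery wavefronts.
Sustained (≥5 ms) crossings of 10% of peak give the two windows; manual
override is available and is used whenever windows are known.

**Timing smoothing.** The benchmark applies a 9-ms Savitzky–Golay filter
(order 3) along time before derivative detection. At 1-ms sampling and
30 dB noise, raw forward differences are dominated by sample-to-sample
noise (timing correlations ≈0.5); the mild smoothing recovers R ≈ 0.95
without shifting clean-signal timings by more than a sample. Unsmoothed
detection remains the API default.

**Localization.** The beat origin is the vertex with the earliest
activation time (ties to the lowest index); localization error is the
Euclidean distance to the true pacing site (geodesic distance is
available).

## Benchmark design and scale

The default benchmark (`ExperimentConfig()`): 400-node heart in a 700-node
torso, 200 electrodes, FHN model, 25 origins per region (LV, RV,
base/apex), component range 2–10, 5 held-out test beats paced alternately
from LV and RV at origins disjoint from every basis origin, 30 dB SNR.
"Recorded" electrograms are the ground-truth simulated potentials at ≈73
mesh nodes matched to two circumferential bands of 99 sites plus 4 apical
sites, emulating epicardial sock electrodes. Reported metrics: Pearson CC
per site pooled over beats, timing correlations R_act/R_rec per beat for
both criteria, localization error per beat, and Wilcoxon signed-rank
p-values of the paired CC comparison against Tikhonov. Every random choice
derives from one seed through named child seeds, so repeated runs are
bitwise identical. These problem sizes keep a full run in a few minutes on
one core; sensitivity sweeps reuse the run's artifacts (basis-beat count:
1–50 beats; basis size: components 2–5 to 2–25; SNR 20–40 dB). The
beat-count sweep draws its subsets region-stratified (shuffled within
regions, then interleaved) so that any prefix keeps whole-surface coverage;
an unstratified random subset of, say, 6 beats can land mostly in one
region and then measures coverage loss rather than beat-count saturation.

## What the phantom shows — and what it cannot

The synthetic benchmark validates the machinery end to end: the sparse
basis reconstruction is accurate (median CC ≈ 0.87 at 30 dB), is markedly
less noise-sensitive than Tikhonov (CC drop of ≈0.03 vs ≈0.09 from
noiseless to 30 dB), and saturates once ≈6 distinct simulated beats feed
the basis. Its robustness also shows in the timing maps: with raw
(unsmoothed) temporal detection, recovery-time correlations from sparse
reconstructions degrade far less under noise than from Tikhonov ones
(R_rec ≈ 0.75 vs ≈ 0.5); with the default 9-ms smoothing both recover to
R ≈ 0.95 on this clean phantom.

Two caveats follow from the phantom's idealizations. First, the transfer
matrix used for inversion is exactly the one that generated the data; real
ECGI suffers segmentation and electrode-registration error that degrades
unconstrained solutions far more than subspace-constrained ones, so the
relative standing of the Tikhonov baseline here is a best case: on this
phantom its median CC (≈0.89 at 30 dB) slightly exceeds the sparse
method's, whose accuracy is capped by the projection of the true pattern
onto the 9-component basis (in-span ceiling ≈0.86–0.90; the solver
operates essentially at that ceiling). Second, the ground truth consists
of simulated APs from the same model family as the basis — morphology
mismatch between cellular APs and extracellular electrograms, a recognized
limitation of the approach on real data, is absent here. Results on this
phantom therefore demonstrate correctness and noise robustness of the
pipeline, not clinical accuracy.

## Known limitations

Homogeneous isotropic conduction only; no anisotropy, infarct or septal
sources; single-beat records (no beat averaging or fractionation indices);
the torso is a single homogeneous compartment (no lungs/bone); the LR92
model is supported throughout but the benchmark default is FHN — LR92 mesh
runs cost ~5× more through the stiff-gate substepping.
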