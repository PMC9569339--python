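# Methods

## Model

`netdim` is built around the S^D geometric soft configuration model.
Each of N nodes carries a hidden degree κ_i > 0 and a position v_i on the
D-sphere (embedded in D+1 dimensions) of radius
R = [N Γ((D+1)/2) / (2 π^((D+1)/2))]^(1/D), chosen so node density is 1.
Pairs connect independently with the Fermi-Dirac (gravity-law) probability

    p_ij = 1 / (1 + chi_ij^beta),    chi_ij = R Δθ_ij / (mu κ_i κ_j)^(1/D).

β > D calibrates the topology-geometry coupling (clustering); β = ∞ is a
first-class value: the law becomes a step at chi = 1 and
μ → Γ(D/2+1)/(π^(D/2) ⟨k⟩). For finite β,
μ = β Γ(D/2) sin(Dπ/β) / (2 π^(1+D/2) ⟨k⟩). κ equals the node's expected
degree in the thermodynamic limit; hidden degrees are sampled from a
Pareto density ρ(κ) = (γ−1) κ₀^(γ−1) κ^(−γ) with
κ₀ = ⟨k⟩(γ−2)/(γ−1), so the distribution mean equals the target mean
degree. The cutoff is a modelling choice (any density with the same mean
and tail exponent would do); the closed form keeps it parameter-free.

Positions are uniform on the sphere via normalized isotropic Gaussians.
Uniformity follows from rotation invariance and is KS-tested.

### Mean-degree refinement

The closed-form μ is exact only in the thermodynamic limit. When a
generated network must hit the target mean degree (the experiment
drivers; ⟨k⟩ = 10.0 ± 0.1 in the sweeps), `refine_mu` root-finds μ on the
exact finite-size expectation

    E⟨k⟩ = (2/N) · [Γ((D+1)/2)/(√π Γ(D/2))] Σ_{i<j} ∫₀^π sin^(D−1)θ p(θ; κ_i κ_j) dθ,

evaluated with hidden degrees log-binned into 600 bins (bin means
preserved; error ~1e-5 on ⟨k⟩) and Brent's method on log μ to an
effective tolerance of 0.01 on ⟨k⟩. Surrogate generation inside the
inference pipeline does not refine μ: there the hidden-degree fixed point
(below) absorbs any finite-size offset.

## Chordless-cycle census

For an edge (i, j) with degrees k_i, k_j and T_ij = |N(i) ∩ N(j)|
triangles, define the exclusive side pools A = N(i) \ (N(j) ∪ {j}),
B = N(j) \ (N(i) ∪ {i}). The per-edge densities are

* triangles: T_ij / (min(k_i, k_j) − 1);
* chordless squares: the number of edges between A and B — each chordless
  square i-a-b-j is exactly one such (a, b) pair — over
  m_s = (k_i−1−T_ij)(k_j−1−T_ij);
* chordless pentagons: among side pairs (a, b) not already consumed by
  triangles or squares, the number joined by an admissible 2-path a-c-b
  (c adjacent to neither i nor j), over
  m_p = (k_i−1−T_ij−s_i)(k_j−1−T_ij−s_j), where s_i, s_j count the side
  neighbours matched in squares.

The pentagon numerator is *pair participation*, not the raw 5-cycle
count: many pentagons can share one (a, b) pair, so the raw count has no
degree-determined maximum (on model graphs it exceeds the pool on ~half
the edges), whereas pair participation is bounded by m_p by construction
and keeps all densities in [0, 1]. The raw count remains available as
`edge_chordless_pentagon_count` and is what the exhaustive-enumeration
tests check. Averages run over edges with both endpoint degrees > 1 and a
positive denominator; zero-denominator edges are excluded rather than
counted as zero. Mean local node clustering C averages the standard local
coefficient over nodes of degree ≥ 2. Cycles longer than pentagons are
not used: in small-world graphs their chordless frequency is negligible.

Two compiled kernels produce identical counts (cross-checked in tests):
a per-node adjacency-bitset kernel (popcount word arithmetic; used for
n ≤ 32768) and a mark-array kernel for larger graphs where the n²-bit
table would not fit comfortably in memory.

## Hidden-degree inference

To generate surrogates with the degree structure of an observed graph,
hidden degrees are found per observed degree class so that the model
expected degree matches the class degree:

    kbar(κ) = [Γ((D+1)/2)/(√π Γ(D/2))] Σ_{classes c} n'_c ∫₀^π sin^(D−1)θ dθ / (1 + (Rθ/(μ κ κ_c)^(1/D))^β)

with n'_c the class multiplicity (own class minus one), and μ computed
from the observed mean degree. Starting from κ = k, classes are updated by
κ ← |κ + (k − kbar(κ)) u| with u ~ U(0,1) per class per iteration (the
noise prevents limit cycles), until ε_max = max |kbar − k| ≤ 1, tracking
the best iterate. Defaults: tolerance 1, max_iter 200. Non-convergence
warns and returns the best iterate rather than raising: at high D the
expected degree responds only weakly to κ and a cold start can need
slightly more than 200 iterations, which is why the ensemble builder
warm-starts each dimension from the neighbouring dimension's solution and
each β from the previous β. The angular integral is evaluated by 64-node
Gauss-Legendre quadrature split at the Fermi angle θ* = (μκκ')^(1/D)/R
(for β = ∞ it reduces to the incomplete sin^(D−1) integral, computed via
the regularized incomplete beta function); iterative callers use a cached
log-grid interpolator rebuilt only when the κ range outgrows it.

## Calibrating the inverse-temperature range

Surrogates should cover a clustering window (C_t* − 0.1, C_t* + 0.1)
around the observed edge-triangle density. A sample of 20 S^1 surrogates
with degree-matched hidden degrees, at β stratified-uniform over (1, 15),
is fitted with C_t(β) = C_max(1 − e^{−a(β−β₀)}); stratification keeps the
marginal distribution uniform while guaranteeing the steep low-β region is
anchored — with i.i.d. draws that region is usually unsampled and the
inverted map misplaces mid-window betas by ~0.1 in C_t. Window values ξ
map to β(ξ, D) = D[β₀ − ln(1 − ξ/C_max)/a], using the empirical scaling
C_t^D(β/D)/C_t,max^D ≈ C_t^1(β)/C_t,max^1 (verified in tests to collapse
within 0.05 RMS for D ≤ 3); betas are clipped below at D + 0.25, the
window is truncated to (0, C_max), and a dimension is skipped only when
the whole window is unreachable. 50 surrogates per dimension by default.
If the fit fails or cannot reach the observed clustering, the β sample is
widened once to (1, 30).

The candidate-dimension ceiling is the largest D (capped at 12) whose
zero-temperature surrogates, with hidden degrees re-inferred per D, reach
the observed C_t (10 realizations per D; the scan stops at the first
failure). If even D = 1 fails, the graph's clustering is anomalous for the
model and the pipeline reports D* = 1 with a flag — likewise for graphs
with no triangles at all.

## Classification

Surrogates live in the phase space (C_t, C_s, C_p). The query graph is
assigned the dimension maximizing f(D) = Σ_i ω_i δ(D_i, D) over its K
nearest surrogates by Euclidean distance, ω_i ∝ 1/d_i normalized to one;
coincident surrogates (d = 0) absorb all weight; argmax ties resolve to
the smallest D. K is selected from {1, 3, …, 25} (capped at ensemble
size) by leave-one-out accuracy over the surrogate ensemble, smallest K
on ties; the LOO accuracy at the chosen K is reported as the resolution
of the estimate. The vote is scikit-learn's distance-weighted
KNeighborsClassifier; tests recompute f(D), the K choice and the LOO
accuracy with independent brute-force implementations. LOO (rather than a
held-out split) is used because the ensemble is cheap to regenerate and
LOO is deterministic.

## Synthetic benchmarks and what they show

`attainable_ct_sweep` reproduces the zero-temperature clustering-versus-
dimension curves (N = 1000, ⟨k⟩ = 10, 10–20 realizations per cell): the
largest D keeping C_t ≥ 0.5 comes out 6–7 at γ = 2.5 and 5 at γ = 3.0,
the practical ceiling on detectable dimensionality at realistic clustering
levels. `evaluate_confusion` generates model networks of known dimension —
β drawn by sampling a C_t interval for the chosen clustering regime
(per-γ intervals for high/low clustering) and mapping it through the
calibration fit — and runs the full pipeline on each; in the high-clustering regime the
row-normalized (D, D*) matrix concentrates on and immediately below the
diagonal (see the fidelity limit below), with confusion spreading over
adjacent dimensions as clustering weakens.

These experiments exercise the generator's own universe, and they expose
the main accuracy limit of the degree-matching step. The per-class fixed
point solves kbar(κ) = k for the *realized* degree k of each class, with
no shrinkage toward the bulk, so the inferred κ distribution inherits the
degree-sampling noise on top of the true κ spread (at N = 1000, γ = 2.7
the κ standard deviation grows from ~12 to ~14). Effectively the
surrogates are slightly more heterogeneous than the generating law: at
identical (D, β, degree sequence) they show C_t higher by ~0.02 and C_p
lower by ~0.03 than fresh model networks, offsets that persist when
low-degree edges are excluded. The β window re-centres C_t, but the query
then sits ~0.02 above every surrogate cloud in C_p — comparable to the
separation between adjacent dimensions at this size — so a fraction of
votes leak to D − 1, most visibly for true D = 2 (D = 1 has no lower
neighbour to leak to). This bounds the confusion-matrix diagonal at
N = 1000 and is a property of the published estimator, not of a tunable
parameter; larger networks tighten the clouds and enlarge the
inter-dimension gaps. Passing tests therefore demonstrate
self-consistency of the pipeline on model graphs; on real data the model
is additionally an approximation (no community structure, no
degree-degree correlations, statistically independent edges).

## Problem sizes

The test suite and the acceptance script run everything at N = 1000
(sweeps with 10–20 realizations per cell, confusion matrices with 10 test
networks per dimension, ensembles of 50 surrogates per dimension), the
size at which the phase-space curves are already well separated; larger
networks only sharpen the statistics.

## Degenerate inputs and conventions

Isolated nodes are dropped (with a warning) before inference; node labels
are mapped to consecutive integers internally and the mapping is kept in
the graph attributes. Input edge lists are cleaned of self-loops and
duplicate edges, with counts logged. Reports are JSON with every seed and
parameter recorded; rerunning a pipeline with the same seed reproduces the
report byte for byte.
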