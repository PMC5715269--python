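# Methods

This note documents the models, conventions and design choices behind
`wmnet`, in the order the pipeline runs them.

## Diffusion model and tensor estimation

Each voxel is modelled as a single Gaussian diffusion compartment: the
signal under gradient direction `g` (unit norm) and weighting `b` (s/mm²)
is `S = S0·exp(−b·gᵀDg)` with `D` a symmetric 3×3 tensor (mm²/s).  Taking
logs linearises the model in `[log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]`, and
the fit is ordinary linear least squares per voxel.  At least six
non-collinear weighted directions plus one b = 0 image are required; the
default scheme is 64 Fibonacci-sphere directions at b = 1000 s/mm², a
common clinical single-shell setup.  Noiseless synthesis followed by the
fit recovers the tensor to machine precision (asserted at 1e-8 relative).
Single-voxel fits reject non-positive signals; the whole-field fit clips
them to a small floor (1e-6) instead, since additive noise can push a
near-zero true signal below zero — set `signal_floor=None` to keep the
strict behaviour.

FA is the standard eigenvalue dispersion measure
`√(3/2)·‖λ−λ̄‖/‖λ‖`, clamped to [0, 1], defined as 0 for an all-zero
tensor.  It is scale-invariant, which the test suite asserts as a
property.

## Tractography conventions

FACT-style deterministic tracking with these documented defaults (the
method family fixes the termination rules — FA ≤ 0.2 or turning angle
> 45° — but not the numerical details):

* one seed at the centre of every voxel with FA above threshold;
* half-voxel step with nearest-neighbour tensor lookup;
* bidirectional propagation; eigenvector sign chosen to maximise the dot
  product with the previous step (the principal axis has no intrinsic
  sign);
* angle measured between successive step vectors; termination on strictly
  greater than 45° (exactly 45° continues);
* streamlines with fewer than two points are discarded; no other minimum
  length.

Tracking has no randomness: the output is a pure function of the tensor
field.  Sub-voxel interpolation and probabilistic variants are out of
scope.

## Network construction

A streamline connects regions *i* and *j* when its two *terminal* points
fall inside the two (distinct, nonzero) labels; this endpoint reading is
the default, with pass-through counting available via a flag since the
convention varies across studies.  The edge weight is the mean over
connecting streamlines of each streamline's mean FA across its visited
voxels (a per-fiber mean, not a pooled-voxel mean, matching the reading of
"mean FA of the fibers"); the streamline count matrix is retained as
auxiliary data.  Label volumes arrive pre-aligned: spatial normalisation
and atlas warping are upstream concerns outside this package.

## Thresholding and graph metrics

Weighted matrices are binarized at sparsity S by keeping the
`⌊S·N(N−1)/2⌋` largest weights; the floor guarantees sparsity ≤ S and
determinism, and ties at the cutoff break by ascending (i, j) order so
equal-weight inputs are reproducible.  The canonical grid is
0.10 ≤ S ≤ 0.20 in steps of 0.01 (11 points).  The lower end is anchored
by the mean-degree heuristic `k̄ > 2 ln N`; note the documented boundary
behaviour at N = 90, S = 0.10: 400 edges give k̄ = 8.89 against
2 ln 90 = 9.00, so the criterion narrowly fails at the grid minimum.

Binary metric definitions (Watts–Strogatz clustering/path length,
Latora–Marchiori efficiencies):

* `C_i = 2t_i/(k_i(k_i−1))`, zero for degree < 2, and Cp is the mean over
  *all* nodes;
* Lp is the mean shortest-path length over reachable ordered pairs;
  disconnected pairs are excluded from Lp and contribute 0 to
  efficiencies (the generated networks are ≥ 90% connected at the minimum
  threshold, so this is a rare edge case, but it must be defined);
* `Eglo` is the mean of 1/d over all ordered pairs; `Eloc` the mean over
  nodes of the efficiency of the neighbour-induced subgraph;
* nodal efficiency `E_i = (1/(N−1))Σ_j 1/d_ij`; betweenness is Brandes
  centrality normalised by (N−1)(N−2)/2 so it lies in [0, 1].

Shortest paths run on a dense level-synchronous BFS (uint8 matmuls),
which at N ≈ 90 is much faster than sparse Dijkstra and is cross-checked
against a hand-written Floyd–Warshall oracle on all sampled graphs with
N ≤ 8; betweenness is cross-checked against explicit shortest-path
enumeration.

Small-world normalisation uses 100 (configurable) degree-preserving
random networks per thresholded graph, generated by Markov-chain
double-edge swaps with 20 attempted swaps per edge (a standard mixing
heuristic), rejecting self-loops and multi-edges; node count, edge count
and the exact degree sequence are invariant.  γ = Cp/⟨Cp_rand⟩,
λ = Lp/⟨Lp_rand⟩, and σ is defined as γ/λ — the orientation under which
the small-world criterion "γ > 1 and λ ≈ 1" implies σ > 1 (the reversed
ratio sometimes seen in print contradicts that criterion).  Graphs with
no swappable edge pair (stars) return copies with a warning.  Metric
curves are summarised by the trapezoidal AUC over the grid; a
single-point grid yields AUC 0 with a warning.

## Statistical inference

* **Demographics.** Welch (unequal-variance) t from group summaries —
  the variant that reproduces published two-decimal summary tables to
  ≤ 0.3% — and Pearson chi-square without continuity correction for 2×2
  gender tables.
* **Covariate removal.** OLS residualization on gender (0/1 coded; any
  affine coding gives identical residuals), age, education and the
  sleep-adjusted HAMA/HAMD scores; residuals are exactly orthogonal to
  every covariate (asserted at 1e-10); rank-deficient designs are
  rejected naming the collinear columns.
* **Group tests.** Label permutation with group sizes fixed, two-sided
  smoothed p = (1+#{|T*| ≥ |T|})/(n_perm+1) (never exactly 0), default
  5000 iterations.  Without covariates the statistic is the group mean
  difference and the test is exact by exchangeability (an exhaustive
  enumeration mode exists for tiny samples).  With covariates the test
  is Freedman–Lane: residualize once, permute residuals, re-residualize
  before recomputing the statistic.  The re-residualization matters —
  the adjusted clinical scores differ strongly between groups, and a
  naive permute-the-residuals scheme measured a 1% type-I rate at
  nominal 5% (the observed group contrast is shrunk by the adjustment
  while permuted contrasts are not).  Freedman–Lane with the raw mean
  difference is conversely slightly liberal (~6% measured), because the
  mean difference is not pivotal under re-residualization; the
  covariate-adjusted path therefore defaults to the studentized Welch t,
  which measured 4.6–5.5% across several 2000–4000-replicate runs.
* **Correlations.** Pearson r between doubly residualized variables with
  df = n−2−k; with k = 0 this is exactly the ordinary Pearson test.
* **Multiple comparisons.** Only the exploratory per-node threshold 1/N
  (0.011 at N = 90), flagged "uncorrected" in all outputs; FDR machinery
  is deliberately not applied.

## Synthetic data generators

All generators are pure functions of their spec including the seed (one
`numpy` Generator per call; the pipeline fans a single seed out to
per-stage substreams via `SeedSequence.spawn`).

**Cohort.** Group sizes default to 30 (IS) vs 62 (NIS) with covariate
moments matching the emulated study's summary table.  The insomnia score
(sum of three HAMD-17 sleep items, so an integer in 0–6, ≥ 1 defining
IS) is drawn from a truncated discrete Gaussian on {1..6} whose location
and scale are moment-matched by Nelder–Mead; clinical totals are built
as adjusted score + sleep component, which makes adjusted ≤ total hold
by construction and reproduces the published totals (2.93 = 1.23 + 1.70
for HAMD).  The HAMA sleep component's mean is pinned by the published
totals; its SD (0.9) is a modelling choice.  Ages are plain normals;
per-item sub-score structure is not modelled.

**Connectomes.** 90 nodes (45 per hemisphere, mirror-paired as in the
AAL ordering).  Base edge affinity = exponential distance decay
(length scale 0.5 on a unit slab) × a same-module bonus (spatially
coherent modules, mirrored across hemispheres) × a homotopic bonus for
mirror pairs; per-subject FA weights are Beta-distributed around
0.15+0.60·affinity with concentration 40.  This produces networks whose
largest connected component covers ≥ 90% of nodes at S = 0.10 and whose
small-world σ exceeds 1 across the grid — the two properties the
analysis assumes.  Real connectomes are sparser and have FA-dependent
edge absence; the generator's dense weight matrix only emulates the
*ranking* structure that thresholding consumes, so passing tests say
nothing about robustness to missing data or registration error.

Effects are planted multiplicatively on weights before clipping to
[0, 1]: group shifts scale within-module edges (raising local
efficiency when positive) and between-module edges (lowering global
efficiency when negative) in the IS group; nodal effects scale one
node's incident weights; insomnia couplings scale incident weights by
1 + slope·score.  The default disruption pattern uses ±0.18 global
shifts and 0.25 nodal magnitudes — large effects by design, chosen so
sign recovery at the study's group sizes is near-certain (the
acceptance run measures the rate over 20 replicates).  Because total
edge count is fixed by the sparsity rule, boosting a node's weights
necessarily drains edges from other nodes; nodal-effect enrichment is
therefore assessed at full 90-node scale where the spillover spreads
thinly.

**Phantoms.** Axis-aligned straight or single-bend tubes (radius in
voxels, Chebyshev cross-section) on grids up to 32³, with axially
symmetric tensors solving the target FA at fixed mean diffusivity
(0.7×10⁻³ mm²/s) inside the bundle and isotropic background; ROI labels
stamp the first/last two centerline slices.  Signal is synthesised
exactly and Gaussian noise added (Rician noise, partial volume, eddy
currents and motion are not modelled).  Endpoints and within-bundle FA
are analytic, so tractography and network construction are checkable
against closed-form truth.

## Problem sizes in tests and the acceptance run

The test-suite and acceptance-script sizes are chosen as desk-scale
versions of the full design: null-ensemble sizes of 8–25 instead of 100,
499–999 permutations instead of 5000, and 20–40-node networks where the
check is structural rather than scale-dependent.  Quantities that depend
on scale — sparsity mechanics, planted-effect recovery, nodal-effect
enrichment — run at the full 90 nodes and 30/62 group sizes.  Type-I
calibration uses 400 null replicates at 499 permutations; recovery uses
20 replicates.

## Known limitations

* Nearest-neighbour FACT on coarse phantoms cannot represent oblique or
  curved-but-trackable geometry; only axis-aligned bundles are generated.
* The connectome generator plants effects through edge-weight rescaling;
  it cannot produce effects confined to betweenness alone, and global
  and nodal effects interact through the fixed edge budget.
* Lp on disconnected graphs is a reachable-pairs mean, which is not
  comparable across graphs with very different component structure; the
  ≥ 90%-connectivity guarantee keeps this marginal.
* The 1/N threshold is an exploratory convention, not an error-rate
  guarantee; outputs flag it as uncorrected.
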