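# Methods

## Model

`sementropy` models a labeled 3D volume as a finite-state Markov chain over
tissue tags. A notional particle starts at a uniformly random point, so its
initial tag distribution p0 is the vector of volume fractions of the tagged
regions (background, label 0, is never a region and the particle can never
enter it). Per time step the particle either stays in its tissue or crosses
into an adjacent one; the crossing probability from tag i to tag j is the
fraction of region i's volume that lies within the *liminal region* toward j —
the part of i close enough to j's boundary for diffusion to carry the particle
across.

Because real segmentations rarely have exactly coincident surfaces, the
liminal region is not computed from surface patches but by morphological
dilation: v_ij = volume(R_i ∩ D(R_j, k)), where D dilates the binary mask of
region j by k applications of a 3D structuring element. The diagonal holds the
retained interior, v_ii = vol(i) − Σ_{j≠i} v_ij, and rows are normalized to
give the stochastic matrix Q. Q is stored row-stochastic, with q_ij the
probability of stepping from tag i to tag j, and distributions propagate as
row vectors: p_n = p0 Qⁿ.

The entropies reported for a model are

- E_n = −Σ_i (p_n)_i log (p_n)_i, the order-n Structural Entropy (E_0 is the
  entropy of the volume fractions alone);
- E_π = −Σ_i π_i log π_i where π = πQ, the Stationary Structural Entropy,
  defined only for ergodic chains;
- E_max = log m, with m the number of retained tags, and the normalized values
  Ē = E / E_max ∈ [0, 1] (0 = maximal structure, 1 = maximal disorder).

The discrete precursor on tagged graphs is included: the order-n Path Entropy
is the entropy of tag sequences over all walks of n edges, counted as ordered
walks in which vertices may repeat (each undirected edge contributes two
directed steps, and immediate back-tracking u→v→u is a distinct walk — a
defensible alternative would exclude it, but a random walker can in fact
return, and excluding it would break the Markov analogy). At order 0 this is
the standard image entropy of the label histogram.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| k | 1 voxel | dilation amount; width of the liminal band in lattice steps |
| connectivity | face | structuring element: face (6), edge (18) or vertex (26) neighbours |
| log_base | 2 | entropy unit (bits); cancels in every normalized quantity |
| orders | 0, 1, 2, 4, 8 | reported finite-order entropies |
| tol / max_iter | 1e-12 / 1e6 | stationary-solver fixed-point tolerance and iteration cap |

k = 1 with face connectivity is the most conservative reading of "dilating by
a small amount": a one-voxel-deep liminal band. On flat interfaces this makes
v_ij = v_ji exactly (each side contributes its own one-voxel layer). Larger k
thickens the band and increases mixing; the choice of structuring element
matters only near edges and corners. Volumes are physical (voxel count ×
product of spacings) but dilation is lattice-step-based, so for anisotropic
voxels the liminal band is geometrically anisotropic — a known limitation; the
measure is exact for isotropic data.

## Numerical choices

- **Entropy sign.** Entropies are the standard negative sums, always ≥ 0;
  0·log 0 contributes 0.
- **Stationary distribution.** Ergodicity is checked first: the positive-entry
  digraph of Q must have a single strongly connected component (disconnected
  anatomical islands fail here) and period 1 (any positive diagonal suffices;
  otherwise a cycle-gcd test). π is the dominant left eigenvector of Q,
  polished by power iterations until the L1 fixed-point residual is ≤ tol;
  on symmetric worked phantoms this contraction lands on the exact fixed
  point. Non-ergodic models produce a report with the stationary entropy
  absent and the reason recorded — an expected data condition, not a failure.
- **Zero-volume tags** are dropped (with a warning) before any matrix is
  built; they indicate defective input. m in E_max counts retained tags only,
  since dropped tags can carry no probability.
- **Diagonal clamping.** For regions thinner than ~2k the liminal volumes
  toward different neighbours overlap and Σ_{j≠i} v_ij can exceed vol(i); the
  diagonal is clamped at 0, the tag is recorded, and the relative neighbour
  weighting is preserved by the row normalization.
- **Single-tag models** have E_max = 0; normalized entropy is 0 by convention
  (maximal structure), with a warning.
- **Path-entropy enumeration** is exact (dynamic programming over
  tag-sequence/end-vertex counts with integer arithmetic) and guarded by a
  walk-count cap (default 10^7) computed from adjacency-matrix powers;
  instances beyond the cap are refused rather than approximated.
- **Exponential trend fit.** E(t) = exp(a·t) + b, two free parameters,
  initialized at a = −0.1, b = min(y), with a bounded ≤ 0. A constant series
  leaves a unidentifiable (a → −∞); it is returned as the degenerate fit
  b = mean. A three-parameter variant A·exp(a·t) + b is available behind a
  flag but is not the default, keeping the fit comparable across series.

## Synthetic phantoms and what they do (not) show

The phantom generator supplies the test substrate: half-slabs, stripes and
checkerboards (50/50 two-tag mixes of varying geometric richness), a thin
shell around a core, and seeded Voronoi tessellations standing in for
many-tissue anatomies. These capture the features the measure responds to —
volume imbalance, interface area, adjacency topology, disconnected islands —
but none of the texture of real anatomy: no heterogeneous tissue size spectrum,
no elongated or branched organs, no segmentation noise. Passing tests on
phantoms therefore validates the *computation* (geometry → chain → entropy),
not any biological claim about a particular atlas.

Two caveats discovered on phantoms are worth knowing. A period-1 checkerboard
makes every voxel liminal (q_ii = 0), giving a deterministic two-state
alternation with no stationary distribution — infinitely fine interdigitation
is a degenerate, periodic chain, and the report says so. And in the
random-merge experiment, near-equal-size Voronoi cells show a noticeably
stronger correlation between entropy and element count (~0.5–0.7) than
heterogeneous anatomical models, because merging equal cells directly reshapes
the volume distribution; the experiment's mechanics (binning, determinism,
exclusion of non-ergodic trials) are what the tests assert.

The Monte-Carlo walker samples the *tag-level* chain (p0, Q) rather than
voxel-level Brownian motion: it is deliberately an oracle for the matrix
computations (independent of the eigen-solver, not of the Q construction),
which is the quantity the measure is actually defined on. Voxel-level
diffusion is out of scope.

## Random-merge experiment

One trial shuffles the tag list with a seeded generator, then sweeps it once:
each not-yet-consumed tag draws up to depth−1 of its adjacent (positive
off-diagonal Q entry in either direction), still-free neighbours uniformly at
random and the group is merged into a fresh label. Groups never chain within
a sweep; tags with no free neighbour stay singletons. Depths 2–4 with 25
replicates per depth (seed = base_seed + running counter) reproduce
bit-for-bit under the same base seed. Trials are binned by surviving element
count (width 5, bins aligned to multiples of 5; per-bin mean and SD with
ddof = 1), and Pearson correlations of each normalized entropy against element
count summarize the dependence; degenerate cases (constant counts or
entropies) report the correlation as absent.

## Problem sizes

Tests and the acceptance script run on phantoms up to 32³ voxels with up to
73 tags, walker ensembles of 10^5, walk enumeration on graphs of ≤ 8 vertices
at orders ≤ 3, and 75 merge trials — sizes chosen so every oracle comparison
(brute-force voxel scans, literal walk enumeration) stays exact and the whole
suite completes in well under a minute. Real atlas volumes are orders of
magnitude larger in voxel count, but the computation scales with (number of
tags)² dilations, not with the measures themselves, and stays practical.

## Known limitations

- Anisotropic voxels: dilation is lattice-based, so liminal bands are not
  metric (see above).
- The dilation workaround assumes regions are close on the lattice wherever
  they are anatomically adjacent; segmentations with gaps between nominally
  touching tissues will under-estimate v_ij (the same data defect the
  dilation approach mitigates but cannot eliminate).
- Dilation is fully 3D; slice-wise 2D behaviour would differ for strongly
  layered data.
- The walker oracle validates the chain, not the geometry→chain step; that
  step is instead validated by exact brute-force voxel scans on small
  phantoms.
- No entropy rate (conditional per-step entropy) is computed — the measure is
  the entropy of the occupancy distribution, which is what normalization by
  log m makes comparable across stages.
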