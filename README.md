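# sementropy

Structural Entropy morphometry for tagged 3D anatomical models.

Quantifying how *ordered* an anatomy is — and how that order changes as an
embryo develops — requires more than the volume fractions of its tissues: a
two-tissue embryo split into neat halves and one with the same 50/50 mix
finely interdigitated have identical composition but very different structure.
`sementropy` measures this with an information-theoretic quantity built on a
random walk over the tagged regions of a labeled volume (e.g. a developmental
atlas segmentation): a notional particle starts at a uniformly random point
and steps between tissues with probabilities set by how much of each region
lies close to each neighbour. The Shannon entropy of where the particle is
likely to be found — after *n* steps, or at stationarity — is the Structural
Entropy. It is intended for developmental biologists and image-analysis
researchers working with labeled (tagged) 3D models: atlases, organoid
segmentations, or any integer-labeled volume with named regions.

## The measure

For a tagged graph *G = (V, E, C, χ)*, the order-*n* Path Entropy is the
entropy of the distribution of tag sequences over all walks of *n* edges:

    p_n(s) = |{σ ∈ S_n : χ_n(σ) = s}| / |S_n|,   E_n = −Σ_s p_n(s) log p_n(s)

For a labeled volume, regions R_i with tags replace vertices. The initial
distribution p0 holds volume fractions, p_c = Σ_{χ(R_i)=c} p(R_i); the
transition matrix comes from *liminal volumes*, computed by morphological
dilation:

    v_ij = ∫ R_i ∩ D(R_j, k) dx   (i ≠ j),   v_ii = vol(R_i) − Σ_{j≠i} v_ij
    q_ij = v_ij / Σ_j v_ij

where D(R_j, k) dilates region j by k lattice steps. Then

    E_n = H(p0 Qⁿ)        (order-n Structural Entropy; E_0 = volume entropy)
    E_π = H(π), π = πQ    (Stationary Structural Entropy, ergodic chains only)
    Ē_· = E_· / log(m)    (normalized by the maximum entropy of m tags)

Normalized values live in [0, 1]: 0 is maximal structure, 1 maximal disorder,
comparable across stages with different tissue counts. Chains with
disconnected or periodic adjacency have no unique π; the report records the
reason instead of a stationary value.

## Worked example

```sh
python examples/phantom_structural_entropy.py
```

```
slab: tags=['A', 'B']
  Q =
[[0.5 0.5]
 [0.5 0.5]]
  E0_norm = 1.0000  Epi_norm = 1.0000  (E_max = 1.0 bits)
thin plane: tags=['plane', 'bulk']
  Q =
[[0.     1.    ]
 [0.3333 0.6667]]
  E0_norm = 0.8113  Epi_norm = 0.8113  (E_max = 1.0 bits)
```

The slab phantom (two equal half-volumes) is maximally disordered by both
measures: equal volumes and a symmetric interface. The thin-plane phantom (a
one-voxel plane against a 48-voxel bulk) scores 0.8113 — the entropy of the
(0.25, 0.75) distribution: the plane is entirely liminal, the particle always
leaves it (q = 0 on its diagonal), and the stationary distribution
concentrates on the bulk. Other examples cover Path Entropy on graphs
(`graph_path_entropy.py`), the Monte-Carlo walker cross-check
(`walker_oracle.py`), the random-merge robustness experiment
(`merge_robustness.py`) and trend fitting over a developmental series
(`developmental_trend.py`).

## Command line

The `sementropy` command wraps the library for shell use:

```sh
sementropy synth --kind voronoi --shape 32,32,32 --m 73 --seed 42 --out phantom
sementropy compute phantom.nii.gz phantom_tags.json --k 1 --connectivity face
sementropy merge phantom.nii.gz phantom_tags.json --replicates 25 --seed 42
sementropy series manifest.tsv --plot trend.svg
sementropy simulate phantom.nii.gz phantom_tags.json --walkers 100000
sementropy graph-entropy vertices.tsv edges.tsv -n 2
```

Volumes are NIfTI (`.nii`, `.nii.gz`) or NRRD; tag maps are JSON
(`{"1": "ectoderm", ...}`) or two-column TSV; a staging manifest for `series`
is a TSV with columns `model_id`, `theiler_stage`, `days`, `volume_path`
(and optionally `tag_map_path`). Atlas models distributed in other formats
(e.g. Woolz) must be converted to NIfTI/NRRD beforehand. Data-quality events —
zero-volume tags, clamped diagonals, non-ergodic chains — are logged to
stderr, and every output file carries a provenance record (version, config,
input checksums, seeds).

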