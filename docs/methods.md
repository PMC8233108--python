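# Methods

`myeloconn` implements a comparison between two weightings of the structural
connectome: the conventional streamline-count weight (NOS, number of
streamlines) and a myelin-sensitive weight given by the median of a
quantitative R1 map (R1 = 1/T1, units 1/s) sampled along each streamline
bundle.  This note records the models, conventions, parameters and design
choices, and what the synthetic phantom does and does not establish.

## Connectome construction

For one subject the inputs are a tractogram (3-D polylines in world mm), an
integer parcellation volume and a scalar R1 volume sharing a voxel-to-world
affine.  The pipeline:

1. **Length filter.** Streamlines with length outside [20, 250] mm are
   discarded.  Bounds are inclusive: the filter removes only streamlines
   strictly shorter than 20 mm or strictly longer than 250 mm.
2. **Endpoint assignment.** Each terminal vertex takes the label of its
   containing voxel (voxel centre convention: voxel *(i,j,k)* is centred at
   `affine @ (i,j,k,1)`); if that voxel is background or outside the volume,
   the nearest labelled voxel whose centre lies within `radius_mm`
   (default 2 mm, a common connectome-mapping choice) is used.  Streamlines
   with an unassigned end or both ends in the same region are dropped.
   With radius 0 the rule reduces to pure containment.
3. **Scalar sampling.** One sample per vertex; trilinear interpolation by
   default (`nearest` available); vertices outside the volume contribute no
   sample.
4. **Edge weights.** For each region pair *(i,j)*: `w_ij` = streamline count;
   `v_ij` = median of the samples pooled over *all* streamlines of the
   bundle ("one median per bundle").  The even-count median is the midpoint
   of the two central order statistics.  The median is preferred over the
   mean because it is robust to outlying samples and makes no distributional
   assumption.  A `per_streamline` pooling switch (median of per-streamline
   medians) exists for sensitivity analysis.
5. **Spurious-connection threshold.** Pairs with fewer than
   `min_streamlines` streamlines (default 2; 5 as the conservative
   robustness setting) are zeroed in **both** matrices, so the NOS and R1
   connectomes always share their edge support.  Bundles whose vertices all
   fall outside the scalar volume are dropped from both.

## Group consensus

An edge enters the group network when present (nonzero) in at least
`ceil(prevalence * n_subjects)` subjects (default prevalence 0.5; for 35
subjects the threshold is 18).  Its consensus weight is the median of its
weights over the subjects *in which it is present*: including absent
subjects as zeros could push a consensus weight below every observed weight,
which we consider unreasonable; a switch restores the plain median.  Shared
variance between weightings is summarised by ordinary least squares over
upper-triangle edges nonzero in both matrices (R², slope, two-sided p for
the slope).  R² is symmetric in the two weightings; which one is called the
response is cosmetic.

## Node centralities and hubs

* NOS strength: `S_i = sum_j w_ij` (row sums).
* R1-weighted average: `S_i = sum_j w_ij v_ij / sum_j w_ij`, the
  count-weighted mean of incident R1 edge values.  By construction it is
  bounded by the incident `v_ij` range, invariant to global rescaling of the
  counts, and deliberately insensitive to how many connections a node has.
  It is undefined (NaN) for isolated nodes, which are excluded from ranking
  with a warning.
* Hubs: nodes with metric ≥ mean + k·SD, k = 2 (or 3, conservative), using
  the *sample* SD (n−1).  A constant metric (SD = 0) yields no hubs — the
  alternative (every node a hub) is uninformative.  Both centralities and
  hubs are computed on the group-consensus networks.

## Multi-resolution modularity

Quality function, for symmetric non-negative `A` with node strengths
`k_i = sum_j A_ij` and total weight `2m = sum_ij A_ij`:

    Q(gamma) = (1/2m) sum_ij (A_ij - gamma * k_i k_j / 2m) delta(c_i, c_j)

i.e. the weighted configuration (Newman–Girvan) null with the conventional
1/2m normalisation and a resolution parameter gamma (gamma < 1 favours
larger modules).  Louvain maximisation is the standard two-phase algorithm:
greedy single-node moves to the best-gain module (visit order shuffled by
the seed; a node moves only on a strictly positive gain beyond a 1e-12
tolerance, ties broken toward the lowest module index), then aggregation of
modules into super-nodes, repeated until no gain.  A run is deterministic
given `(A, gamma, seed)`.

The resolution sweep covers gamma = 0.5 to 3.0 in steps of 0.1 (26 levels)
with 1,000 Louvain runs per level by default.  Because Q values at
different resolutions are not comparable (Q decreases essentially linearly
in gamma for any fixed partition), the working resolution is chosen where
the solutions are most *stable*: the gamma maximising the mean pairwise
z-scored Rand coefficient of the runs, ties broken toward the smaller
gamma.  A `max_q` selection rule is available behind a flag.  Pairwise
similarity uses the z-Rand statistic (pair-counting Rand coefficient
z-scored under the hypergeometric null with fixed module sizes, after Traud
et al.); with more than 150 runs per level the mean is taken over a random
subsample of 10,000 pairs, below that over all pairs.

The consensus partition at the selected gamma clusters the co-assignment
(agreement) matrix of the runs: entries not exceeding the chance level
(mean agreement over 100 independent per-partition label permutations) are
zeroed, Louvain (gamma = 1) is re-run 10 times on the thresholded matrix,
and the procedure iterates on the new partitions until all runs agree
(cap 100 rounds, then an error with diagnostics).

## Rank-based class comparison

Nodes are ranked within each weighting (rank 1 = highest; ties get average
ranks); `d_i = rank_R1_i − rank_NOS_i` is z-scored across nodes with the
sample SD (an all-zero `d` maps to all-zero z), and summarised per
functional (7 Yeo-style labels) and per cytoarchitectonic (7 von
Economo-style labels) class by the median.  Sign convention: since rank 1
is highest, a class whose R1-weighted centrality outranks its
streamline-count centrality has *negative* median d/z.  A `flip_sign`
option serves plotting conventions that draw "overrepresented" upward.
Module-by-class composition is a plain contingency table of node counts
(row sums = module sizes).

## Synthetic phantom

The generator replaces an MRI cohort with planted ground truth.

* **Edges.** A population template draws edge existence once per pair
  (Bernoulli: 0.9 within-module, 0.1 between, under a planted partition of
  4 equal modules over 60 regions by default); each of the 35 subjects keeps
  a template edge with probability 0.8.  This dropout gives the
  50%-prevalence consensus rule both kept and rejected edges.  The
  inter-subject variability model is an artifact choice — the study design
  this package mirrors does not specify one.
* **Counts.** NOS on existing edges is Poisson(lambda) truncated to ≥ 1,
  lambda = 20 within modules and 2 between (a zero rate degenerates to
  count 1).
* **Scalars.** `v_ij = 1.1 + mean(class offsets of i, j) + subject offset +
  N(0, 0.05)`, clipped to the physiological R1 envelope (0, 3) 1/s.  The
  default class offsets are +0.05 1/s for the five transmodal functional
  classes (DA, VA, LIM, FP, DMN) and 0 for the unimodal ones (VIS, SM),
  planting the transmodal > unimodal myelin gradient the rank analysis is
  meant to recover.  The subject offset is N(0, 0.02)·1.1, a global
  per-subject shift.  Functional classes cycle with period 7 and
  cytoarchitectonic classes with period 49, so neither aligns with the
  contiguous planted modules.
* **Geometry mode** additionally lays regions out as 3-voxel blocks on a
  jittered 3-D lattice (2 mm isotropic voxels, 64³ grid), draws
  streamlines as straight 1-mm-step polylines with a bundle-specific 6 mm
  lateral bow and sub-voxel wobble, endpoints pinned inside their blocks,
  and paints each bundle's planted value along its corridor.  The lattice
  jitter breaks colinear region triples and the bow separates corridors
  between them; where corridors still overlap (shared endpoint regions,
  crossings) voxel ownership is resolved first-painted-wins with a repair
  pass that re-claims voxels for any bundle left without a strict majority
  of its own samples — a strict majority is exactly what makes the pooled
  *median* equal the planted value.  All streamline lengths fall in
  [20, 250] mm by construction.

What the phantom does **not** emulate: curved or crossing fibre geometry,
tracking errors and distance biases, scanner noise models, realistic
parcellation shapes, or spatial autocorrelation of R1.  Passing tests
therefore establish the correctness of the implemented arithmetic and the
recoverability of planted structure under idealised conditions — not
performance on real MRI data.

## Numerical conventions and degenerate inputs

* Coordinates: world mm (RAS+); voxel indices 0-based; TRK's voxel-corner
  convention is converted on read (via nibabel).  Matrices are dense CSV
  with node-id header; floats are written as shortest round-trip reprs and
  parsed with round-trip precision, so write→read is bit-identical.
* Symmetry tolerance for input matrices: 1e-9 (violations are reported with
  the offending row/column).
* All randomness descends from one master seed (`numpy.random.SeedSequence`
  spawning per-stage seeds, recorded in the provenance log); reruns are
  byte-identical.
* Degenerate cases: empty graphs are errors for modularity; constant hub
  metrics yield no hubs; a constant regression predictor is an error while
  a constant response returns R² = 0; z-Rand of fewer than 4 nodes is an
  error and a degenerate null variance returns 0; isolated nodes propagate
  as NaN metrics and are excluded from ranks with a warning.

## Problem sizes used in the shipped experiments

The planted-recovery experiment uses 20 cohorts (60 nodes, 35 subjects)
with a thinned sweep (gamma 0.5–3.0 step 0.25, 100 runs per level); the
rank-sign experiment uses 100 cohorts; the Louvain-optimality check uses 50
random graphs with up to 8 nodes against exhaustive enumeration of all set
partitions; sampling-fidelity checks use 12-region geometry phantoms.
These sizes give stable rates while keeping a full run in the order of
minutes on one CPU; the full-resolution sweep (26 levels × 1,000 runs) is
exercised on the single default cohort in `scripts/acceptance.py`.

## Known limitations

* The Louvain implementation is the classic greedy heuristic; it can miss
  the global optimum on adversarial graphs (the shipped check requires
  ≥ 95% exact matches on small random graphs, not 100%).
* Consensus clustering assumes the input runs agree better than chance; if
  the thresholded agreement matrix vanishes it raises rather than guessing.
* The edge regression is a plain OLS on common-support edges — no log
  transform, no distance correction.
* Endpoint assignment and scalar interpolation rules are configurable
  because tractography pipelines differ on them; defaults follow common
  practice (2 mm radius, trilinear sampling, pooled-median per bundle).
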