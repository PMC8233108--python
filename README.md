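# myeloconn

Myelin-sensitive weighting of structural brain connectomes.

Tractography-based connectomes conventionally weight the connection between
two cortical regions by the number of reconstructed streamlines (NOS).
That weight says how *many* connections were found, not what they are made
of.  `myeloconn` builds, alongside the NOS-weighted connectome, a network
whose edges carry the median longitudinal relaxation rate
(R1 = 1/T1, units s⁻¹ — a quantitative MRI parameter sensitive to myelin
content) sampled along each streamline bundle, and provides the analyses
needed to compare the two weightings:

* per-subject connectome construction from a tractogram (TCK/TRK), a
  parcellation volume and an R1 map (NIfTI): length filtering (20–250 mm),
  endpoint-to-region assignment, scalar sampling, bundle-median edge
  weights `v_ij`, streamline counts `w_ij`, and a spurious-edge threshold
  (≥ 2 streamlines, conservatively ≥ 5) applied to both matrices jointly;
* group-consensus networks (edges present in ≥ 50% of subjects; weight =
  median across the subjects that have the edge) and the shared variance
  (R²) between weightings over common edges;
* node centralities — NOS strength `S_i = Σ_j w_ij` and the R1-weighted
  average `S_i = Σ_j w_ij v_ij / Σ_j w_ij` — with hub detection at
  mean + 2·SD (and 3·SD);
* multi-resolution modularity `Q(γ) = (1/2m) Σ_ij (A_ij − γ k_i k_j/2m)
  δ(c_i,c_j)` maximised by an in-package Louvain implementation, swept over
  γ = 0.5…3.0 (step 0.1, 1,000 runs per level), with the working resolution
  selected by run-to-run stability (mean pairwise z-Rand) and a consensus
  partition distilled from the runs at that resolution;
* a rank-based comparison: nodes ranked in each weighting (1 = highest),
  per-node difference `d_i = rank_R1 − rank_NOS` z-scored and summarised by
  the median per functional (Yeo-style) and cytoarchitectonic (von
  Economo-style) class, plus module-by-class composition tables.

Because such analyses need ground truth to be testable, the package ships a
first-class synthetic phantom generator: multi-subject cohorts with planted
modules, a planted transmodal > unimodal R1 gradient, inter-subject
variability, and (optionally) full geometry — label volume, R1 volume and
polyline streamlines — so every stage from sampling to consensus
clustering can be validated against known answers.

Intended users: network-neuroscience researchers working with quantitative
MRI weightings of structural connectomes, and anyone needing a tested,
seed-reproducible Louvain/z-Rand/consensus-clustering stack on dense
weighted matrices.

## Worked example

Run the full pipeline on a synthetic cohort (60 regions, 35 subjects,
4 planted modules; thinned sweep for speed):

```python
from myeloconn import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="example_out", n_regions=60, n_subjects=35,
                     gamma_step=0.25, n_runs=100, seed=7)
report = run_pipeline(cfg)
print(report["provenance"]["regression_scalar_on_nos"]["r_squared"])
print(report["provenance"]["selected_gamma"],
      report["provenance"]["n_modules"])
print(report["class_medians"]["functional"].round(3))
```

prints (abridged):

```
4.5680798052149006e-05
{'nos': 0.5, 'scalar': 2.25} {'nos': 4, 'scalar': 5}
DA    -0.359
DMN    0.258
FP    -0.359
LIM   -0.730
SM     0.404
VA    -0.539
VIS    0.853
```

Reading the output: the edge-weight R² near zero says the R1 weights share
almost no variance with the streamline counts — the two weightings carry
different information (the phantom plants R1 values independent of edge
counts).  The NOS sweep selects γ = 0.5 and recovers exactly the 4 planted
modules.  In the class medians, negative values mark classes whose
R1-weighted centrality outranks their count-based centrality: the
transmodal classes (DA, VA, LIM, FP) sit below zero while the unimodal
VIS/SM sit above, recovering the planted +0.05 s⁻¹ transmodal gradient
(rank 1 is highest, so "better R1 rank" means a *smaller* rank number and
a negative difference).

The same pipeline is scriptable from a shell:

```
myeloconn simulate --seed 7 --out cohort/ --geometry
myeloconn build --tck cohort/tractogram.tck --labels cohort/labels.nii.gz \
    --scalar cohort/scalar.nii.gz --min-streamlines 2 --out subj01
myeloconn consensus --cohort cohort/ --prevalence 0.5 --out group
myeloconn communities --matrix group_nos.csv --runs 1000 --seed 42 \
    --out sweep.json partition.csv
myeloconn run --seed 7 --out full_pipeline_out/
```

## Layout

```
src/myeloconn/
  phantom.py      synthetic cohorts and phantom geometry (planted truth)
  tracts.py       streamline lengths, filtering, endpoint assignment, sampling
  build.py        per-subject NOS + R1-median connectome construction
  consensus.py    group-consensus networks, edge-weight regression
  metrics.py      strength, R1-weighted average, hub detection
  modularity.py   Q(γ), Louvain, z-Rand, γ sweep, consensus partition
  ranks.py        rank-difference z-scores, class medians, compositions
  io.py           CSV / NIfTI / TCK / TRK readers and writers
  pipeline.py     end-to-end driver with seed and provenance handling
  cli.py          `myeloconn` command-line umbrella
```

See `docs/methods.md` for the full model description, parameter defaults,
numerical conventions and limitations.
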