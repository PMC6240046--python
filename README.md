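# tmrconn

Graph-theoretic analysis of cued memory reactivation during slow-wave
sleep, rebuilt as a tested, reusable Python pipeline and exercised
end-to-end on synthetic fMRI-like data with a known, planted ground truth.

## The scientific problem

Targeted memory reactivation (TMR) presents learning-associated sensory
cues — here, object sounds paired with object-location associations —
while a subject is in slow-wave sleep, to bias which memories the sleeping
brain consolidates. The question this pipeline addresses is a network one:
when a cue sound arrives during deep sleep, does the sensory cortex that
encoded the memory (early visual / occipital cortex for object-location
learning) transiently *integrate* with the rest of the brain, and does the
size of that integration shift predict how well the subject's memories
survive the night?

The analysis chain, applied identically to cue sounds (associated with
learned material; 25 sounds × 2 presentations) and control sounds (never
associated; 5 sounds × 5 presentations):

1. **Beta time-series.** Every sound presentation gets its own regressor —
   a 5 s boxcar convolved with the canonical double-gamma HRF — in a single
   GLM with six motion and three compartment nuisance regressors, a 128 s
   discrete-cosine high-pass filter, and AR(1) prewhitening. The trial
   coefficients β̂ form a node × trial "beta series" per condition
   (50 cue points, 25 control points).
2. **Connectivity graphs.** Node-pairwise Pearson correlations of the beta
   series, thresholded by keeping only edges significant at FDR *q* = 0.05
   (Benjamini–Hochberg over all unique edges; negative edges removed).
3. **Two-scale module mapping.** Community structure is estimated once on
   the coarse 115-parcel graph with weighted Louvain modularity
   maximisation, Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j),
   and the module labels are propagated to voxels. Each voxel's
   **participation coefficient**

   PC_i = 1 − Σ_s (κ_is / k_i)²

   (κ_is = strength of node *i* into module *s*, k_i = total strength)
   quantifies how evenly its connections spread across modules: 0 for a
   provincial node, approaching 1 − 1/M for a perfectly even connector.
4. **Group inference.** Cue-vs-control PC maps compared with a paired
   t-test; cluster-extent correction at a cluster-forming threshold of
   Z > 2.33 by max-extent sign-flipping permutation (a Gaussian-Random-Field
   approximation is available); seed-based Fisher-z connectivity contrasts;
   second-level covariate maps; small-volume correction with BH across ROIs.
5. **Behavior.** Overnight forgetting Δerror = Test2 − Test1 placement
   error (cm, positive = forgetting), Kendall τ_b brain–behavior
   associations, and the Williams–Hotelling t (df = n − 3) for comparing
   two dependent correlations sharing a variable.

Because no subject data are distributable, the package ships a first-class
synthetic generator (`tmrconn.synthesize`) that emulates the stimulation
protocol exactly (50 cue / 25 control trials in blocks of five, 4–8 s
jittered ISIs, TR = 2.511 s), plants a modular correlation structure on a
115-parcel contiguous atlas, adds a cue-specific cross-module coupling
boost at one "occipital" seed parcel, and couples that boost negatively to
overnight forgetting across subjects — so every stage of the pipeline can
be validated against a known truth.

## Worked example

A desk-scale demo (6 subjects, 12³ voxel grid, 115 parcels) from the shell:

```bash
tmrconn all --config examples/demo_config.yaml --workdir demo_run --seed 7
```

This simulates the cohort, fits the trial-wise GLMs, builds and thresholds
the graphs, maps participation coefficients, and runs group and behavioral
statistics. With seed 7 the run prints/writes (`demo_run/clusters_pc.tsv`,
`demo_run/behavior_stats.json`):

```
Region     X  Y  Z   Peak Z-value  Cluster Size  P-value
cluster_1  6  2  10  3.135         12            0.017
cluster_2  6  7  9   2.785          9            0.017
...
overall forgetting: mean 0.573 cm, sem 0.124, t(5) = 4.61, p = 0.0058
kendall: tau = -0.467, p = 0.260
pc_increase per subject: 0.481 0.650 0.042 0.268 0.156 0.555
```

Reading these numbers: the two largest permutation-significant clusters of
increased cue-vs-control participation (corrected p = 0.017) overlap the
planted seed parcel (mean z over the seed parcel 2.31 vs 0.65 brain-wide);
every subject's mean PC increase at the seed is positive; subjects forget
overnight (Δerror > 0, t-test on 6 subjects); and the planted negative
coupling between network integration and forgetting appears with the
expected sign (τ = −0.47) though 6 subjects are too few for significance —
at the study's n = 22 the recovery power exceeds 0.8 (see the test suite).

The same pipeline is available as a library:

```python
from tmrconn import RunConfig, run_cohort
parcellation, boosts, results = run_cohort(RunConfig(n_subjects=22, seed=1))
```

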