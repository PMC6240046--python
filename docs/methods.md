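# Methods

This note documents the models, defaults and numerical choices behind
`tmrconn`, and what the synthetic validation does and does not establish.

## Trial-wise GLM (beta series)

Each sound presentation is modelled as a boxcar of `model_duration` (5 s,
deliberately longer than the 500 ms sound, reflecting uncertainty about
when and for how long a cue-induced reactivation unfolds) convolved with
the canonical double-gamma HRF (response peak 6 s, undershoot 16 s,
dispersions 1 s, peak:undershoot ratio 6, 32 s kernel, unit-sum
normalised). All trials enter one GLM ("least-squares-all"), together with
six motion and three compartment nuisance series; a least-squares-separate
variant is not implemented. High-pass filtering uses the discrete-cosine
basis with `floor(2T/cutoff)` regressors (cutoff 128 s), applied by
residualising both the data and the non-DCT regressors against the
constant-plus-DCT subspace — algebraically identical to including the DCT
columns, and it keeps the reported coefficient block small.

Prewhitening is one Cochrane–Orcutt iteration: OLS fit, per-node lag-1
residual autocorrelation ρ̂ (clipped into (−0.99, 0.99) with a warning if
it saturates), exact stationary AR(1) transform of data and design
(first sample scaled by √(1−ρ²)), refit. A pooled-ρ shortcut is not
enabled by default. The acceptance suite verifies that the sampling
variance of this estimator matches the closed-form variance of the
known-ρ GLS estimator at 1,000 replicates; the small (~2–6%) inflation
from estimating ρ on finite runs sits inside the Monte-Carlo tolerance.

Rank deficiency is reported by name using QR column pivoting. Identical
duplicated onsets are rejected up front for the same reason.

## Graphs, modules and the participation coefficient

Connectivity is the Pearson correlation of beta series across trials,
diagonal zeroed. Edge-level significance uses the t-transform of r with
n_trials − 2 df; Benjamini–Hochberg runs at q = 0.05 **per condition over
that condition's unique edges** — the literal reading of thresholding each
condition's matrix, even though cue (n = 50) and control (n = 25) then
face different critical correlations. Negative edges are removed
unconditionally after p computation (order is irrelevant as removal does
not depend on the BH outcome).

Community detection follows the two-step coarse-to-fine procedure:
weighted Louvain (γ = 1) on the 115-parcel graph only, 100 random-restart
passes keeping the highest modularity Q, ties broken toward the
lexicographically lowest canonical labelling; Q is always re-evaluated
directly from the modularity formula rather than trusted from the solver.
Voxels inherit their parcel's module, and the participation coefficient is
computed on the fine thresholded graph. Zero-strength nodes get PC = 0 by
convention. The attainable supremum is 1 − 1/M for M modules, asserted on
all outputs; the informal description of PC "up to 1" is not treated as a
testable claim.

## Group statistics

Paired node-wise t-tests convert to z by the signed probit transform of
the two-sided p (mirroring the common display convention), capped at
|z| = 37 where p underflows. Zero-variance nodes are flagged and excluded
from clustering. The cluster-forming threshold default is Z > 2.33,
one-sided in the contrast's reported direction; clusters are face-connected
(6-neighbour) components — configurable to 18/26, with 6 chosen as the
stricter convention. The primary corrected inference is sign-flipping
permutation on the maximum cluster extent, corrected
p = (1 + #{null ≥ observed}) / (1 + n_perm). A Gaussian-Random-Field
approximation (residual-smoothness FWHM estimate plus the standard
expected-cluster-size formula) is provided for comparison only; it is
approximate by construction and is not used by the validation suite.

Small-volume correction restricts cluster inference to each named ROI
mask, takes the ROI's minimum corrected cluster p, and applies the
Benjamini–Hochberg critical-p rule across ROIs (the largest sorted p(i)
with p(i) ≤ i·q/m, 0 if none).

Second-level covariate maps regress subject contrast maps on a
mean-centred covariate (slope t, df = n − 2); exact fits flag a capped
statistic instead of overflowing. Seed contrasts are implemented as the
paired t-test of per-condition Fisher-z seed-correlation maps, which makes
the internal-consistency identity with `paired_t_map` structural; r is
clipped at |r| = 0.999999 before atanh.

## Behavioral statistics

Δerror is fixed as Test 2 − Test 1 (positive = overnight forgetting);
summaries are reported overall and split by cueing, and the cued-vs-uncued
comparison is a paired t on (Δ_cued − Δ_uncued), the two-level equivalent
of a repeated-measures F (F = t²). Kendall's τ is the tau-b variant with
tie correction, with a normal-approximation p using the tie-corrected
variance of S and a continuity correction of 1. The Williams–Hotelling
statistic for two dependent correlations sharing one variable uses
df = n − 3 and requires the 3 × 3 correlation matrix to be positive
semidefinite.

## The synthetic generator

The generator reproduces the stimulation protocol exactly: 25 cue sounds
twice and 5 control sounds five times, grouped in condition-homogeneous
blocks of five (the 2:1 trial ratio with five-presentation blocks implies
10 cue + 5 control blocks; mixed blocks are the other possible reading of
the protocol and are not modelled), 500 ms sounds, uniform 4–8 s jitter
after every presentation, randomised block order, TR = 2.511 s, run length
sized to the events plus a 30 s tail. The default spatial scale is a
12 × 12 × 12 voxel grid carrying a 115-parcel contiguous random
parcellation (randomised multi-source flood fill), a desk-scale stand-in
for a whole-brain anatomical atlas; all problem sizes in the validation
suite (22 subjects, 12³ grids, 100–2,000 replicate calibrations) are the
package's chosen desk-scale defaults.

Trial-wise parcel amplitudes are multivariate normal with unit variances:
within-module correlation 0.6, between-module 0.1, five modules. In the
cue condition only, `seed_cross_boost` is added to the correlations
between one seed parcel and all parcels outside its module; boosted
matrices are projected to the nearest positive-definite matrix by
eigenvalue clipping at 10⁻⁶. Voxel amplitudes are their parcel's amplitude
plus idiosyncratic scatter (sd 0.1). Time series add a slow sinusoidal
drift, smooth random-walk motion/compartment nuisance contributions, and
AR(1) noise (ρ = 0.3, sd 0.3).

The noise level deserves a word. The trial regressors of this protocol are
strongly collinear (5 s boxcars, ~6 s mean ISI), so the per-trial beta
standard error is roughly twice the residual sd. The generator emulates
*analysis-ready* data — preprocessing, including spatial smoothing, is out
of scope — so its residual sd (0.3 in amplitude units) represents the
post-smoothing noise level at which beta-series correlations take
realistic values (within-module ≈ 0.4–0.5 after attenuation). At
substantially higher noise the 25-trial control graph fragments after FDR
thresholding and no analysis of this design could recover the planted
structure; that regime is a property of the protocol, not of the
implementation.

Behavior: per-item Test 1 errors are truncated normal at 0 cm (resampling)
around a subject mean (population 2.74 cm, between-subject sd 0.5, item
sd 0.85); Test 2 adds per-subject forgetting (mean 0.37 cm, sd 0.25) plus
item retest noise (sd 1.0), truncated at 0. The per-subject forgetting
decreases linearly in the subject's *mean-centred* integration boost
(slope −2.5 cm per unit boost; centring keeps the population mean
forgetting fixed so the net-forgetting invariant holds independently of
the coupling). Cued items carry the full slope, uncued items 0.6 of it,
emulating a context-general rather than item-specific benefit. The
coupling default is a deliberately strong scenario: it yields τ ≈ −0.55
and ≥ 0.8 recovery power at n = 22, the regime the planted-effect
validation is defined on.

## What the synthetic validation does and does not show

Passing tests establish that the implementation computes what it claims:
oracle-exact graph metrics, calibrated type-I/FWER behaviour of every
second-level statistic under their null simulations, unbiased GLM
estimates with correct GLS-level variance, and end-to-end recovery of a
planted effect whose generating mechanism matches the analysis
assumptions. They do not show that the pipeline would detect such effects
in real sleep fMRI: the generator has no anatomy, no spatially correlated
noise, no motion-by-signal interactions, no sleep-stage nonstationarity,
and its amplitude covariances are exactly block-structured. Reported
real-data quantities (peak coordinates, z-values, τ = −0.311 and similar)
depend on unavailable subject data; only design constants and
arithmetically checkable values (the ROI-table BH critical p-values 0.031
and 0.038) are reproduced numerically.

## Known limitations

- GRF cluster p-values are a rough approximation; use permutation.
- Louvain is stochastic; results are seed-pinned with 100 restarts, but a
  different restart budget can change tie regions of the partition.
- The Cochrane–Orcutt single iteration underestimates autocorrelation on
  very short runs; runs under ~60 scans should use `ar1="none"` or longer
  designs.
- Voxel-level graphs are dense in memory (O(V²)); the default grid keeps
  V ≤ 2,000.
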