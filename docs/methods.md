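# Methods

This note documents the models and procedures `sentstruct` implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Parse structures

A sentence's structure is a rooted dependency tree: every token points at
its head, the main verb is the root, and a token's *parse depth* is its
edge count to the root (root = 0, `depth(w) = depth(head(w)) + 1`).
Token positions are 1-based; the CoNLL-U convention HEAD = 0 marks the
root.  Validation rejects multiple roots, cycles, self-heads and
out-of-range head indices, naming the offending token.

The temporarily ambiguous target sentences carry two whole-sentence
parses.  In the passive parse the first verb (V1) heads a reduced
relative clause attached to the subject noun (depth 2); in the active
parse V1 is the root (depth 0).  The *landmark vector* of an
interpretation for a k-word prefix is the full tree's depth vector
sliced to the prefix — landmarks are static because the reference parses
are whole-sentence objects.  For the canonical (determiner, subject noun,
V1) prefix the landmarks are (2, 1, 2) and (2, 1, 0).  Fixture-tree
attachment conventions (preposition to the verb it modifies, its noun to
the preposition, determiners to their nouns, auxiliaries to their main
verb) are encoded in the CoNLL-U fixtures, not in code.

## Structural probe

The probe is a linear map `B` (k x d) on contextual word embeddings `h`;
the predicted parse depth of a word is `‖B h‖²`.  Training minimises the
L1 error between predicted and gold depths, normalised per sentence by
sentence length — the established objective for this probe family; the
probe rank k defaults to d and is configurable.  The optimiser is
full-batch Adam (learning rate 0.02, halved after 50 non-improving
iterations, stop at relative tolerance 1e-6 or 2000 iterations).  A
plain fixed-step subgradient method cannot reach the sub-1e-3 accuracy
the noiseless identifiability property requires — with a nonsmooth
objective it oscillates at the step size — so an adaptive optimiser is
used while the loss itself is kept L1.

Training restarts 10 times from random initialisations; the returned
model is the restart with the lowest loss, and depth predictions are
averaged across restarts *in depth space* (not transform space, where
averaging is meaningless because `B` is only identified up to rotation).
*Root accuracy* is the fraction of sentences whose minimum predicted
depth falls on the main verb when the whole sentence is input; a
non-unique minimum counts as incorrect.  Position contributions are
measured by shuffling one position's depths across sentences and
averaging the Spearman distance (1 − rho) between original and shuffled
vectors.

## Constraint measures

With raw counts and smoothing constant s (default 0; zero denominators
are an explicit error, and the synthetic generator guarantees positive
counts):

* agenthood = (agent + s) / (patient + s); patienthood its reciprocal;
* transitivity = (DO frames + s) / (other frames + s); intransitivity
  its reciprocal;
* passive index = patienthood × transitivity; active index = agenthood ×
  intransitivity (their product is 1 at s = 0);
* non-directional index = log(agenthood) × log(intransitivity), fixed to
  the agent-side sign convention.  Logging before multiplying removes
  directionality: jointly replacing both ratios by their reciprocals
  leaves it unchanged, which the directional indices do not satisfy.

Contextual analogues come from continuation counts: DO probability after
V1 gives contextual transitivity DO/(1 − DO) (probabilities of exactly 0
or 1 are clipped at 1e-3 with a warning); the main-verb probability
after the prepositional phrase indexes the passive reading directly.

Permutation Spearman correlation permutes y, uses the add-one estimator
p = (1 + #{|rho_perm| ≥ |rho|}) / (n_perm + 1), and defaults to the
two-sided alternative (the conservative reading for signed
correlations); one-sided variants are available.  Multiple testing uses
Benjamini–Hochberg.  The summary-statistics two-sample t uses pooled
variance with df = n1 + n2 − 2; it exists so printed group contrasts
(e.g. the verb-set transitivity contrast at df 117) can be reproduced
without raw data.

## Interpretation geometry

Distances in the 3-D (Det, SN, V1) model space are Euclidean by default;
the cosine form is reserved for the *interpretative mismatch* (1 − cosine
similarity between an estimated incremental depth vector and a landmark,
smaller = stronger preference), which is scale-invariant by
construction.  Trajectory step deltas are consecutive-step distance
differences (negative = movement toward that landmark) and telescope to
the net change.  PCA is computed per prefix position across sentences;
component signs are fixed by making each component's largest-magnitude
loading positive.  Model RDMs use absolute difference for scalars and
cosine distance for vectors; all RDM constructors enforce symmetry, zero
diagonal and finite entries, and serialised RDMs carry a JSON sidecar
with the condition order so order mismatches are detectable.

## Spatiotemporal searchlight RSA

A searchlight is the set of vertices within 10 mm (Euclidean in source
coordinates; a precomputed distance matrix can be supplied for geodesic
use) crossed with a ±30 ms window (60 ms total), clipped at epoch edges
rather than dropped; window centers default to every sample with a
configurable stride.  Per sentence the searchlight pattern is the
flattened vertices × samples block; the data RDM is pairwise Pearson
correlation distance (1 − r).  Optional multivariate normalization
whitens channels by the inverse square root of a shrinkage covariance
(sample covariance shrunk 0.4 toward its own diagonal) estimated from
trial-mean-removed patterns within the searchlight.

Model fit is Spearman rho between the lower triangles of model and data
RDM.  Group inference: one-tailed one-sample t across participants at
every vertex/time; nodes above the t quantile at vertex-wise p = 0.01
(df = n − 1) form clusters; connectivity links vertices within the
cluster radius (default = searchlight radius) at the same window and the
same vertex at consecutive windows.  Clusters are scored by summed t and
compared with the maximum-cluster-mass null over 5000 random
whole-map sign flips per participant (the standard permutation scheme
for a one-sample design; exhaustive flips with a warning when 2^n is
smaller); cluster-wise threshold p < 0.05.  Summaries: vertex t-mass
(summed t over a vertex's significant samples), per-cluster t-mass time
series, and ROI peak-t series when region labels exist.

## NMF and Granger causality

Per participant, whole-brain fit maps are z-scored per vertex over time,
concatenated along time, and negatives are zeroed.  NMF uses
multiplicative updates (Frobenius objective, which the updates make
non-increasing; traces are recorded), 20 random restarts per candidate
rank, and rank search 2–50 by least best-of-restarts RMS residual.
Because the Frobenius RMS of an exact best factorisation is
non-increasing in rank, on noisy data this criterion drifts toward the
top of the searched range; it is retained as the stated procedure, and
pipeline runs use a narrower range.

Granger causality fits one joint VAR over both factor sets, pooled
across participants (participants are independent realisations; a
per-participant mode is available), with AIC order selection up to
max_order and a stability guard (spectral radius < 1, else connections
are flagged).  The statistic per directed pair is time-domain
conditional GC: log of the ratio of the target's residual variance with
the source's lags removed vs the full model — invariant to separate
linear rescaling of each series.  Significance uses 1000 surrogates
built by shuffling contiguous windows of length = model order of the
source series (trailing partial windows stay in place), add-one p
values, a generalised-Pareto tail fit to the top 10% of surrogate values
for p < 0.005 (falling back to the permutation p when the fit fails or
the observation is below the tail threshold), and BH-FDR over all
tested connections.

## Synthetic data: what it emulates and what it does not

Defaults mirror the study conditions: 60 sentence sets × 6 sentences
(two ambiguous targets per set, 120 targets), 16 participants, 600 ms
epochs at 200 Hz (120 samples), continuation pre-tests with 30 and 18
respondents.  Each target draws a latent log-transitivity from its
condition's calibrated distribution — means 0.895 (high transitivity)
and −0.241 (low), i.e. direct-object probabilities 0.71 and 0.44, sd
0.78 chosen by the delta method to give probability sds near 0.16/0.19 —
and that one latent drives every downstream bias: corpus counts
(with patienthood coherently tracking transitivity, slope 0.6),
continuation counts, and the interpretation schedule.

Embeddings plant the depth code exactly: for target depth δ, a vector
`h` is built with `‖B0 h‖² = δ` (plus probe-invisible null-space
variance and optional Gaussian noise).  Scheduled depths blend the
active parse toward the passive parse as the prefix grows — all targets
start active-biased, the blend weight during the prepositional phrase
follows the verb's transitivity, and the main verb forces the passive
parse — plus per-sentence, per-word depth jitter (sd 0.15) so sentences
spread around the context-free depths instead of collapsing onto them.

Source epochs are Gaussian noise with exponential spatial covariance
(length scale 15 mm) and white temporal structure, independent per
participant, over a random vertex cloud (default 200 vertices in a
70 mm box, matching a real mesh's per-searchlight vertex count rather
than its geometry).  Effects are planted by classical-MDS embedding of
the target RDM (rank ≤ 10) mapped onto random orthonormal spatiotemporal
patterns inside the effect's vertex set and window, scaled by effect
size × noise sd; overlapping effects with contradictory RDMs are
rejected.  Word timing metadata (onsets, uniqueness points, offsets) is
generated for annotation only.

Not emulated: real cortical geometry and forward-model noise structure
(temporal autocorrelation, 1/f spectra, inter-participant anatomical
variability), real lexical content, and any transformer inference.
Passing tests therefore demonstrate the statistical machinery — error
control, recovery, identifiability — under the stated noise model, not
performance on real recordings.

## Problem sizes used in tests

Test and demo runs scale the study conditions down while keeping the
statistical structure: the family-wise-error check uses 200 null
simulations with 12 participants, a 50-vertex mesh and 500 permutations;
planted-effect recovery uses 20 datasets of 60 sentences; Granger
direction specificity uses 20 simulations of 8 participants × 200
samples with 200 surrogates; the packaged demo pipeline uses 20 sets, a
50-vertex mesh and 12 participants.  These sizes are the package's demo
conditions; all defaults remain at study scale.

## Known limitations

* The probe optimiser is first-order; on adversarially conditioned
  embedding distributions convergence to the stated tolerance is not
  guaranteed (restarts mitigate).
* Cluster-level inference licenses statements about clusters, not about
  individual vertices within them; absorbed chance neighbors are
  expected.
* The NMF rank criterion (least RMS) is retained from the stated
  procedure despite its monotone tendency; users wanting parsimony
  should narrow `k_range` or add their own elbow criterion.
* GC pooling assumes a common VAR across participants; heterogeneous
  coupling violates this and is only partially addressed by the
  per-participant mode.
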