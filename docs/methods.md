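# Methods

This note documents the models, parameter choices and numerical decisions
behind `tonepred`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus model

Tone sequences are first-order Markov chains over four carrier frequencies
(log-spaced 200–2000 Hz; 100 ms tones with 5 ms fades — fade duration is
carried as metadata only, no audio is synthesised) presented isochronously
at 3 Hz. A condition's transition matrix places 0.25 on the diagonal,
`p_dom` on each tone's dominant successor (a fixed-point-free permutation,
cyclic by default) and splits the remainder equally. This family is doubly
stochastic for any `p_dom` in [0.25, 0.75], so the stationary tone
distribution is uniform in every condition and tone frequency is never
confounded with condition.

The two intermediate conditions are not uniquely determined by a verbal
description of "intermediate" regularity; we take `p_dom` linearly spaced
(0.25, 5/12, 7/12, 0.75), which preserves the 25% diagonal, double
stochasticity and a strictly decreasing entropy rate (2.000, 1.888, 1.551,
0.811 bits/transition). The four `p_dom` values are configurable so any
alternative intermediate matrices can be substituted.

Block generation: sequences are resampled (fresh sub-seed, ≤100 attempts)
until each tone count is within ±10% of n/4 ("balanced" blocks); omissions
(10% of stimuli, exactly n/40 per tone class) are placed uniformly at
random within class under two constraints — none in the first three events,
and never two in a row. The adjacency constraint prevents the downstream
exclusion of "sounds preceded by an omission" from cascading. The omitted
event records the tone that would have been presented; removing the flags
reproduces the tone sequence exactly.

Sampling tolerances: at 40,000 steps the per-entry standard error of the
empirical transition matrix is ≈0.005 (row counts ≈10,000), so entrywise
checks use a 3.5-SE band while the designed scalar quantities (25%
self-repetition, 75% dominant transitions), which average four entries, are
held to ±1 percentage point.

## Synthetic sensor data

Each subject's epochs (−1000…+1000 ms around event onset, 100 Hz, 201
samples) are generated as a sum of:

* **evoked response**: a gamma-like kernel (t/p)·e^(1−t/p), unit peak at
  p = 100 ms, times the tone's sensor topography; absent on omissions;
* **persistence**: the previous tone's evoked kernel launched one SOA
  (333 ms) earlier and decaying with τ = 400 ms, scaled by 0.3 — a
  memory-trace component that makes pre-onset decoding of the *previous*
  tone possible, as a time-generalization analysis assumes;
* **anticipation**: the expected tone's topography under a raised-cosine
  envelope in [−250, 0] ms, amplitude a·g_c (default a = 0.6). The expected
  tone is the dominant successor of the previous tone; the predictability
  index g_c = (p_dom − 0.25)/0.5 is 0, 1/3, 2/3, 1 for RD→OR, so no
  anticipation exists in the random condition by construction;
* **omission response**: on omission trials, the expected tone's topography
  in [0, 250] ms, amplitude o·g_c (default o = 0.6);
* **entropy signature**: a fixed random per-condition sensor offset,
  amplitude e (default 0.15), the slow block-wise component that makes the
  entropy level decodable from single trials; optionally jittered across
  subjects (`entropy_gain_sd`) to create the between-subject variability
  needed by correlation analyses;
* **noise**: zero-mean Gaussian with exponential spatial covariance
  (length 0.3 over a random planar sensor embedding), band-limited to 30 Hz
  by direct spectral synthesis (white spectrum truncated at the cutoff,
  inverse FFT, analytic variance normalisation), sd 1.0; and a
  multiplicative log-normal per-trial amplitude jitter (sd 0.1) on the
  signal components.

Topographies are unit-norm columns built as √c·(shared direction) +
√(1−c)·(orthogonalised residual), so the pairwise class correlation equals
c (default 0.5) exactly in expectation — emulating the high topographic
overlap of tonotopic sources without any biophysical forward model.

What the generator deliberately does **not** emulate: realistic sensor
geometry or lead fields, eye/heart artifacts, non-stationary noise, 1/f
spectra, or the amplitude of real evoked fields. Passing recovery tests
therefore shows that the analysis chain is correct and powered for effects
of the injected form, not that real recordings contain such effects or that
real-data accuracies would match.

Default effect amplitudes were chosen once so that single-trial decoding is
non-trivial (accuracies far from both chance and ceiling at realistic trial
counts); they are configuration parameters, not calibrated claims about
physiological effect sizes.

## Decoding

Multiclass LDA with scores x·W_k + b_k, W_k = Σ̂⁻¹m_k,
b_k = −½m_kᵀΣ̂⁻¹m_k + log(1/K), where Σ̂ = (1−λ)Σ_pooled + λ(trΣ/d)I.
λ defaults to Ledoit–Wolf analytic shrinkage computed on the class-centred
residuals (equivalent to `sklearn.covariance.ledoit_wolf_shrinkage` with
`assume_centered=True`; the batched per-time implementation is tested
against it). Priors are uniform — balancing makes classes near-equal — and
argmax ties resolve to the lowest class index. Per-train-time fits are
vectorised over time; the vectorised path is tested for exact equivalence
with the single-time reference implementation and with a brute-force
evaluation of the discriminant equations.

Cross-validation is stratified 5-fold × 5 repeats with fold assignment
re-drawn per repeat from the scheme seed; accuracy is the plain proportion
correct. Cross-decoding (RD-trained → other conditions, sounds → omissions)
uses the full training set with no folding; train and test sets are
required to be disjoint. N−1/N balancing subsamples, within each target
class, all previous-class cells to the minimum cell count; it is performed
once per scheme per seed (not re-drawn per CV repeat) and is invariant (as
a multiset of kept cells) to input trial order. Note that strictly ordered
sequences cannot be N−1/N balanced — two transitions per class have
probability zero — which is precisely why the design trains on the random
condition only.

W1/W2 training windows default to 75–125 ms and 125–333 ms; an alternative
early window of 50–125 ms is available via configuration (both variants are
in circulation for this analysis family; we default to the one printed in
the statistical-analysis description of the source design).

## Activation patterns

For extraction filters W, the forward-model patterns are
A = Σₓ W Σₛ⁻¹ with Σₛ the covariance of the discriminant scores
(pseudo-inverse when rank-deficient). For K classes the discriminants are
first centred across classes: only the (K−1)-dimensional contrast subspace
carries class information, and the common mode is a near-degenerate score
direction whose inverse amplifies noise. Exact identities tested: with
white data and a single discriminant A ∝ W; for a 1-D forward model
x = t·s + noise the generating topography t is recovered up to sign/scale
(r > 0.95 at SNR ≥ 5). For multiclass problems with correlated noise the
exact correction equals M̃·pinv(M̃ᵀΣₙ⁻¹M̃) (M̃ the centred class means),
a mildly mixed basis of the centred topographies — the informative
*subspace* is identified (principal-angle cosines > 0.95 in tests), the
individual columns only approximately. Σₓ is estimated per train-time point
on the same trials as the classifier. Spatial filters (e.g. beamformers)
are consumed as user input, never constructed.

## Group statistics

The dependent-samples regression computes, per subject and map location,
the least-squares slope of accuracy on the condition code (1…4, random →
ordered) and a one-sample t of slopes against zero (df = n−1). It is
invariant to affine recoding of the codes up to the sign of the scale.
Locations with zero slope variance across subjects are returned as t = 0
when the mean slope is also zero and flagged NaN otherwise.

Cluster inference thresholds the t map at the per-tail α = 0.025 quantile,
forms 4-connected clusters on the train×test lattice, scores them by summed
t, and builds the null by permuting condition codes independently within
each subject (the exchangeability unit). For two-tailed tests each cluster
is compared against the null distribution of the maximum |cluster mass|
over both tails; using per-tail maxima would double the family-wise rate.
p = (1 + #{null ≥ observed})/(n_perm + 1), bounded below by the permutation
resolution. Degenerate permutations with zero slope variance contribute
zero mass. Spearman correlation maps use the t transform
ρ√((n−2)/(1−ρ²)) with average ranks for ties and permute the covariate
across subjects; permuting the covariate is a permutation of its ranks, so
all null maps are computed in a single matrix product. W1 and W2 are
analysed separately without cross-window correction.

Family-wise error control and the stochastic dominance of null p-values
over the uniform distribution are verified by simulation in the test suite
(500 null datasets × 200 permutations for the error rate; the empirical
rate must stay below 0.065 at nominal 0.05).

## Problem sizes and scale presets

Full-scale defaults mirror the experimental design (4000 stimuli/block,
10,000 permutations, 102 sensors). The `desk` preset (102 sensors, 20
subjects, 2000 stimuli, 2000 permutations) and `ci` preset (32 sensors, 12
subjects, 880 stimuli, 1000 permutations) trade trial counts for runtime;
`ci` keeps the printed 10% omission rate (88 omissions, 792 sounds per
block). The replicate parameter-recovery experiment runs at a further
reduced scale chosen for throughput on a single CPU — 8 subjects, 24
sensors, 440 stimuli/condition, training grid −100…350 ms, testing grid
−350…350 ms, 500 permutations — at which the injected anticipation effect
is reliably detected and the no-effect arm reliably yields none.

## Reproducibility

All randomness flows from one master seed through documented
`numpy.random.SeedSequence` spawning; per-block, per-subject and per-stage
sub-seeds are recorded in the run report. Re-running any deterministic
stage with the same configuration and seed reproduces its outputs
bit-identically (runtimes are kept out of the serialized report for this
reason). Epoch tensors and accuracy maps persist as `.npy` arrays with CSV
sidecars; round-trips are bit-exact.

## Known limitations

* The generator's linear-superposition signal model cannot probe failures
  specific to nonlinear or non-stationary neural responses.
* The entropy signature is a constant offset, so entropy-level decoding in
  the simulation is easier and more temporally uniform than in real data.
* The regression permutation scheme permutes condition labels within
  subjects; alternative schemes (e.g. sign-flipping subject slopes) are not
  implemented.
* Cluster connectivity is fixed to the 4-neighbourhood of the train×test
  lattice.
* Reading real MEG recordings is out of scope; an adapter would need to
  epoch, downsample to 100 Hz and label trials to produce an `EpochSet`.
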