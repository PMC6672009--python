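# tonepred

Feature-specific auditory prediction analysis on synthetic MEG-like data:
entropy-graded Markov tone sequences with omissions, time-generalized
multiclass decoding, covariance-corrected activation patterns, and
cluster-based permutation group statistics.

## The scientific problem

When a listener is exposed to an isochronous sequence of pure tones whose
order follows a first-order Markov chain, the brain forms predictions about
*which* tone comes next — not just *when*. If those predictions are
feature-specific, the sensor pattern associated with a tone's carrier
frequency should be decodable **before** the tone plays (anticipatory
preactivation), and even when an expected tone is **omitted** (a silent gap
where feedforward input is absent). Both effects should grow as the
sequence becomes more ordered.

`tonepred` implements this analysis end-to-end and exercises it on a
synthetic sensor-data generator with injectable, recoverable ground-truth
effects, so that every stage — sequence design, decoding, pattern
extraction, inference — is verifiable against known truth. It is aimed at
researchers who want a tested reference implementation of the method chain,
or a harness for power/validity studies of it.

## The design and the model

**Stimuli.** Four tones, log-spaced 200–2000 Hz (200, 431, 928, 2000 Hz),
100 ms each, presented at 3 Hz in blocks of 4000 stimuli (~22 min). Four
conditions differ only in the transition matrix: random (RD), midminus
(MM), midplus (MP), ordered (OR). Every matrix has 25% on the diagonal
(self-repetition controlled across conditions) and is doubly stochastic;
the probability of each tone's designated successor rises linearly
(0.25, 5/12, 7/12, 0.75). The Markov entropy rate
H = Σᵢ πᵢ (−Σⱼ Tᵢⱼ log₂ Tᵢⱼ) then decreases strictly:

```
RD: p_dom=0.2500  H=2.0000 bits
MM: p_dom=0.4167  H=1.8879 bits
MP: p_dom=0.5833  H=1.5511 bits
OR: p_dom=0.7500  H=0.8113 bits
```

10% of stimuli are replaced by omissions, exactly 100 per tone class per
block, never consecutively.

**Decoding.** Per time point, a multiclass shrinkage-LDA
(w_k = Σ̂⁻¹ m_k with Σ̂ = (1−λ)Σ_pooled + λ(trΣ/d)I, Ledoit–Wolf λ) is
trained on sensor vectors and tested at every other time point, giving a
train×test accuracy map (chance 1/4). Carrier-frequency decoders are
trained only on random-sequence sounds (5-fold × 5-repeat CV within RD;
pure cross-decoding to MM/MP/OR sounds and to omissions, which are labelled
by the tone that *would* have been presented). Sounds preceded by an
omission are discarded, and the training set is N−1/N balanced so each
target class is preceded equally often by every tone.

**Patterns.** Classifier weights are converted to interpretable activation
patterns via the data covariance, A = Σₓ W Σₛ⁻¹ (with the class
discriminants centred; see `docs/methods.md`), and can be projected through
user-supplied spatial filters.

**Statistics.** Entropy dependence is tested by a dependent-samples
regression (per-subject slope of accuracy on entropy rank, one-sample t
across subjects) with a 2-D cluster-based permutation test (4-connected
clusters, summed-t mass, per-tail cluster-forming α = 0.025, within-subject
permutation of condition codes). Time courses use Bonferroni-corrected
pointwise tests; across-subject effects use Spearman correlation maps with
cluster permutation.

## Worked example

```python
import tonepred as tp
from tonepred.decoding import TimeGeneralizationDecoder, drop_post_omission, balance_n1n

design = tp.BlockDesign(n_stimuli=440, omission_rate=0.10)
cohort = tp.simulate_cohort(n_subjects=2, n_sensors=24, design=design, seed=0)
ep = cohort.subjects[0]

rd = drop_post_omission(ep).where(condition="RD", event_type="sound")
kept = balance_n1n(rd.labels["tone_class"].to_numpy(),
                   rd.labels["prev_tone_class"].to_numpy(), seed=0)
rd = rd.select(kept)
res = TimeGeneralizationDecoder(rd, rd.labels["tone_class"].to_numpy(),
                                train_window_s=(-0.2, 0.4),
                                test_window_s=(-0.2, 0.4)).fit(seed=0)
print(res.summary())
```

prints

```
Time-generalization decoding results
====================================
scheme:          {'cv': '5x5', 'cross_decoding': False, 'shrinkage': 'auto'}
train times:     -200..400 ms (61 points)
test times:      -200..400 ms (61 points)
train trials:    292
test trials:     292
chance level:    0.250
mean accuracy:   0.3226
peak accuracy:   0.6363
```

292 trials survive exclusion and balancing out of 396 RD sounds; the
decoder is far above the 0.25 chance level around the evoked response
(peak 0.64 near train=test≈100 ms) and the mean over the whole map stays
above chance because the simulated response persists beyond the stimulus.

The full pipeline — cohort simulation, sound- and omission-locked
time-generalization, entropy regression with cluster permutation, W1/W2
window courses, entropy-level decoding, Spearman correlation, Haufe
patterns — runs from the command line:

```
tonepred full --scale ci --seed 7 --out run1 --verbose
```

and writes maps, cluster tables, pattern tables, and a reproducible
`report.json`/`report.txt` into `run1/`.

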