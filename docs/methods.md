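# Methods

`evoseizure` implements a patient-specific, evolutionary approach to EEG
seizure prediction: a genetic algorithm (GA) searches for a set of five
*hyper-features* — windowed, operator-aggregated first-level EEG features
placed on a pre-seizure timeline — whose quality is judged by the end-to-end
performance of a logistic-regression predictor with Firing-Power alarm
regularisation. This note records the model, the numerical choices, the
design decisions that were genuinely open, and what the synthetic data can
and cannot show.

## Signal model and first-level features

Scalp EEG (19 channels, 10–20 montage, 256 Hz) is notch-filtered at 50 Hz
(Q = 30) and band-passed 0.1–120 Hz. Both stages run forward–backward
(zero phase) as one cascade of second-order sections. The bandpass is a
Butterworth with eight biquad sections: with the textbook fourth-order
design, a second pass through the filter changed broadband RMS by ~1.3%,
which breaks the intended idempotence of pre-processing; the steeper filter
brings the second-pass change below 1%.

The record is segmented into non-overlapping 5-s windows (half-open
`[start, start + 5)`; timestamps are window starts). Per window and
electrode, 12 features are extracted:

* relative spectral power in delta (0.5–3.5 Hz), theta (4–7.5 Hz), alpha
  (8–12 Hz), beta (13–35 Hz) and three gamma sub-bands (36–50, 51–70,
  71–90 Hz), each normalised by total power over 0.5–90 Hz;
* average power (mean PSD over 0.5–90 Hz) and mean normalized frequency
  (spectral centroid, Hz);
* normalized mean amplitude (`mean|x| / max|x|`), mean amplitude
  (`mean|x|`, also addressable under the alias *medium temporal intensity*)
  and amplitude variance.

The PSD is a Welch estimate with 1-s Hann segments at 50% overlap — a
variance-reducing choice for 5-s windows; the estimator is implemented as a
batched strided-view FFT that is numerically identical to the reference
Welch routine and to applying the single-window operations one window at a
time. All-zero windows are flagged degenerate and yield zeros, never NaNs.

## Genotype and decoding

Each individual is exactly five hyper-features; each hyper-feature carries
seven genes: a dominant-feature flag (band-wave vs non-band-wave), a
band-wave feature (one of the 7 relative powers), a non-band-wave feature
(one of the 5 remaining features), a mathematical operator
(mean, median, variance, max, min), an electrode, a window length
(1, 5, 10, 15, 20 min) and a time instant (0–20 min before the minimum
pre-ictal boundary). Every gene has a neighbourhood graph: ordinal genes are
chains in natural order, the electrode gene uses the 10–20 scalp adjacency,
the categorical genes are chains in listed order, and the dominant flag is a
two-node graph. Mutation is a unitary step to a neighbour; recombination
pairs the two parents' hyper-features by temporal rank (time instant, ties
by electrode order) and draws each offspring gene uniformly from the union
of nodes on all shortest paths between the parent values (endpoints
included).

Decoding expresses the dominant feature of each hyper-feature, and derives
the timeline: the pre-ictal duration is the configured minimum pre-ictal
period (40, 50 or 60 min) plus the largest time instant; the seizure
occurrence period (SOP) is that duration minus the fixed 10-min seizure
prediction horizon (SPH). Example: minimum 40 min with maximum time instant
15 min gives a 55-min pre-ictal period and a 45-min SOP.

## Fitness and prospective testing

For a candidate phenotype, hyper-feature series are built on a 1-min
reference grid: at reference time `r`, hyper-feature *i* applies its
operator to the 5-s feature stream over `[r − (t_i + w_i), r − t_i]`
minutes. Rows whose aggregation window would reach before the record start
are excluded. Lags of 1–3 min are appended (20 columns), redundant columns
(|Pearson ρ| > 0.95, greedy left-to-right) are dropped, columns are
z-scored with training statistics only, and a class-weighted logistic
regression is fitted (weights `N/(2 N_c)`; ridge penalty at scikit-learn's
default `C = 1`; with no penalty, near-separable designs return arbitrary
coefficient magnitudes and the interpretability study's |β| ranking becomes
meaningless).

Labels on the grid: pre-ictal in `[onset − pre_ictal, onset − SPH)`,
excluded in the SPH and for a 30-min post-onset guard, inter-ictal
elsewhere. Sample metrics come from the raw classifier outputs (p > 0.5):
`S_s` (fraction of pre-ictal rows classified pre-ictal) and `T_f` (fraction
of inter-ictal rows classified pre-ictal). Alarm metrics come from the
Firing Power, the trailing moving average of the binary outputs over the
pre-ictal duration (warm-up emits partial means). An alarm fires at an
upward crossing of 0.70; during prospective testing a refractory period of
SOP + SPH suppresses further alarms, re-arms at expiry, and is excluded from
the FPR/h denominator. A seizure counts as predicted (`S_p = 1`) when at
least one alarm falls inside its pre-ictal window. Each evaluated seizure is
scored

```
performance = (S_s + S_p) × 0.5 − FPR/h × (1 + T_f)
```

which equals 1 exactly for a perfect prediction. Fitness is the iterative
retraining mean: for seizures j = 2..k, train on seizures 1..j−1 and
evaluate seizure j (no refractory); individuals whose model cannot be
fitted (degenerate designs) get a sentinel fitness of −10.

## Genetic algorithm

Population 100, initialized uniformly at random. Each generation selects 50
parents by binary tournament (contestants drawn without replacement within a
tournament, winner = higher fitness, sampling with replacement across
tournaments), produces 50 offspring — with probability 0.80 by shortest-path
recombination of two distinct parents, otherwise by cloning one selected
parent — and mutates every offspring once (mutation rate 1.0). Replacement
is elitist: parents and offspring are pooled and the best 100 survive, with
offspring preferred on exact fitness ties. The tie rule matters: under
strict parent-preference, genes whose target value lies two or more steps
away in their neighbourhood graph can never traverse the intervening
fitness-neutral values, and the search provably stalls on plateau
landscapes. Stopping: fitness ≥ 1, 50 stagnant generations, or 15000
evaluations (fresh evaluations only; genotypes are memoised within an
execution). Per-execution seeds are `master_seed + execution_index`.

## Statistical validation

The surrogate predictor re-scores the *fixed* alarm train against randomly
shifted onset times: per repetition (default 30), each onset is drawn
uniformly over the placements that keep its shifted pre-ictal window fully
inside the record, and the surrogate sensitivity is the fraction of shifted
onsets with an alarm inside their window. An execution is above chance when
its real per-seizure sensitivities beat the surrogate repetitions in a
one-tailed Welch t-test at α = 0.01. Degenerate cases: when both groups
are constant the means are compared exactly; when only the real group is
constant (every test seizure predicted, or none — common with few test
seizures) the t statistic would treat a two-point binary mean as certain,
so the p-value is the exact Monte-Carlo exceedance
`(1 + #{surrogate ≥ real mean})/(n_reps + 1)`, the standard surrogate-data
rank test. Across a set of executions, the count individually above chance
is compared with a binomial null, `P(i, I, α) = Σ_{j≥i} C(I,j) α^j (1−α)^{I−j}`
at α = 0.05.

## Phenotype study

For each execution's solutions, every hyper-feature receives a scalar
weight — the mean |β| over its retained (lagged) design columns of the
deployed model (the classifier refit on all training seizures); `sum` is
available as an alternative collapse rule. A gene value's predictive power
is the summed weight of the hyper-features carrying it; presence uses unit
weights. Both are normalized to sum to 1 per dimension (decoded feature,
band-wave gene — the 7 bands, counted only where a band is actually
expressed — operator, electrode, lobe, hemisphere, window length, time
instant; electrode→lobe/hemisphere uses the standard 10–20 assignment,
shipped as an editable table). Reports aggregate the per-individual normalized vectors
over a set of solutions. When few executions are run, each execution
contributes its top distinct final-population genotypes (default 10), so a
3-execution run still aggregates ~30 solutions, mirroring the
30-best-of-execution design at reduced scale. Co-occurrence statistics
count distinct window lengths, time instants and lobes per individual.

## Synthetic data generator

The generator emulates the acquisition regime end-to-end: 19-channel
256 Hz records, per-seizure 4-h training segments ending at their onset,
and one continuous testing stretch with multiple onsets. Per channel the
background is `1/f^γ` coloured noise (γ = 1, RMS 20 µV), an alpha rhythm
generated as 8–12 Hz band-limited noise (RMS 5 µV — band-limited rather
than a fixed sine so its relative power waxes and wanes as physiological
alpha does), and a band-limited component in the signature band (RMS 6 µV)
present on every channel. Spectral shaping draws the complex spectrum
directly in independent 30-s blocks (equivalent in law to FFT-shaping white
noise, an order of magnitude faster); identical seeds give bit-identical
records.

On the signature electrodes the band component's amplitude gain rises from
1 to `effect_size` over the first half of the planted window
`[onset − signature_onset, onset]` and then holds (`signature_ramp_fraction`
configurable; 1.0 recovers a pure linear ramp). The plateau shape was a
deliberate design choice: under a pure ramp the early pre-ictal labels
carry almost no signal, so even a perfectly matched detector cannot reach
the performance optimum, and any search as intensive as 2000 adaptive
evaluations will instead overfit the two held-out training seizures (on
signal-free data the GA reliably reaches fitness ≈ 0.98 this way). A
drift that settles into an established pre-ictal state makes the planted
ground truth actually learnable and is equally compatible with the gradual
pre-ictal drift hypothesis. The signature channel is renormalized by its
expected total RMS so the plant is a shift of power *into* the band — what
relative-power features measure — rather than a broadband amplitude change.
The default signature onset is 60 min so the drift spans every explored
pre-ictal duration (40 + up to 20 min of time instant). Ictal activity is
not modelled beyond a flagged 60-s placeholder burst at onset; the method
never uses ictal samples. Optional knobs add slow per-band power wander or
per-record component variability (both default off — in testing, every such
nonstationarity *lowered* the effective degrees of freedom of the held-out
segments and made selection overfitting easier, not harder).

### What passing tests do and do not show

The generator's background is far tamer than real scalp EEG: no artifacts
(blinks, EMG), no circadian structure, no concept drift between segments,
and a planted signature that is exactly the kind of band-power shift the
feature set measures. Recovery results therefore demonstrate that the
pipeline finds and correctly attributes a genuine pre-ictal band-power
drift when one exists, and that its statistical validation does not flag
signal-free data — not that comparable sensitivity would be reached on
clinical recordings. Two further caveats are inherent to the study design
itself: with only two held-out training seizures, an evolutionary search
can overfit them (fitness near 1 on null data), which is why prospective
testing against the surrogate predictor — not training fitness — is the
measure of merit; and relative powers are compositional, so a planted shift
into one band necessarily moves every other band's share and the spectral
centroid. Those coupled features are genuine detectors of the same event
with only moderately lower separability, so while the recovery study
localises the signature *electrodes* essentially always and beats the
surrogate chance level, the attribution of the drift to the planted band
itself is unreliable at the scaled search budget — the fitness has many
optima along the coupled routes and the search entrenches whichever it
finds first. The recovery test asserts band attribution separately so this
limitation is measured, not hidden.

## Problem sizes used in the test suite

Unit tests run on seconds-to-minutes of synthetic signal. The end-to-end
recovery study uses one planted patient (3 training seizures × 4 h, one
continuous 4-h test stretch with 2 onsets, theta signature on T3/T5 at
effect size 2.0) with ten 3-execution runs at a 2000-evaluation GA budget;
the null calibration uses five signal-free patients (2 × 2-h training
segments, ~3.75-h test stretch) with ten prospective executions each. The
GA benchmark uses the full 15000-evaluation budget on a 35-gene
hidden-target task with the stagnation stop disabled (the benchmark bounds
the evaluation budget, not patience).
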