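# Methods

`passive-lp` implements two passive-listening EEG assays of low-level
language processing, the statistics that make them interpretable at the
single-trial level, the aggregation and patient-categorization logic used
to compare clinical groups, and a synthetic-data generator that provides
calibrated inputs for every stage.

## The two assays

**Differential phoneme-class response (DPR).** The preprocessed EEG is cut
into 500 ms epochs beginning at every phoneme onset (onsets map to the
nearest sample; at 250 Hz an epoch is 125 samples, timepoints 0–496 ms).
Phonemes are grouped by manner of articulation into approximants (A),
fricatives (F), nasals (N), plosives (P) and vowels (V). For each of the
C(5,2) = 10 unordered class pairs, each channel and each timepoint, the
amplitude distributions of the two classes across epochs are compared with
a two-tailed Wilcoxon rank-sum test. Within each channel the 125 p-values
are corrected with the Benjamini–Hochberg (BH) step-up procedure at
α = 0.05 (a global channels × timepoints family is available by
configuration). The 10 boolean masks are averaged into a trial-level
frequency map whose cells take values {0, 0.1, …, 1}: the fraction of
pairs differing significantly at that (channel, timepoint).

Because epochs are much longer than the mean phoneme (79.5 ms, range
30–320 ms), epochs overlap heavily; the rank-sum test is applied across
epochs independently at each timepoint, exactly as the single-cell
contract requires, and no independence across timepoints is assumed — the
FDR correction is what licenses the map.

**Natural speech envelope (NSE) tracking.** The stimulus envelope is the
magnitude of the analytic signal of the mono (binaural-averaged) audio,
resampled to the EEG rate and then passed through the same 2–15 Hz
band-pass and standardization as the EEG. EEG and envelope are cut into
paired non-overlapping 2 s segments. The tracking statistic at channel c
and lag L ∈ {0, 4, …, 500} ms is the mean over segments of the Pearson
correlation between the envelope segment and the EEG segment delayed by L
(EEG after audio; only non-negative lags, since auditory responses follow
the stimulus). Significance is empirical: the segment pairing is permuted
10,000 times (uniform random permutations, identity excluded and
re-drawn), the statistic is recomputed per permutation, and the two-tailed
p-value is (1 + #{|null| ≥ |obs|}) / (n_shuffles + 1). BH-FDR across lags
within channel is shared with the DPR stage.

The full segment-by-segment correlation matrix (channels × lags ×
segments × segments) is computed once; every shuffle is then a sparse
selection of one entry per row/column, so the 10,000-shuffle null for a
148 s, 8-channel trial costs a few seconds.

## Preprocessing

Trials are notch-filtered at 60 Hz (4th-order Butterworth band-stop,
±2 Hz), band-pass filtered to 2–15 Hz (4th-order Butterworth band-pass),
both applied forward–backward so they are zero-phase — the assays
interpret component latencies down to 30–60 ms, which a causal filter
would shift. Each channel is standardized to zero mean and unit variance;
moments are computed over artifact-free samples only. Artifact spans
(from visual inspection, supplied as second intervals) are handled by
masking, not deletion: samples stay in place so annotation-to-sample
alignment stays exact, and any epoch or segment touching a masked sample
is excluded downstream. Trials with more than ~15 s of artifact are
excluded entirely. Epochs containing any amplitude beyond 10 SD (units of
the standardized trial) are rejected as residual artifact.

## Statistics: implementation notes

- **Rank-sum.** For group sizes up to 8 the exact permutation distribution
  of the rank-sum statistic is enumerated on midranks (so ties are handled
  exactly); the two-tailed p counts reassignments whose statistic deviates
  from its mean at least as much as observed. Larger groups use the normal
  approximation with tie and continuity corrections (verified against
  `scipy.stats.mannwhitneyu`). Cells where all pooled amplitudes are
  identical return p = 1.
- **BH-FDR.** Delegated to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`), applied per correction family; ties at the threshold are all
  rejected (standard step-up). Verified against a literal implementation
  of the step-up definition on random vectors.
- **Empirical p-values.** The +1 correction keeps p in (0, 1] and makes
  the p-values valid (super-uniform) under the shuffle null; with 10,000
  shuffles the smallest attainable p is 1/10001.

## Null calibration and what "chance" means

With 125 independent null p-values per channel, BH at α = 0.05 rejects on
average ~0.05 timepoints per channel — an overall significant-cell
frequency of ~0.0004. The package reproduces this for the DPR stage:
white-noise epoch simulations (`pipeline.dpr_null_calibration`) measure
~0.05 false positives per channel and a cell frequency of ~0.0004.

For the NSE stage the same nominal figure is **not** attained, and this is
a property of the method, not of the implementation. The tracking
statistics at neighbouring lags are strongly dependent (the band-limited
envelope's autocorrelation decays over tens of milliseconds), so under the
null BH rejects in clumps: the probability that a channel has any
significant lag stays near α, and the empirical p-values are marginally
valid (both verified by simulation), but the *expected count* of
significant cells is roughly an order of magnitude above α/m —
`pipeline.nse_null_calibration` measures ~0.004–0.007 against the nominal
~0.0004. FDR (a rate over discoveries) is still controlled; users reading
NSE maps should treat isolated significant-lag clusters, not single cells,
as the unit of evidence.

## Aggregation and categorization

Maps are combined by cellwise arithmetic mean, first across trials within
a subject, then across subjects with **equal subject weight** (a subject
with five trials counts the same as a subject with one). Group maps record
n_s (subjects) and n_v (visits).

Patients are categorized from the subject/visit metadata by a decision
tree: CF+ if any visit shows command-following on the EEG or fMRI
motor-imagery assay; LP+ (any evidence of language processing) if CF+ or
if any visit's bedside classification is MCS+ or eMCS (behavioural
command-following); otherwise LP−. `not_done` contributes no evidence in
either direction. CF+ ⇒ LP+ by construction. Counts are emitted at both
subject level (any-visit evidence) and visit level (each visit on its own
row), because group figures are typically reported per visit while
prevalence claims are per subject; on the packaged cohort fixture the
subject-level tallies are CF+ 16 and LP+ 19 of 24 patients.

## The synthetic-data generator

The generator emulates the study conditions so that every stage can be
tested without patient data:

- **Annotation**: contiguous phoneme intervals tiling the trial. Durations
  are log-normal (σ = 0.45) truncated to [30, 320] ms with the location
  parameter solved numerically so the truncated mean is exactly 79.5 ms;
  at the default 148 s this yields ≈1860 phonemes. Class labels are drawn
  with probabilities proportional to the stimulus passage's class counts
  (A 163, F 264, N 147, P 355, V 617), then a concrete ARPAbet phoneme of
  that class is assigned.
- **Envelope/audio**: a per-phoneme intensity profile (class-dependent
  level, log-normal jitter, vowels loudest) smoothed with a 20 ms
  Gaussian; the audio rendering modulates a 220 Hz tone at 44.1 kHz,
  duplicated to two identical binaural channels. The pipeline's envelope
  extraction recovers the generating envelope from the WAV with r ≥ 0.9.
- **EEG**: per-channel Gaussian noise with 1/f power shaping, band-passed
  to 2–15 Hz and standardized to unit variance, plus optional effects:
  class-locked half-sine bumps (amplitude in SD units, centered at a
  configurable latency, projected on a channel-weight vector), an
  envelope-following component (standardized envelope convolved with a
  narrow half-sine kernel peaking at a configurable lag — narrow so the
  cross-correlation peak localizes the lag sharply), and artifact bursts
  whose ground-truth intervals are returned as the mask.
- All outputs are pure functions of (config, seed).

What the generator does **not** emulate: volume conduction and realistic
scalp topographies, phonetically realistic audio, non-stationary noise,
eye/muscle artifact morphologies, or any dependence of the evoked response
on phonetic context. Passing recovery tests therefore show that the
pipeline detects the effects it models at the stated SNR — not that real
patient EEG contains such effects.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| rate_hz | 250 | EEG sampling rate (samples/s) |
| notch_hz | 60 | mains notch frequency |
| band | 2–15 Hz | analysis band of both assays |
| epoch_reject_sd | 10 | epoch amplitude rejection threshold (SD units) |
| window_ms | 500 | DPR epoch length after phoneme onset |
| seg_s | 2 | NSE segment length (s) |
| max_lag_ms | 500 | largest EEG-after-audio lag tested |
| n_shuffles | 10000 | permutations for the empirical null |
| alpha | 0.05 | FDR level, per correction family |
| scope | within_channel | BH family: lags/timepoints within a channel |
| duration_s | 148 | synthetic trial length (s) |
| n_channels | 8 | synthetic montage size (up to 37, 10–20 labels) |

Sub-interval summaries default to the bins 0–80, 84–148, 152–300, 304–400
and 404–500 ms (inclusive edges on the 4 ms grid); the bins are
configurable.

## Design choices where the design was open

- **Affricates** (CH, JH) are absent from the default ARPAbet
  manner-of-articulation map: an affricate is a plosive released into a
  fricative and assigning it to either class is arbitrary, so such labels
  are reported as unmapped rather than silently classified.
- **Epoch window**: 125 samples (0–496 ms); an inclusive 500 ms endpoint
  would add a 126th sample, but half-open windows compose cleanly with the
  4 ms grid. The lag axis, by contrast, includes both endpoints (126 lags,
  0–500 ms), since lag 0 and lag 500 are both meaningful hypotheses.
- **Envelope vs raw audio**: the tracking statistic correlates the EEG
  with the *envelope* (that is what "envelope tracking" denotes, and the
  raw waveform carries no energy below 15 Hz after resampling); a
  raw-audio mode is available behind a flag.
- **Statistic**: the mean of per-segment Pearson correlations rather than
  one pooled covariance — robust to slow level shifts between segments.
- **Null permutations** exclude the identity pairing so the observed
  statistic never contaminates its own null.
- **Calibration scale**: null calibrations and recovery tests run at 8
  channels and 148 s (74 segments) with 10,000 shuffles, and the
  acceptance script uses 60 pure-noise replicates for the epoch-stage
  calibration and 40 for the envelope stage — sizes at which the
  Monte-Carlo standard errors are small relative to the quantities
  measured.

## Known limitations

- EDF export quantizes to 16 bits over the per-channel range (~3 × 10⁻³ µV
  error at typical amplitudes) and pads recordings to whole seconds; the
  delimited format is exact.
- The NSE chance level is nominal, not empirical (see above).
- The per-visit LP tally double-counts subjects whose category changed
  across visits; both tallies are reported, neither is canonical.
- Zero-variance segments correlate as 0 rather than being dropped; this
  only arises for degenerate (constant) synthetic inputs.
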