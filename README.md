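# passive-lp

Passive EEG assays of low-level language processing for clinical
neurophysiology: **differential phoneme-class response (DPR)** mapping and
**natural speech envelope (NSE)** tracking, with the null-calibration,
aggregation and patient-categorization machinery needed to apply them to
disorders-of-consciousness cohorts.

Behavioural command-following tests miss patients with preserved cognition
but absent motor output, and motor-imagery EEG/fMRI tests demand sustained
attention. Both assays here are *passive*: the subject simply hears a
narrated story while EEG is recorded, and the analysis asks (i) whether
responses time-locked to phoneme onsets differ between manner-of-
articulation classes, and (ii) whether the EEG tracks the slow amplitude
envelope of the speech at some lag.

## The statistics at the core

**DPR.** Epochs x(t), t ∈ [0, 500) ms, locked to each phoneme onset, are
grouped into five classes (approximants, fricatives, nasals, plosives,
vowels). For each of the 10 class pairs, channel c and timepoint t, a
two-tailed Wilcoxon rank-sum test compares amplitude distributions across
epochs; within each channel the 125 p-values receive Benjamini–Hochberg
FDR correction at α = 0.05, so random data yields ≈0.05 false-positive
timepoints per channel (cell frequency ≈0.0004). The frequency map is the
fraction of pairs significant at each (c, t).

**NSE.** With the stimulus envelope e(t) (analytic-signal magnitude,
resampled to 250 Hz, 2–15 Hz band-passed, standardized like the EEG) and
paired non-overlapping 2 s segments, the statistic is

  ρ(c, L) = mean over segments of corr( e_seg , x_seg(c) delayed by L ),
  L = 0, 4, …, 500 ms,

with two-tailed empirical p-values from 10,000 random re-pairings of the
segments and the same within-channel FDR correction.

Maps are averaged across trials within subject, then across subjects with
equal weight. Patients are categorized by a decision tree: **CF+** if any
visit shows command-following on EEG or fMRI motor imagery, **LP+** if CF+
or bedside MCS+/eMCS at any visit, else **LP−**.

## Worked example

Generate a synthetic trial containing both effects — a 2 SD vowel-locked
component at 120 ms on channels C3/Cz-neighbours (indices 2, 3) and
envelope coupling at 48 ms on all channels — then run both assays:

```python
import numpy as np
from passive_lp import SyntheticConfig, generate_dataset, preprocess_trial
from passive_lp import dpr_mapping as dpr, nse_tracking as nse
from passive_lp.synthetic import ClassEffect, EnvelopeCoupling
from passive_lp.preprocess import bandpass_series, standardize_series

weights = np.zeros(8); weights[[2, 3]] = 1.0
cfg = SyntheticConfig(
    seed=11, duration_s=148.0, n_channels=8,
    class_effects={"V": ClassEffect(amplitude_sd=2.0, latency_ms=120.0,
                                    channel_weights=weights)},
    envelope_coupling=EnvelopeCoupling(amplitude_sd=0.25, lag_ms=48.0),
)
trial = generate_dataset(cfg)
rec = preprocess_trial(trial["recording"])

sets = dpr.reject_epochs(dpr.extract_epochs(rec, trial["annotation"]))
print("epochs per class:", {c: s.n_epochs for c, s in sets.items()})

results = [dpr.pair_result(sets, pair) for pair in dpr.ALL_PAIRS]
fmap = dpr.average_pair_maps(results, rec.channel_labels)
summary = dpr.subinterval_summary(fmap)
print("channel C3 sub-interval frequencies:", np.round(summary[2], 3))
print("channel Fp1 sub-interval frequencies:", np.round(summary[0], 3))

env = nse.EnvelopeSignal(
    standardize_series(bandpass_series(trial["envelope"].values, 250.0)), 250.0)
res = nse.nse_analysis(rec, env, n_shuffles=10000, seed=12)
print("per-channel peak-correlation lag (ms):",
      res.lags_ms[np.argmax(np.abs(res.statistic), axis=1)])
```

Output:

```
epochs per class: {'A': 212, 'F': 323, 'N': 189, 'P': 431, 'V': 734}
channel C3 sub-interval frequencies: [0.271 0.359 0.239 0.    0.   ]
channel Fp1 sub-interval frequencies: [0.119 0.124 0.042 0.    0.   ]
per-channel peak-correlation lag (ms): [48. 48. 68. 68. 56. 48. 52. 52.]
```

Reading the numbers: ~1900 phonemes in 148 s give a few hundred epochs per
class. On C3 (index 2, which carries the injected vowel bump) up to 36 %
of class pairs differ significantly in the 84–148 ms sub-interval — the
injected 120 ms latency — and nothing survives beyond 300 ms. Fp1 carries
no vowel bump, but its frequencies still sit far above the 0.0004 chance
level: the envelope coupling feeds class information (vowels are louder)
into *every* channel. The NSE peak lag lands on the injected 48 ms on the
envelope-only channels and is pulled later (56–68 ms) on the channels
that also carry the evoked vowel component.

The same pipeline runs from the shell:

```sh
passive-lp synth --seed 11 --coupling 0.25 --coupling-lag 48 --out trial/
passive-lp dpr  --eeg trial/eeg.edf --annot trial/annotation.tsv --out out_dpr/
passive-lp nse  --eeg trial/eeg.edf --audio trial/stimulus.wav --seed 12 --out out_nse/
passive-lp calibrate --seed 1 --replicates 20 --out calibration.json
passive-lp group --metadata cohort.tsv --maps-dir maps/ --out groups/
```

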