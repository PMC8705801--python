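# rsikit

Resilience-to-stress indices from multichannel psychophysiological
recordings.

Given per-subject recordings of five channels — electromyography (EMG),
blood volume pulse (BVP), breathing (BR), skin conductance (SC) and
peripheral temperature (PT) — sampled uniformly (256 Hz by default) over a
phased stress protocol, `rsikit`:

1. **conditions** each channel (0.5-s offset trim, median filter with an
   automatically chosen odd kernel, population-sd standardization, and an
   optional Yeo-Johnson power transform for the linear-PCA path);
2. **builds features**: each channel plus its t−1 and t−2 differences
   (15 columns), with per-sample phase labels;
3. **measures phase separation** from the baseline cluster by four methods —
   Euclidean distance of PCA centroids (`edpca`), mean Mahalanobis distance
   under the pooled-pair covariance (`md`), mean silhouette with a
   Mahalanobis metric (`cvid`), and Euclidean distance of kernel-PCA
   centroids on 1-Hz medians (`edkpca`);
4. **computes cohort-relative indices**: the resilience index
   RSI = ΔR / max ΔR with ΔR = D(last stressor) − D(last recovery), and the
   alteration factor AF = min-max-normalized maximum baseline-relative
   stretch;
5. **validates**: normality-gated Pearson/Spearman correlation of indices
   against questionnaire totals, Friedman comparison across methods, and
   per-channel baseline-vs-final-phase rank correlations.

A synthetic cohort simulator with controlled ground truth (per-subject
recovery fraction and stress-shift magnitude) makes the whole pipeline
testable without real recordings.

## CLI

```sh
# 20 synthetic subjects (recovery fraction varies across the cohort)
rsikit simulate -n 20 --seed 1 -o data/

# full pipeline: distances + indices for every subject and method
rsikit compute -i data/ -o results/ --methods edpca,md,cvid,edkpca

# correlate per-method indices with questionnaire totals
rsikit validate --indices results/indices.csv --scores scores.csv -o report/
```

Recordings are plain CSV with a header naming the five channels
(case-insensitive aliases accepted: `gsr` for SC, `temp` for PT, `resp` for
BR). Protocols are YAML (`phases:` list with `name`, `start_s`, `end_s`,
`role`); the default is five 120-s phases (baseline, stressor, recovery,
stressor, recovery). Every run writes a `manifest.json` recording all
parameters and seeds.

## Library use

```python
from rsikit import simulate_cohort, analyze_cohort

recordings, truth = simulate_cohort(20, master_seed=1)
distances, indices = analyze_cohort(recordings)
print(indices.table)        # subject_id, method, D2..D5, delta_r, rsi, af
print(indices.normalizers)  # per-method cohort normalizers
```

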