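# bulbarvoice

Voice-based screening pipeline for dysarthric/dysphonic sustained vowels:
from mono WAV recordings of the five Spanish vowels to a 50-feature table,
statistically screened features, and cross-validated classification reports.

Stages:

1. **preprocess** — decimate 44,100 Hz recordings by 5 (anti-aliased,
   zero-phase) to 8,820 Hz, z-score the whole signal, cut a 150 ms segment
   centred on the phonation midpoint.
2. **phonatory** — 15 features: jitter (absolute, relative, rap, ppq5),
   shimmer (dB, relative, apq3/5/11), HNR mean/SD and pitch mean/SD/min/max
   from an autocorrelation pitch tracker plus pitch-guided cycle marking.
3. **tfr / tffeatures** — 35 features from the normalized Choi–Williams
   distribution of the segment and the interference-free joint density
   pD(f,t) built from its marginals: per-band energies, peak and centroid
   frequencies over a 7-band partition of 0–4410 Hz, Shannon entropies,
   per-band spectral information, time-marginal kurtosis, and joint
   time-frequency moments (t1f1, t7f7, t15f15).
4. **selection** — per-comparison (C vs B, C vs NB, B vs NB, C vs A;
   A = B ∪ NB), per-sex screening: per-feature F tests at p < 0.05 with a
   Wilks' Λ omnibus when the covariance permits.
5. **classify** — stratified 10-fold CV of SVM, NN, LDA, LR and RF with
   training-fold standardization and minority upsampling, scored at the 50%
   threshold; accuracy / sensitivity / specificity from pooled confusion
   counts.
6. **synthvoice** — a source–filter synthetic vowel generator with exact
   per-cycle ground truth (jitter, shimmer, HNR, formants, spectral tilt,
   type-2 subharmonics), so the whole pipeline is testable without clinical
   recordings.

## CLI

```bash
# generate a synthetic cohort (WAVs + metadata.csv + ground_truth.csv)
bulbarvoice synth --n-per-group 10 --sex F --seed 7 --out cohort/

# extract the 50-feature table from recordings listed in a metadata CSV
bulbarvoice extract --metadata cohort/metadata.csv --out features.csv

# screen features for one comparison
bulbarvoice select --features features.csv --comparison C_vs_B --sex F

# 10-fold CV of the five models
bulbarvoice classify --features features.csv --comparison C_vs_B --sex F --seed 7

# everything end-to-end on a synthetic cohort
bulbarvoice run-all --synthetic --n-per-group 10 --sex F --seed 7 --out results/
bulbarvoice report --results results/
```

Real recordings are described by a CSV with columns
`subject_id, sex, group, vowel, path` (group ∈ {C, B, NB}; mono RIFF PCM
WAV, nominally 44,100 Hz, 3–4 s sustained phonation per file).

## Python API

```python
from bulbarvoice import VoiceSpec, synthesize_vowel
from bulbarvoice.pipeline import RunConfig, extract_features

rec, truth = synthesize_vowel(VoiceSpec(f0=120, jitter_rel=1.0, seed=0))
features = extract_features(rec, RunConfig())   # dict of 50 named values
```
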