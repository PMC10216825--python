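# gcq — a Granger-causality quantifier for EEG emotion recognition

`gcq` implements a connectivity-based pipeline for recognizing dimensional
emotions (valence–arousal quadrants) from multichannel EEG. Instead of
classifying raw channel features, it summarizes each trial's directed brain
network by a single scalar and classifies that:

1. **Band extraction** — each channel is decomposed with a level-5
   Daubechies discrete wavelet transform and reconstructed per frequency
   band (δ 0–4 Hz, α 8–16 Hz, β 16–32 Hz, γ 32–64 Hz, plus the unfiltered
   "all" band; θ is available but off by default).
2. **Electrode combination** — the 32 electrodes of the standard 10–20
   montage are averaged into six brain areas (left/right frontal,
   central–temporal, parieto-occipital; the four midline electrodes join
   no area), shrinking the pairwise analysis from 992 to 30 directed pairs.
3. **Normalization** — each signal is mapped affinely onto [−1, 1]:
   `X = 2·(E − E_min)/(E_max − E_min) − 1`.
4. **Granger causality** — for every ordered pair (x, y) an F-statistic
   compares the restricted autoregression
   `y(t) = c + Σᵢ aᵢ·y(t−i) + e(t)` with the unrestricted model that adds
   `Σⱼ bⱼ·x(t−j)`:
   `F = ((RSS_r − RSS_u)/p) / (RSS_u/(n_eff − 2p − 1))`,
   giving a directed n × n connectivity matrix (row = target,
   column = source).
5. **Quantification** — the scalar feature is the sum of all off-diagonal
   F-values strictly above a threshold (default 60). A matrix whose
   suprathreshold cells hold 101.54, 91.93 and 68.17 quantifies to 261.64.
6. **Classification** — the per-trial scalar (min–max normalized) feeds
   one-vs-all KNN and SVM classifiers under stratified k-fold
   cross-validation, sweeping K = 1..20 and k = 2..20, reporting accuracy,
   sensitivity and F1 per class.

The reference data shape is the DEAP benchmark (32 subjects × 40 trials ×
32 channels × 63 s at 128 Hz, self-rated valence/arousal 1–9 cut at 4.5
into four classes), but no download is needed: a bundled generator
produces DEAP-shaped synthetic recordings from a latent vector
autoregression with known directed inter-area coupling, so every stage
can be validated against ground truth.

Intended users: researchers in affective computing / EEG connectivity who
want a small, fully tested reference implementation of the
thresholded-F-sum network feature, or a controlled sandbox for directed
connectivity methods.

## Worked example

```bash
gcq run --subjects 6 --trials 20 --samples 1024 --bands all,beta \
        --seed 7 --out runs/demo
```

or equivalently in Python:

```python
from gcq import RunConfig, run
res = run(RunConfig(out_dir="runs/demo", n_subjects=6, n_trials_per_subject=20,
                    n_samples=1024, bands=("all", "beta"), seed=7))
```

This synthesizes 120 balanced trials (directed coupling strength grows
with the class index), extracts the quantifier per trial, and sweeps both
classifiers. The feature CSV starts:

```
subject_id trial_id  class_id  quantifier_raw  quantifier_normalized band  mode
       s01      t01         1        0.000000              -1.000000  all areas
       s01      t02         2      844.483039              -0.734204  all areas
       s01      t03         3     2263.489434              -0.287580  all areas
       s01      t04         4     4143.922153               0.304275  all areas
```

Class 1 has no inter-area coupling, so no F-value crosses the threshold
and its quantifier is 0; classes 2–4 carry one to three directed links of
increasing strength and their quantifier ranges (here 332–952, 1665–2839,
3961–6354) are disjoint. The best-accuracy summary for the unfiltered
band is consequently perfect:

```
classifier  class_id    AC    SE    F1   K  k_fold
       knn         1 100.0 100.0 100.0 1.0       2
       knn         2 100.0 100.0 100.0 1.0       2
       knn         3 100.0 100.0 100.0 1.0       2
       knn         4 100.0 100.0 100.0 1.0       2
       svm         1 100.0 100.0 100.0 NaN       2
       ...
```

while the β-band run (coupling is broadband in the generator, so band
filtering discards part of it) lands in the 74–93% accuracy range —
useful for seeing how the feature degrades when the connectivity signal
is only partially captured. `runs/demo/` also contains one representative
connectivity-matrix CSV per (band, class), the per-record performance
tables, the verbatim config and a run log with per-stage GC-fit counts
(30 fits/trial in 6-area mode versus 992 in 32-channel mode).

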