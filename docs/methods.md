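# Methods

This note documents the model underlying `gcq`, the choices made where
the method's published description is open, and what the synthetic
validation does and does not establish.

## Emotion classes

Trials carry self-assessed valence and arousal scores in [1, 9]. Both
axes are cut at 4.5, with the boundary counting as "high", giving four
classes: 1 = LALV, 2 = HALV, 3 = LAHV, 4 = HAHV. `assign_class` is total
on the score square and partitions it into four rectangles meeting at
(4.5, 4.5).

## Montage and electrode combination

The reference montage is the 32-electrode 10–20 layout used by DEAP. Six
areas are defined symmetrically per hemisphere — frontal (5 channels
each), central–temporal (4 each), parieto-occipital (5 each) — and an
area signal is the unweighted arithmetic mean of its members. The four
midline electrodes (Fz, Cz, Pz, Oz) belong to neither hemisphere and are
assigned to no area; they participate in 32-channel mode only.
`validate_montage` therefore passes a montage when every channel is
either assigned to exactly one area or explicitly excluded.

Because averaging and the wavelet reconstruction are both linear, area
averaging commutes with band extraction. The pipeline's areas mode
combines first and band-filters the six area signals (≈5× fewer DWTs);
the equivalence to decompose-then-combine is asserted to 1e−8 by a
property test rather than assumed.

## Frequency bands

Bands are defined by their classical frequency ranges: δ 0–4, θ 4–8,
α 8–16, β 16–32, γ 32–64 Hz. At the 128 Hz reference rate a level-5
DWT (Daubechies, order 4 by default, symmetric signal extension) splits
the axis dyadically into A5 ≈ 0–2, D5 ≈ 2–4, D4 ≈ 4–8, D3 ≈ 8–16,
D2 ≈ 16–32 and D1 ≈ 32–64 Hz. Each band is reconstructed from the
coefficient sets whose dyadic interval falls mostly inside its range
(δ ← A5 + D5, θ ← D4, α ← D3, β ← D2, γ ← D1), by zeroing all other
coefficient vectors and inverse-transforming, so the output has the
input's length and the five bands plus θ reproduce the signal exactly
(perfect reconstruction). θ is implemented but excluded from the default
band list because its F-values rarely cross the operating threshold.
Other sampling rates are accepted; the dyadic intervals are recomputed
and a warning notes that the band names then shift in frequency. The
band-dominance tests assert relative energy orderings that hold for
Daubechies orders 2–8 rather than order-specific values.

Edge handling: symmetric padding contaminates a filter-length
neighbourhood of each boundary, so energy assertions exclude the outer
samples; the reconstructed signals themselves are returned full-length.

## Normalization

`X = 2·(E − E_min)/(E_max − E_min) − 1` maps each signal onto [−1, 1]
with the extrema attained exactly; a constant signal has no dynamic
range and raises an error rather than silently returning zeros. The
source extrema are retained as metadata. The Granger F-statistic is
invariant to affine rescaling of either series (asserted to 1e−8), so
normalization placement cannot change the connectivity values; it is
applied per signal after area combination, and again to the finished
feature vector before classification.

## Granger causality

For an ordered pair (driver x, response y) and lag order p, two OLS
regressions are fitted on the common sample (the first p points
dropped), both with an intercept:

- restricted: y on its own p lags;
- unrestricted: additionally on p lags of x.

The statistic is `F = ((RSS_r − RSS_u)/p) / (RSS_u/(n_eff − 2p − 1))`
with `n_eff = n − p`. Under the null of no predictive improvement it
follows F(p, n_eff − 2p − 1); the empirical test size at α = 0.05 is
checked by simulation (0.05 ± 0.02 over 1000 white-noise pairs). The
binary causal verdict (F beyond the α = 0.05 critical value) is exposed
as `GCResult.causal` but plays no role in the quantifier, which consumes
the raw F-values.

Lag policy: the lag order is either fixed by the caller or selected per
pair as the BIC minimizer of the unrestricted model over 1..20 (each
candidate evaluated on its own effective sample). BIC is the standard
operationalization of an "optimal" lag; a fixed order is the
reproducible default in the pipeline and every report records the order
used. Rank-deficient designs (e.g. x identical to y) raise a
collinearity error; inside a matrix computation any failing cell — a
constant signal, a collinear pair — is recorded as F = 0 with a warning
instead of aborting the remaining cells.

Matrix orientation is an explicit convention: entry (i, j) is the
F-statistic for "signal j Granger-causes signal i" (row = target,
column = source). The quantifier sums over all off-diagonal cells, so
this convention cannot affect any headline number.

The implementation is cross-checked two ways: against an independent
brute-force normal-equations oracle (1e−6 relative) and against
`statsmodels`' ssr-based Granger F-test (1e−9 relative); `statsmodels`
is a test-time dependency only.

## Quantifier

The scalar feature is the sum of off-diagonal F-values **strictly**
greater than the threshold (default 60, configurable). The sum covers
the full directed matrix, not a triangle; with three suprathreshold
values 101.54, 91.93, 68.17 the quantifier is 261.64. It is monotone in
every matrix entry, antitone in the threshold, and depends only on the
multiset of off-diagonal values. Per-trial failures during feature
extraction drop that trial (with its label) and are logged; if every
trial quantifies identically, the feature vector has no dynamic range
and normalization raises.

## Classification and reporting

Each class is evaluated one-vs-all with stratified k-fold
cross-validation; folds are assigned once per k on the four-class labels
with a seeded shuffle, so all four binary tasks share folds, and a
training fold missing either binary class raises a stratification error.
Confusion counts are pooled across folds before computing
AC/SE/F1 (micro-averaging; per-fold macro-averaging is available).
SE and F1 are reported as NaN with a warning when their denominators are
zero. KNN uses Euclidean distance on the 1-D normalized feature with
voting ties (possible at even K) broken toward the positive class; the
SVM uses an RBF kernel with scikit-learn defaults (linear selectable).
The sweep covers K = 1..20 and k = 2..20 and each class is summarized by
the configuration attaining the highest accuracy (ties resolved toward
the smallest k, then the smallest K, for determinism).

## Synthetic data generator

Six latent nodes — one per brain area — follow a stationary VAR(p)
(default VAR(1), self-coefficient 0.5, unit-variance Gaussian
innovations). Stationarity is enforced by rejecting any coefficient set
whose companion-matrix spectral radius reaches 1. Every channel of an
area observes its node plus independent white Gaussian sensor noise
(default SNR 10 dB); the midline channels observe independent noise at
the typical signal amplitude. Band-limited content is injected as
amplitude-modulated sinusoids at 2/12/24/48 Hz (default amplitude 0.3,
independent phase per node) so wavelet tests have known energy targets.
Default trial length is 8064 samples at 128 Hz, the DEAP preprocessed
shape; tests and the demo configs use 512–2048 samples to keep runtimes
in seconds-to-minutes, which preserves every qualitative property (the
F-statistic scales roughly linearly with length).

Class structure: class c carries c − 1 directed cross-area links, with
per-link strength growing with the class (0.9, 1.35, 2.0 for classes
2–4; all cross-links are acyclic, so the spectral radius stays at the
self-coefficient). The class separation is therefore multiplicative —
more suprathreshold cells *and* larger F per cell — which gives the
quantifier cleanly disjoint per-class ranges at trial lengths ≥ 1024.
These strengths are chosen for unambiguous parameter recovery; nothing
is known about real per-emotion effect sizes, and no claim is made that
the generator mimics them. Valence/arousal labels are drawn uniformly
inside the class's score quadrant (with a 0.5-point margin from the 4.5
cut), so they always re-classify to the generating class.

Seeding: a master seed expands to per-trial generators via
`default_rng([seed, subject_index, trial_index])`, so any single trial
is regenerable without the rest of the dataset.

What passing tests do **not** show: the generator has no 1/f spectrum,
no artifacts, no volume conduction across areas, and broadband (not
band-specific) coupling, so perfect synthetic accuracy says nothing
about accuracy on real EEG — it validates the machinery, not the
neuroscience. Band-filtered runs on the generator illustrate this:
filtering discards part of the broadband coupling and accuracy drops
into the 70–95% range.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; the restricted-model RSS is clamped to
  be ≥ the unrestricted RSS to absorb float jitter (the inequality holds
  mathematically), and a perfect unrestricted fit maps to F = ∞.
- The DWT level-5 minimum signal length is 2⁵ = 32; shorter inputs raise
  with the minimum stated.
- Granger fitting requires n > 3p + 2.
- Thresholding is strict (`>`): a cell exactly at 60 is excluded.
- All artifacts of a pipeline run are byte-reproducible from
  config + seed; the run log (wall-clock timings) is the only
  non-deterministic output.

## Known limitations

- Pairwise (bivariate) Granger causality only — no conditional,
  multivariate or spectral variants, and no multiple-testing correction
  across the matrix (raw F-values are thresholded by design).
- The single-scalar feature discards which cells were suprathreshold;
  two very different networks can quantify identically.
- Subject-independent evaluation only; no per-subject models.
- The threshold (60) is an operating constant of the method, not a
  calibrated quantile; its sensitivity is exposed via configuration but
  not analysed here.
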