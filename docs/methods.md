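# Methods

## Signal model and pre-processing

The unit of analysis is a 5-second single-channel ECG segment. Records are
tiled into non-overlapping half-open windows `[start, start + n)` (sliding
windows available via `overlap`); a trailing remainder shorter than one
window is dropped. Each segment is detrended by subtracting its
least-squares straight line (intercept + slope against time) — the minimal
trend removal that leaves rhythm morphology untouched; the operation is an
orthogonal projection, hence idempotent and linear. All sources are
resampled to a common 250 Hz (polyphase band-limited resampling) so that a
given wavelet scale means the same frequency regardless of the native rate
of the source database (e.g. 360 Hz vs 250 Hz archives). WFDB reading
covers signal formats 212 and 16 with gain/baseline conversion to mV.

## Operator-modulated scalogram

The Gabor mother wavelet is

    psi(t) = (2 pi sigma^2)^(-1/2) exp(-t^2 / (2 sigma^2)) exp(i w0 t)

with defaults sigma = 1, w0 = 2. The continuous wavelet transform

    Wf(a, b) = a^(-1/2) * integral f(t) conj(psi((t - b)/a)) dt

is discretized as cross-correlation with the sampled conjugate wavelet,
dt = 1/fs as Riemann weight, zero-padded boundaries, evaluated with FFT
convolution per scale. The kernel is truncated at ±8·sigma·a, where the
Gaussian tail is ~1e-14, so the fast path agrees with the untruncated
double-sum evaluation (`gabor_cwt_direct`, kept as an independent oracle)
to ~1e-12 relative error.

The scalogram is E(a,b) = H(L(a)·Wf(a,b)). L(a) is a scale multiplier
("pseudo-differential-like operator": it acts on wavelet coefficients the
way a Fourier multiplier acts on frequency components; L(a)=1/a behaves
like a fractional derivative). Available forms: 1, 1/a, a, (1/a)^2,
(1/a)^(1/2), a^gamma. H(y)=|y|^q with q > 0. The adopted operating point
is L(a)=1/a with q=1/4: raising magnitudes to the 1/4 power expands the
small-amplitude part of the coefficient range (0.0001 -> 0.1), which is
where PEA, VF and VT differ; L(a)=1 with q=2 reproduces the conventional
energy scalogram.

**Frequency convention.** With w0 = 2 the wavelet's centre frequency at
scale a is w0/(2 pi a) = 1/(pi a) Hz, so the scale axis converts to Hz by
F(a) = 1/(pi a) exactly. The default grid is 64 logarithmically spaced
scales spanning 0.5–32 Hz, covering PEA's sub-Hz complexes through VF's
4–7 Hz oscillation with harmonics.

**A note on the scale response.** For a pure tone f0, the mean |Wf| over
time is proportional to sqrt(a)·exp(-sigma^2 (2 pi f0 a - w0)^2 / 2); the
sqrt(a) factor from the 1/sqrt(a) normalization shifts the maximizing
scale slightly above 1/(pi f0) — for sigma = 1 and f0 = 5 Hz the peak sits
near 4.5 Hz, about 10% below the tone. The response is unimodal in scale
and the tests assert the peak against this analytic maximizer. The
energy-weighted spectral centroid (NSI, below) of a conventional-setting
scalogram recovers a 5 Hz tone within one grid-frequency step.

No cone-of-influence masking is applied (all time columns are used);
property tests exclude a 0.5–1 s margin where boundary effects matter.

## NSI / NTI and the 16 features

NSI(b) = sum_a E(a,b) F(a) / sum_a E(a,b) — the per-column energy-weighted
mean frequency (spectral centroid time series, Hz). NTI(a) =
sum_b E(a,b) T(b) / sum_b E(a,b) — the per-row energy-weighted mean time
(temporal centroid spectrum, s). Both are convex combinations, hence
bounded by the grid's frequency/time range, and invariant under positive
rescaling of E. Zero-energy columns/rows are marked undefined and excluded
from statistics rather than imputed; with q = 1/4 exact zeros occur only
for an identically zero signal.

Eight statistics of each series form the 16-feature vector. The named
statistics fix conventions that the bare names leave open; all are
configurable:

| statistic | convention | default |
|---|---|---|
| mean | arithmetic | — |
| variance | population (÷n) | — |
| slope | OLS of value vs natural axis (time s for NSI, frequency Hz for NTI) | — |
| kurtosis | Pearson m4/m2² (not excess); 0 for constant series | — |
| skewness | m3/m2^(3/2); 0 for constant series | — |
| entropy | Shannon, bits, equal-width histogram, 0·log 0 := 0 | 32 bins |
| power | mean of squared values | — |
| mode | midpoint of most populated bin, leftmost on ties | 32 bins |

Whether "entropy" should instead be spectral or sample entropy, and what
the slope's abscissa is, are genuinely open; the defaults above are one
reproducible reading and are isolated behind `FeatureConventions`.

## Feature ranking

Per feature, within-class scatter S_w and between-class scatter S_b are
computed with class priors P_i = n_i/N, and the separability score is
J = S_b/S_w (+inf sentinel when S_w = 0). Two weighting conventions are
implemented for S_w: `literal` weights each sample by its class prior P_i;
`normalized` weights each sample by 1/N (the standard Fisher form).
`literal` is the default for fidelity to the stated definition; the two
coincide for balanced classes, and only under `normalized` does the total
scatter decompose exactly as S_t = S_w + S_b. J is invariant under affine
rescaling of a feature under both conventions, so ranking does not depend
on feature units. Features are ranked by J (ties broken by canonical table
order, NSI block first) and the top three are selected. Because features
are scored one at a time, no matrix scalarization (trace/determinant
criteria) is involved.

## Decision rule

The dissimilarity rho(x,y) = sum_j lambda_j |x_j - y_j|^(p_j), or more
generally w A w^T with w_j = |x_j - y_j|^(p_j/2) and A symmetric positive
definite (A = diag(lambda) recovers the diagonal form). rho is symmetric,
nonnegative and zero iff x = y, but need not satisfy the triangle
inequality — the diagonal form violates it whenever some p_j > 1 (for
p_j <= 1 every term is subadditive, so the diagonal form is itself
subadditive). The open balls of rho generate a topology; classification
assigns a test point the label of the single training point inside the
largest open ball around it, which is exactly the rho-nearest training
point, computed as an O(M) exact argmin (D = 3 and M of order 10^2–10^3
make spatial indexing pointless).

Ties at the exact minimum are resolved by a deterministic,
order-independent chain: majority label among tied points, then larger
training-class size, then lexicographic label order.

Default operating point: D = 3 on (mean NSI, variance NSI, mean NTI),
lambda = (6, 1, 1), p = (1, 1, 1). Features enter on their raw scales —
lambda itself plays the role of per-axis standardization, and tuning
lambda_1 relative to the others selects how strongly the mean-NSI axis
dominates the geometry.

## Evaluation

Stratified k-fold cross-validation (default k = 4, seeded): within each
class, samples are permuted and dealt round-robin, so per-class fold sizes
differ by at most one. Confusion matrices are oriented rows = predicted,
columns = actual. Per class: precision, recall, F1, and one-vs-rest
accuracy (TP+TN)/total. Macro averages are means of per-class values —
macro-F1 is the mean of per-class F1, not the harmonic mean of macro-P and
macro-R (these differ; the worked-example values confirm the former).
Micro averages pool TP/FP/FN and all equal the overall accuracy for
single-label prediction. 0/0 ratios are defined as 0 with a warning.
Pooled (all-test-sample) metrics are computed from the summed confusion
matrix over folds.

Binary schemes require per-sample four-class labels (cross-class errors
must be attributable): `normal_vs_abnormal` maps SR to negative and the
rest to positive on all samples; `pea_vs_shockable` restricts to samples
whose true class is abnormal and maps predictions VF/VT to shock and PEA
to non-shock. An SR prediction on an abnormal sample counts as non-shock
advice — the conservative choice (no shock delivered); it is configurable
(`sr_prediction_counts_as="shock"`).

## Synthetic rhythm generator

The generator produces class-conditional morphologies whose spectral
content and relative amplitudes match what the method assumes about each
rhythm, so that end-to-end tests exercise the pipeline's discriminative
mechanism — it makes no claim of clinical realism (no PQRST dynamical
model, no artifacts, no inter-patient variability):

- **SR**: Gaussian QRS pulses (sd 25 ms) at 1.2 Hz, 1 mV, 4% timing
  jitter, plus a trailing 15%-amplitude T-wave bump;
- **PEA**: broad (sd 120 ms) low-amplitude (0.15 mV) complexes at 0.8 Hz
  with 12% timing jitter — organized but slow and weak;
- **VT**: regular 3.3 Hz quasi-sinusoid, 1.5 mV, small second harmonic;
- **VF**: sinusoid whose instantaneous frequency follows a reflected
  random walk in 4–7 Hz, amplitude-modulated at 0.4–0.9 Hz, 1 mV.

White Gaussian noise (sd 0.05 mV) is added and each segment detrended.
Defaults: fs = 250 Hz, 5 s, 40 segments per class. Per-segment seeds are
CRC-32 of `"{seed}:{label}:{index}"` masked to 31 bits, so any segment is
reproducible in isolation and datasets are order-stable.

Consequently a high cross-validated accuracy here demonstrates that the
scalogram features and the weighted-metric rule separate rhythms *whose
spectral signatures differ as the four classes' do*; it does not predict
performance on archived patient data, where class overlap, artifacts and
the segment-selection policy dominate.

## Problem sizes and numerical choices

The reference evaluation uses 160 synthetic segments (40 per class) under
4-fold cross-validation with 64 scales x 1250 samples per scalogram; the
full run takes a few seconds on one core. Oracle-equivalence checks run
the quadratic-cost direct transform on 500-sample signals and 16 scales.
Degenerate inputs are handled explicitly: all-zero scalograms are
rejected, zero-variance series produce 0 kurtosis/skewness with a warning,
zero within-class scatter produces an infinite J with a warning, and 0/0
metric ratios are 0 with a warning.

## Known limitations

- Annotation-file (.atr) parsing is out of scope, so real-data labels must
  be supplied externally; artifact rejection and multi-lead fusion are not
  implemented.
- The grid (sigma, w0, scale count/range) behind archival reference
  figures is unknown; figure-level reproduction is not attempted.
- The inverse transform is not provided (the analysis is one-way).
- `pea_vs_shockable` on data where classifiers frequently predict SR for
  abnormal samples is sensitive to the SR-prediction convention above.
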