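# Methods

`mifala` implements a complete 4-class motor-imagery (MI) EEG
classification chain: band-pass preprocessing, local characteristic-scale
decomposition (LCD) of selected sensorimotor channels, one-vs-rest common
spatial patterns (CSP) over the ISC-augmented channel set, serial feature
fusion, wrapper feature selection by a firefly algorithm whose absorption
coefficient is adapted per member by a learning automaton (FA-LA), and
spectral regression discriminant analysis (SRDA) classification. This note
records the model assumptions, the defaults and why they hold, and the
design choices made where the construction was genuinely open.

## Signal model and preprocessing

Motor imagery modulates the power of sensorimotor rhythms in roughly the
8–30 Hz (mu/beta) band with a class-specific spatial distribution. All
trials are band-pass filtered with a 5th-order Butterworth design, 8–30 Hz
by default at fs = 250 Hz. Offline filtering is forward–backward
(zero-phase) so that epoch samples are not delayed relative to the cue;
`zero_phase=False` gives the causal single-pass variant a real-time system
would use. Epochs are cut from the half-open window [onset + 2.5 s,
onset + 3.5 s), 0-based sample indexing, i.e. 250 samples per trial at the
default rate — the early-imagery second, where discriminative
desynchronization is strongest in cue-paced paradigms.

A 50 Hz notch is available for ingested recordings
(`signals.notch_filter`) but is not part of the synthetic path, which
simulates no line noise.

## Synthetic data

The generator (`signals.generate_synthetic_mi`) emulates the statistical
structure the pipeline exploits, not the waveform detail of real EEG. Each
trial is unit-variance white Gaussian noise on every channel plus a shared
band-limited rhythm — a sum of four sinusoids with trial-random
frequencies in [8, 30] Hz and random phases, normalized to unit variance —
loaded onto the informative channels with class-dependent amplitudes. The
class-k covariance is therefore exactly `I + a_k a_k^T`. Each class boosts
a different informative channel cyclically (amplitude ratio 2:1), and the
loadings are scaled so the mean rhythm-to-noise power ratio over the
informative channels equals the configured `snr`. Defaults: 100
trials/class, 22 channels of which 4 informative, fs 250 Hz, 1 s epochs,
snr 2. Informative channels receive standard sensorimotor labels (C3, C4,
Cz, ...) so the LCD channel defaults resolve.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity within trials, volume-conduction correlation between
noise channels, artifacts (EOG/EMG), and inter-subject variability.
Passing tests on this data therefore demonstrates the correctness and the
directional behaviour of the algorithms (planted spatial structure is
found and exploited), not expected accuracy on recorded EEG.

A feature-level benchmark (`signals.generate_synthetic_features`) plants 6
informative columns (distinct per-class sign patterns of amplitude 1.0
over unit noise) among 24 standard-normal distractors; it is the ground
truth for selector-recovery checks.

## LCD

A signal is decomposed as `x = sum_p ISC_p + u_n`. The local mean at an
extremum tau_k is `a·L_k + (1−a)·X_k` with `L_k` the chord value between
the neighbouring extrema and `a = 0.5`; control points are joined by
linear interpolation and the two nearest extrema are mirrored about each
end of the signal. Sifting subtracts this mean repeatedly until the
relative change statistic `SD = sum_t |h_k − h_{k−1}|² / h_{k−1}²` falls
below 0.3 (conventional range for Cauchy-type stopping rules) or 30
iterations elapse; samples with a zero denominator are skipped and
counted. Up to 3 components are extracted, highest local frequency first;
a remainder with fewer than 3 extrema becomes the residue. Conservation
(components + residue = input) holds to machine precision by construction.

Per-ISC descriptors are the log10 band-integrated Welch powers of 20
equal-width sub-bands spanning 8–30 Hz, floored at 1e−12 so silent
components stay finite. This gives a deterministic 20-dimensional
descriptor matching the physiology (ERD/ERS is band-power modulation);
with 3 channels × 3 ISCs the frequency block F1 has 180 entries.

## CSP

Per-trial covariances are trace-normalized before averaging, making the
spatial features invariant to global trial amplitude. For classes A and B
the whitener of `R_A + R_B` is `P = eps^{−1/2} U0'`; diagonalizing
`P R_A P'` gives `U` and the filters `W = U' P`, rows ordered by
descending class-A eigenvalue, eigenvector signs fixed by making the
largest-magnitude entry positive (determinism across LAPACK builds).
Because whitening sends the composite covariance to the identity, the
class eigenvalues are complementary (`λ_A + λ_B = 1`). A numerically
singular composite covariance is ridge-regularized by `1e−10·trace/N` and
flagged. The multiclass extension is one-vs-rest: one filter set per
class against the pooled rest; all N filters are kept per class by
default (giving the 4N-dimensional F2 block; with 22 + 9 = 31 augmented
channels, 124 entries), with optional truncation to the m most
discriminative filters from each end of the spectrum.

## Fusion

The augmented trial stacks the original channels and then 3 ISCs per LCD
channel in channel-major order. Serial fusion normalizes each constituent
sub-vector — each per-ISC 20-vector of F1 and each per-class CSP block of
F2 — to unit Euclidean norm and concatenates F1 before F2; the
normalization granularity follows the per-sub-vector definition of the
fusion rule rather than a single global norm. Default fused dimension:
9·20 + 4·31 = 304.

## FA-LA feature selection

Each swarm member is a weight vector in [0,1]^D; weights strictly above
0.5 activate the corresponding feature (a member with no active feature
activates its single largest weight so its fitness stays defined).
Fitness is `1/CAv`, the reciprocal of SRDA validation accuracy on a
stratified 75/25 inner split held fixed for the whole run; zero accuracy
maps to a finite penalty of 1e6.

Attractiveness is the bounded form
`β(r) = β_min + (β0 − β_min)·exp(−γ r²)` with β0 = 1, β_min = 0.3, and r
the Euclidean distance normalized by √D so the (0,1] quantization of γ is
dimension-independent. Members move toward the current best member
(`θ' = clamp(θ + β·(θ_best − θ) + α(u − ½))`, α = 1, u uniform per
dimension); the best member itself is not moved (elitism), so the best
fitness history is non-increasing. An all-pairs classical sweep is
available behind `all_pairs=True`.

Each member carries one row of the N×20 transition matrix C, initialized
uniformly at 0.05 over the 20 γ levels {0.05, 0.10, ..., 1.00}. Per
generation the member's γ is drawn from its row by roulette (cumulative
sum rule on r uniform in (0,1]); after the member moves and is
re-evaluated, the row is updated by the linear reward–penalty scheme
(a = b = 0.1, e = 20):

- improved (new fitness < member's previous fitness):
  `C_j ← C_j + a(1 − C_j)`, others `← (1 − a)C_x`;
- otherwise: `C_j ← (1 − b)C_j`, others `← b/(e−1) + (1 − b)C_x`.

Both branches preserve row sums exactly; the penalty constant is
`b/(e−1)`, the classical normalization-preserving L_RP form. The reward
comparison baseline is the member's own previous-generation fitness,
initialized from the evaluation of the random initial population; the
within-generation order is draw γ → move → evaluate → reinforce, so the
reinforcement credits the γ that actually produced the move being judged.
The run is a pure function of (features, labels, config): every random
stream derives from the single config seed. Defaults: 50 members, 50
generations; the `fixed_gamma` option disables the automaton for a
plain-FA ablation at identical budget.

## SRDA

Class structure is encoded as c−1 response vectors by Gram–Schmidt
orthogonalization of the class indicator vectors against the constant
vector; each response is regressed on the centered feature matrix with
ridge penalty α = 0.01 (small, for conditioning when D exceeds the trial
count; solved by the D×D normal equations, ample at D ≈ 300).
Classification is nearest class centroid in the projected space,
Euclidean metric, ties to the smaller class index — the standard
discriminant-analysis assignment. Agreement with a generalized-eigenvalue
regularized LDA is a test oracle, not an implementation path.

Metrics: accuracy; Cohen's kappa from the confusion matrix (for balanced
data with uniform marginals this equals `(acc − 1/k)/(1 − 1/k)`);
per-class precision, recall and F-measure `2PR/(P+R)`, with
zero-denominator rates reported as 0 and counted.

## Pipeline and evaluation protocol

`run_pipeline` splits trials stratified (25% test by default), fits the
CSP bank, the FA-LA mask and the final SRDA on the training side only,
and applies all three unchanged to the test side. `cross_validate` deals
each class's seed-shuffled trials round-robin into k stratified folds
(default 10) and refits everything per fold; fold test sets partition the
data exactly.

## Problem sizes used in tests and the acceptance script

Checks run at desk scale, chosen as the smallest sizes at which each
property is clearly resolved: conservation and algebra identities on
100/50 random instances; selector recovery on the 6-informative/24-noise
benchmark at 100 trials/class, 20 fireflies, 30 generations, 10 seeds;
the end-to-end directional comparison on 12-channel synthetic MI data
(4 informative, snr 2, 100 trials/class), 20 fireflies, 15 generations,
5 seeds. At snr 2 this synthetic task is easy enough that both the
selected and the all-features classifiers approach 100% test accuracy, so
the end-to-end comparison typically resolves as a tie; the selector's
value shows in the roughly halved feature count and in the recovery
benchmark, where selected subsets beat the full set outright.

## Known limitations

- The 20-band log-power ISC descriptor is one reasonable choice of
  per-component features; alternatives (AR coefficients, wavelet powers)
  are not implemented.
- LCD endpoint handling mirrors only the two nearest extrema; very short
  or extrema-poor signals fall back to residue status rather than being
  extrapolated.
- The wrapper fitness uses a single fixed inner split rather than inner
  cross-validation; this is faster and reproducible but noisier as a
  subset-quality estimate.
- SRDA provides no probabilistic outputs and no kernel variant.
- EDF/GDF ingestion requires the optional `mne` dependency and maps
  annotations to labels by a user-supplied table.
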