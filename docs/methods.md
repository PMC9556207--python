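# Methods

`eegmusic` implements a closed-loop EEG music-feedback pipeline for mild
depression: decode a ternary emotion state from short frontal-EEG windows,
map it to a music stimulus, and evaluate the intervention with standard
depression rating scales. Because no recordings or questionnaire data are
publicly available for this paradigm, the package ships a synthetic-data
module that defines the "world" every other module is tested against. This
note documents the models, the parameters that matter, and what a green test
does and does not establish.

## 1. Synthetic EEG world (`eegmusic.synth`)

**Clean signal.** Each channel is a sum of three band-limited Gaussian
carriers (theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz) plus a 1/f background
(2 µV RMS). Band carriers model volume conduction: one shared cortical
carrier per band, seen by every channel through a random gain in [0.7, 1.0],
blended with a channel-specific carrier at relative weight 0.3. Frontal
electrodes (FP1/FP2/FPZ, the default montage) are strongly correlated in
practice, and this rank structure is what makes ICA-based artifact removal
work; fully independent channels would be an unrealistic worst case.

**Emotion states.** A hidden state per 0.5-s window — `active`, `passive`,
`normal` — drives the band amplitudes: beta is elevated when active, alpha
when passive (the standard affective-EEG convention of arousal-linked beta
and disengagement-linked alpha). Amplitudes form a geometric ladder
(4, 8, 16 µV RMS) so adjacent states are equidistant in *log band power*,
the scale spectral classifiers operate on. The per-window envelope is
smoothed with a 25-ms raised-cosine crossfade. States are drawn in 6-s
blocks (twelve windows), matching the music-decision cadence.

**Contamination** is strictly additive, so denoisers have exact ground
truth: Poisson-timed (default 0.2 Hz) 400-ms raised-cosine ocular blinks of
~80 µV peak with ±20% amplitude jitter; a mains sinusoid (50 Hz, 10 µV); and
white sensor noise of 2 µV SD (research-grade amplifier noise is 1–2 µV
RMS). Blink onset times are recorded in the session truth.

**What the generator does not emulate:** non-stationary electrode drift,
muscle (EMG) artifacts, inter-subject variability, realistic cortical
geometry, or any genuine emotional physiology. A green decoding benchmark
therefore establishes that the pipeline machinery is correct and
well-calibrated on a separable world — not that emotion can be decoded at
these accuracies from real frontal EEG.

**Scale cohorts.** Longitudinal SCL-90 / SDS / PHQ-9 scores for three
groups (4 feedback-training, 8 depression-control, 4 normal-control
subjects; six weekly tests) are truncated-normal draws around per-test
target trajectories: declining means for the feedback group, flat means for
both controls. Baseline draws are truncated to the enrolment criteria
(mild-depression band: SCL-90 > 26, SDS 53–62, PHQ-9 5–9; normal controls:
SCL-90 < 8, SDS < 53, PHQ-9 < 5), later tests only to each scale's
admissible range. The missing fifth test occasion in the source trajectories
is interpolated as the midpoint of its neighbours. A `trend` factor scales
the decline (1 = study-like, 0 = flat null).

## 2. Denoising (`eegmusic.preprocessing`)

**EMD.** Classic Huang sifting: cubic-spline envelopes through local
extrema, two extrema mirrored at each boundary, Cauchy SD stop at 0.2 with
at most 10 sifting passes per IMF and at most 10 IMFs. Sifting of a
candidate stops early only when it has no zero crossings at all (a
non-oscillatory tail that belongs in the residue). The residue is computed
by subtraction, so reconstruction is exact to round-off. The textbook
extrema/zero-crossing identity holds to within ~2% per IMF under the capped
schedule; we deliberately do not iterate until it is exact.

**FastICA.** Symmetric fixed-point iteration with tanh contrast, PCA
whitening to the numerical rank, symmetric decorrelation, tolerance 1e-6,
at most 200 iterations, seeded random orthonormal initialization.
Non-convergence returns the best iterate flagged `converged=False`.

**Artifact rejection** (both ICA routes): a component is discarded when it
looks ocular — excess kurtosis above `5 + 3·SE(kurt)` (SE ≈ √(24/n_eff),
n_eff from the zero-crossing count) *and* more than 40% of its power below
5 Hz — or when more than 60% of its periodogram power lies within ±1 Hz of
the mains frequency. The low-frequency gate exists because state-modulated
oscillatory carriers are leptokurtic scale mixtures that a bare kurtosis
threshold would clip; the standard-error inflation exists because very slow
components carry few independent samples, so their sample kurtosis scatters
widely. The EMD-only
route instead drops leading IMFs whose |correlation| with the channel falls
below a tenth of the best IMF–channel correlation — the common EMD denoising
heuristic; on realistic fixtures it rarely fires, which reproduces the
expected ranking of EMD as the weakest of the three routes.

**EMD+FastICA.** Per-channel sifting, then ICA across the pooled IMFs of
all channels, rejection as above, back-projection and per-channel
re-summation (plus residues). Pooling gives ICA ~10 observation rows per
electrode, which is what lets a 3-channel montage isolate blinks, mains and
sensor noise simultaneously; the depth of sifting matters, since the slow
blink energy lives in IMFs 6–10.

**Metrics.** SNIR is reported in dB as `SNR_out(dB) − SNR_in(dB)` with
noise defined against the known clean signal; it reduces to
`10·log10(P_noise_in / P_noise_out)`. Mean energy is `(1/n)·Σx²` (µV² — we
do not repeat the µV unit slip of the source tables). MAPE excludes samples
whose clean amplitude is below 1% of the clean RMS: the relative error is
undefined at zero, and for zero-mean oscillatory signals an absolute
near-zero guard lets sub-quantization samples dominate the average with
meaningless ~1e4% ratios. MAPE values on EEG remain large (>100%) because
most samples are small; only comparisons between methods are meaningful.

## 3. CNN classifier (`eegmusic.cnn`)

A window `[N_e, N_s, 1]` is treated as a gray image. Default architecture:
four (1×7) valid-mode convolutions with 8/16/32/64 filters, each followed
by (1×2) max pooling with trainable per-map affine parameters β (init 1)
and b (init 0); two ReLU dense stages (64, 16 units; dropout 0.2 on the
first); a 2-unit softmax head with log-sum-exp stabilization. Training is
plain full-batch gradient descent (η default 0.01) on cross-entropy, with
optional L1 penalty added as a subgradient. Pooling zero-pads ragged edges
on the right. Gradients are exact reverse-mode differentiation, verified
against central finite differences (< 1e-4 max relative error) for every
layer type. Dropout masks are drawn from a seeded stream so training is
bit-reproducible. Unprinted architectural constants (kernel sizes, filter
counts, dense widths) are package choices; everything is configurable, and
the architecture validator enforces only the conv→pool alternation and the
softmax head.

## 4. Gradient boosting (`eegmusic.boosting`)

Binary classifier maximizing the Bernoulli log-likelihood under the link
`p = e^F/(e^F + e^{-F}) = logistic(2F)`, with `F_0 = 0` (so `p_0 = 0.5`).
Each stage fits OLS projections `a^T o_i(t)` of per-time-index feature
vectors to the pseudo-residuals `2(y − p)`, keeps the `(a, t)` with minimal
SSE (smallest `t` on ties; singular designs fall back to a 1e-8 ridge with a
warning), line-searches the stage weight γ by bounded scalar maximization
on [−10, 10] (the likelihood is concave in γ), and shrinks the step by
ε = 0.1. Because the shrunk step stays on the concave ascent path between 0
and the optimum, the training likelihood is non-decreasing by construction;
training stops early when the gain drops below 1e-8. Shrinkage 0 is
accepted as a documented degenerate case (the model stays at `F_0`).

Feature representations: decimated per-channel amplitudes (`time`), log
band-power per channel (`bandpower`), or the CNN's penultimate activations
(`cnn`). The pipeline default is `bandpower`: linear weak learners cannot
separate classes that differ only in variance, so the logarithmic power
nonlinearity is supplied explicitly; it proved markedly better calibrated
than CNN-feature boosting in the end-to-end benchmark.

## 5. Feedback loop (`eegmusic.feedback`, `eegmusic.pipeline`)

**Ternary bridge.** The classifiers are binary; the three states come from
dual-thresholding the positive-class score (defaults θ_lo = 0.4,
θ_hi = 0.6). Classifiers trained to convergence are over-confident, so the
pipeline fits one temperature per model (a scalar applied to the logit)
on the fully labelled training session, by coarse grid search maximizing
ternary agreement; the ensemble score is the mean of calibrated
probabilities. Without this step the mid-range (`normal`) band is
essentially never populated. The evaluation session is simulated and seeded
independently of the training session.

**Music decisions.** Each consecutive block of twelve windows (6 s) votes
by majority; ties yield the neutral `medium` stimulus; trailing partial
blocks are dropped. State→valence mapping reinforces the decoded direction
(active→positive music) and is configurable for compensatory protocols.
Stimuli are fixed symbolic motif tables (ascending C-major at 120 bpm,
C-pentatonic drone at 90 bpm, descending A-minor at 60 bpm) rendered as
event lists — no audio synthesis. 399 six-second segments correspond to
4788 half-second markers; the identity `markers = 12 × segments` is exposed
as pure arithmetic.

**Protocol.** The default session schedule (scales 10 min, preparation 3,
breathing 3, two 13-min feedback exercises) totals 42 min; construction of
any schedule over the 45-min cap raises.

## 6. Statistics layer (`eegmusic.scales`)

Severity bands: SCL-90 ≤26 normal / >26 mild (the instrument's higher bands
are not used here); SDS 0–52 / 53–62 / 63–72 / >72; PHQ-9 0–4 / 5–9 /
10–14 / 15–19 / 20–27. Enrolment criteria are stricter than the bands and
are kept separate (a normal control needs SCL-90 < 8, not merely ≤26).
Group comparisons are independent two-sample t-tests from summary
statistics — pooled variance by default (df = n₁+n₂−2), Welch–Satterthwaite
by flag — with two identical degenerate groups returning t = 0, p = 1 by
convention. p-values come from scipy's t distribution and the implementation
is cross-checked against `scipy.stats.ttest_ind_from_stats` to 1e-10. No
multiple-testing correction is applied (matching the evaluated design). The
longitudinal report emits per-scale, per-test group means ± SDs, the three
pairwise p-values, and least-squares trend signs of group means.

## 7. Numerical and design choices

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  every pipeline sub-seed derives from the single config seed.
- SNIR saturates at +300 dB when the output residual is exactly zero, and
  raises when the input noise power is zero (nothing to denoise).
- Cross-entropy clips probabilities at 1e-12; the GB likelihood does the
  same.
- Weak-learner ties break to the smallest time index; majority-vote ties to
  `medium`; max-pool ties to the first window element.
- CSV is the canonical EEG container (wide, one column per channel, µV,
  `# eegmusic fs_hz=…` metadata line, %.17g precision so round trips are
  exact). Music goes to CSV event tables. EDF/MIDI writers were omitted —
  no suitable library is available in the target environment and binary
  containers add nothing to the analyses here.
- The scaled-down end-to-end benchmark uses a 120-s training session and a
  60-s evaluation session at 250 Hz; the suite's smoke tests shrink this
  further to stay fast.

## 8. Known limitations

- The synthetic world is deliberately separable; decoding accuracies have
  no clinical meaning.
- MAPE on zero-mean signals is scale-sensitive and reported only for
  method-to-method comparison.
- The EMD+FastICA identity on artifact-free input is approximate: the
  slowest 1/f background components occasionally trip the ocular rejection
  rule (observed distortion 0–12% MAPE across seeds).
- The EMD-only route is a near no-op on realistic contamination (its
  correlation rule rarely fires) — consistent with its expected last-place
  ranking, but it should not be used as a serious denoiser.
- FastICA on three raw channels cannot isolate more artifact sources than
  electrodes; its middling performance is structural, not a bug.
- Printed p-values of the source tables are not reproducible from rounded
  summary statistics and are not targets anywhere in the suite.
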