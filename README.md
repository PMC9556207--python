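# eegmusic

Closed-loop EEG emotion decoding and music feedback for depression
neurofeedback studies — a tested, fully synthetic re-implementation of the
complete pipeline: EEG simulation with ground truth, EMD/FastICA artifact
removal with quality metrics, from-scratch CNN and gradient-boosting emotion
classifiers, conversion of decoded states into music stimuli, and the
depression-scale statistics used to evaluate the intervention.

## Who this is for

Researchers prototyping BCI neurofeedback loops who need every stage —
signal cleaning, per-window classification, stimulus scheduling, outcome
statistics — testable end to end *without* human recordings. All inputs are
simulated with known ground truth, so each stage's claims are checkable.

## The science in brief

- **Denoising.** Frontal EEG (FP1/FP2/FPZ) is contaminated by ocular
  blinks, mains hum and sensor noise. Three routes are compared: empirical
  mode decomposition (EMD), FastICA, and EMD+FastICA (ICA across the pooled
  IMFs of all channels). Quality is scored by the signal-to-noise
  improvement ratio `SNIR = 10·log10(P_noise_in / P_noise_out)` (dB), mean
  energy `(1/n)Σx²`, and MAPE against the known clean signal. The combined
  route wins on both SNIR and MAPE in ≥ 8/10 seeded runs.
- **Classification.** A 0.5-s window `[N_e, N_s, 1]` is classified by (a)
  a small CNN — four conv(1×7)/max-pool(1×2) stages, two dense stages, a
  softmax pair — trained by batch gradient descent on cross-entropy, and
  (b) gradient boosting maximizing the Bernoulli log-likelihood under
  `p = e^F/(e^F+e^{-F})` with OLS weak learners `a^T o_i(t)`, line-searched
  stage weights and shrinkage ε = 0.1.
- **Feedback.** Calibrated classifier scores are dual-thresholded
  (0.4 / 0.6) into `active`/`normal`/`passive` states; each 6-s block of
  twelve windows votes by majority for a positive / medium / negative music
  stimulus rendered from fixed symbolic motif tables. 399 segments ↔ 4788
  half-second markers.
- **Evaluation.** SCL-90 / SDS / PHQ-9 severity banding, study-group
  assignment, and pooled/Welch two-sample t-tests on six-week group
  trajectories.

See `docs/methods.md` for models, assumptions, parameter defaults, and what
the synthetic world does and does not establish.

## Worked example

```python
from eegmusic.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=0), outdir="pipeline_out")
for k in ("snir_db", "window_agreement", "n_segments", "music_counts"):
    print(k, report[k])
```

prints (exact numbers for seed 0):

```
snir_db 9.28881669538927
window_agreement 0.9416666666666667
n_segments 10
music_counts {'positive': 3, 'medium': 2, 'negative': 5}
```

Read: the EMD+FastICA denoiser improved the evaluation session's SNR by
~9.3 dB against ground truth; 94.2% of the 120 half-second windows were
decoded to the true hidden emotion state by the calibrated CNN+GB ensemble
(trained on a separate 120-s synthetic session); the 60-s session yielded
ten 6-s music decisions, three positive and five negative. `pipeline_out/`
holds the
noisy and denoised recordings (CSV), truth and decoded label tracks, the
music event table, and both serialized models.

The same loop is scriptable from the shell:

```bash
eegmusic simulate eeg --duration 60 --seed 3 --out sess
eegmusic train-gb --data sess_noisy.csv --labels sess_labels.csv --out gb.json
eegmusic classify --in sess_noisy.csv --gb gb.json --out decoded.csv
eegmusic feedback --labels decoded.csv --out music.csv
eegmusic run --seed 0 --out pipeline_out     # full pipeline in one step
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it simulates a fresh contaminated session under the given seed, denoises it
with EMD+FastICA, trains both classifiers on a matched training session,
decodes the emotion sequence, renders the music decisions, and prints the
resulting session report before writing the results file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
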