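# Methods

## The experiment being modeled

Each trial shows a fixation cross for a uniform 800–1300 ms, then a static
image: bistable (condition c1) or unambiguous (c2), in an exact shuffled
50/50 split per 100-trial block (stratified assignment, not coin flips, so
realized counts are always 50/50). The participant presses a button at the
first interpretation and, for c1, again at the perceptual reversal, which
ends the trial; otherwise the trial times out at 5000 ms. A session is 10
training trials (alternating the two pre-selected images) plus three test
blocks — 310 stimuli. Training trials are excluded from analysis.

Between trials the simulator inserts a fixed 1500 ms gap plus a 2700 ms
blink-reminder period. Together with the ≥ 800 ms fixation this puts at
least 5000 ms between any trial's end and the next stimulus onset, so a
[−1000, +5000] ms epoch locked to any event can never reach the next
trial's stimulus window. (A button press can coincide with trial end, so
nothing shorter guarantees this.)

## Synthetic EEG

The background is independent per-channel noise, pink (amplitude ∝ 1/√f,
flat below 1 Hz, no DC) by default — raw EEG is not white — with white
noise as an analytically clean option; σ is the time-domain SD in µV
(default 10 µV). Noise is synthesized in the frequency domain at an
FFT-friendly length and truncated; each channel is normalized empirically
to σ.

**ERP components** are Gaussian bumps g(t) = A·exp(−(t−ℓ)²/2w²) added at
every matching lock event (latency ℓ = center, width w = SD, signed peak A,
per-channel gains). The source literature describes components only by
window and polarity; a smooth unimodal bump is the minimal faithful shape.
With σ = 0 and one component, the recording equals the analytic waveform to
1e-9 µV before filtering (tested).

**Band-power modulations** multiply the background's expected power in a
band B over a window by a factor g ≥ 1: a burst of band-limited filtered
noise (generation band inset 1 Hz so transition-band leakage stays inside
B) is windowed with 100 ms cosine ramps and scaled to variance
(g−1)·σ²·φ(B), where φ(B) is the analytic fraction of the noise variance in
B. Welch band power over the window then converges to g × baseline within
10% over ≥ 200 trials (tested). A small positive bias (~0.2–0.3 dB at
g = 2) remains from window-leakage and mean-removal details; it is well
inside every tolerance used.

Default reversal probabilities (second press given a first press, c1 only)
are FD 0.55 / FN 0.65 / FI 0.75 — the FI > FD ordering follows the
hypothesis that field-independent observers reverse more readily; the
magnitudes are free parameters of the generator, not empirical claims.
First-press latency is truncated-normal (900 ± 250 ms on [300, 2000]);
the press-1→press-2 delay 800 ± 300 ms on [400, 2300], keeping press 2
inside the timeout. A first press occurs with probability 0.95 in either
condition.

**HFT responses.** Two regimes. The 2-parameter model draws item
correctness independently given ability a ∈ [0, 1] with
P(correct) = a^d (item difficulty exponent d > 0), so a = 1 ⇒ all correct
and a = 0 ⇒ all incorrect. The parallel-item regime targets a *realized*
0/1 inter-item correlation r: items share a Gaussian factor with loading
ρ = sin(πr/2), thresholded at 0 — the arcsine law φ = (2/π)·asin(ρ)
inverted at p = ½ — so Cronbach's α matches the Spearman–Brown closed form
k·r/(1+(k−1)·r) (≈ 0.868 at k = 32, r = 0.17). Group ability centers are
FD 0.25 / FN 0.55 / FI 0.85 (SD 0.05): with a 32-item penalized score the
binomial noise is ≈ 5 points SD, and this separation is what makes a
tertile split recover planted FD/FI labels with ≥ 90% agreement, the
generator's documented recovery property.

## Preprocessing

The 2–65 Hz band-pass is a cascade of two Hamming windowed-sinc kernels:
a high-pass with 2 Hz transition width (cutoff 3 Hz) and a low-pass with
10 Hz transition (cutoff 60 Hz), orders from the Hamming rule
N ≈ 3.3·fs/Δf rounded to even (total order 992 at fs = 500). The cascade is
re-symmetrized to exact c[k] = c[N−k] (type-I linear phase). Application is
single-pass with group-delay compensation — centered convolution of a
symmetric kernel — not forward–backward filtering, which would square the
magnitude response; edges are reflection-padded and trimmed. Passband
ripple is within ±1% over [4, 55] Hz and stopbands are > 50 dB down.

Epochs are half-open sample windows [e + round(−1000·fs/1000),
e + round(+5000·fs/1000)) around each lock event; trials whose window
leaves the recording are dropped with a logged reason. Baseline correction
subtracts, per trial and channel, the mean over [−1000, 0) ms before *that
trial's stimulus onset* — also for button-locked epochs. Anchoring button
epochs to their own prestimulus would subtract reversal-related activity;
a single prestimulus anchor per trial is the only internally consistent
reading. Because button-locked epochs do not contain the prestimulus
window, baselines are computed from the continuous recording and passed to
the correction step. Correction is idempotent by construction.

Virtual locations L1 {Fp1, F7, FC1}, L2 {Fp2, F8, FC2},
L3 {TP9, CP5, CP1, P3, O1}, L4 {TP10, CP6, CP2, P4, O2}, L5 = L1∪L3,
L6 = L2∪L4 are unweighted channel means, appended to the 24 electrodes for
30 analysis locations. Group features are computed on the group-averaged
waveform, never as means of per-channel feature values (the two differ for
latencies; the averaged-signal convention is asserted by test).

## Features

Local peaks: a sample is a local extremum if it strictly exceeds every
sample within ±20 ms (the neighborhood default mirrors common ERP
peak-measurement practice; the window bounds are inclusive). If the search
window contains no local extremum of the requested polarity, the windowed
absolute extremum is returned flagged `is_local=False`. Ties break to the
earliest latency. "Positivity" features report the signed maximum,
"negativity" features the signed minimum; downstream comparisons use the
signed values. Features 1–8 are measured on the condition-wise onset-locked
ERP; feature 10 on the press-1- and press-2-locked ERPs of c1 trials, each
within [−300, −200] ms of its own press (needed for the press-1 vs.
press-2 comparison). A participant contributes a value only where ≥ 5
trials underlie the average (configurable; the protocol states no minimum);
below that the row is emitted as missing, never silently dropped.

Welch estimation uses 500-point Hamming windows, 500-point FFT, no
overlap — on the 1000 ms (500-sample) segments this is a single modified
periodogram on a 1 Hz grid. Normalization makes ∫PSD df equal the
windowed, mean-removed signal power (Parseval identity, tested to 1e-6).
Band integrals sum bins whose centers lie in [low, high] inclusive: alpha
8–13 Hz = 6 bins, low gamma 26–40 = 15, gamma 26–60 = 35. The pre-onset
low-gamma segment [−200, −50) ms is only 75 samples; there the window
shrinks to the segment and the FFT is zero-padded to 500 points so the
reporting grid stays at 1 Hz — the canonical 500-point window cannot apply
verbatim to a 150 ms segment, and discarding data would be worse. This
feature is computed *without* baseline correction: its window lies inside
the baseline interval, and subtracting the baseline mean there would
confound the effect of interest. Estimation modes are deliberately
distinct code paths: alpha (feature 11) is Welch of the trial-averaged
waveform; the gamma features (9, 12) are per-trial Welch with the linear
band powers averaged before the dB transform. For phase-locked identical
trials the two coincide; for random-phase oscillations the averaged-trial
estimate is strictly smaller (tested). Band powers are reported as
10·log₁₀(µV²) with the linear value kept as an auxiliary column; dB is the
natural scale for the negative spectral means such analyses report, though
the exact transform used historically is not documented — only the
difference structure matters for the t-tests, and a monotone transform
changes none of the qualitative conclusions.

## Statistics

Families: (a) c1 vs. c2, onset features 1–9, paired within participant;
(b) press 1 vs. press 2, features 10–12, c1 only, paired; (c) FD vs. FI on
c1 (button features on the press-2 epoch), two-sample. The two-sample test
is pooled-variance Student — df = n₁+n₂−2 is the design's bookkeeping
(19 at 14 vs. 7) — not Welch. Paired tests drop incomplete pairs;
two-sample tests drop missing entries; realized n is recorded per row and
df is asserted against the design formula per row. Exactly equal samples
return t = 0, p = 1; zero variance with unequal means is an error.

Holm–Bonferroni is applied per feature across its 30 locations by default
(`--family` switches to global or none). The family the original analyses
used is not recoverable — reported "significant" raw p-values near 0.047
could not survive any plausible 30-location Holm family — so every output
carries both the raw and the adjusted column and the report header states
which one selected its rows; neither is asserted as the historical choice.

## Validation studies and problem sizes

* **ERP recovery** (100 runs, 150 trials, σ = 1 µV, single-channel
  montage): measured peak amplitude is compared to the analytic component
  *after* the analysis band-pass, latency to the injected latency. A
  Gaussian bump is DC-centered in frequency, so the 2 Hz high-pass removes
  ~0.5–1.2 µV from a 4 µV bump at any width — an inherent property of
  high-pass filtering slow ERP components, not an estimation error; the
  filtered waveform is the attainable target. Achieved: mean |Δamp|
  ≈ 0.04 µV, mean |Δlat| ≈ 0.3 ms, 100% of runs within ±0.5 µV / ±8 ms.
* **Null FWER** (25–30 cohorts of 10 participants × 24 trials, pure-noise
  background so conditions, press epochs and groups share one generative
  law): fraction of per-feature Holm families with ≥ 1 rejection ≈ 0.05,
  within binomial error of the nominal level.
* **Planted-effect power** (8–10 cohorts, 7 FD vs. 5 FI, 30 trials): an
  FD-only gamma doubling in [−1000, 0] ms before the reversal press at
  T8/CP6/TP10 is detected per channel with power 1.0 after Holm, and the
  measured FD−FI difference is ≈ 10·log₁₀2 ≈ 3 dB.

Replicate counts are sized for single-CPU runs of a few minutes; the
statistics they estimate (error rates, power) are stable at these sizes
because each replicate's feature estimates average many trials.

## Known limitations

No eye movements, blinks, EMG, or volume-conduction head model (per-channel
gains only); no artifact rejection or re-referencing (none is modeled);
inter-trial intervals guarantee epoch separation that real recordings may
not honor (a real-data run may truncate late epochs). Passing tests show
the *pipeline* is correct under the generator's assumptions — stationary
1/f noise, additive phase-locked components — not that real EEG satisfies
those assumptions. GDF input and scalp-map rendering are out of scope; a
per-channel CSV export replaces topographic graphics.
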