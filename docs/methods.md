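# Methods

This note documents the models, parameter choices and numerical decisions
behind `gripdecode`, and what the synthetic benchmark does and does not
establish about real recordings.

## Synthetic recording model

The generator produces 96-channel voltage (μV) as the sum of four parts:

* **Baseline noise** — white Gaussian, sd `noise_sd_uv` (default 10 μV),
  independent per channel; a stand-in for thermal/amplifier noise and
  distant background activity.
* **Movement modulation** — band-limited Gaussian noise (4th-order
  Butterworth band-pass over `fs/2^7 … fs/2^3`, exactly the union of the
  wavelet scales the features use), scaled per channel and per cue: during
  a cue of movement *m*, the added RMS on channel *c* is
  `modulation_rms_uv · p[m, c] · sqrt(1 − decline)`, zero during rest.
  Band-power modulation is the minimal structure that makes an MWP analysis
  meaningful — MWP measures multiunit-band power, nothing else about the
  signal matters downstream.
* **Spikes** — a fixed 1 ms biphasic template (sharp ~0.27 ms negative
  lobe, smaller slow rebound; half-sample-centered so the lobe survives any
  sampling rate) placed at Poisson times. The rate is
  `spike_rate_hz · (1 + spike_rate_gain · envelope/noise_sd)`, i.e. spiking
  shares the movement-modulation drive, which is what makes mean wavelet
  power and threshold-crossing counts correlate, as they do in real
  multiunit recordings. Only threshold-crossing *counts* matter downstream,
  so the waveform is deliberately simple.
* **Stimulation artifacts** — at the FES pulse rate (50 Hz default) the
  targeted channels are railed to ±`artifact_amp_uv` (default 800 μV) for a
  0.5 ms rectangular biphasic flat-top (amplifier saturation), followed by
  an additive 1 ms exponential settle. The flat-top *replaces* the signal,
  which both matches saturating front-ends and guarantees the detectability
  contract (window max ≥ configured amplitude). Ground-truth onsets and
  spike times ride along in recording metadata.

The `decline` knob multiplies modulation **power** by (1 − decline) — a
decline of 0.33 removes a third of the movement-related band power while
leaving the noise floor untouched, emulating chronic signal-quality loss.

**Spatial patterns.** Each movement's 96-dim pattern is nonnegative
(entries weight RMS gains) with unit L2 norm. Patterns are built from a
globally shared component, optional pair-shared components, and
per-movement components on *disjoint channel supports*, mixed as
`sqrt(ρ)·shared + sqrt(ρ_pair−ρ)·pair + sqrt(1−ρ_pair)·individual`, so
every pairwise cosine equals its target exactly rather than approximately.
The default base correlation is 0.2 (a separable regime); experiments on
representation overlap raise one pair (block/paperweight by convention in
the analysis drivers) toward 0.9.

**Cue protocol.** Training blocks hold 3 cues per movement in globally
shuffled order, each cue 3–4 s uniform, bounded by 4–5 s uniform rests
(so n movements × c cues produce nc movement cues and nc+1 rests).
Expected block duration with 7 movements is 21·3.5 + 22·4.5 = 172.5 s,
≈ 3 minutes.

## Problem sizes

`SimConfig` defaults to the hardware rate of 30 kHz. The analysis drivers,
the heavier tests and the acceptance script run the full cue protocol at
**3 kHz**: the feature bands are defined dyadically (`fs/2^7 … fs/2^3`), so
every stage is rate-consistent, and a five-block session (≈ 870 s × 96
channels) stays desk-sized. Two stages keep higher rates where physics
demands it: the acquisition-filter and artifact-excision checks run at
30 kHz (the 7.5 kHz corner needs the bandwidth; 3.5 ms = 105 samples), and
the MWP–threshold-crossing correlation fixture runs at 15 kHz because a
1 ms spike spans only 3 samples at 3 kHz and the crossing detector then
misses most events even though the underlying coupling is present.

## Preprocessing decisions

* **Noise RMS** for threshold crossings is the RMS of the 250 Hz
  high-passed trace over the full analyzed segment (after artifact
  excision); a median-based robust estimate (`robust_rms=True`) is
  available when spike contamination of the estimate matters.
* **Excision window alignment**: 0.5 ms before the detection sample +
  3.0 ms after, 3.5 ms total; overlapping windows merge; edge windows are
  truncated and logged. The artifact log maps cleaned sample indices back
  to original ones, and non-artifact samples are conserved exactly.
* **Crossing events** get a 1 ms lockout so a single spike is never
  counted twice.
* The 12-channel artifact-detection subset is drawn once per session from
  the session seed and recorded in the log.
* Filters are applied causally (forward-only), as real-time hardware does;
  the 0.3 Hz first-order high-pass has a ~0.53 s time constant, so
  DC-step and impulse responses need a few seconds — not fractions of a
  second — to settle below microvolt/1e-6 levels.

## Feature decisions

* "Mean coefficient" per bin/channel/scale is the mean of **absolute**
  detail coefficients (a zero-mean band's signed mean is ~0 and carries no
  power information); mean-of-squares is available via
  `WaveletSpec(magnitude="square")`.
* The transform is the **undecimated (stationary)** wavelet transform run
  over each continuous block with symmetric end padding, then binned —
  full dyadic depth cannot be extracted from an isolated 100 ms bin, and
  the stationary transform preserves per-bin attribution at every needed
  scale without block-edge loss. Only scales up to the deepest used scale
  are materialized.
* Standardization parameters are **frozen from training** and reused at
  decode time (a deployed decoder cannot re-standardize on the fly);
  standard deviations are floored at 1e-9 with the floored entries logged.
* Trailing partial bins are dropped, never padded.

## Decoder decisions

The published interface contract is: one output class per movement with a
bounded score in [−1, 1], a zero activation threshold, and
highest-score-wins arbitration. The scorer behind that contract here is a
one-vs-rest Gaussian-kernel SVM (rest bins are negatives in every
scorer; rest itself has no scorer), decision values squashed by tanh.
Kernel width uses the median heuristic on up to 1,000 training rows
(`γ = 1/(2·median²)`); regularization is fixed at C = 10. Exact score
ties break to the earlier label in the model's canonical order.

**Individual accuracy** is whole-block binary agreement between a
movement's activation indicator and its cue indicator — with seven
movements this makes per-movement values in the high-90s the natural
scale, consistent with per-movement accuracies reported for such systems;
a cue-restricted variant (`cue_restricted=True`) is provided for
sensitivity-style analysis. **Response-probability** rows are computed over
decoder-active bins within each cue and sum to 1; cues with no active bins
are flagged and excluded rather than imputed.

## Representation analysis decisions

* Bins enter the analysis only when the decoder is active for the cued
  movement *and* the bin lies inside that movement's cue.
* PCA removes channel means only — MWP is already standardized, and
  variance-scaling would distort the spatial pattern geometry. Component
  signs are fixed (largest-|loading| channel positive) for determinism.
* One Gaussian per movement cluster is fit for visualization; clusters
  with fewer than 3 selected bins are skipped in the summary (the
  underlying fit function still refuses them loudly).
* Regression inference is standard OLS (t on the slope, n−2 df);
  correlation inference is Pearson's t-transform.
* PCA is fit on bins pooled across movements (not per movement).

## Closed loop and GRT scoring

The loop consumes one 100 ms feature bin at a time, scores and arbitrates
it independently, and is bit-for-bit identical to offline decoding of the
same features. Scripted intent replaces the human: each transfer attempt
is reach (rest, 1 s) → [Hand Open, 1 s — Can only] → grasp (0.5 s) → hold/
transfer (1.5 s) → release (rest, 0.5 s), repeated through the 30 s
window; durations are configurable.

Transfer rules: the grasp must be acquired during grasp/hold; the Can
additionally requires a Hand-Open activation during its pre-positioning
phase (two decoder classes per transfer). A grip is **dropped** (attempt
failed) when the grasp class stays inactive for *more than one
consecutive* hold bin: grip force persists through a single 100 ms decoder
flicker — with a per-bin rule, a 99.3%-accurate decoder would fail ~10% of
ideal-intent attempts, which contradicts the intended "perfect intent ⇒
all transfers succeed" behavior — while a ≥ 200 ms dropout (e.g. a
scripted 500 ms rest injection) still fails the attempt. An attempt still
gripping when the window closes is **incomplete**. Transfer time is
release time − grasp onset. These operational definitions are explicit
configuration (`drop_tolerance_bins`), since failed/incomplete are not
standardized beyond "the object was dropped".

## Benchmark fixtures and what they show

The **default separable fixture** (pattern cosine 0.2, modulation 15 μV ≈
bin-level z-shifts well above 2 on patterned channels) yields held-out
individual accuracies above 99% for all seven movements — evidence that
the pipeline is implemented correctly, *not* that real cortex is this
separable. The **overlap sweep** runs the block/paperweight pair through
cosines 0.3→0.9 at 10 μV modulation — an intermediate regime chosen
because at 15 μV accuracy saturates regardless of overlap and at 5 μV
noise swamps both accuracy and the distance estimates; there the pair's
aggregate separability and held-out accuracy fall together (positive rank
correlation), the pair is recovered as the minimum-distance pair, and the
degraded model completes fewer simulated GRT transfers on matched seeds.

What the generator does **not** emulate: spike waveform diversity and
sorting ambiguity, oscillatory LFP structure, electrode impedance drift,
non-stationary day-to-day representation change, movement/FES artifacts
other than the periodic pulse train, and any biomechanics of real grasps.
Passing tests therefore validate the analysis machinery and its internal
consistency, not clinical performance.

## Known limitations

* The desk-scale rate (3 kHz) shifts the feature bands to 23–375 Hz;
  results are internally consistent but absolute band frequencies differ
  from the 30 kHz deployment described above.
* The SVM's hyperparameters are pragmatic defaults, not tuned replicas of
  any deployed decoder.
* GRT outcome definitions (drop tolerance, incomplete) are explicit
  configuration; other conventions will change absolute transfer counts.
* The pipeline runner's resume logic hashes outputs per stage; it re-runs
  the whole simulate/extract phase if any block's outputs are corrupted.
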