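# Methods

This note records the modeling choices behind `p300fuse`: what the pipeline
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Paradigm model

A session spells `n_characters` characters; each character block runs
`n_repetitions` rounds in which all 12 rows/columns flash once in random
order (a fresh seeded permutation per round, unconstrained — consecutive
repeats of the same row/column across round boundaries are allowed). Exactly
2 of the 12 flashes per round are targets. Stimulus codes are 1–6 for
columns (left→right) and 7–12 for rows (top→bottom); the bases are arguments
of `build_event_stream` for datasets using another convention.

Timing presets:

- `DATASET_I` — 35 characters × 10 rounds at 240 Hz with a 125 ms
  stimulus-onset asynchrony (100 ms flash + 25 ms gap). The asynchrony is
  the physically plausible reading of the source paradigm's sub-millisecond
  "ISI" figure.
- `DATASET_II` — 1 character × 15 rounds; 100 ms flash + 75 ms gap (175 ms
  SOA) at 240 Hz.

Character blocks are separated by a 2 s cue pause (also inserted before the
first block) so that no epoch of one block overlaps another block's flashes.
The spelled text defaults to cycling the matrix alphabet; the actual
characters only determine which codes are targets.

Fusion rosters: an 8-subject roster splits into four pairs or two
quadruples in roster order; for triples, two full triples are formed and the
leftover pair is completed by one seeded random pick from the
already-grouped subjects, so one subject appears twice.

## Preprocessing

Filtering runs on the continuous recording, before epoching, so filter edge
transients stay outside the trials:

1. 50 Hz notch (second-order IIR, Q = 30), zero-phase.
2. 0.1–30 Hz Butterworth, order 4, zero-phase. The band is realized as
   lowpass followed by highpass rather than one bandpass cascade: the 0.1 Hz
   corner has a multi-second impulse response, and pad-and-reflect initial
   conditions leak drift transients large enough to dominate a short
   record's stopband. The highpass therefore uses Gustafsson's exact
   forward–backward initialization (`filtfilt(..., method="gust")`). With
   this arrangement a 10 s, 50 Hz tone is attenuated by ~66 dB while 10 Hz
   passes within 0.01 dB.

Epochs are `[onset, onset + epoch_samples)` windows — no pre-stimulus
baseline. The canonical window is 702 raw samples (≈2.9 s at 240 Hz), chosen
so that decimation by 2 yields exactly the 351 time points the classifier's
published shape consumes; the quoted "1 s" source window is inconsistent
with both the rate and that shape, so the network input is treated as
authoritative. At a 125 ms SOA such windows overlap neighboring flashes;
that is inherent to the paradigm, and the classifier must rely on the
*time-locked* response rather than window-exclusive content.

Decimation keeps every factor-th sample (no averaging); this is alias-safe
only because the 30 Hz lowpass precedes it, and `downsample` documents that
precondition rather than re-filtering.

Normalization is per-epoch, per-channel z-scoring with population variance;
zero-variance channels become all-zero instead of NaN. A recording-wide
scope is available behind the `scope` flag.

## Fusion

Epoch alignment across subjects is by event index in the shared stimulus
stream — the paradigm guarantees simultaneity, so no cross-correlation
alignment is attempted, and differing label vectors are a hard error rather
than something to reconcile. Parallel fusion stacks channels in subject
order (subject 1's channels first); serial fusion concatenates time in
subject order. Fused sets are not re-normalized: serial concatenation can
introduce a step at the joins, but each segment is already z-scored and
re-normalizing would mix subjects' statistics.

## Network and training

Architecture as in the README table. Open details resolved as follows:

- The first convolution's published count (1,040) pins only 64 weight
  elements per filter; the default geometry is 8×8 (fits both the 16- and
  8-channel input widths), with (64,1), (16,4), (32,2) and transposes
  selectable — all reproduce the count. The second kernel is forced to 6×6
  by its count (18,464) and is not configurable.
- Dropout rate 0.5 (unstated in the source; the conventional default).
- Glorot-uniform initialization with an explicit seed; training shuffles
  and dropout masks come from the same seeded generator, so runs are
  bit-reproducible on a fixed BLAS.
- "Batch normalisation" in the source abstract is read as mini-batch
  training; the published layer tables contain no BatchNorm layer and none
  is implemented.
- Softmax is folded into the cross-entropy head for gradient stability;
  `predict_proba` applies it explicitly.
- Optional inverse-frequency class weights (`class_weight="balanced"`)
  counter the 1:5 target/non-target imbalance; off by default, since the
  reference results report the imbalance rather than correcting it.
- No early stopping; a fixed number of epochs (default 75).
- Train/test split: stratified 80/20 over shared event indices with a fixed
  seed (the source states none); splitting on event indices keeps fused
  sets aligned.

The engine computes convolutions as im2col GEMMs in float32. The first conv
layer skips its input gradient during training (nothing sits below it);
ties in max-pooling split the gradient equally. Exactness of all gradients
is asserted against central finite differences in `tests/test_nn.py`.

## Synthetic sessions

`generate_session` emulates the statistical structure the method needs, not
biophysics:

- **Shared events** — all subjects receive field-identical event streams.
- **P300 template** — a positive Gaussian bump, full width 200 ms
  (σ = 33 ms), peak 6–12 µV (sampled per subject), latency 280–330 ms with
  20–30 ms per-trial jitter, spatial gain peaking at Pz/Cz over the montage
  Fz, Cz, P3, Pz, P4, PO7, PO8, Oz. Added at target onsets only; truncated
  at 5σ where the tail is <4·10⁻⁶ of peak.
- **Background** — 1/f-power noise, independent per channel, smoothed
  across neighboring channels with a fixed [0.15, 0.7, 0.15] kernel to
  mimic volume conduction, RMS renormalized per channel afterwards. An
  optional 10 Hz alpha sinusoid is off by default.
- **SNR presets** — noise RMS relative to template peak: high 0.25×,
  moderate 1×, low 4×.

Not emulated: N200 and other ERP components, eye/muscle artifacts,
non-stationarity, inter-channel noise correlation structure beyond the
smoothing kernel, and electrode drift. Passing tests therefore demonstrate
that the pipeline recovers a time-locked class-discriminative deflection
under realistic SNR — not performance on real recordings.

## Benchmark scale

The seed-averaged classification benchmark (in the acceptance tests) uses
sessions of 6 characters × 5 rounds (360 flashes, 60 targets per subject),
4 subjects forming 4 single-subject models and 2 two-person parallel
groups, 0.6 s epoch windows (144 raw samples → 72 points at 120 Hz — long
enough to contain the slowest simulated P300 plus jitter and template
width), 10 training epochs with balanced class weights, averaged over 5
seeds. These sizes are the package's chosen desk-scale experiment; the
canonical full-session settings remain the defaults of the respective
functions.

## Known limitations

- The NumPy engine targets this architecture class (stride-1 same conv,
  2×2 pooling, dense); it is not a general deep-learning framework.
- Bit-reproducibility holds for a fixed BLAS; across BLAS builds,
  float32 GEMM reduction order may differ in the last ulp.
- The MAT-file reader covers the BCI-Competition-III field layout only and
  infers repetitions from flash order (character boundaries are not encoded
  in that layout).
- `partition_subjects` generalizes the 8-subject scheme to other roster
  sizes by the same leftover-filling rule; for rosters where the leftover
  exceeds the grouped pool it raises rather than guessing.
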