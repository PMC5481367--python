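# Methods

This note documents the generative model behind the synthetic sessions, the
signal-processing and statistical choices in the pipeline, the parameters
that matter, and what the tests do and do not establish about real data.

## Synthetic session model

A session is a continuous multichannel recording (µV, 250 Hz by default) on a
reduced 10-channel montage: Pz, Cz, F3, F4, M1, M2 (EEG), VEOG, HEOG (EOG),
EMG over the right tibialis anterior, and ECG. Every signal the analysis
touches lives on these channels; Pz is the analysis target, Cz the recording
reference (the Cz channel is identically flat before re-referencing, as in a
Cz-referenced acquisition), M1/M2 support the linked-mastoids montage and
F3/F4 give the ocular artifacts a frontal projection.

**Paradigm.** Five conditions (foot/hand execution and imagination, rest), 25
trials each, shuffled as one deck. Per trial: 3 s instruction, 1 s pause, six
low tones at 1 Hz over a 6 s task window (high tones 0.5 s after each), 1 s
inter-trial pause. Tones are represented purely as event markers — they serve
only as time anchors, and the movement-locked potential is absent during rest
despite identical tones, so no audio is modeled.

**Movement-locked component.** During foot-execution trials only, each cue
contributes one damped oscillation cycle,
`w(t) = sin(2πt/T)·exp(−2t/T)` over one cue period `T = 1 s`, normalized to
unit peak, positive phase first by default (a `negative_first` polarity is
available; minorities of real subjects show it). Movement *k* (k = 1…6) is
scaled by `oscillation_amplitude_uV · amplitude_decay^(k−1)` — the potential
is strongest at the first movements and fades across the trial. Each trial
carries the component with probability `trial_response_probability` (default
0.9 for the responder preset; the potential is not present in every trial
even in strong responders). The component projects onto the montage with
weights maximal at Pz (1.0) and small at the mastoids (0.12) and frontal
sites (0.03) — recorded, Cz-referenced weights. Its peak sits
`component_peak_latency_s` (default 0.15 s) after that movement's EMG onset;
the latency of the potential relative to EMG versus tone onset is not an
established quantity, so it is an explicit parameter rather than an
assumption.

**EMG.** In `normal_bursts` mode each cue of a foot-execution trial triggers
a ~200 ms broadband burst (white noise under a flat-topped envelope, 80 µV
peak) at `cue + reaction time (0.2 s) + N(0, jitter_sd)` with jitter SD 50 ms
shared with the component, so EMG-locked averages stay crisp. The SCI-like
modes: `noise_only` (continuous low-amplitude broadband activity, no
task-related bursts), `flat` (near-zero line), `spastic_sporadic` (bursts at
Poisson times, ~2/min, uncoupled from any stimulus), and `rhythmic_weak`
(cue-rhythm bursts at 15 % of normal amplitude — rhythmic EMG without any
cortical potential).

**Artifacts and background.** Background noise is 1/f-weighted Gaussian
noise (flat below 0.5 Hz), RMS `background_noise_scale` (default 12 µV on
EEG, 60 % of that on EOG). Blinks are ~350 ms biphasic VEOG transients
(160 µV, 0.3× on F3/F4) at `blink_rate`/min; eye movements are step-like
HEOG deflections (150 µV, ±0.2× frontal) at `eye_movement_rate`/min; both
are deliberately supra-threshold for the 100 µV ocular detector — only their
detectability matters downstream. Transient bad-channel episodes (250 ms,
300 µV bursts on a random scalp channel) occur at
`bad_channel_episode_rate`/min. ECG is a ~72 bpm spike train, simulated but
never analyzed.

**Seeding.** One integer seed drives named sub-streams (background, per-trial
responses, ocular, bad-channel, ECG, EMG extras) via spawned seed sequences;
identical (spec, profile, seed) gives a bit-identical recording.

## Preprocessing choices

Filter families and cutoffs are fixed by the analysis (0.1 Hz recursive
highpass, 30 Hz FIR lowpass); the concrete designs are choices: a 1st-order
Butterworth highpass and a Hamming-windowed linear-phase FIR with a
30 → 37.5 Hz transition band (111 taps at 250 Hz), both applied
forward–backward so the cascade is zero-phase — component latency is
analysis-relevant and must not be shifted. Whether the original analysis was
zero-phase is unknowable from its description, so `zero_phase` is a config
flag. The highpass has a ~1.6 s time constant; filtering reflect-pads by
3 time constants so edge transients stay outside the data. The filter's
analytic magnitude response (via `freqz`) serves as the oracle for passband/
stopband tests: the cascade passes 1 Hz at ≈ 0.99 of input amplitude and
attenuates 60 Hz to < 10⁻³.

EMG onset detection rectifies the signal, smooths with a 50 ms moving
average, and takes the first sample in the task window where the envelope
exceeds the pre-task-pause baseline mean + 3 SD for ≥ 50 ms. All three
constants are exposed. On jitter-free synthetic bursts the detected onset
falls within 40 ms of the true burst start (the flat-topped envelope rises in
~25 ms; the smoother contributes the rest).

Epochs are half-open `[lock − 2 s, lock + 6 s)` windows (8 s total), 0-based
sample indexing; locks outside the recording are dropped with a recorded reason, so
segments produced + dropped always equals eligible trials. Baseline
correction subtracts the per-channel mean of the first 2 s and is idempotent.
Re-referencing is applied per use after epoching — linked mastoids for visual
inspection, common average (over EEG-role channels only, mastoids included)
for statistics — and is a tagged no-op when the requested reference is
already active. The recording itself is generated Cz-referenced; the full
provenance chain (filter, baseline, reference, policy) rides along in each
container.

## Artifact rejection

"Bad channel" is read as: maximum peak-to-peak range within a 100 ms moving
window, strict inequality against 200 µV (a range exactly at threshold does
not flag — the rule is *exceeded*). The windowed scan is dense (stride 1),
implemented with running max/min filters and verified against an exhaustive
O(n·w) scan by property test. The same machinery at 100 µV on VEOG/HEOG
yields blink/eye-movement flags; an absolute-amplitude variant
(|x| > 100 µV) is available behind `ocular_method` since a windowed versus
absolute criterion cannot be distinguished from the rule's description.
Rejection is per segment and never repairs or interpolates. By construction
the strictly-included set is a subset of the leniently-included set; this is
asserted per condition on random artifact-heavy sessions.

## Permutation test

The per-sample statistic is a pooled-variance two-sample *t* (two-sided);
a per-sample mean difference is offered as an alternative track, but cluster
forming always thresholds the *t* track at the Student-t quantile for the
cluster-forming α (default 0.05), since the mean difference has no natural
threshold. Cluster mass is the sum of the statistic over a contiguous
same-sign supra-threshold run; the null is the distribution of the maximum
|mass| over random relabelings of the pooled trials (group sizes preserved),
which controls family-wise error over time. p-values use the add-one
estimator `(1 + #{null ≥ observed}) / (N + 1)`; ties count against the
observed cluster (conservative). When the number of distinct relabelings is
at most the requested partitions the test switches to exact enumeration and
reports `#{null ≥ observed} / N_total` (the observed labeling is one of the
enumerated partitions). Epochs are mean-corrected internally — each trial's
own epoch mean is removed — which makes the test invariant to constant
offsets per group. Significant intervals are clusters with p < α, reported at
one-sample resolution and merged when adjacent.

Under a pure-noise null (both groups drawn from the identical 1/f process)
the empirical family-wise false-positive rate sits at the nominal 0.05 within
binomial error; the calibration suite runs 1000 replicates of 25-vs-25
epochs at 200 partitions each — partitions scaled down from the analysis
default of 2000, which leaves the per-replicate p-value granularity at
1/201 ≈ 0.005, ample for a 0.05-level decision.

## ERP features

`dominant_frequency` detrends and Hann-tapers the windowed average and takes
the argmax of the rFFT power in 0.25–15 Hz; without zero-padding the
resolution over the 6 s task window is 1/6 Hz, and all frequency statements
carry that one-bin tolerance. `count_peaks` counts positive local maxima
whose prominence exceeds 15 % of the windowed peak-to-peak range (floor
1 µV), so noise ripples riding on the oscillation do not count as movement
peaks. `peak_amplitude` is the signed extremum of largest magnitude.

## Problem sizes

The defaults are the study conditions: 250 Hz, five conditions × 25 trials,
2000 random partitions, α = 0.05. The test suite exercises scaled-down
sessions (2–12 trials, sometimes only foot execution + rest) where a property
does not depend on the full deck, and the acceptance checks run the full
25-trial session; the calibration study uses 200 partitions per replicate as
described above.

## What passing tests do not show

The generator reproduces the statistical structure the pipeline assumes, not
real electrophysiology: no volume conduction or source geometry, no alpha/mu
rhythms or spectral peaks beyond 1/f, no drifting electrodes, no EMG bleed
into EEG channels, no movement-observation condition, and sessions are
independent (no multi-session pooling). Detection rates and false-positive
calibration measured here therefore characterize the method under idealized
noise, and say nothing about between-subject variability in real recordings.
Patient-specific oddities (e.g. a pre-stimulus negative component seen in one
individual) are not modeled. The EDF writer quantizes to 16 bits over the
per-channel range; round-trip error is bounded by half a quantization step
and verified against an independent reader.
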