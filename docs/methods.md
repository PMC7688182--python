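# Methods

`classtalk` quantifies a focal preschool child's social interactions and
exposure to child-directed speech (CDS) from egocentric audiovisual
*feature* streams — face detections, face-recognition matches and diarized
automatic-speech-recognition (ASR) output — without ever touching raw audio
or video.  This note describes the models and procedures, the parameters
that matter, what the synthetic-session generator does and does not
emulate, and the numerical choices made where the design was open.

## Pipeline

1. **Ingest.** Face detections are joined to recognition matches
   (timestamp within 250 ms, bounding-box IoU ≥ 0.5, similarity ≥ 92);
   matched faces take their enrolled participant class, faces matched to
   non-teacher adults (research staff) are removed, and unenrolled faces
   default to the peer class — in a preschool classroom nearly every
   unenrolled face is a child.  ASR segments are split into utterances at
   sentence-final punctuation (`.`, `?`, `!`); tokens are lowercased,
   stripped of punctuation, and contractions are expanded from a fixed
   table (`you're` → `you are`) so automatic and reference transcripts
   count words identically.
2. **Feature series.** Everything is rasterized onto a 250 ms grid into 15
   channels: six facial features (box area — the proximity proxy — yaw,
   roll, pitch, mouth-open and eyes-open confidence) for the
   *representative* (largest-box) adult and peer face, plus speech
   activity (0/1), segment word confidence and segment loudness.  Faces
   arrive at a 500 ms native rate and each sample covers its native
   period.
3. **Preprocessing**, in fixed order: *infill* → *clip* → *normalize*.
   Infilling replaces face-channel gaps with the mean of observed values
   in a centered 5-bin (1.25 s) window — this restores the 250 ms rate and
   bridges brief occlusion dropouts.  Gaps with no observation inside the
   window are long absences, not dropouts; they are filled with 0, the
   no-face baseline, so that face *presence* stays encoded in the channel
   itself.  (Extending the nearest face's features across long absences
   would instead paint non-interaction stretches with interaction-like
   values and destroy the presence signal.)  Each channel's upper tail is
   clipped at its 99th percentile (Boolean channels untouched; lower tail
   untouched).  Channels are z-scored with mean/SD pooled over *training*
   sessions only; constant channels pass through.
4. **Interaction detectors.**  One bidirectional LSTM sequence classifier
   per partner class labels every 250 ms sample interaction /
   not-interaction.  The *full* feature set uses all 15 channels; the
   *reduced* set uses only the partner class's face area and speech
   activity, emulating what a non-invasive proximity sensor could supply.
   The default architecture is 200 hidden units per direction trained for
   30 epochs; the network is implemented in NumPy (forward/backward LSTM,
   per-timestep softmax, masked cross-entropy, Adam) and its
   backpropagation-through-time gradients are verified against central
   finite differences in the test suite.  Predicted per-bin labels are
   run-length encoded into intervals and smoothed: gaps shorter than 1 s
   are merged first, then intervals shorter than 1 s are deleted.  This
   order makes smoothing idempotent and guarantees the output contains no
   sub-second interval or gap.
5. **Diarization.**  CDS is operationalized as talk temporally
   intersecting an interaction: an utterance overlapping an adult
   interval is adult-CDS; otherwise overlapping a peer interval, peer-CDS;
   otherwise non-CDS.  Overlap must be strictly positive under the
   half-open `[onset, offset)` convention, and the adult class takes
   precedence when both overlap.  Assignment depends only on overlap, not
   the speaker — a peer talking during an adult interaction is adult-CDS.
   The focal child's own utterances are partitioned the same way
   (directed-to-adult / directed-to-peer / excluded).
6. **Measures.**  Per partner class and session: TNU, TNW, NDW (counts),
   MLU = TNW/TNU and TTR = NDW/TNW (ratios of *raw* counts).  Counts are
   normed by 10 minutes (× 10/recording-minutes); MLU and TTR are
   scale-free and never normed; with zero utterances they are undefined
   (`None`), never 0.  Interaction tracks yield frequency (normed),
   median and SD of duration, and total duration (TDI), in seconds.
7. **Validation and calibration.**  Leave-one-subject-out (LOSO): for each
   held-out child, normalization statistics, detector weights and measure
   calibrations are fitted on the other children only.  Detector agreement
   is scored per 250 ms sample (accuracy, precision, recall, F1, in
   percent).  Measure agreement uses the absolute relative error
   ARE = |X_r − X_p| / X_r × 100, its median over children (mARE), the
   signed mean relative error (MRE; negative = underestimation) and
   Pearson r.  Raw automatic measures are calibrated by ordinary least
   products (OLP, type II / geometric-mean) regression — slope
   sign(r)·sd(y)/sd(x), intercept through the means — fitted inside the
   LOSO loop.  Children with a zero reference value are excluded from that
   measure's error summaries (the ARE is undefined) with a log entry;
   degenerate calibration inputs (< 3 points or zero variance) fall back
   to the identity with a warning.

## Synthetic sessions

Real classroom recordings of this kind are private, and their
featurization ran through commercial cloud services; the generator
replaces both so the whole pipeline is trainable and testable offline.
Per partner class, interaction onsets follow a homogeneous Poisson process
and durations are log-normal (the duration law is a package choice — the
observed data constrain only the frequency/duration *contrast*), with
overlapping same-class intervals merged.  Defaults encode ~40-minute
sessions in which adult interactions are long and infrequent (1.2 per
10 min, median 90 s) and peer interactions sparse and short (2 per
10 min, median 20 s).  During interactions the partner's face appears on
the 500 ms grid with probability 1 − occlusion (default occlusion 0.2)
with a large (near) box; background false faces (4/min) have small (far)
boxes, and occasional research-staff faces (0.5/min) carry an
`other_adult` recognition match to exercise the removal path.  Partner
speech fills interactions, the focal child replies inside interactions
with probability 0.7, and background speech (2 utterances/min) occurs
outside interactions so diarization sees true negatives.  Words are drawn
Zipf-weighted from a fixed vocabulary (default 200 types, including
contractions).  The ASR view deletes each word with probability
`wer_del` (default 0.3) or substitutes a random vocabulary word with
probability `wer_sub` (default 0.1, with depressed confidence),
reproducing the systematic undercount of automatic transcripts.  All
randomness flows from one master seed through named spawned streams;
identical configs give byte-identical sessions, and exact per-class
reference measures are bookkept at generation time.

What the generator does *not* emulate: acoustics (loudness is emitted
directly as a numeric channel), face geometry and camera motion,
correlated/bursty ASR errors, speaker-confusable diarization errors, and
whole-group activities.  Passing tests therefore demonstrate correctness
of the pipeline's logic and recoverability under the stated statistical
structure — not performance on real classroom recordings.

## Problem sizes and numerical choices

- Detector recovery checks run on a noiseless 13-child cohort of
  40-minute sessions with a compact network (10 hidden units, 6 epochs,
  learning rate 0.05, 60 s training windows in mini-batches of 32);
  the task is separable, so a small network suffices and keeps the full
  LOSO loop fast on one CPU.  The end-to-end command-line regression uses
  3 children × 8 minutes.  The acceptance study
  (`scripts/acceptance.py`) uses 13 children × 20 minutes with 12 hidden
  units and 8 epochs.
- Mini-batch order is fixed and nothing is shuffled, so training is
  deterministic given the seed.  Forget-gate biases initialize at 1;
  other weights are Glorot-uniform from the spec seed.
- The calibration-recovery comparison (adapted vs raw mARE) uses a
  40-child cohort: word-level deletion biases TNU only through utterances
  losing *all* their words, so the bias is small and a larger cohort is
  needed to keep OLP estimation noise below it.
- Tie-breaks: representative-face ties keep the earliest face in input
  order; contested raster bins take the utterance with the largest
  overlap, earliest first; equal-similarity identity matches prefer the
  smaller time offset, then the larger IoU.
- Degenerate inputs: empty tracks yield frequency 0 and undefined
  median/SD; all-gap channels fill with 0 under a warning; zero-division
  metrics are `None` and excluded from means.

## Known limitations

The loudness channel is consumed as data (precomputed channel or a simple
energy proxy with a fixed power-law transform); no psychoacoustic model is
implemented.  The corruption model treats word errors as independent,
which understates utterance-level losses relative to real ASR.  Unmatched
faces are classed as peers by a single configurable default rather than an
age model.  Architecture search for the recurrent detector is out of
scope.
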