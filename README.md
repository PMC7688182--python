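# classtalk

Detection of a focal preschool child's social interactions with adults and
peers, and measurement of the child-directed speech (CDS) occurring within
those interactions, from egocentric audiovisual *feature* streams — face
detections, face-recognition matches and diarized automatic-speech-
recognition (ASR) output.  No raw audio or video is processed.

Researchers studying early language environments traditionally
hand-transcribe classroom recordings; `classtalk` implements the automatic
alternative end to end, together with a synthetic classroom-session
generator so the whole pipeline can be trained, calibrated and validated
offline with known ground truth.

## The method

Per 250 ms sample the pipeline assembles 15 channels — six facial features
(box area as a proximity proxy, yaw/roll/pitch, mouth- and eyes-open
confidence) for the representative adult and peer face, plus speech
activity, word confidence and loudness.  A bidirectional LSTM sequence
classifier per partner class labels each sample interaction /
not-interaction; predicted intervals under 1 s are merged or deleted.
Each utterance is then assigned by temporal overlap: adult-CDS if it
intersects an adult interaction (adult precedence), else peer-CDS, else
non-CDS.  Per child and partner class the package computes

- TNU, TNW, NDW — numbers of utterances, words and distinct words,
  normed by 10 minutes,
- MLU = TNW/TNU and TTR = NDW/TNW (raw-count ratios),
- interaction frequency, median/SD duration and total duration (TDI),

and validates them leave-one-subject-out (LOSO): sample-level accuracy /
precision / recall / F1 for the detectors, and median absolute relative
error (mARE), signed mean relative error (MRE) and Pearson *r* for the
measures, before and after ordinary-least-products (OLP, type II)
calibration fitted strictly on training-fold children.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from classtalk import DetectorSpec, SimConfig, generate_cohort
from classtalk.pipeline import (
    detector_table, measures_table, run_loso_experiment, session_inputs,
)

cohort = generate_cohort(SimConfig(session_minutes=10, seed=7), 6)
inputs = [session_inputs(s) for s in cohort]
spec = dict(hidden_units=12, epochs=10, window_bins=240, batch_size=16)
res = run_loso_experiment(
    inputs,
    DetectorSpec("adult", "full", seed=0, **spec),
    DetectorSpec("peer", "reduced", seed=1, **spec),
)
print(detector_table(res["detection"]))
mt = measures_table(res["measure_eval"])
print(mt[mt.measure == "TNW"].to_string(index=False))
```

prints (about half a minute on one CPU):

```
  partner  n_children  accuracy   precision     recall         f1
0   adult           6    99.875  100.000000  98.866427  99.429363
1    peer           6    99.625   97.850354  98.627605  98.223146

speaker measure adaptation      mARE        MRE        r  n_children
  adult     TNW        raw 29.026317 -29.026317 0.999586           2
  adult     TNW    adapted  8.915568   0.396650 0.998278           2
   peer     TNW        raw 32.537313 -33.252676 0.998118           6
  ...
```

The detectors recover the simulated interaction tracks almost perfectly
(F1 ≈ 98–99).  The raw word counts are ~30 % *below* the reference —
exactly the configured ASR word-deletion probability of 0.3 — and the
OLP calibration removes that bias (signed error near zero, mARE down to
single digits).  Children without any adult interaction in a short
session are excluded from the adult rows, hence the smaller `n_children`.

The same pipeline is available from the shell:

```bash
classtalk simulate --out cohort --seed 5 --children 13
classtalk loso --cohort cohort --out report --hidden 12 --epochs 8
```

which writes `report/detector_metrics.csv`, `report/measures_report.csv`
and `report/predicted_intervals.csv`, plus a manifest with the seeds and
configuration hash needed to reproduce them.

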