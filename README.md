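# performotor

Automatic assessment of the four cardinal parkinsonian motor signs —
**tremor**, **levodopa-induced dyskinesia (LID)**, **bradykinesia** and
**freezing of gait (FoG)** — from a five-unit body-worn inertial sensor set:
tri-axial accelerometers on both wrists and ankles plus a combined
accelerometer/gyroscope on the waist. The package is aimed at digital-health
researchers and engineers who need a tested, reproducible reference pipeline
from raw multi-sensor CSV recordings to per-window severity-confidence
timelines, clinician summaries, and cohort-level validation metrics.

Because clinical recordings of this kind are rarely shareable, the package
ships a seeded synthetic episode simulator that emulates both recording
protocols (a short in-clinic lie → sit → walk → task session, and long
at-home sessions with a half-hour self-report diary) with injected symptom
episodes of known class and severity. Every recognizer is exercised
end-to-end on simulator output.

## Methods at a glance

Signals are segmented with symptom-specific sliding windows (tremor 3 s /
1.5 s step; LID and FoG 1 s / 0.5 s; bradykinesia 5 s / 50% overlap on
1–3 Hz band-passed signals). Per window:

* **Tremor** — time/frequency features per limb axis (RMS, range, log band
  energies, spectral entropy, dominant frequency, low-frequency ratio,
  amplitude-histogram entropy) plus gravity-derived posture features feed a
  supervised Gaussian hidden Markov model over severity classes
  {0, 1, 2, 3/4}; a second HMM over body action-posture states
  {rest-like, postural-like, active} supplies the tremor type
  (rest/postural). Forward–backward posteriors give the per-window
  confidence for each severity: γ_t(k) = P(S_t = k | x_1..T).
* **LID** — per-axis statistics, sub-band energies (0.5–1, 1–2, 2–4,
  4–8 Hz) and spectral entropy feed a C4.5 decision tree (gain-ratio
  splits, pessimistic pruning, CF = 0.25); leaf class distributions are the
  confidences.
* **Bradykinesia** — approximate entropy ApEn(m=2, r=0.2·SD), zero-lag
  cross-correlation of contralateral limb pairs, and range on the
  band-passed signals feed an RBF SVM (C = 1, γ = 1/p); an exhaustive
  feature-family combination search reproduces how this subset is selected.
* **FoG** — signal entropy per axis of every sensor feeds a 10-tree
  unpruned bootstrap random forest; confidence is the vote fraction.

Validation follows leave-one-patient-out cross-validation with
majority-class subsampling in the training folds only (20% of normal
instances; 4% of no-freeze instances for FoG), scored by pooled accuracy
and unweighted average recall. Long-term sessions are scored against the
half-hour diary by mean absolute error after duration-weighted aggregation
of predictions into diary bins.

## Worked example

```bash
# simulate a 4-minute labelled tremor session (deterministic in --seed)
performotor simulate --symptom TREMOR --out demo --seed 5 --duration 240
# -> demo/SIM0005_manifest.yaml

performotor validate demo/SIM0005_manifest.yaml
# OK: session SIM0005 patient P00 fs=64 Hz duration=240 s (15360 samples/channel, 5 units)

performotor extract demo/SIM0005_manifest.yaml --symptom tremor \
    --out demo/tremor.csv --labels demo/SIM0005_TREMOR.tsv
# demo/tremor.csv: 159 windows x 129 features
```

From the library, the full cohort protocol:

```python
from performotor import synthetic_data as sd, evaluation as ev

cfg = sd.default_config("TREMOR")          # 8-patient study conditions
rset = sd.simulate_cohort(8, 2, cfg, seed=0)
report = ev.run_lopo(rset, "TREMOR", seed=0)
print(f"accuracy={report.accuracy:.3f} avg_recall={report.avg_recall:.3f}")
# accuracy=0.989 avg_recall=0.993
```

The accuracy is the pooled fraction of correctly classified windows over
all 8 held-out patients; average recall is the unweighted mean of per-class
recalls, so it is not inflated by the large normal class.

## Layout

- `performotor.signal_model` — data model + CSV/TSV/manifest I/O
- `performotor.synthetic_data` — seeded episode simulator and cohorts
- `performotor.features` — windowing and all feature operators
- `performotor.recognizers` — HMM, C4.5, SVM, random forest, wrapper
  selection, assessment timelines
- `performotor.evaluation` — LOPO protocol, scoring, diary MAE, summaries
- `performotor.cli` — `performotor` command (validate / simulate / extract /
  train / assess / evaluate / report)

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
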