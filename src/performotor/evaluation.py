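"""Validation protocol and clinician summary statistics.

Leave-one-patient-out (LOPO) cross-validation with majority-class
subsampling in the training folds only (20% of normal instances by default,
4% of no-freeze instances for the FoG module), pooled confusion matrices,
accuracy and unweighted average recall, long-term diary mean absolute
error, and the daily/weekly/monthly symptom summaries (duration per
severity, mean severity, left/right asymmetry, episode onsets and counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureMatrix, extract
from .recognizers import (
    HMMModel,
    decode_posteriors,
    train_c45,
    train_forest,
    train_hmm,
    train_svm,
)
from .signal_model import (
    LIMB_UNITS,
    AnnotationTrack,
    DiaryTrack,
    RecordingSet,
    SensorRecording,
    labels_for_windows,
)
from .recognizers.assess import SymptomAssessment

#: Training-fold majority-class subsampling fraction per symptom.
SUBSAMPLE_FRACTIONS: Dict[str, float] = {
    "TREMOR": 0.2,
    "LID": 0.2,
    "BRADY": 0.2,
    "FOG": 0.04,
}

ASYMMETRY_SENTINEL = 99.0


@dataclass
class FoldResult:
    patient_id: str
    test_sessions: List[str]
    confusion: np.ndarray
    accuracy: float
    avg_recall: float


@dataclass
class EvaluationReport:
    symptom: str
    classes: np.ndarray
    confusion: np.ndarray  # pooled over folds
    accuracy: float
    avg_recall: float
    folds: List[FoldResult]
    subsample_fraction: float
    seed: int

    def validate(self) -> "EvaluationReport":
        if self.confusion.sum() != sum(f.confusion.sum() for f in self.folds):
            raise ValueError("pooled confusion inconsistent with folds")
        return self


def lopo_folds(rset: RecordingSet) -> List[Tuple[List[str], List[str]]]:
    """One fold per patient; all of a patient's sessions test together."""
    patients = rset.patients
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    folds = []
    for pid in patients:
        test = [r.session_id for r in rset.recordings if r.patient_id == pid]
        train = [r.session_id for r in rset.recordings if r.patient_id != pid]
        folds.append((train, test))
    return folds


def subsample_majority(
    fm: FeatureMatrix,
    fraction: float,
    majority_class: int = 0,
    seed: int = 0,
) -> FeatureMatrix:
    """Keep round(fraction * n_majority) majority rows (uniform, without
    replacement) and every minority row. Training folds only; callers must
    leave test folds untouched."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fm.labels is None:
        raise ValueError("labelled matrix required")
    labels = fm.labels
    maj = np.nonzero(labels == majority_class)[0]
    mino = np.nonzero(labels != majority_class)[0]
    n_keep = int(round(fraction * len(maj)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AB5]))
    kept = rng.choice(maj, size=n_keep, replace=False) if n_keep < len(maj) else maj
    idx = np.sort(np.concatenate([kept, mino]))
    return FeatureMatrix(
        window_centers=fm.window_centers[idx],
        names=fm.names,
        X=fm.X[idx],
        labels=labels[idx],
        patient_id=fm.patient_id,
        session_id=fm.session_id,
        symptom=fm.symptom,
    )


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[int]
) -> np.ndarray:
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    lookup = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[lookup[int(t)], lookup[int(p)]] += 1
    return cm


def score(confusion: np.ndarray) -> Dict[str, float]:
    """Accuracy = trace/total; average recall = unweighted mean of per-class
    recalls, classes with zero support excluded."""
    confusion = np.asarray(confusion, dtype=float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(confusion) / total)
    support = confusion.sum(axis=1)
    nz = support > 0
    recalls = np.diag(confusion)[nz] / support[nz]
    return {"accuracy": accuracy, "avg_recall": float(np.mean(recalls))}


# ---------------------------------------------------------------------------
# LOPO protocol
# ---------------------------------------------------------------------------


def _labelled_features(
    rset: RecordingSet, symptom: str
) -> Dict[str, FeatureMatrix]:
    """Extract fused features + window labels once per session."""
    out: Dict[str, FeatureMatrix] = {}
    for rec in rset.recordings:
        fm = extract(rec, symptom)
        track = rset.annotations[rec.session_id][symptom]
        fm.labels = labels_for_windows(track, fm.window_centers)
        out[rec.session_id] = fm
    return out


def _train_predict(
    symptom: str,
    train_fms: List[FeatureMatrix],
    test_fms: List[FeatureMatrix],
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Train the symptom's recognizer and predict the test windows."""
    Xtr = np.vstack([fm.X for fm in train_fms])
    if symptom == "TREMOR":
        label_seqs = [fm.labels for fm in train_fms]
        model = train_hmm(Xtr, label_seqs, min_per_class=2)
        preds = [
            model.states[np.argmax(decode_posteriors(model, fm.X), axis=1)]
            for fm in test_fms
        ]
    else:
        ytr = np.concatenate([fm.labels for fm in train_fms])
        if symptom == "LID":
            model = train_c45(Xtr, ytr)
        elif symptom == "BRADY":
            model = train_svm(Xtr, ytr, seed=seed)
        elif symptom == "FOG":
            model = train_forest(Xtr, ytr, seed=seed)
        else:
            raise ValueError(f"unknown symptom {symptom!r}")
        preds = [model.predict(fm.X) for fm in test_fms]
    y_true = np.concatenate([fm.labels for fm in test_fms])
    y_pred = np.concatenate(preds)
    return y_true, y_pred


def run_lopo(
    rset: RecordingSet,
    symptom: str,
    seed: int = 0,
    subsample_fraction: Optional[float] = None,
    features: Optional[Dict[str, FeatureMatrix]] = None,
) -> EvaluationReport:
    """Full LOPO protocol for one symptom: extract, subsample the normal
    class in training folds, train, assess the held-out patient, pool."""
    if subsample_fraction is None:
        subsample_fraction = SUBSAMPLE_FRACTIONS[symptom]
    if features is None:
        features = _labelled_features(rset, symptom)
    folds = lopo_folds(rset)
    classes = np.unique(np.concatenate([fm.labels for fm in features.values()]))
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    fold_results: List[FoldResult] = []
    ss = np.random.SeedSequence([int(seed), 0x10F0])
    fold_seeds = ss.generate_state(len(folds))
    for k, (train_ids, test_ids) in enumerate(folds):
        fold_seed = int(fold_seeds[k] % (2**31 - 1))
        train_fms = [
            subsample_majority(features[sid], subsample_fraction, seed=fold_seed)
            for sid in train_ids
        ]
        test_fms = [features[sid] for sid in test_ids]
        y_true, y_pred = _train_predict(symptom, train_fms, test_fms, fold_seed)
        cm = confusion_matrix(y_true, y_pred, classes)
        metrics = score(cm)
        pid = rset.session(test_ids[0]).patient_id
        fold_results.append(
            FoldResult(pid, list(test_ids), cm, metrics["accuracy"], metrics["avg_recall"])
        )
        pooled += cm
    metrics = score(pooled)
    return EvaluationReport(
        symptom=symptom,
        classes=classes,
        confusion=pooled,
        accuracy=metrics["accuracy"],
        avg_recall=metrics["avg_recall"],
        folds=fold_results,
        subsample_fraction=subsample_fraction,
        seed=seed,
    ).validate()


# ---------------------------------------------------------------------------
# Whole-cohort model fitting (for assessment timelines / long-term use)
# ---------------------------------------------------------------------------


def fit_tremor_models(
    rset: RecordingSet, subsample_fraction: float = 0.2, seed: int = 0
) -> Tuple[HMMModel, HMMModel]:
    """Fit the dual-HMM tremor pipeline on a whole annotated cohort.

    The severity HMM is trained on segment-local limb features (rows pooled
    over all four limbs of every session, so one model serves any limb); the
    posture HMM on gravity features with the activity-script posture labels.
    """
    sev_fms: List[FeatureMatrix] = []
    post_fms: List[FeatureMatrix] = []
    for rec in rset.recordings:
        tremor_track = rset.annotations[rec.session_id]["TREMOR"]
        for seg in LIMB_UNITS:
            fm = extract(rec, "TREMOR", segment=seg)
            fm.labels = labels_for_windows(tremor_track, fm.window_centers)
            sev_fms.append(subsample_majority(fm, subsample_fraction, seed=seed))
        pfm = extract(rec, "POSTURE")
        posture_track = rset.annotations[rec.session_id]["POSTURE"]
        pfm.labels = labels_for_windows(posture_track, pfm.window_centers)
        post_fms.append(pfm)
    severity_model = train_hmm(
        np.vstack([fm.X for fm in sev_fms]),
        [fm.labels for fm in sev_fms],
        min_per_class=2,
    )
    posture_model = train_hmm(
        np.vstack([fm.X for fm in post_fms]),
        [fm.labels for fm in post_fms],
        min_per_class=2,
    )
    return severity_model, posture_model


# ---------------------------------------------------------------------------
# Long-term diary comparison
# ---------------------------------------------------------------------------


def diary_mae(
    assessment: SymptomAssessment, diary: DiaryTrack, mode: str = "mean"
) -> float:
    """Mean absolute error between half-hour-aggregated predictions and diary.

    Predictions are aggregated per 1800 s bin by the duration-weighted mean
    predicted severity (``mode='mean'``; ``mode='majority'`` uses the modal
    label instead). Bins without predictions are skipped.
    """
    centers = assessment.window_centers
    sev = assessment.severity_series().astype(float)
    errs = []
    for bin_start, label in diary.bins:
        sel = (centers >= bin_start) & (centers < bin_start + DiaryTrack.BIN_S)
        if not sel.any():
            continue
        if mode == "mean":
            agg = float(np.mean(sev[sel]))
        elif mode == "majority":
            vals, counts = np.unique(sev[sel], return_counts=True)
            agg = float(vals[np.argmax(counts + np.arange(len(vals)) * 1e-9)])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        errs.append(abs(agg - label))
    if not errs:
        raise ValueError("no overlapping diary bins")
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# Clinician summaries
# ---------------------------------------------------------------------------


@dataclass
class SymptomSummary:
    symptom: str
    period: str
    duration_per_severity_s: Dict[int, float]
    mean_severity: float
    asymmetry: Optional[float]  # left/right duration-weighted severity ratio
    onsets_s: List[float]
    episode_count: int
    assessed_time_s: float


def _episodes_from_labels(
    centers: np.ndarray, labels: np.ndarray, step: float
) -> List[Tuple[float, float, int]]:
    """Maximal runs of severity > 0, as (start, end, max severity)."""
    episodes = []
    start = None
    sev = 0
    for c, l in zip(centers, labels):
        if l > 0:
            if start is None:
                start, sev = c - step / 2, int(l)
            else:
                sev = max(sev, int(l))
        elif start is not None:
            episodes.append((start, c - step / 2, sev))
            start = None
    if start is not None:
        episodes.append((start, centers[-1] + step / 2, sev))
    return episodes


def summarize(
    assessments: Sequence[SymptomAssessment], period: str = "daily"
) -> SymptomSummary:
    """Aggregate assessments into the clinician summary for one symptom."""
    if not assessments:
        raise ValueError("no assessments to summarize")
    if period not in ("daily", "weekly", "monthly"):
        raise ValueError(f"unknown period {period!r}")
    symptom = assessments[0].symptom
    dur: Dict[int, float] = {}
    onsets: List[float] = []
    n_episodes = 0
    left_wsum = right_wsum = 0.0
    sev_time = 0.0
    assessed = 0.0
    for a in assessments:
        for seg_name, seg in a.segments.items():
            centers = seg.window_centers
            step = float(np.median(np.diff(centers))) if len(centers) > 1 else 1.0
            for l in seg.labels:
                dur[int(l)] = dur.get(int(l), 0.0) + step
            assessed += step * len(centers)
            sev_time += step * float(np.sum(seg.labels))
            eps = _episodes_from_labels(centers, seg.labels, step)
            n_episodes += len(eps)
            onsets.extend(ep[0] for ep in eps)
            wsum = step * float(np.sum(seg.labels))
            if seg_name.startswith("L"):
                left_wsum += wsum
            elif seg_name.startswith("R"):
                right_wsum += wsum
    if left_wsum == 0 and right_wsum == 0:
        asym: Optional[float] = 1.0
    elif right_wsum == 0:
        asym = ASYMMETRY_SENTINEL
    else:
        asym = left_wsum / right_wsum
    has_sides = any(
        seg.startswith(("L", "R")) for a in assessments for seg in a.segments
    )
    return SymptomSummary(
        symptom=symptom,
        period=period,
        duration_per_severity_s=dict(sorted(dur.items())),
        mean_severity=sev_time / assessed if assessed else 0.0,
        asymmetry=asym if has_sides else None,
        onsets_s=sorted(onsets),
        episode_count=n_episodes,
        assessed_time_s=assessed,
    )
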