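"""Per-recording symptom assessment: the confidence-vs-time output.

Each assessment holds, per body segment, the window centers, the severity
classes, a row-stochastic confidence matrix and the argmax label sequence
(ties resolved toward the lower severity — the conservative clinical
reading). Tremor and bradykinesia are assessed per limb (LW, RW, LL, RL);
dyskinesia and freezing of gait over the whole body ('BODY' segment).

Tremor merges two models: the severity HMM on limb-local features and the
body action-posture HMM on gravity features. The merge reports a
(severity, type) tuple per window: severity 0 forces type 'none'; a
rest-like posture gives 'rest', otherwise 'postural'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from ..features import FeatureMatrix, extract
from ..signal_model import LIMB_UNITS, SensorRecording, TREMOR_TYPES
from .c45 import TreeModel
from .forest import ForestModel
from .hmm import HMMModel, decode_posteriors
from .svm import MarginModel


@dataclass
class SegmentAssessment:
    window_centers: np.ndarray
    classes: np.ndarray
    confidence: np.ndarray  # (windows, classes), rows sum to 1
    labels: np.ndarray  # argmax class values
    tremor_type: Optional[List[str]] = None

    def validate(self) -> "SegmentAssessment":
        if not np.allclose(self.confidence.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("confidence rows must sum to 1")
        return self


@dataclass
class SymptomAssessment:
    symptom: str
    segments: Dict[str, SegmentAssessment] = field(default_factory=dict)
    patient_id: str = ""
    session_id: str = ""

    @property
    def window_centers(self) -> np.ndarray:
        return next(iter(self.segments.values())).window_centers

    def severity_series(self) -> np.ndarray:
        """Whole-body severity per window: the max over segments (a diary
        reflects the worst-affected limb)."""
        stacked = np.stack([seg.labels for seg in self.segments.values()])
        return stacked.max(axis=0)


def _segment_from_conf(
    centers: np.ndarray, classes: np.ndarray, conf: np.ndarray
) -> SegmentAssessment:
    conf = np.asarray(conf, dtype=float)
    conf = conf / conf.sum(axis=1, keepdims=True)
    labels = classes[np.argmax(conf, axis=1)]  # first max = lower severity
    return SegmentAssessment(centers, classes, conf, labels).validate()


def merge_tremor(severity: int, posture_state: int) -> tuple:
    """Merge rule for the two tremor models.

    severity 0 overrides the type to 'none'; posture 0 (rest-like) -> rest
    tremor; postural-like or active -> postural tremor.
    """
    if severity == 0:
        return 0, "none"
    return severity, ("rest" if posture_state == 0 else "postural")


def assess_tremor(
    rec: SensorRecording,
    severity_model: HMMModel,
    posture_model: HMMModel,
) -> SymptomAssessment:
    """Per-limb tremor severity + type from the dual-HMM pipeline."""
    posture_fm = extract(rec, "POSTURE")
    posture_post = decode_posteriors(posture_model, posture_fm.X)
    posture_states = posture_model.states[np.argmax(posture_post, axis=1)]
    out = SymptomAssessment(
        "TREMOR", patient_id=rec.patient_id, session_id=rec.session_id
    )
    for seg in LIMB_UNITS:
        fm = extract(rec, "TREMOR", segment=seg)
        conf = decode_posteriors(severity_model, fm.X)
        sa = _segment_from_conf(fm.window_centers, severity_model.states, conf)
        sa.tremor_type = [
            merge_tremor(int(sev), int(pos))[1]
            for sev, pos in zip(sa.labels, posture_states)
        ]
        out.segments[seg] = sa
    return out


def assess_lid(rec: SensorRecording, model: TreeModel) -> SymptomAssessment:
    fm = extract(rec, "LID")
    conf = model.predict_proba(fm.X)
    out = SymptomAssessment("LID", patient_id=rec.patient_id, session_id=rec.session_id)
    out.segments["BODY"] = _segment_from_conf(fm.window_centers, model.classes, conf)
    return out


def assess_brady(rec: SensorRecording, model: MarginModel) -> SymptomAssessment:
    """Per-limb bradykinesia severity from segment-local band-passed features."""
    out = SymptomAssessment(
        "BRADY", patient_id=rec.patient_id, session_id=rec.session_id
    )
    for seg in LIMB_UNITS:
        fm = extract(rec, "BRADY", segment=seg)
        conf = model.predict_proba(fm.X)
        out.segments[seg] = _segment_from_conf(fm.window_centers, model.classes, conf)
    return out


def assess_fog(rec: SensorRecording, model: ForestModel) -> SymptomAssessment:
    fm = extract(rec, "FOG")
    conf = model.predict_proba(fm.X)
    out = SymptomAssessment("FOG", patient_id=rec.patient_id, session_id=rec.session_id)
    out.segments["BODY"] = _segment_from_conf(fm.window_centers, model.classes, conf)
    return out
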