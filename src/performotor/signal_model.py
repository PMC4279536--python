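"""Data model and I/O for multi-sensor recordings, annotations and diaries.

The sensor layout mirrors a five-unit body-worn configuration: tri-axial
accelerometers on the left/right wrist (LW, RW) and left/right ankle
(LL, RL), plus a combined accelerometer + gyroscope on the waist (WAIST).
Acceleration is expressed in g (gravity-normalized), angular rate in deg/s.
Timestamps are seconds from session start; the wall-clock start time is
carried only as metadata.

Annotation intervals are half-open ``[start, end)``: a window center lying
exactly on a shared boundary belongs to the later interval, and unannotated
time is class 0 (normal).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

UNIT_IDS: Tuple[str, ...] = ("LW", "RW", "LL", "RL", "WAIST")
LIMB_UNITS: Tuple[str, ...] = ("LW", "RW", "LL", "RL")
ACCEL_AXES: Tuple[str, ...] = ("x", "y", "z")
GYRO_AXES: Tuple[str, ...] = ("gx", "gy", "gz")

SYMPTOMS: Tuple[str, ...] = ("TREMOR", "LID", "BRADY", "FOG")

#: Severity label domain per track kind. TREMOR/LID/BRADY use the 0-3 scale
#: where 3 encodes merged clinical severities 3/4; FOG is binary. POSTURE is
#: an internal track (0 rest-like, 1 postural-like, 2 active) used by the
#: body action-posture recognizer.
LABEL_DOMAINS: Dict[str, Tuple[int, ...]] = {
    "TREMOR": (0, 1, 2, 3),
    "LID": (0, 1, 2, 3),
    "BRADY": (0, 1, 2, 3),
    "FOG": (0, 1),
    "POSTURE": (0, 1, 2),
}

TREMOR_TYPES: Tuple[str, ...] = ("none", "rest", "postural")


def unit_axes(unit_id: str) -> Tuple[str, ...]:
    """Channel names for a unit (waist carries the gyroscope)."""
    if unit_id == "WAIST":
        return ACCEL_AXES + GYRO_AXES
    return ACCEL_AXES


def all_channels() -> List[Tuple[str, str]]:
    """Every (unit, axis) pair in canonical order — 18 channels."""
    return [(u, ax) for u in UNIT_IDS for ax in unit_axes(u)]


class ValidationError(ValueError):
    """Raised when a recording, annotation or diary violates its contract."""


@dataclass
class SensorRecording:
    """One synchronized multi-sensor session.

    ``data`` maps unit id to an (n_samples, n_axes) float array; limb units
    have 3 accelerometer axes, the waist 3 accelerometer + 3 gyroscope axes.
    """

    patient_id: str
    session_id: str
    fs: float
    data: Dict[str, np.ndarray]
    start_time: str = "1970-01-01T00:00:00"

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.data.values())).shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, unit: str, axis: str) -> np.ndarray:
        return self.data[unit][:, unit_axes(unit).index(axis)]

    def validate(self) -> "SensorRecording":
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        missing = [u for u in UNIT_IDS if u not in self.data]
        if missing:
            raise ValidationError(f"missing unit {missing[0]}")
        n = None
        for u in UNIT_IDS:
            arr = np.asarray(self.data[u], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(unit_axes(u)):
                raise ValidationError(
                    f"unit {u}: expected {len(unit_axes(u))} axes, got shape {arr.shape}"
                )
            if arr.shape[0] == 0:
                raise ValidationError(f"unit {u}: zero-length data")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValidationError(
                    f"unit {u}: sample count {arr.shape[0]} != {n} of other units"
                )
            if not np.all(np.isfinite(arr)):
                bad = np.unique(np.where(~np.isfinite(arr))[0])
                raise ValidationError(
                    f"unit {u}: non-finite samples at rows {bad[:10].tolist()}"
                )
            self.data[u] = arr
        return self


@dataclass
class AnnotationTrack:
    """Labelled half-open intervals for one symptom (or the posture track).

    ``intervals`` holds (start_s, end_s, label) triples; ``types`` optionally
    carries the tremor type ('rest' / 'postural') per interval.
    """

    symptom: str
    intervals: List[Tuple[float, float, int]] = field(default_factory=list)
    types: Optional[List[str]] = None

    def validate(self) -> "AnnotationTrack":
        if self.symptom not in LABEL_DOMAINS:
            raise ValidationError(f"unknown symptom {self.symptom!r}")
        order = np.argsort([iv[0] for iv in self.intervals], kind="stable")
        self.intervals = [self.intervals[i] for i in order]
        if self.types is not None:
            self.types = [self.types[i] for i in order]
        domain = LABEL_DOMAINS[self.symptom]
        prev_end = -np.inf
        for start, end, label in self.intervals:
            if not start < end:
                raise ValidationError(f"interval ({start}, {end}) is empty or reversed")
            if start < prev_end:
                raise ValidationError(
                    f"overlapping intervals near {start:.3f} s in {self.symptom} track"
                )
            if int(label) != label or int(label) not in domain:
                raise ValidationError(
                    f"label {label!r} outside domain {domain} for {self.symptom}"
                )
            prev_end = end
        return self

    def label_at(self, t: float) -> int:
        for start, end, label in self.intervals:
            if start <= t < end:
                return int(label)
        return 0


@dataclass
class DiaryTrack:
    """Half-hour self-report bins: (bin_start_s, label) at exact 1800 s spacing."""

    symptom: str
    bins: List[Tuple[float, int]] = field(default_factory=list)

    BIN_S: float = 1800.0

    def validate(self) -> "DiaryTrack":
        if self.symptom not in LABEL_DOMAINS:
            raise ValidationError(f"unknown symptom {self.symptom!r}")
        starts = [b[0] for b in self.bins]
        if sorted(starts) != starts:
            raise ValidationError("diary bins must be sorted")
        for prev, cur in zip(starts, starts[1:]):
            if abs((cur - prev) - self.BIN_S) > 1e-6:
                raise ValidationError(
                    f"diary bin spacing {cur - prev} != {self.BIN_S} s"
                )
        domain = LABEL_DOMAINS[self.symptom]
        for _, label in self.bins:
            if int(label) not in domain:
                raise ValidationError(f"diary label {label} outside domain {domain}")
        return self


@dataclass
class RecordingSet:
    """A cohort: recordings plus per-session annotation (and diary) tracks."""

    recordings: List[SensorRecording]
    annotations: Dict[str, Dict[str, AnnotationTrack]]
    diaries: Optional[Dict[str, Dict[str, DiaryTrack]]] = None

    @property
    def patients(self) -> List[str]:
        seen: List[str] = []
        for rec in self.recordings:
            if rec.patient_id not in seen:
                seen.append(rec.patient_id)
        return seen

    def session(self, session_id: str) -> SensorRecording:
        for rec in self.recordings:
            if rec.session_id == session_id:
                return rec
        raise KeyError(session_id)

    def validate(self) -> "RecordingSet":
        sessions = {rec.session_id for rec in self.recordings}
        for sid in self.annotations:
            if sid not in sessions:
                raise ValidationError(f"annotation references unknown session {sid!r}")
        if self.diaries:
            for sid in self.diaries:
                if sid not in sessions:
                    raise ValidationError(f"diary references unknown session {sid!r}")
        return self


# ---------------------------------------------------------------------------
# Recording I/O: one CSV per unit plus a YAML/JSON manifest.
# ---------------------------------------------------------------------------

def read_recording(manifest_path: os.PathLike) -> SensorRecording:
    """Load and validate a recording from its manifest.

    The manifest maps each unit to a CSV with header ``t,x,y,z[,gx,gy,gz]``.
    The time column must be strictly increasing and uniform (jitter below 1%
    of the sample period); the inferred rate must match the declared ``fs``
    within 0.1%.
    """
    manifest_path = Path(manifest_path)
    manifest = _load_manifest(manifest_path)
    fs = float(manifest["fs"])
    units = manifest.get("units", {})
    missing = [u for u in UNIT_IDS if u not in units]
    if missing:
        raise ValidationError(f"missing unit {missing[0]}")
    data: Dict[str, np.ndarray] = {}
    for unit in UNIT_IDS:
        csv_path = manifest_path.parent / units[unit]
        if not csv_path.exists():
            raise ValidationError(f"missing unit {unit}: file {csv_path} not found")
        df = pd.read_csv(csv_path)
        expected_cols = ("t",) + unit_axes(unit)
        if tuple(df.columns) != expected_cols:
            raise ValidationError(
                f"unit {unit}: columns {tuple(df.columns)} != {expected_cols}"
            )
        nan_rows = df.index[df.isna().any(axis=1)]
        if len(nan_rows):
            raise ValidationError(
                f"unit {unit}: NaN rows at indices {list(nan_rows[:10])}"
            )
        t = df["t"].to_numpy(dtype=float)
        _check_uniform_time(t, fs, unit)
        data[unit] = df[list(unit_axes(unit))].to_numpy(dtype=float)
    rec = SensorRecording(
        patient_id=str(manifest["patient_id"]),
        session_id=str(manifest["session_id"]),
        fs=fs,
        data=data,
        start_time=str(manifest.get("start_time", "1970-01-01T00:00:00")),
    )
    return rec.validate()


def _check_uniform_time(t: np.ndarray, fs: float, unit: str) -> None:
    if len(t) < 2:
        return
    dt = np.diff(t)
    period = 1.0 / fs
    jitter = np.max(np.abs(dt - period))
    if jitter > 0.01 * period:
        raise ValidationError(
            f"unit {unit}: non-uniform time base (jitter {jitter:.3e} s "
            f"> 1% of period {period:.3e} s)"
        )
    fs_inferred = (len(t) - 1) / (t[-1] - t[0])
    if abs(fs_inferred - fs) / fs > 1e-3:
        raise ValidationError(
            f"unit {unit}: inferred rate {fs_inferred:.4f} Hz differs from "
            f"declared {fs} Hz by more than 0.1%"
        )


def _load_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_recording(rec: SensorRecording, out_dir: os.PathLike) -> Path:
    """Write a recording as per-unit CSVs + a YAML manifest; returns the manifest path.

    Round-trips through :func:`read_recording` to within 1e-9 per sample.
    """
    rec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = rec.times
    units_map: Dict[str, str] = {}
    for unit in UNIT_IDS:
        fname = f"{rec.session_id}_{unit}.csv"
        cols = {"t": t}
        for j, ax in enumerate(unit_axes(unit)):
            cols[ax] = rec.data[unit][:, j]
        pd.DataFrame(cols).to_csv(
            out_dir / fname, index=False, float_format="%.12g"
        )
        units_map[unit] = fname
    manifest = {
        "patient_id": rec.patient_id,
        "session_id": rec.session_id,
        "fs": rec.fs,
        "start_time": rec.start_time,
        "units": units_map,
    }
    manifest_path = out_dir / f"{rec.session_id}_manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    )
    return manifest_path


# ---------------------------------------------------------------------------
# Annotation / diary I/O (TSV)
# ---------------------------------------------------------------------------

def read_annotations(path: os.PathLike, symptom: Optional[str] = None) -> AnnotationTrack:
    """Parse a tab-separated interval file ``start_s<TAB>end_s<TAB>symptom<TAB>label``.

    An optional fifth column carries the tremor type. The file must contain a
    single symptom unless ``symptom`` filters it.
    """
    intervals: List[Tuple[float, float, int]] = []
    types: List[str] = []
    seen_symptoms = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValidationError(f"malformed annotation line: {line!r}")
        start, end, sym, label = parts[0], parts[1], parts[2], parts[3]
        if symptom is not None and sym != symptom:
            continue
        seen_symptoms.add(sym)
        intervals.append((float(start), float(end), int(float(label))))
        types.append(parts[4] if len(parts) > 4 else "none")
    if symptom is None:
        if len(seen_symptoms) > 1:
            raise ValidationError(
                f"file mixes symptoms {sorted(seen_symptoms)}; pass symptom="
            )
        symptom = next(iter(seen_symptoms)) if seen_symptoms else "TREMOR"
    track = AnnotationTrack(symptom=symptom, intervals=intervals)
    if any(tp != "none" for tp in types):
        track.types = types
    return track.validate()


def write_annotations(track: AnnotationTrack, path: os.PathLike) -> Path:
    track.validate()
    lines = []
    for i, (start, end, label) in enumerate(track.intervals):
        row = [f"{start:.6f}", f"{end:.6f}", track.symptom, str(int(label))]
        if track.types is not None:
            row.append(track.types[i])
        lines.append("\t".join(row))
    path = Path(path)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_diary(path: os.PathLike, symptom: Optional[str] = None) -> DiaryTrack:
    """Parse a diary TSV ``bin_start_s<TAB>symptom<TAB>label``."""
    bins: List[Tuple[float, int]] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        start, sym, label = line.split("\t")[:3]
        if symptom is not None and sym != symptom:
            continue
        seen.add(sym)
        bins.append((float(start), int(float(label))))
    if symptom is None:
        if len(seen) > 1:
            raise ValidationError(f"file mixes symptoms {sorted(seen)}; pass symptom=")
        symptom = next(iter(seen)) if seen else "TREMOR"
    return DiaryTrack(symptom=symptom, bins=bins).validate()


def write_diary(diary: DiaryTrack, path: os.PathLike, append: bool = False) -> Path:
    diary.validate()
    lines = [
        f"{start:.6f}\t{diary.symptom}\t{int(label)}" for start, label in diary.bins
    ]
    path = Path(path)
    text = "\n".join(lines) + ("\n" if lines else "")
    if append and path.exists():
        path.write_text(path.read_text() + text)
    else:
        path.write_text(text)
    return path


# ---------------------------------------------------------------------------
# Bridging interval ground truth to window-level labels
# ---------------------------------------------------------------------------

def labels_for_windows(
    track: AnnotationTrack, window_centers: Sequence[float]
) -> np.ndarray:
    """Label each window center by the half-open interval containing it.

    Centers in unannotated gaps get label 0. Total: every center receives
    exactly one label.
    """
    centers = np.asarray(window_centers, dtype=float)
    labels = np.zeros(len(centers), dtype=int)
    if not track.intervals:
        return labels
    starts = np.array([iv[0] for iv in track.intervals])
    ends = np.array([iv[1] for iv in track.intervals])
    vals = np.array([iv[2] for iv in track.intervals], dtype=int)
    # index of last interval with start <= center; half-open [start, end)
    idx = np.searchsorted(starts, centers, side="right") - 1
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = centers[valid] < ends[idx[valid]]
    labels[inside] = vals[idx[inside]]
    return labels
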