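"""Seeded synthetic multi-sensor episode simulator.

Emulates the two recording protocols the recognizers are designed for: a
short in-clinic session (lying -> rising/sitting -> walking and manual
tasks, ~15 min in the clinical protocol, scaled down here) and long at-home
sessions with a half-hour diary. Symptom episodes of known class and
severity are injected on top of a baseline built from three parts per
channel: the gravity projection for the current posture, a smooth
low-frequency voluntary-movement process, and white measurement noise.

Episode overlays:

* **Tremor** — sinusoid plus second harmonic at 4-6 Hz (rest) or 5-8 Hz
  (postural), peak amplitude monotone in severity, applied to affected limb
  units; the posture context (lying/sitting vs. arm extended during tasks)
  distinguishes rest from postural tremor through the gravity direction.
* **LID (dyskinesia)** — band-limited (1-4 Hz) non-rhythmic noise bursts on
  limbs and waist, RMS amplitude monotone in severity.
* **Bradykinesia** — attenuation of the voluntary-movement and locomotion
  amplitude (and bandwidth) monotone in severity.
* **FoG (freezing of gait)** — during walking, the ~1.6 Hz locomotion
  component on the leg units is replaced by low-amplitude 3-8 Hz trembling.

All randomness flows from ``SimulationConfig.seed``; identical config gives
bit-identical output. The generator is an idealization: it reproduces the
class structure (spectral bands, amplitude ordering, posture contexts) of
parkinsonian inertial signals, not their biomechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .signal_model import (
    ACCEL_AXES,
    LABEL_DOMAINS,
    LIMB_UNITS,
    UNIT_IDS,
    AnnotationTrack,
    DiaryTrack,
    RecordingSet,
    SensorRecording,
    unit_axes,
)

PHASES = ("lie", "sit", "transition", "walk", "task")

#: Phases in which each episode kind may be injected.
ALLOWED_PHASES: Dict[str, Tuple[str, ...]] = {
    "FOG": ("walk",),
    "TREMOR_rest": ("lie", "sit"),
    "TREMOR_postural": ("task",),
    "LID": ("walk", "task"),
    "BRADY": ("walk", "task"),
}

#: Posture class per activity phase (rest-like, postural-like, active).
PHASE_POSTURE: Dict[str, int] = {
    "lie": 0,
    "sit": 0,
    "transition": 2,
    "walk": 2,
    "task": 1,
}

# Gravity direction (unit vector in sensor frame) per unit per phase. Lying
# puts the limb long axis horizontal; sitting/standing aligns it with
# gravity; during manual tasks the forearms are extended forward.
_G_LIE = (1.0, 0.0, 0.0)
_G_UP = (0.0, 0.0, 1.0)
_G_EXT = (0.0, 1.0, 0.0)


def _gravity_dir(unit: str, phase: str) -> Tuple[float, float, float]:
    if phase == "lie":
        return _G_LIE
    if phase == "task" and unit in ("LW", "RW"):
        return _G_EXT
    return _G_UP


@dataclass
class EpisodeRequest:
    """A symptom episode to be scheduled by :func:`plan_episodes`."""

    symptom: str
    severity: int
    duration_s: float
    params: dict = field(default_factory=dict)


@dataclass
class Episode:
    symptom: str
    start_s: float
    end_s: float
    severity: int
    params: dict = field(default_factory=dict)


@dataclass
class EpisodePlan:
    """Scheduled episodes, keyed by symptom; same-symptom episodes disjoint."""

    episodes: Dict[str, List[Episode]] = field(default_factory=dict)

    def all_episodes(self) -> List[Episode]:
        return [ep for eps in self.episodes.values() for ep in eps]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated session.

    Severity->amplitude maps give tremor peak amplitude and dyskinesia RMS
    in g; bradykinesia maps severity to a multiplicative gain (< 1) on the
    voluntary-movement process. ``asymmetry`` is the left/right amplitude
    ratio applied to limb overlays (1.0 = symmetric).
    """

    fs: float = 64.0
    duration_s: float = 240.0
    seed: int = 0
    activity_script: List[Tuple[str, float, float]] = field(default_factory=list)
    episode_requests: List[EpisodeRequest] = field(default_factory=list)
    noise_sd: float = 0.02
    voluntary_sd: Dict[str, float] = field(
        default_factory=lambda: {
            "lie": 0.01,
            "sit": 0.02,
            "transition": 0.08,
            "task": 0.08,
            "walk": 0.06,
        }
    )
    tremor_amplitude: Dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.15, 3: 0.4}
    )
    lid_amplitude: Dict[int, float] = field(
        default_factory=lambda: {1: 0.04, 2: 0.12, 3: 0.3}
    )
    brady_gain: Dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.3, 3: 0.12}
    )
    rest_band: Tuple[float, float] = (4.0, 6.0)
    postural_band: Tuple[float, float] = (5.0, 8.0)
    lid_band: Tuple[float, float] = (1.0, 4.0)
    fog_band: Tuple[float, float] = (3.0, 8.0)
    fog_amplitude: float = 0.12
    walk_freq: float = 1.6
    walk_amplitude: float = 0.3
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if not self.activity_script:
            self.activity_script = default_activity_script(self.duration_s)

    def validate(self) -> "SimulationConfig":
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        script = sorted(self.activity_script, key=lambda p: p[1])
        cursor = 0.0
        for phase, start, end in script:
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
            if abs(start - cursor) > 1e-9 or end <= start:
                raise ValueError("activity phases must tile [0, duration]")
            cursor = end
        if abs(cursor - self.duration_s) > 1e-9:
            raise ValueError("activity phases must tile [0, duration]")
        for amp_map in (self.tremor_amplitude, self.lid_amplitude):
            if any(a < 0 for a in amp_map.values()):
                raise ValueError("amplitudes must be >= 0")
        return self


def default_activity_script(duration_s: float) -> List[Tuple[str, float, float]]:
    """Short-protocol script (lie -> sit -> walk -> tasks) scaled to duration."""
    f = duration_s / 240.0
    return [
        ("lie", 0.0, 60.0 * f),
        ("transition", 60.0 * f, 66.0 * f),
        ("sit", 66.0 * f, 120.0 * f),
        ("transition", 120.0 * f, 126.0 * f),
        ("walk", 126.0 * f, 168.0 * f),
        ("task", 168.0 * f, 240.0 * f),
    ]


def active_activity_script(duration_s: float) -> List[Tuple[str, float, float]]:
    """Activity-dominated script for symptoms defined relative to movement."""
    f = duration_s / 240.0
    return [
        ("sit", 0.0, 16.0 * f),
        ("transition", 16.0 * f, 22.0 * f),
        ("walk", 22.0 * f, 130.0 * f),
        ("task", 130.0 * f, 240.0 * f),
    ]


# ---------------------------------------------------------------------------
# Episode planning
# ---------------------------------------------------------------------------

def _episode_kind(req: EpisodeRequest) -> str:
    if req.symptom == "TREMOR":
        ttype = req.params.get("tremor_type", "rest")
        return f"TREMOR_{ttype}"
    return req.symptom


def plan_episodes(cfg: SimulationConfig) -> EpisodePlan:
    """Schedule requested episodes into phase-compatible, non-overlapping slots.

    FoG only inside walk phases; rest tremor in lie/sit; postural tremor in
    task phases; dyskinesia and bradykinesia in active (walk/task) phases.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xE715]))
    plan = EpisodePlan()
    for req in cfg.episode_requests:
        if req.symptom not in LABEL_DOMAINS:
            raise ValueError(f"unknown symptom {req.symptom!r}")
        if req.severity not in LABEL_DOMAINS[req.symptom] or req.severity == 0:
            raise ValueError(
                f"severity {req.severity} outside domain for {req.symptom}"
            )
        kind = _episode_kind(req)
        allowed = ALLOWED_PHASES[kind]
        slots = [
            (start, end)
            for phase, start, end in cfg.activity_script
            if phase in allowed and end - start >= req.duration_s
        ]
        if not slots:
            raise ValueError(
                f"no {'/'.join(allowed)} phase can host a "
                f"{req.duration_s:.0f} s {kind} episode"
            )
        existing = plan.episodes.setdefault(req.symptom, [])
        placed = None
        for _ in range(200):
            lo, hi = slots[rng.integers(len(slots))]
            start = float(rng.uniform(lo, hi - req.duration_s))
            end = start + req.duration_s
            if all(end <= ep.start_s or start >= ep.end_s for ep in existing):
                placed = (start, end)
                break
        if placed is None:
            raise ValueError(
                f"could not place {kind} episode of {req.duration_s:.0f} s "
                "without overlap; reduce episode load"
            )
        params = dict(req.params)
        if req.symptom == "TREMOR" and "freq" not in params:
            band = (
                cfg.rest_band
                if params.get("tremor_type", "rest") == "rest"
                else cfg.postural_band
            )
            params["freq"] = float(rng.uniform(*band))
        params.setdefault("limbs", list(LIMB_UNITS))
        existing.append(
            Episode(req.symptom, placed[0], placed[1], req.severity, params)
        )
    for eps in plan.episodes.values():
        eps.sort(key=lambda ep: ep.start_s)
    return plan


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _band_noise(rng, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz."""
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _spiky_band_noise(rng, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited noise with bursty, heavy-tailed amplitude.

    Freezing trembling is jerky rather than a stationary Gaussian process;
    squaring the envelope produces the leptokurtic amplitude distribution
    seen in knee-trembling struggling steps.
    """
    a = _band_noise(rng, n, fs, lo, hi)
    b = _band_noise(rng, n, fs, lo, hi)
    y = a * np.abs(b)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _ramp_mask(t: np.ndarray, start: float, end: float, ramp: float = 0.5) -> np.ndarray:
    """Soft on/off envelope for an episode (half-cosine ramps)."""
    m = np.zeros_like(t)
    inside = (t >= start) & (t < end)
    m[inside] = 1.0
    if ramp > 0:
        up = inside & (t < start + ramp)
        m[up] = 0.5 - 0.5 * np.cos(np.pi * (t[up] - start) / ramp)
        dn = inside & (t >= end - ramp)
        m[dn] = 0.5 - 0.5 * np.cos(np.pi * (end - t[dn]) / ramp)
    return m


def _side_factor(unit: str, asymmetry: float) -> float:
    """Left/right amplitude factors with ratio `asymmetry`, mean-preserving:
    left gets 2a/(1+a), right 2/(1+a), so amplitudes stay in clinical range."""
    if unit.startswith("L"):
        return 2.0 * asymmetry / (1.0 + asymmetry)
    return 2.0 / (1.0 + asymmetry)


def simulate_recording(
    cfg: SimulationConfig,
    plan: Optional[EpisodePlan] = None,
    patient_id: str = "P00",
    session_id: str = "S00",
) -> Tuple[SensorRecording, Dict[str, AnnotationTrack], Dict[str, DiaryTrack]]:
    """Synthesize one session; annotations mirror the plan exactly.

    Returns (recording, annotation tracks keyed by symptom incl. the internal
    POSTURE track, diary tracks keyed by symptom).
    """
    cfg.validate()
    if plan is None:
        plan = plan_episodes(cfg)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    if n <= 0:
        raise ValueError("zero-length recording")
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x51A7]))

    phase_idx = np.zeros(n, dtype=int)
    for phase, start, end in cfg.activity_script:
        sel = (t >= start) & (t < end)
        phase_idx[sel] = PHASES.index(phase)
    phase_names = np.array(PHASES)[phase_idx]

    # Bradykinesia gain envelope (applies to voluntary movement + locomotion).
    brady_gain = np.ones(n)
    for ep in plan.episodes.get("BRADY", []):
        g = cfg.brady_gain.get(ep.severity, 1.0)
        mask = _ramp_mask(t, ep.start_s, ep.end_s)
        brady_gain = brady_gain * (1.0 - mask) + g * mask

    # Walk on/off and FoG masks.
    walk_mask = _lowpass((phase_names == "walk").astype(float), fs, 1.0)
    fog_mask = np.zeros(n)
    for ep in plan.episodes.get("FOG", []):
        fog_mask = np.maximum(fog_mask, _ramp_mask(t, ep.start_s, ep.end_s))

    data: Dict[str, np.ndarray] = {}
    for unit in UNIT_IDS:
        axes = unit_axes(unit)
        arr = np.zeros((n, len(axes)))

        # Gravity projection per phase, softened at posture changes.
        gdir = np.empty((n, 3))
        for k, phase in enumerate(PHASES):
            sel = phase_idx == k
            if sel.any():
                gdir[sel] = _gravity_dir(unit, phase)
        gdir = _lowpass(gdir.T, fs, 0.8).T
        arr[:, :3] += gdir

        # Voluntary movement: low-pass (<2 Hz) Gaussian with phase-dependent
        # amplitude, attenuated inside bradykinesia episodes.
        sd_env = np.array([cfg.voluntary_sd[p] for p in phase_names])
        sd_env = _lowpass(sd_env, fs, 0.8) * brady_gain
        for j in range(3):
            v = _lowpass(rng.standard_normal(n), fs, 2.0)
            s = np.std(v)
            if s > 0:
                v /= s
            arr[:, j] += v * sd_env

        # Locomotion during walking (legs and waist), anti-phase legs.
        if unit in ("LL", "RL", "WAIST"):
            phase0 = {"LL": 0.0, "RL": np.pi, "WAIST": np.pi / 2}[unit]
            amp = cfg.walk_amplitude * (0.4 if unit == "WAIST" else 1.0)
            loco = amp * np.sin(2 * np.pi * cfg.walk_freq * t + phase0)
            loco_env = walk_mask * brady_gain
            if unit != "WAIST":
                # Freezing: locomotion collapses, replaced by 3-8 Hz trembling.
                tremble = cfg.fog_amplitude * _spiky_band_noise(rng, n, fs, *cfg.fog_band)
                loco_env = loco_env * (1.0 - 0.9 * fog_mask)
                arr[:, 2] += tremble * fog_mask * walk_mask
                arr[:, 0] += 0.5 * tremble * fog_mask * walk_mask
            arr[:, 2] += loco * loco_env
            arr[:, 0] += 0.5 * loco * loco_env

        # Tremor overlays on affected limb units.
        if unit in LIMB_UNITS:
            for ep in plan.episodes.get("TREMOR", []):
                if unit not in ep.params.get("limbs", LIMB_UNITS):
                    continue
                amp = cfg.tremor_amplitude.get(ep.severity, 0.0)
                amp *= _side_factor(unit, cfg.asymmetry)
                f = ep.params.get("freq", np.mean(cfg.rest_band))
                phi = rng.uniform(0, 2 * np.pi)
                mask = _ramp_mask(t, ep.start_s, ep.end_s)
                wave = np.sin(2 * np.pi * f * t + phi) + 0.3 * np.sin(
                    4 * np.pi * f * t + 2 * phi
                )
                arr[:, 0] += amp * wave * mask
                arr[:, 1] += 0.6 * amp * wave * mask

        # Dyskinesia bursts on limbs and waist.
        for ep in plan.episodes.get("LID", []):
            amp = cfg.lid_amplitude.get(ep.severity, 0.0)
            if unit in LIMB_UNITS:
                amp *= _side_factor(unit, cfg.asymmetry)
            mask = _ramp_mask(t, ep.start_s, ep.end_s)
            for j in range(3):
                amp_j = amp * (1.0 if j < 2 else 0.6)
                arr[:, j] += amp_j * _band_noise(rng, n, fs, *cfg.lid_band) * mask

        # Measurement noise; waist gyro channels in deg/s.
        arr[:, :3] += rng.normal(0.0, cfg.noise_sd, (n, 3))
        if unit == "WAIST":
            gyro = rng.normal(0.0, 1.0, (n, 3))
            gyro[:, 2] += 25.0 * np.sin(2 * np.pi * cfg.walk_freq * t) * walk_mask * brady_gain
            for ep in plan.episodes.get("LID", []):
                amp = cfg.lid_amplitude.get(ep.severity, 0.0)
                mask = _ramp_mask(t, ep.start_s, ep.end_s)
                gyro[:, 0] += 60.0 * amp * _band_noise(rng, n, fs, *cfg.lid_band) * mask
            arr[:, 3:] = gyro

        data[unit] = arr

    rec = SensorRecording(
        patient_id=patient_id, session_id=session_id, fs=fs, data=data
    ).validate()
    annotations = _annotations_from_plan(cfg, plan)
    diaries = {
        sym: _diary_from_track(track, cfg.duration_s)
        for sym, track in annotations.items()
        if sym != "POSTURE"
    }
    return rec, annotations, diaries


def _annotations_from_plan(
    cfg: SimulationConfig, plan: EpisodePlan
) -> Dict[str, AnnotationTrack]:
    tracks: Dict[str, AnnotationTrack] = {}
    for sym in ("TREMOR", "LID", "BRADY", "FOG"):
        eps = plan.episodes.get(sym, [])
        intervals = [(ep.start_s, ep.end_s, ep.severity) for ep in eps]
        track = AnnotationTrack(symptom=sym, intervals=intervals)
        if sym == "TREMOR" and eps:
            track.types = [ep.params.get("tremor_type", "rest") for ep in eps]
        tracks[sym] = track.validate()
    posture = [
        (start, end, PHASE_POSTURE[phase])
        for phase, start, end in sorted(cfg.activity_script, key=lambda p: p[1])
    ]
    tracks["POSTURE"] = AnnotationTrack(symptom="POSTURE", intervals=posture).validate()
    return tracks


def _diary_from_track(track: AnnotationTrack, duration_s: float) -> DiaryTrack:
    """Duration-weighted majority label per 1800 s bin; ties -> higher severity."""
    bin_s = DiaryTrack.BIN_S
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    bins: List[Tuple[float, int]] = []
    for b in range(n_bins):
        lo, hi = b * bin_s, min((b + 1) * bin_s, duration_s)
        durations: Dict[int, float] = {}
        cursor = lo
        for start, end, label in track.intervals:
            s, e = max(start, lo), min(end, hi)
            if e > s:
                durations[0] = durations.get(0, 0.0) + max(0.0, s - cursor)
                durations[int(label)] = durations.get(int(label), 0.0) + (e - s)
                cursor = max(cursor, e)
        durations[0] = durations.get(0, 0.0) + max(0.0, hi - cursor)
        best = max(durations.items(), key=lambda kv: (kv[1], kv[0]))[0]
        bins.append((lo, best))
    return DiaryTrack(symptom=track.symptom, bins=bins).validate()


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_patients: int,
    sessions_per_patient: int,
    cfg_template: SimulationConfig,
    seed: int,
) -> RecordingSet:
    """Simulate a cohort with per-patient parameter jitter.

    Each patient draws their own tremor frequency (within the configured
    bands) and an overall amplitude scale in [0.8, 1.25], so leave-one-
    patient-out evaluation is a genuine generalization test.
    """
    recordings = []
    annotations: Dict[str, Dict[str, AnnotationTrack]] = {}
    diaries: Dict[str, Dict[str, DiaryTrack]] = {}
    for pid, sid, cfg in cohort_session_configs(
        n_patients, sessions_per_patient, cfg_template, seed
    ):
        rec, ann, dia = simulate_recording(cfg, patient_id=pid, session_id=sid)
        recordings.append(rec)
        annotations[sid] = ann
        diaries[sid] = dia
    return RecordingSet(recordings, annotations, diaries).validate()


def cohort_session_configs(
    n_patients: int,
    sessions_per_patient: int,
    cfg_template: SimulationConfig,
    seed: int,
) -> List[Tuple[str, str, SimulationConfig]]:
    """The per-session (patient_id, session_id, config) triples of a cohort.

    Patient-level draws: tremor frequencies within the configured bands and
    an amplitude scale in [0.8, 1.25] shared by all of a patient's sessions.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients for a cohort")
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0407]))
    out = []
    for i in range(n_patients):
        pid = f"P{i:02d}"
        amp_scale = float(root.uniform(0.8, 1.25))
        rest_f = float(root.uniform(*cfg_template.rest_band))
        post_f = float(root.uniform(*cfg_template.postural_band))
        for s in range(sessions_per_patient):
            sid = f"{pid}-S{s:02d}"
            sub_seed = int(root.integers(0, 2**31 - 1))
            requests = []
            for req in cfg_template.episode_requests:
                params = dict(req.params)
                if req.symptom == "TREMOR":
                    params["freq"] = (
                        rest_f
                        if params.get("tremor_type", "rest") == "rest"
                        else post_f
                    )
                requests.append(replace(req, params=params))
            cfg = replace(
                cfg_template,
                seed=sub_seed,
                episode_requests=requests,
                tremor_amplitude={
                    k: v * amp_scale for k, v in cfg_template.tremor_amplitude.items()
                },
                lid_amplitude={
                    k: v * amp_scale for k, v in cfg_template.lid_amplitude.items()
                },
            )
            out.append((pid, sid, cfg))
    return out


def long_term_tremor_session(
    seed: int = 0, fs: float = 64.0, duration_s: float = 7200.0
) -> Tuple[SimulationConfig, EpisodePlan]:
    """An at-home half-day session for diary validation.

    Alternating long lying/sitting phases with one sustained rest-tremor
    episode per half-hour bin (covering ~90% of its bin), so each diary bin
    is dominated by a single state — the clinical picture of slow ON/OFF
    fluctuation that half-hour self-reports can resolve.
    """
    bin_s = DiaryTrack.BIN_S
    n_bins = int(duration_s // bin_s)
    script = []
    for b in range(n_bins):
        phase = "lie" if b % 2 == 0 else "sit"
        script.append((phase, b * bin_s, (b + 1) * bin_s))
    if n_bins * bin_s < duration_s:
        script.append(("sit", n_bins * bin_s, duration_s))
    severities = [0, 2, 1, 3]  # per bin, cycling
    episodes = []
    for b in range(n_bins):
        sev = severities[b % len(severities)]
        if sev == 0:
            continue
        margin = 0.05 * bin_s
        episodes.append(
            Episode(
                "TREMOR",
                b * bin_s + margin,
                (b + 1) * bin_s - margin,
                sev,
                {"tremor_type": "rest", "freq": 5.0, "limbs": list(LIMB_UNITS)},
            )
        )
    plan = EpisodePlan(episodes={"TREMOR": episodes})
    cfg = SimulationConfig(
        fs=fs, duration_s=duration_s, seed=seed, activity_script=script
    )
    return cfg, plan


def default_config(
    symptom: str, duration_s: float = 240.0, fs: float = 64.0, **overrides
) -> SimulationConfig:
    """Study-condition template per symptom, with one episode per severity.

    The tremor template follows the full lie -> sit -> walk -> task protocol
    (rest tremor while lying/sitting, postural during tasks); the other
    symptoms use an activity-dominated script since they are defined
    relative to voluntary movement.
    """
    f = duration_s / 240.0
    if symptom == "TREMOR":
        script = default_activity_script(duration_s)
        requests = [
            EpisodeRequest("TREMOR", 1, 24.0 * f, {"tremor_type": "rest"}),
            EpisodeRequest("TREMOR", 2, 24.0 * f, {"tremor_type": "rest"}),
            EpisodeRequest("TREMOR", 3, 24.0 * f, {"tremor_type": "postural"}),
        ]
    elif symptom == "LID":
        script = active_activity_script(duration_s)
        requests = [
            EpisodeRequest("LID", 1, 30.0 * f),
            EpisodeRequest("LID", 2, 30.0 * f),
            EpisodeRequest("LID", 3, 30.0 * f),
        ]
    elif symptom == "BRADY":
        script = active_activity_script(duration_s)
        requests = [
            EpisodeRequest("BRADY", 1, 30.0 * f),
            EpisodeRequest("BRADY", 2, 30.0 * f),
            EpisodeRequest("BRADY", 3, 30.0 * f),
        ]
    elif symptom == "FOG":
        # Freezing is rare: ~2.5% of session time frozen, matching the
        # strong No-FoG/FoG imbalance the 4% subsampling rule presumes.
        duration_s = max(duration_s, 480.0)
        f = duration_s / 240.0
        script = [
            ("sit", 0.0, 10.0 * f),
            ("transition", 10.0 * f, 16.0 * f),
            ("walk", 16.0 * f, 210.0 * f),
            ("task", 210.0 * f, 240.0 * f),
        ]
        requests = [
            EpisodeRequest("FOG", 1, 3.0 * f),
            EpisodeRequest("FOG", 1, 3.0 * f),
        ]
    else:
        raise ValueError(f"unknown symptom {symptom!r}")
    return SimulationConfig(
        fs=fs,
        duration_s=duration_s,
        activity_script=script,
        episode_requests=requests,
        **overrides,
    )
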