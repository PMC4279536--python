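"""Sliding-window segmentation and the feature operators behind the recognizers.

Window lengths are symptom-specific (3 s / 1.5 s step for tremor, 1 s /
0.5 s for dyskinesia and freezing, 5 s / 2.5 s for bradykinesia) and are
specified in seconds, converted to samples by rounding, so everything here
is agnostic to the sampling rate.

Scalar operators (``basic_stats``, ``signal_entropy``, ``spectral_features``,
``approx_entropy``, ``sample_entropy``, ``cross_correlation``,
``posture_features``) are the public primitives; :func:`extract` applies the
per-symptom recipe over a whole recording and returns a
:class:`FeatureMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .signal_model import (
    ACCEL_AXES,
    LIMB_UNITS,
    UNIT_IDS,
    SensorRecording,
    all_channels,
    unit_axes,
)

# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Sliding window geometry in seconds; step = length - overlap."""

    length_s: float
    step_s: float

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError("require 0 < step_s <= length_s")


#: Per-symptom window geometry. POSTURE shares the tremor grid so the two
#: tremor HMMs operate on aligned windows.
WINDOW_SPECS: Dict[str, WindowSpec] = {
    "TREMOR": WindowSpec(3.0, 1.5),
    "LID": WindowSpec(1.0, 0.5),
    "BRADY": WindowSpec(5.0, 2.5),
    "FOG": WindowSpec(1.0, 0.5),
    "POSTURE": WindowSpec(3.0, 1.5),
}


def sliding_windows(
    n_samples: int, fs: float, spec: WindowSpec
) -> List[Tuple[int, int, float]]:
    """Window index ranges and centers: floor((T - L)/S) + 1 windows.

    A trailing partial window is dropped. Raises if the recording is shorter
    than one window.
    """
    L = int(round(spec.length_s * fs))
    S = int(round(spec.step_s * fs))
    if L < 1 or S < 1:
        raise ValueError("window shorter than one sample")
    if n_samples < L:
        raise ValueError(
            f"recording of {n_samples} samples shorter than one "
            f"{spec.length_s} s window"
        )
    n_win = (n_samples - L) // S + 1
    out = []
    for k in range(n_win):
        start = k * S
        end = start + L
        out.append((start, end, (start + end) / 2.0 / fs))
    return out


# ---------------------------------------------------------------------------
# Scalar operators
# ---------------------------------------------------------------------------


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward), same length."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) for fs={fs}")
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def basic_stats(w: np.ndarray) -> Dict[str, float]:
    """Mean, population SD, RMS and range (max - min) of a window."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return {
        "mean": float(np.mean(w)),
        "sd": float(np.std(w)),
        "rms": float(np.sqrt(np.mean(w**2))),
        "range": float(np.max(w) - np.min(w)),
    }


def _hist_entropy_rows(W: np.ndarray, n_bins: int) -> np.ndarray:
    """Shannon entropy (bits) of equal-width amplitude histograms, per row."""
    W = np.asarray(W, dtype=float)
    mn = W.min(axis=1, keepdims=True)
    mx = W.max(axis=1, keepdims=True)
    span = mx - mn
    flat_rows = span[:, 0] <= 0
    safe = np.where(span == 0, 1.0, span)
    idx = np.minimum((n_bins * (W - mn) / safe).astype(int), n_bins - 1)
    rows = np.arange(W.shape[0])[:, None]
    counts = np.bincount(
        (rows * n_bins + idx).ravel(), minlength=W.shape[0] * n_bins
    ).reshape(W.shape[0], n_bins)
    p = counts / W.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    H = -terms.sum(axis=1)
    H[flat_rows] = 0.0
    return H


def signal_entropy(w: np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy (bits) of the amplitude histogram over [min, max].

    Equal-width bins; 0 log 0 := 0; a constant window has entropy 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    w = np.asarray(w, dtype=float)
    return float(_hist_entropy_rows(w[None, :], n_bins)[0])


def _periodogram_rows(W: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    f, P = sps.periodogram(W, fs=fs, axis=-1)
    return f, P


def spectral_features(
    w: np.ndarray,
    fs: float,
    bands: Sequence[Tuple[float, float]] = ((0.5, 3.0), (3.0, 8.0)),
) -> Dict[str, float]:
    """Periodogram band energies, spectral entropy, dominant frequency and
    low-frequency ratio.

    * spectral entropy = Shannon entropy (bits) of the normalized power
      spectrum (0 for an all-zero window);
    * dominant_freq = argmax of the spectrum above 0.5 Hz;
    * low_freq_ratio = energy in 0.5-3 Hz over total energy above 0.5 Hz.
    """
    w = np.asarray(w, dtype=float)
    for lo, hi in bands:
        if not 0 <= lo < hi <= fs / 2:
            raise ValueError(f"band ({lo}, {hi}) outside (0, fs/2)")
    f, P = _periodogram_rows(w[None, :], fs)
    P = P[0]
    out: Dict[str, float] = {}
    for i, (lo, hi) in enumerate(bands):
        sel = (f >= lo) & (f < hi)
        out[f"band_energy_{i}"] = float(P[sel].sum())
    total = P.sum()
    if total <= 0:
        out.update(spectral_entropy=0.0, dominant_freq=0.0, low_freq_ratio=0.0)
        return out
    p = P / total
    nz = p > 0
    out["spectral_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    above = f > 0.5
    if above.any() and P[above].sum() > 0:
        out["dominant_freq"] = float(f[above][np.argmax(P[above])])
        low = above & (f <= 3.0)
        out["low_freq_ratio"] = float(P[low].sum() / P[above].sum())
    else:
        out["dominant_freq"] = 0.0
        out["low_freq_ratio"] = 0.0
    return out


def _match_matrices(x: np.ndarray, m: int, tol: float):
    """Boolean Chebyshev-match matrices at template lengths m and m+1.

    Built incrementally from the scalar |x_i - x_j| <= tol matrix: a pair of
    length-m templates matches iff all m shifted scalar pairs match.
    """
    B1 = np.abs(x[:, None] - x[None, :]) <= tol
    Bm = B1
    for k in range(1, m):
        Bm = Bm[:-1, :-1] & B1[k:, k:]
    Bm1 = Bm[:-1, :-1] & B1[m:, m:]
    return Bm, Bm1


def approx_entropy(w: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) with Chebyshev distance.

    ``r`` is relative: the tolerance is ``r * SD(window)``. Self-matches are
    included (the classic definition); a constant window returns 0.
    """
    x = np.asarray(w, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("window length must exceed m + 1")
    tol = r * float(np.std(x))
    if tol == 0:
        return 0.0
    Bm, Bm1 = _match_matrices(x, m, tol)
    phi_m = float(np.mean(np.log(Bm.mean(axis=1))))
    phi_m1 = float(np.mean(np.log(Bm1.mean(axis=1))))
    return phi_m - phi_m1


def sample_entropy(w: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r): -log(A/B) over N - m templates,
    self-matches excluded; tolerance is ``r * SD(window)``.

    When no template pair matches at length m or m+1 the value is capped at
    log(n - m) to keep feature matrices finite.
    """
    x = np.asarray(w, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("window length must exceed m + 1")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    tol = r * sd
    cap = float(np.log(n - m))
    N = n - m  # templates comparable at both lengths
    Bm, Bm1 = _match_matrices(x, m, tol)
    B = int((Bm[:N, :N].sum() - N) // 2)
    A = int((Bm1[:N, :N].sum() - N) // 2)
    if B == 0 or A == 0:
        return cap
    return float(min(cap, -np.log(A / B)))


def cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation in [-1, 1]; 0 if either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.clip(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb), -1, 1))


#: Unit pairs whose gravity-vector angle is reported as an intersegment angle.
POSTURE_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("LW", "RW"),
    ("LL", "RL"),
    ("LW", "WAIST"),
    ("RW", "WAIST"),
)


def posture_features(
    windows: Dict[str, np.ndarray], min_gravity_g: float = 0.2
) -> Dict[str, float]:
    """Gravity-derived posture features from per-unit accelerometer windows.

    The gravity estimate is the mean of the window's low-frequency content
    (callers typically pass already low-passed (<0.5 Hz) signal; the mean of
    a short raw window is an adequate estimate as well). Inclination is the
    angle between the gravity estimate and the unit's z axis; intersegment
    angles are between gravity estimates of paired units. A unit whose
    gravity magnitude falls below ``min_gravity_g`` yields NaN features for
    the window (flagged invalid).
    """
    gvec: Dict[str, np.ndarray] = {}
    feats: Dict[str, float] = {}
    for unit in UNIT_IDS:
        w = np.asarray(windows[unit], dtype=float)[:, :3]
        g = w.mean(axis=0)
        norm = np.linalg.norm(g)
        if norm < min_gravity_g:
            gvec[unit] = np.full(3, np.nan)
            feats[f"{unit}_inclination_deg"] = np.nan
            continue
        g = g / norm
        gvec[unit] = g
        feats[f"{unit}_inclination_deg"] = float(
            np.degrees(np.arccos(np.clip(g[2], -1, 1)))
        )
    for ua, ub in POSTURE_PAIRS:
        ga, gb = gvec[ua], gvec[ub]
        if np.isnan(ga).any() or np.isnan(gb).any():
            feats[f"{ua}_{ub}_angle_deg"] = np.nan
        else:
            feats[f"{ua}_{ub}_angle_deg"] = float(
                np.degrees(np.arccos(np.clip(np.dot(ga, gb), -1, 1)))
            )
    return feats


# ---------------------------------------------------------------------------
# FeatureMatrix and whole-recording extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with time stamps and optional labels."""

    window_centers: np.ndarray
    names: List[str]
    X: np.ndarray
    labels: Optional[np.ndarray] = None
    patient_id: str = ""
    session_id: str = ""
    symptom: str = ""

    def validate(self) -> "FeatureMatrix":
        if self.X.shape != (len(self.window_centers), len(self.names)):
            raise ValueError("X shape inconsistent with centers/names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        return self

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(
            self.window_centers,
            list(names),
            self.X[:, idx],
            self.labels,
            self.patient_id,
            self.session_id,
            self.symptom,
        )


#: Cross-correlation pairing: homologous axes of contralateral limbs plus
#: each limb's z axis against the waist z axis.
CROSSCORR_PAIRS: List[Tuple[Tuple[str, str], Tuple[str, str]]] = [
    (("LW", ax), ("RW", ax)) for ax in ACCEL_AXES
] + [(("LL", ax), ("RL", ax)) for ax in ACCEL_AXES] + [
    ((u, "z"), ("WAIST", "z")) for u in LIMB_UNITS
]

LID_BANDS: Tuple[Tuple[float, float], ...] = ((0.5, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0))
TREMOR_BANDS: Tuple[Tuple[float, float], ...] = ((0.5, 3.0), (3.0, 8.0))


def _window_matrix(x: np.ndarray, L: int, S: int) -> np.ndarray:
    return sliding_window_view(x, L)[::S]


def _stats_rows(W: np.ndarray) -> Dict[str, np.ndarray]:
    return {
        "mean": W.mean(axis=1),
        "sd": W.std(axis=1),
        "rms": np.sqrt((W**2).mean(axis=1)),
        "range": W.max(axis=1) - W.min(axis=1),
    }


def _spectral_rows(
    W: np.ndarray, fs: float, bands: Sequence[Tuple[float, float]]
) -> Dict[str, np.ndarray]:
    f, P = _periodogram_rows(W, fs)
    out: Dict[str, np.ndarray] = {}
    for i, (lo, hi) in enumerate(bands):
        sel = (f >= lo) & (f < hi)
        out[f"band_energy_{i}"] = P[:, sel].sum(axis=1)
    total = P.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    p = P / safe[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out["spectral_entropy"] = np.where(total > 0, -terms.sum(axis=1), 0.0)
    above = f > 0.5
    fa = f[above]
    Pa = P[:, above]
    tot_a = Pa.sum(axis=1)
    dom = np.where(tot_a > 0, fa[np.argmax(Pa, axis=1)], 0.0)
    out["dominant_freq"] = dom
    low = fa <= 3.0
    out["low_freq_ratio"] = np.where(tot_a > 0, Pa[:, low].sum(axis=1) / np.where(tot_a > 0, tot_a, 1.0), 0.0)
    return out


def _log_energy(e: np.ndarray) -> np.ndarray:
    return np.log10(e + 1e-12)


def _apen_rows(W: np.ndarray, m: int, r: float) -> np.ndarray:
    return np.array([approx_entropy(w, m, r) for w in W])


def _gravity_series(rec: SensorRecording) -> Dict[str, np.ndarray]:
    """Low-passed (<0.5 Hz) acceleration per unit for posture estimation."""
    sos = sps.butter(4, 0.5, btype="low", fs=rec.fs, output="sos")
    return {
        u: sps.sosfiltfilt(sos, rec.data[u][:, :3], axis=0) for u in UNIT_IDS
    }


def _posture_block(
    rec: SensorRecording, wins: List[Tuple[int, int, float]]
) -> Tuple[List[str], np.ndarray]:
    grav = _gravity_series(rec)
    names: List[str] = []
    cols: List[np.ndarray] = []
    rows = []
    for start, end, _ in wins:
        feats = posture_features({u: grav[u][start:end] for u in UNIT_IDS})
        rows.append(feats)
    names = list(rows[0].keys())
    block = np.array([[row[n] for n in names] for row in rows])
    # NaN = posture invalid for that window (free-fall-like); impute with the
    # column median so downstream matrices stay finite.
    for j in range(block.shape[1]):
        col = block[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(col) if np.isfinite(col).any() else 0.0
            col[bad] = med
    return names, block


def extract(
    rec: SensorRecording,
    symptom: str,
    segment: Optional[str] = None,
    include_optional: bool = False,
    apen_m: int = 2,
    apen_r: float = 0.2,
    entropy_bins: int = 10,
) -> FeatureMatrix:
    """Apply a symptom's window spec and feature recipe over a recording.

    Recipes (fused, ``segment=None``):

    * TREMOR (3 s / 1.5 s): per limb-unit axis — mean/sd/rms/range, log band
      energies (0.5-3, 3-8 Hz), spectral entropy, dominant frequency,
      low-frequency ratio, amplitude-histogram entropy; plus gravity posture
      features (5 inclinations + 4 intersegment angles).
    * LID (1 s / 0.5 s): per axis of all five units (incl. waist gyro) —
      mean, sd, histogram entropy, log energies in 0.5-1/1-2/2-4/4-8 Hz
      sub-bands, spectral entropy.
    * BRADY (5 s / 2.5 s, on 1-3 Hz band-passed signals): per limb-unit
      axis — approximate entropy and range (the selected subset), with
      sample entropy and RMS behind ``include_optional``; plus the maximum
      absolute zero-lag cross-correlation over contralateral/waist pairs.
    * FOG (1 s / 0.5 s): histogram entropy per axis of every unit
      (30 features).
    * POSTURE (3 s / 1.5 s): the gravity posture features alone (feeds the
      body action-posture model).

    With ``segment`` set (TREMOR/BRADY only), the recipe is restricted to
    that limb unit with unit-agnostic feature names, so one segment-level
    model can be applied to any limb.
    """
    rec.validate()
    if symptom not in WINDOW_SPECS:
        raise ValueError(f"unknown symptom {symptom!r}")
    spec = WINDOW_SPECS[symptom]
    wins = sliding_windows(rec.n_samples, rec.fs, spec)
    centers = np.array([c for _, _, c in wins])
    L = int(round(spec.length_s * rec.fs))
    S = int(round(spec.step_s * rec.fs))
    names: List[str] = []
    cols: List[np.ndarray] = []

    def add(name: str, values: np.ndarray) -> None:
        names.append(name)
        cols.append(np.asarray(values, dtype=float))

    if symptom in ("TREMOR", "POSTURE"):
        if symptom == "TREMOR":
            units = [segment] if segment else list(LIMB_UNITS)
            for unit in units:
                prefix = "acc" if segment else unit
                for j, ax in enumerate(ACCEL_AXES):
                    W = _window_matrix(rec.data[unit][:, j], L, S)
                    st = _stats_rows(W)
                    for k in ("mean", "sd", "rms", "range"):
                        add(f"{prefix}_{ax}_{k}", st[k])
                    sp = _spectral_rows(W, rec.fs, TREMOR_BANDS)
                    for i in range(len(TREMOR_BANDS)):
                        add(f"{prefix}_{ax}_logE{i}", _log_energy(sp[f"band_energy_{i}"]))
                    add(f"{prefix}_{ax}_spec_entropy", sp["spectral_entropy"])
                    add(f"{prefix}_{ax}_dominant_freq", sp["dominant_freq"])
                    add(f"{prefix}_{ax}_low_freq_ratio", sp["low_freq_ratio"])
                    add(f"{prefix}_{ax}_entropy", _hist_entropy_rows(W, entropy_bins))
        if segment:
            # segment-local posture: own inclination + angle to the waist
            grav = _gravity_series(rec)
            incl = np.zeros(len(wins))
            angle = np.zeros(len(wins))
            for i, (start, end, _) in enumerate(wins):
                gs = grav[segment][start:end].mean(axis=0)
                gw = grav["WAIST"][start:end].mean(axis=0)
                ns, nw = np.linalg.norm(gs), np.linalg.norm(gw)
                if ns < 0.2 or nw < 0.2:
                    incl[i], angle[i] = np.nan, np.nan
                    continue
                gs, gw = gs / ns, gw / nw
                incl[i] = np.degrees(np.arccos(np.clip(gs[2], -1, 1)))
                angle[i] = np.degrees(np.arccos(np.clip(np.dot(gs, gw), -1, 1)))
            for name, col in (("seg_inclination_deg", incl), ("seg_waist_angle_deg", angle)):
                bad = ~np.isfinite(col)
                if bad.any():
                    col[bad] = np.nanmedian(col) if np.isfinite(col).any() else 0.0
                add(name, col)
        else:
            pnames, pblock = _posture_block(rec, wins)
            for i, n in enumerate(pnames):
                add(n, pblock[:, i])

    elif symptom == "LID":
        for unit, ax in all_channels():
            j = unit_axes(unit).index(ax)
            W = _window_matrix(rec.data[unit][:, j], L, S)
            st = _stats_rows(W)
            add(f"{unit}_{ax}_mean", st["mean"])
            add(f"{unit}_{ax}_sd", st["sd"])
            add(f"{unit}_{ax}_entropy", _hist_entropy_rows(W, entropy_bins))
            sp = _spectral_rows(W, rec.fs, LID_BANDS)
            for i in range(len(LID_BANDS)):
                add(f"{unit}_{ax}_logE{i}", _log_energy(sp[f"band_energy_{i}"]))
            add(f"{unit}_{ax}_spec_entropy", sp["spectral_entropy"])

    elif symptom == "BRADY":
        filt = {
            u: bandpass(rec.data[u][:, :3].T, rec.fs, 1.0, 3.0).T
            for u in LIMB_UNITS + ("WAIST",)
        }
        units = [segment] if segment else list(LIMB_UNITS)
        for unit in units:
            prefix = "acc" if segment else unit
            for j, ax in enumerate(ACCEL_AXES):
                W = _window_matrix(filt[unit][:, j], L, S)
                add(f"{prefix}_{ax}_apen", _apen_rows(W, apen_m, apen_r))
                add(f"{prefix}_{ax}_range", W.max(axis=1) - W.min(axis=1))
                if include_optional:
                    add(
                        f"{prefix}_{ax}_sampen",
                        np.array([sample_entropy(w, apen_m, apen_r) for w in W]),
                    )
                    add(f"{prefix}_{ax}_rms", np.sqrt((W**2).mean(axis=1)))
        if segment:
            contra = {"LW": "RW", "RW": "LW", "LL": "RL", "RL": "LL"}[segment]
            pairs = [((segment, ax), (contra, ax)) for ax in ACCEL_AXES] + [
                ((segment, "z"), ("WAIST", "z"))
            ]
        else:
            pairs = CROSSCORR_PAIRS
        pair_wins = {}
        for (ua, axa), (ub, axb) in pairs:
            for u, ax in ((ua, axa), (ub, axb)):
                if (u, ax) not in pair_wins:
                    j = ACCEL_AXES.index(ax)
                    pair_wins[(u, ax)] = _window_matrix(filt[u][:, j], L, S)
        xc = np.zeros(len(wins))
        for (a, b) in pairs:
            Wa, Wb = pair_wins[a], pair_wins[b]
            sa = Wa.std(axis=1)
            sb = Wb.std(axis=1)
            num = ((Wa - Wa.mean(axis=1, keepdims=True)) * (Wb - Wb.mean(axis=1, keepdims=True))).mean(axis=1)
            rho = np.where((sa > 0) & (sb > 0), num / np.where(sa * sb > 0, sa * sb, 1.0), 0.0)
            xc = np.maximum(xc, np.abs(np.clip(rho, -1, 1)))
        add("crosscorr_max", xc)

    elif symptom == "FOG":
        for unit, ax in all_channels():
            j = unit_axes(unit).index(ax)
            W = _window_matrix(rec.data[unit][:, j], L, S)
            add(f"{unit}_{ax}_entropy", _hist_entropy_rows(W, entropy_bins))

    X = np.column_stack(cols) if cols else np.zeros((len(wins), 0))
    return FeatureMatrix(
        window_centers=centers,
        names=names,
        X=X,
        patient_id=rec.patient_id,
        session_id=rec.session_id,
        symptom=symptom,
    ).validate()


def write_feature_csv(fm: FeatureMatrix, path) -> None:
    """Serialize a FeatureMatrix as CSV with a ``#`` metadata header block."""
    import pandas as pd

    header = (
        f"# symptom={fm.symptom}\n"
        f"# patient_id={fm.patient_id}\n"
        f"# session_id={fm.session_id}\n"
    )
    df = pd.DataFrame(fm.X, columns=fm.names)
    df.insert(0, "center_s", fm.window_centers)
    if fm.labels is not None:
        df["label"] = fm.labels
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_feature_csv(path) -> FeatureMatrix:
    import pandas as pd

    import io

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        body_start += 1
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    centers = df.pop("center_s").to_numpy(dtype=float)
    return FeatureMatrix(
        window_centers=centers,
        names=list(df.columns),
        X=df.to_numpy(dtype=float),
        labels=labels,
        patient_id=meta.get("patient_id", ""),
        session_id=meta.get("session_id", ""),
        symptom=meta.get("symptom", ""),
    ).validate()
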