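"""Feature operators vs. independent brute-force oracles, windowing
arithmetic and whole-recording extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from performotor import features as ft
from tests.conftest import make_recording

rng = np.random.default_rng(1234)


# --- independent oracles (naive loops / direct formulas) -------------------

def stats_oracle(w):
    n = len(w)
    mean = sum(w) / n
    var = sum((v - mean) ** 2 for v in w) / n
    rms = (sum(v * v for v in w) / n) ** 0.5
    return mean, var**0.5, rms, max(w) - min(w)


def entropy_oracle(w, n_bins):
    mn, mx = min(w), max(w)
    if mx == mn:
        return 0.0
    counts = [0] * n_bins
    for v in w:
        counts[min(int(n_bins * (v - mn) / (mx - mn)), n_bins - 1)] += 1
    H = 0.0
    for c in counts:
        if c:
            p = c / len(w)
            H -= p * np.log2(p)
    return H


def apen_oracle(x, m, r):
    n = len(x)
    tol = r * np.std(x)

    def phi(mm):
        N = n - mm + 1
        acc = 0.0
        for i in range(N):
            cnt = 0
            for j in range(N):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    cnt += 1
            acc += np.log(cnt / N)
        return acc / N

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    n = len(x)
    tol = r * np.std(x)
    N = n - m

    def count(mm):
        c = 0
        for i in range(N):
            for j in range(i + 1, N):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    c += 1
        return c

    B, A = count(m), count(m + 1)
    cap = np.log(n - m)
    if A == 0 or B == 0:
        return cap
    return min(cap, -np.log(A / B))


# --- windowing -------------------------------------------------------------

class TestSlidingWindows:
    @pytest.mark.parametrize(
        "duration,length,step,expected",
        [(900, 3.0, 1.5, 599), (900, 1.0, 0.5, 1799), (60, 5.0, 2.5, 23)],
    )
    def test_window_count(self, duration, length, step, expected):
        fs = 64.0
        wins = ft.sliding_windows(int(duration * fs), fs, ft.WindowSpec(length, step))
        assert len(wins) == expected

    def test_too_short_recording(self):
        with pytest.raises(ValueError, match="shorter"):
            ft.sliding_windows(4 * 64, 64.0, ft.WindowSpec(5.0, 2.5))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ft.WindowSpec(1.0, 2.0)


# --- band-pass filter --------------------------------------------------------

class TestBandpass:
    fs = 64.0
    t = np.arange(int(20 * fs)) / fs

    def trimmed_rms(self, y):
        n = len(y)
        c = y[n // 10 : -n // 10]
        return np.sqrt(np.mean(c**2))

    def test_dc_rejected(self):
        y = ft.bandpass(np.full(2000, 3.0), self.fs, 1, 3)
        assert np.max(np.abs(y[200:-200])) < 1e-6

    def test_passband_gain_near_unity(self):
        x = np.sin(2 * np.pi * 2.0 * self.t)
        y = ft.bandpass(x, self.fs, 1, 3)
        assert self.trimmed_rms(y) == pytest.approx(self.trimmed_rms(x), rel=0.05)

    def test_stopband_attenuated(self):
        x = np.sin(2 * np.pi * 10.0 * self.t)
        y = ft.bandpass(x, self.fs, 1, 3)
        assert self.trimmed_rms(y) < 0.05 * self.trimmed_rms(x)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            ft.bandpass(np.zeros(100), self.fs, 3, 1)


# --- scalar operators vs oracles --------------------------------------------

class TestOperatorOracles:
    def test_basic_stats_trivial(self):
        s = ft.basic_stats(np.full(10, 5.0))
        assert (s["mean"], s["sd"], s["rms"], s["range"]) == (5, 0, 5, 0)
        s = ft.basic_stats(np.array([-1.0, 1.0] * 50))
        assert (s["mean"], s["rms"], s["range"]) == (0, 1, 2)

    def test_basic_stats_random_oracle(self):
        for _ in range(20):
            w = rng.standard_normal(100)
            s = ft.basic_stats(w)
            mean, sd, rms_, rg = stats_oracle(list(w))
            for got, want in zip((s["mean"], s["sd"], s["rms"], s["range"]),
                                 (mean, sd, rms_, rg)):
                assert got == pytest.approx(want, abs=1e-12)

    def test_signal_entropy_conventions(self):
        assert ft.signal_entropy(np.full(50, 2.0)) == 0.0
        w = np.repeat(np.arange(8), 10) + 0.001  # hits each of 8 bins equally
        assert ft.signal_entropy(w, n_bins=8) == pytest.approx(3.0)

    def test_signal_entropy_random_oracle(self):
        for _ in range(20):
            w = rng.standard_normal(200)
            assert ft.signal_entropy(w, 10) == pytest.approx(
                entropy_oracle(list(w), 10), abs=1e-12
            )

    def test_spectral_pure_tone(self):
        fs = 64.0
        t = np.arange(256) / fs
        w = np.sin(2 * np.pi * 5.0 * t)
        out = ft.spectral_features(w, fs, bands=[(4, 6), (6, 12)])
        df = fs / len(w)
        assert abs(out["dominant_freq"] - 5.0) <= df
        total_above = out["band_energy_0"] + out["band_energy_1"]
        assert out["band_energy_0"] >= 0.95 * total_above

    def test_spectral_zero_window(self):
        out = ft.spectral_features(np.zeros(128), 64.0)
        assert out["spectral_entropy"] == 0.0
        assert out["dominant_freq"] == 0.0
        assert all(out[f"band_energy_{i}"] == 0.0 for i in range(2))

    def test_spectral_entropy_white_noise_near_max(self):
        fs, n = 64.0, 256
        ents = []
        for _ in range(20):
            out = ft.spectral_features(rng.standard_normal(n), fs)
            ents.append(out["spectral_entropy"])
        n_bins = n // 2 + 1
        assert np.mean(ents) >= 0.9 * np.log2(n_bins)

    def test_apen_trivial_and_ordering(self):
        assert ft.approx_entropy(np.full(50, 1.0)) == 0.0
        t = np.arange(300) / 64.0
        sine = np.sin(2 * np.pi * 5 * t)
        noise = rng.standard_normal(300)
        assert ft.approx_entropy(sine, 2, 0.2) < ft.approx_entropy(noise, 2, 0.2)

    def test_apen_random_oracle(self):
        for _ in range(5):
            x = rng.standard_normal(100)
            assert ft.approx_entropy(x, 2, 0.2) == pytest.approx(
                apen_oracle(x, 2, 0.2), abs=1e-10
            )

    def test_sampen_random_oracle_and_cap(self):
        assert ft.sample_entropy(np.full(40, 2.0)) == 0.0
        for _ in range(5):
            x = rng.standard_normal(100)
            assert ft.sample_entropy(x, 2, 0.2) == pytest.approx(
                sampen_oracle(x, 2, 0.2), abs=1e-10
            )
        ramp = np.arange(20, dtype=float)
        assert ft.sample_entropy(ramp, 2, 1e-6) == pytest.approx(np.log(18))

    def test_cross_correlation(self):
        a = rng.standard_normal(200)
        assert ft.cross_correlation(a, a) == pytest.approx(1.0)
        assert ft.cross_correlation(a, -a) == pytest.approx(-1.0)
        assert ft.cross_correlation(np.full(10, 1.0), a[:10]) == 0.0
        vals = [
            ft.cross_correlation(rng.standard_normal(500), rng.standard_normal(500))
            for _ in range(10)
        ]
        assert all(abs(v) < 0.15 for v in vals)


class TestPosture:
    def unit_windows(self, vecs):
        return {u: np.tile(np.asarray(v, float), (16, 1)) for u, v in vecs.items()}

    def test_inclinations(self):
        base = {u: (0, 0, 1) for u in ("LW", "RW", "LL", "RL", "WAIST")}
        f = ft.posture_features(self.unit_windows(base))
        assert f["LW_inclination_deg"] == pytest.approx(0.0)
        base["LW"] = (1, 0, 0)
        f = ft.posture_features(self.unit_windows(base))
        assert f["LW_inclination_deg"] == pytest.approx(90.0)

    def test_intersegment_angle(self):
        base = {u: (0, 0, 1) for u in ("LW", "RW", "LL", "RL", "WAIST")}
        base["LW"] = (0, 0, 1)
        base["RW"] = (0, 1, 0)
        f = ft.posture_features(self.unit_windows(base))
        assert f["LW_RW_angle_deg"] == pytest.approx(90.0)

    def test_low_gravity_flagged_invalid(self):
        base = {u: (0, 0, 1) for u in ("LW", "RW", "LL", "RL", "WAIST")}
        base["LL"] = (0, 0, 0.05)
        f = ft.posture_features(self.unit_windows(base))
        assert np.isnan(f["LL_inclination_deg"])


# --- scale behaviour (property tests) ---------------------------------------

@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(min_value=0.1, max_value=100.0),
    offset=st.floats(min_value=-5.0, max_value=5.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_scale_invariance_and_linearity(scale, offset, seed):
    r = np.random.default_rng(seed)
    w = r.standard_normal(120)
    v = scale * w + offset
    assert ft.signal_entropy(v) == pytest.approx(ft.signal_entropy(w), abs=1e-9)
    assert ft.approx_entropy(v, 2, 0.2) == pytest.approx(
        ft.approx_entropy(w, 2, 0.2), abs=1e-9
    )
    b = r.standard_normal(120)
    assert ft.cross_correlation(v, b) == pytest.approx(
        ft.cross_correlation(w, b), abs=1e-9
    )
    sw, sv = ft.basic_stats(w), ft.basic_stats(v)
    assert sv["range"] == pytest.approx(scale * sw["range"], rel=1e-9)
    assert sv["sd"] == pytest.approx(scale * sw["sd"], rel=1e-9)


# --- whole-recording extraction ---------------------------------------------

class TestExtract:
    def test_row_counts_and_columns(self):
        rec = make_recording(n_samples=int(60 * 64), fs=64.0, seed=5)
        assert ft.extract(rec, "TREMOR").X.shape[0] == 39  # (60-3)/1.5+1
        assert ft.extract(rec, "BRADY").X.shape[0] == 23  # (60-5)/2.5+1
        fog = ft.extract(rec, "FOG")
        assert fog.X.shape == (119, 18)  # entropy per axis: 4*3 accel + 3+3 waist
        assert len(set(fog.names)) == 18

    def test_segment_extraction_unit_agnostic_names(self):
        rec = make_recording(n_samples=int(30 * 64), seed=6)
        lw = ft.extract(rec, "TREMOR", segment="LW")
        rw = ft.extract(rec, "TREMOR", segment="RW")
        assert lw.names == rw.names
        assert all(n.startswith(("acc_", "seg_")) for n in lw.names)

    def test_finite_and_deterministic_on_simulated_data(self, tremor_recording):
        rec, _, _ = tremor_recording
        a = ft.extract(rec, "TREMOR")
        b = ft.extract(rec, "TREMOR")
        assert np.array_equal(a.X, b.X)
        assert np.all(np.isfinite(a.X))

    def test_feature_csv_round_trip(self, tmp_path, random_recording):
        fm = ft.extract(random_recording, "FOG")
        fm.labels = np.zeros(fm.X.shape[0], dtype=int)
        ft.write_feature_csv(fm, tmp_path / "f.csv")
        back = ft.read_feature_csv(tmp_path / "f.csv")
        assert back.names == fm.names
        assert np.allclose(back.X, fm.X, atol=1e-8)
        assert np.array_equal(back.labels, fm.labels)
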