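"""LOPO protocol mechanics, scoring, diary MAE and clinician summaries."""

import numpy as np
import pytest

from performotor import evaluation as ev
from performotor import synthetic_data as sd
from performotor.features import FeatureMatrix
from performotor.recognizers.assess import SegmentAssessment, SymptomAssessment
from performotor.signal_model import AnnotationTrack, DiaryTrack, RecordingSet
from tests.conftest import make_recording


def metadata_set(patient_sessions):
    """Tiny RecordingSet with given {patient: [session, ...]} structure."""
    recs = []
    ann = {}
    for pid, sids in patient_sessions.items():
        for sid in sids:
            recs.append(make_recording(n_samples=8, patient=pid, session=sid))
            ann[sid] = {
                "TREMOR": AnnotationTrack("TREMOR", [(0.0, 0.1, 1)]).validate()
            }
    return RecordingSet(recs, ann).validate()


class TestLopoFolds:
    def test_two_patients_complementary(self):
        rset = metadata_set({"A": ["A-1"], "B": ["B-1"]})
        folds = ev.lopo_folds(rset)
        assert folds == [(["B-1"], ["A-1"]), (["A-1"], ["B-1"])]

    def test_24_patients_39_recordings(self):
        sessions = {}
        n = 0
        for i in range(24):
            extra = 1 if i < 15 else 0  # 24 + 15 = 39 recordings
            sessions[f"P{i:02d}"] = [
                f"P{i:02d}-S{j}" for j in range(1 + extra)
            ]
            n += 1 + extra
        assert n == 39
        rset = metadata_set(sessions)
        folds = ev.lopo_folds(rset)
        assert len(folds) == 24
        tested = [sid for _, test in folds for sid in test]
        assert sorted(tested) == sorted(
            s for sids in sessions.values() for s in sids
        )
        for train, test in folds:
            pid = test[0].split("-")[0]
            assert all(not t.startswith(pid) for t in train)
            assert all(t.startswith(pid) for t in test)

    def test_single_patient_rejected(self):
        rset = metadata_set({"A": ["A-1", "A-2"]})
        with pytest.raises(ValueError, match="2 patients"):
            ev.lopo_folds(rset)


def labelled_matrix(n_majority, n_minority, seed=0):
    n = n_majority + n_minority
    labels = np.array([0] * n_majority + [1] * n_minority)
    return FeatureMatrix(
        window_centers=np.arange(n, dtype=float),
        names=["f0"],
        X=np.arange(n, dtype=float)[:, None],
        labels=labels,
    )


class TestSubsampling:
    def test_twenty_percent_of_majority(self):
        fm = ev.subsample_majority(labelled_matrix(1000, 50), 0.2, seed=1)
        assert (fm.labels == 0).sum() == 200
        assert (fm.labels == 1).sum() == 50

    def test_four_percent_of_majority(self):
        fm = ev.subsample_majority(labelled_matrix(1000, 0), 0.04, seed=1)
        assert (fm.labels == 0).sum() == 40

    def test_fraction_one_is_identity(self):
        src = labelled_matrix(100, 10)
        fm = ev.subsample_majority(src, 1.0, seed=1)
        assert np.array_equal(fm.X, src.X)

    def test_rows_are_a_subset_without_replacement(self):
        fm = ev.subsample_majority(labelled_matrix(100, 10), 0.3, seed=2)
        assert len(np.unique(fm.window_centers)) == len(fm.window_centers)


class TestScore:
    def test_perfect_diagonal(self):
        m = ev.score(np.diag([5, 7, 9]))
        assert m == {"accuracy": 1.0, "avg_recall": 1.0}

    def test_hand_computed(self):
        m = ev.score(np.array([[8, 2], [3, 7]]))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["avg_recall"] == pytest.approx((0.8 + 0.7) / 2)

    def test_zero_support_class_excluded(self):
        m = ev.score(np.array([[0, 0, 0], [0, 9, 1], [0, 2, 8]]))
        assert m["avg_recall"] == pytest.approx((0.9 + 0.8) / 2)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ev.score(np.zeros((2, 2)))


def assessment_from_labels(centers, labels, segment="BODY", symptom="TREMOR"):
    labels = np.asarray(labels, dtype=int)
    k = 4
    conf = np.full((len(labels), k), 1e-6)
    conf[np.arange(len(labels)), labels] = 1.0
    conf /= conf.sum(axis=1, keepdims=True)
    seg = SegmentAssessment(
        window_centers=np.asarray(centers, dtype=float),
        classes=np.arange(k),
        confidence=conf,
        labels=labels,
    )
    return SymptomAssessment(symptom, segments={segment: seg})


class TestDiaryMae:
    def test_identical_prediction_zero(self):
        centers = np.arange(0, 3600, 2.0)
        labels = np.where(centers < 1800, 2, 1)
        a = assessment_from_labels(centers, labels)
        diary = DiaryTrack("TREMOR", [(0.0, 2), (1800.0, 1)]).validate()
        assert ev.diary_mae(a, diary) == 0.0

    def test_off_by_one_everywhere(self):
        centers = np.arange(0, 3600, 2.0)
        a = assessment_from_labels(centers, np.full(len(centers), 2))
        diary = DiaryTrack("TREMOR", [(0.0, 1), (1800.0, 3)]).validate()
        assert ev.diary_mae(a, diary) == pytest.approx(1.0)

    def test_hand_computed_mixed_bins(self):
        centers = np.arange(0, 5400, 1.0)
        labels = np.zeros(len(centers), dtype=int)
        labels[(centers >= 1800) & (centers < 2700)] = 1  # half of bin 2 -> 0.5
        labels[centers >= 3600] = 1  # bin 3 fully 1, diary says 2 -> |1-2|=1
        a = assessment_from_labels(centers, labels)
        diary = DiaryTrack(
            "TREMOR", [(0.0, 0), (1800.0, 0), (3600.0, 2)]
        ).validate()
        assert ev.diary_mae(a, diary) == pytest.approx((0 + 0.5 + 1) / 3)

    def test_no_overlap_rejected(self):
        a = assessment_from_labels([10.0, 20.0], [0, 0])
        diary = DiaryTrack("TREMOR", [(36000.0, 1)]).validate()
        with pytest.raises(ValueError, match="overlap"):
            ev.diary_mae(a, diary)


class TestSummarize:
    def test_single_left_episode(self):
        centers = np.arange(1.0, 600.0, 2.0)
        labels = np.where((centers >= 100) & (centers < 220), 2, 0)
        left = assessment_from_labels(centers, labels, segment="LW")
        right = assessment_from_labels(centers, np.zeros_like(labels), segment="RW")
        a = SymptomAssessment("TREMOR", segments={**left.segments, **right.segments})
        s = ev.summarize([a])
        assert s.duration_per_severity_s[2] == pytest.approx(120.0, abs=4.0)
        assert s.episode_count == 1
        assert len(s.onsets_s) == 1
        assert s.asymmetry == ev.ASYMMETRY_SENTINEL  # right side all zero

    def test_symmetric_assessments_unit_asymmetry(self):
        centers = np.arange(1.0, 300.0, 2.0)
        labels = np.where(centers < 100, 1, 0)
        a = SymptomAssessment(
            "TREMOR",
            segments={
                "LW": assessment_from_labels(centers, labels, "LW").segments["LW"],
                "RW": assessment_from_labels(centers, labels, "RW").segments["RW"],
            },
        )
        s = ev.summarize([a])
        assert s.asymmetry == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.summarize([])

    def test_severity_durations_sum_to_assessed_time(self):
        centers = np.arange(1.0, 500.0, 2.0)
        labels = (centers // 100).astype(int) % 3
        a = assessment_from_labels(centers, labels, "LW")
        s = ev.summarize([a])
        assert sum(s.duration_per_severity_s.values()) == pytest.approx(
            s.assessed_time_s
        )


@pytest.fixture(scope="module")
def tremor_setup(small_tremor_cohort):
    feats = ev._labelled_features(small_tremor_cohort, "TREMOR")
    return small_tremor_cohort, feats


class TestRunLopo:
    def test_confusion_totals_all_test_windows(self, tremor_setup):
        rset, feats = tremor_setup
        rep = ev.run_lopo(rset, "TREMOR", seed=0, features=feats)
        n_windows = sum(fm.X.shape[0] for fm in feats.values())
        assert rep.confusion.sum() == n_windows

    def test_same_seed_identical_report(self, tremor_setup):
        rset, feats = tremor_setup
        r1 = ev.run_lopo(rset, "TREMOR", seed=3, features=feats)
        r2 = ev.run_lopo(rset, "TREMOR", seed=3, features=feats)
        assert np.array_equal(r1.confusion, r2.confusion)
        assert [f.accuracy for f in r1.folds] == [f.accuracy for f in r2.folds]

    def test_test_fold_features_untouched(self, tremor_setup):
        rset, feats = tremor_setup
        before = {sid: fm.X.copy() for sid, fm in feats.items()}
        ev.run_lopo(rset, "TREMOR", seed=0, features=feats)
        for sid, fm in feats.items():
            assert np.array_equal(fm.X, before[sid])
            assert fm.X.shape[0] == len(before[sid])
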