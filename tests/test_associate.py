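import numpy as np
import pandas as pd
import pytest

from hrvstim import associate as assoc
from hrvstim import synth
from hrvstim.core import RrSeries
from hrvstim.schedule import Epoch, StimulusSchedule


def make_segment(n=60, rr_ms=1000.0, subject="S000", subclass="c", seed=None):
    if seed is None:
        iv = np.full(n, rr_ms)
    else:
        iv = np.random.default_rng(seed).normal(rr_ms, 30, n)
    return assoc.Segment(subject, "g", subclass, RrSeries(iv), segment_id=f"{subject}/x")


@pytest.fixture
def long_rr():
    return RrSeries(np.full(120, 1000.0))


class TestSegmentEpochs:
    def test_one_segment_per_epoch(self, long_rr):
        sched = StimulusSchedule(
            [Epoch(10 * k, 10, "g", "c") for k in range(3)]
        )
        segs = assoc.segment_epochs(long_rr, sched, 10)
        assert len(segs) == 3
        # the first epoch's opening beat anchors at t=1; later epochs span 10
        assert [len(s.rr) for s in segs] == [9, 10, 10]

    def test_short_epoch_dropped_with_warning(self, long_rr):
        sched = StimulusSchedule([Epoch(0, 5, "g", "c")])
        with pytest.warns(UserWarning, match="dropped"):
            segs = assoc.segment_epochs(long_rr, sched, 10)
        assert segs == []

    def test_epoch_past_record_end(self, long_rr):
        sched = StimulusSchedule([Epoch(115, 20, "g", "c")])
        with pytest.raises(ValueError, match="past"):
            assoc.segment_epochs(long_rr, sched, 10)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusSchedule([Epoch(0, 10, "g", "c"), Epoch(5, 10, "g", "d")])

    def test_half_open_boundary(self, long_rr):
        """An interval anchored exactly at an epoch's end belongs to the next."""
        sched = StimulusSchedule(
            [Epoch(0, 10, "g", "a"), Epoch(10, 10, "g", "b")]
        )
        a, b = assoc.segment_epochs(long_rr, sched, 5)
        assert a.rr.anchor_times_s.max() < 10
        assert 10.0 in b.rr.anchor_times_s


class TestAugment:
    def test_window_count(self):
        segs = assoc.augment(
            [make_segment(60)], "windowing", window_s=10, overlap=0.5
        )
        assert len(segs) == 11

    def test_noise_addition_count_and_labels(self):
        base = [make_segment(subclass=c) for c in ("x", "y", "z")]
        out = assoc.augment(base, "noise_addition", k=4, seed=0)
        assert len(out) == 12
        assert sorted({s.subclass for s in out}) == ["x", "y", "z"]
        assert all(s.parent_id for s in out)

    def test_window_equal_to_segment_is_identity(self):
        out = assoc.augment([make_segment(60)], "windowing", window_s=60, overlap=0.5)
        assert len(out) == 1
        assert len(out[0].rr) == 60

    def test_oversize_window_passes_through(self):
        with pytest.warns(UserWarning, match="exceeds"):
            out = assoc.augment([make_segment(20)], "windowing", window_s=60)
        assert len(out) == 1 and out[0].parent_id is None

    def test_label_multiset_conserved(self):
        base = [make_segment(subclass=c) for c in ("x", "x", "y")]
        out = assoc.augment(base, "noise_addition", k=3, seed=1)
        assert {s.subclass for s in out} == {s.subclass for s in base}


class TestBuildFeatureDataset:
    def test_shape_and_alignment(self):
        segs = [make_segment(seed=i, subclass="ab"[i % 2]) for i in range(6)]
        ds = assoc.build_feature_dataset(segs)
        assert len(ds) == 6
        assert len(ds.labels) == len(ds.subjects) == 6
        assert not ds.X.isna().any().any()

    def test_flagged_columns_dropped_not_silently(self):
        segs = [make_segment(seed=i) for i in range(4)] + [make_segment()]  # constant
        ds = assoc.build_feature_dataset(segs)
        assert "sd1_sd2_ratio" in ds.dropped_columns
        assert "sd1_sd2_ratio" not in ds.X.columns

    def test_impute_policy_keeps_columns(self):
        segs = [make_segment(seed=i) for i in range(4)] + [make_segment()]
        ds = assoc.build_feature_dataset(segs, missing_policy="impute")
        assert ds.dropped_columns == ()
        assert not ds.X.isna().any().any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no segments"):
            assoc.build_feature_dataset([])


class TestScalogram:
    def test_shape(self):
        seg = make_segment(200, seed=0)
        sg = assoc.scalogram(seg, scales=np.arange(2, 34))
        assert sg.magnitude.shape == (32, 200)

    def test_ridge_maps_to_input_frequency(self):
        t = np.arange(300) * 1.0
        iv = 1000 + 50 * np.sin(2 * np.pi * 0.1 * t)
        seg = assoc.Segment("s", "g", "c", RrSeries(iv, t))
        sg = assoc.scalogram(seg)
        ridge = sg.frequencies_hz[np.argmax(sg.magnitude.mean(axis=1))]
        assert ridge == pytest.approx(0.1, rel=0.1)

    def test_zero_input_zero_magnitude(self):
        seg = make_segment(100)  # constant RR -> centred signal is zero
        sg = assoc.scalogram(seg, scales=np.arange(2, 20))
        assert np.allclose(sg.magnitude, 0.0)

    def test_too_short_segment(self):
        with pytest.raises(ValueError, match="short"):
            assoc.scalogram(make_segment(10), scales=[4, 50])


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            y = np.array(["a", "b"] * 40)
            X = rng.normal(size=(80, 6))
            X[:, 3] = (y == "a") + rng.normal(0, 0.1, 80)
            ds = assoc.Dataset(
                pd.DataFrame(X, columns=[f"f{i}" for i in range(6)]),
                tuple(y), tuple("s" for _ in y),
            )
            hits += assoc.rank_features(ds, 1)[0] == "f3"
        assert hits >= 0.95 * n_rep

    def test_tie_break_by_column_index(self):
        X = pd.DataFrame({"a": [1.0] * 10, "b": [1.0] * 10, "c": [1.0] * 10})
        ds = assoc.Dataset(X, tuple("xy" * 5), tuple("s" for _ in range(10)))
        assert assoc.rank_features(ds, 3) == ["a", "b", "c"]

    def test_top_k_too_large(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        ds = assoc.Dataset(X, ("x", "y"), ("s", "s"))
        with pytest.raises(ValueError, match="top_k"):
            assoc.rank_features(ds, 2)


def _toy_dataset(n=100, n_subjects=5, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    labels = tuple(rng.choice(["x", "y"], n))
    subjects = tuple(f"S{i % n_subjects}" for i in range(n))
    return assoc.Dataset(X, labels, subjects)


class TestSplitDataset:
    def test_fraction_respected(self):
        ds = _toy_dataset()
        plan = assoc.split_dataset(ds, 0.8, seed=1)
        assert len(plan.train_idx) == 80 and len(plan.test_idx) == 20
        assert sorted(plan.train_idx + plan.test_idx) == list(range(100))

    def test_group_aware_subject_disjoint(self):
        ds = _toy_dataset()
        plan = assoc.split_dataset(ds, 0.8, group_aware=True, seed=2)
        train_subj = {ds.subjects[i] for i in plan.train_idx}
        test_subj = {ds.subjects[i] for i in plan.test_idx}
        assert train_subj.isdisjoint(test_subj)
        assert test_subj  # never empty

    def test_k_folds_partition(self):
        ds = _toy_dataset()
        plan = assoc.split_dataset(ds, 0.8, k_folds=5, seed=3)
        assert len(plan.folds) == 5
        all_idx = sorted(i for f in plan.folds for i in f)
        assert all_idx == list(range(100))
        assert {len(f) for f in plan.folds} == {20}

    def test_determinism(self):
        ds = _toy_dataset()
        a = assoc.split_dataset(ds, 0.7, seed=7)
        b = assoc.split_dataset(ds, 0.7, seed=7)
        assert a == b

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.5])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError, match="train_fraction"):
            assoc.split_dataset(_toy_dataset(), frac)


class TestFitPredict:
    def _separable(self, n, seed, scale=5.0):
        rng = np.random.default_rng(seed)
        y = np.array(["a", "b"] * (n // 2))
        X = rng.normal(size=(n, 4))
        X[y == "a", 0] += scale
        return assoc.Dataset(
            pd.DataFrame(X, columns=list("wxyz")), tuple(y),
            tuple(f"S{i % 4}" for i in range(n)),
        )

    def test_separable_classes_high_mcc(self):
        from hrvstim import evaluate as ev

        mccs = []
        for r in range(20):
            ds = self._separable(80, seed=r)
            plan = assoc.split_dataset(ds, 0.8, seed=r)
            pred = assoc.fit_predict(ds.take(plan.train_idx), ds.take(plan.test_idx))
            cm = ev.confusion_matrix(
                list(ds.take(plan.test_idx).labels), pred, ["a", "b"]
            )
            mccs.append(ev.mcc(cm))
        assert np.mean(mccs) >= 0.9

    def test_shuffled_labels_near_zero_mcc(self):
        from hrvstim import evaluate as ev

        mccs = []
        for r in range(20):
            rng = np.random.default_rng(1000 + r)
            ds = self._separable(80, seed=r)
            shuffled = list(ds.labels)
            rng.shuffle(shuffled)
            train = assoc.Dataset(ds.X, tuple(shuffled), ds.subjects)
            test = self._separable(40, seed=500 + r)
            pred = assoc.fit_predict(train, test)
            cm = ev.confusion_matrix(list(test.labels), pred, ["a", "b"])
            mccs.append(ev.mcc(cm))
        assert abs(np.mean(mccs)) <= 0.15

    def test_empty_test_gives_empty_predictions(self):
        ds = self._separable(40, seed=0)
        empty = assoc.Dataset(ds.X.iloc[:0], (), ())
        assert assoc.fit_predict(ds, empty) == []

    def test_single_class_training_warns_constant(self):
        ds = self._separable(40, seed=0)
        const = assoc.Dataset(ds.X, tuple("a" for _ in ds.labels), ds.subjects)
        with pytest.warns(UserWarning, match="single-class"):
            pred = assoc.fit_predict(const, ds, assoc.NearestCentroidBackend())
        assert set(pred) == {"a"}

    def test_end_to_end_seed_determinism(self, hierarchy_2x2):
        import warnings

        outs = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                study = synth.generate_study(
                    hierarchy_2x2, 3, 2, 10, 1.0, include_ecg=False, seed=21
                )
                segs = []
                for rec in study.records:
                    segs += assoc.segment_epochs(
                        rec.rr_truth, rec.schedule, 10, subject_id=rec.subject_id
                    )
                segs = assoc.augment(segs, "noise_addition", k=2, seed=5)
                ds = assoc.build_feature_dataset(segs)
                plan = assoc.split_dataset(ds, 0.8, group_aware=True, seed=5)
                ranking = assoc.rank_features(ds, 5)
                pred = assoc.fit_predict(
                    ds.take(plan.train_idx), ds.take(plan.test_idx)
                )
            outs.append((plan, ranking, tuple(pred)))
        assert outs[0] == outs[1]
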