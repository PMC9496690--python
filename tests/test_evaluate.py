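import numpy as np
import pytest

from sersdx.augment import AugmentConfig
from sersdx.classifier import PredictionSet
from sersdx.evaluate import (
    EXPECTED_CLASS,
    classify,
    leave_one_group_out,
    leave_one_out,
    load_reference_scores,
    results_from_scores,
    summarize,
    vote_score,
)


def _preds(labels, group="G", classes=("dementia", "normal")):
    """Hard one-hot prediction set from a list of argmax labels."""
    idx = {c: i for i, c in enumerate(classes)}
    p = np.zeros((len(labels), len(classes)))
    for r, l in enumerate(labels):
        p[r, idx[l]] = 1.0
    return PredictionSet(p, classes, (group,) * len(labels))


class StubBackend:
    """Predicts the class encoded in each spectrum's first feature."""

    def __init__(self, classes=("dementia", "normal"), invert=False):
        self.classes = tuple(classes)
        self.invert = invert

    def fit(self, X, labels, groups, forbidden_groups=frozenset()):
        self.fit_groups = set(groups)
        leaked = self.fit_groups & set(forbidden_groups)
        if leaked:
            raise AssertionError(f"leak: {leaked}")
        return self

    def predict(self, X, group_ids=None):
        idx = np.clip(np.round(np.asarray(X)[:, 0]), 0, len(self.classes) - 1).astype(int)
        if self.invert:
            idx = len(self.classes) - 1 - idx
        p = np.zeros((len(idx), len(self.classes)))
        p[np.arange(len(idx)), idx] = 1.0
        gids = tuple(group_ids) if group_ids is not None else ("",) * len(idx)
        return PredictionSet(p, self.classes, gids)


class TestVoteScore:
    def test_unanimous_vote(self):
        pred, score = vote_score(_preds(["normal"] * 10), "normal")
        assert pred == "normal" and score == 100.0

    def test_five_of_sixteen(self):
        labels = ["dementia"] * 11 + ["normal"] * 5
        pred, score = vote_score(_preds(labels), "normal")
        assert pred == "dementia"
        assert score == pytest.approx(31.25)

    def test_twentynine_of_thirtytwo(self):
        labels = ["dementia"] * 29 + ["normal"] * 3
        _, score = vote_score(_preds(labels), "dementia")
        assert score == pytest.approx(90.625)

    def test_tie_broken_toward_non_expected(self):
        labels = ["dementia"] * 5 + ["normal"] * 5
        pred, score = vote_score(_preds(labels), "normal")
        assert pred == "dementia" and score == 50.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        labels = ["dementia"] * 7 + ["normal"] * 9
        base = vote_score(_preds(labels), "normal")
        for _ in range(5):
            rng.shuffle(labels)
            assert vote_score(_preds(labels), "normal") == base

    def test_mixed_groups_rejected(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        bad = PredictionSet(p, ("a", "b"), ("g1", "g2"))
        with pytest.raises(ValueError):
            vote_score(bad, "a")


class TestClassify:
    @pytest.mark.parametrize(
        "score,call",
        [(49.0, "incorrect"), (53.0, "correct"), (50.0, "indeterminate"),
         (31.25, "incorrect"), (100.0, "correct"), (0.0, "incorrect")],
    )
    def test_threshold_rule(self, score, call):
        assert classify(score) == call

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(101.0)


class TestLeaveOneGroupOut:
    def _encoded_cohort(self, n_groups=6, n_spectra=5):
        """Groups whose spectra encode their class in feature 0."""
        from sersdx.spectra_io import MappingGroup, Spectrum

        grid = 550.0 + np.arange(16.0)
        groups, labels = [], {}
        for i in range(n_groups):
            label = ("dementia", "normal")[i % 2]
            code = 0.0 if label == "dementia" else 1.0
            spectra = [
                Spectrum(grid, np.full(16, 0.5) + code * np.eye(16)[0], {"sample_id": f"g{i}"})
                for _ in range(n_spectra)
            ]
            groups.append(MappingGroup(f"g{i}", spectra))
            labels[f"g{i}"] = label
        return groups, labels

    def test_one_result_per_group_each_held_out_once(self):
        groups, labels = self._encoded_cohort()
        results = leave_one_group_out(
            groups, labels, backend_factory=StubBackend, preprocess=False,
            augment_config=AugmentConfig(augment_factor=1),
        )
        assert [r.sample_id for r in results] == [g.sample_id for g in groups]
        assert all(r.n_test_spectra == len(g) for r, g in zip(results, groups))

    def test_oracle_backend_scores_100(self):
        groups, labels = self._encoded_cohort()
        results = leave_one_group_out(
            groups, labels, backend_factory=StubBackend, preprocess=False,
            augment_config=AugmentConfig(augment_factor=1),
        )
        assert all(r.score == 100.0 and r.call == "correct" for r in results)

    def test_anti_oracle_scores_0(self):
        groups, labels = self._encoded_cohort()
        results = leave_one_group_out(
            groups, labels, preprocess=False,
            backend_factory=lambda: StubBackend(invert=True),
            augment_config=AugmentConfig(augment_factor=1),
        )
        assert all(r.score == 0.0 and r.call == "incorrect" for r in results)

    def test_test_group_never_in_training(self):
        groups, labels = self._encoded_cohort()
        seen = []

        class AuditBackend(StubBackend):
            def fit(self, X, labels_, groups_, forbidden_groups=frozenset()):
                super().fit(X, labels_, groups_, forbidden_groups)
                seen.append((set(groups_), set(forbidden_groups)))
                return self

        leave_one_group_out(
            groups, labels, backend_factory=AuditBackend, preprocess=False,
            augment_config=AugmentConfig(augment_factor=2),
        )
        assert seen
        for train_groups, forbidden in seen:
            assert not train_groups & forbidden

    def test_single_class_pool_rejected(self):
        groups, labels = self._encoded_cohort(n_groups=4)
        labels = {k: "dementia" for k in labels}
        with pytest.raises(ValueError):
            leave_one_group_out(groups, labels, backend_factory=StubBackend, preprocess=False)

    def test_fad_groups_share_full_training_pool(self):
        groups, labels = self._encoded_cohort(n_groups=6)
        # relabel two groups as FAD: carriers encode like dementia spectra,
        # non-carriers like normal, and neither may appear in any training set
        labels["g0"] = "fad_pos"   # g0 spectra encode dementia
        labels["g1"] = "fad_neg"   # g1 spectra encode normal
        fit_groups = []

        class AuditBackend(StubBackend):
            def fit(self, X, labels_, groups_, forbidden_groups=frozenset()):
                super().fit(X, labels_, groups_, forbidden_groups)
                fit_groups.append(set(groups_))
                return self

        results = leave_one_group_out(
            groups, labels, backend_factory=AuditBackend, preprocess=False,
            augment_config=AugmentConfig(augment_factor=1),
        )
        for gs in fit_groups:
            assert "g0" not in gs and "g1" not in gs
        by_id = {r.sample_id: r for r in results}
        assert by_id["g0"].expected_label == "dementia" and by_id["g0"].score == 100.0
        assert by_id["g1"].expected_label == "normal" and by_id["g1"].score == 100.0


class TestLeaveOneOut:
    def _data(self, n=12):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(n, 4))
        X[:, 0] = np.repeat([0.0, 1.0], n // 2)
        y = np.array(["dementia"] * (n // 2) + ["normal"] * (n // 2))
        return X, y

    def test_oracle_stub_100(self):
        X, y = self._data()
        assert leave_one_out(X, y, StubBackend) == 100.0

    def test_anti_oracle_stub_0(self):
        X, y = self._data()
        assert leave_one_out(X, y, lambda: StubBackend(invert=True)) == 0.0

    def test_nearest_template_on_separated_classes(self):
        from sklearn.neighbors import NearestCentroid

        class CentroidBackend:
            def fit(self, X, labels, groups, forbidden_groups=frozenset()):
                self.clf = NearestCentroid().fit(X, labels)
                self.classes = tuple(self.clf.classes_)
                return self

            def predict(self, X, group_ids=None):
                pred = self.clf.predict(X)
                p = np.zeros((len(pred), len(self.classes)))
                for i, l in enumerate(pred):
                    p[i, self.classes.index(l)] = 1.0
                gids = tuple(group_ids) if group_ids is not None else ("",) * len(pred)
                return PredictionSet(p, self.classes, gids)

        rng = np.random.default_rng(1)
        a = np.array([1.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.0, 1.0])
        X = np.array([a] * 6 + [b] * 6) + 0.01 * rng.normal(size=(12, 4))
        y = np.array(["dementia"] * 6 + ["normal"] * 6)
        assert leave_one_out(X, y, CentroidBackend) == 100.0

    def test_kfold_approximation(self):
        X, y = self._data()
        assert leave_one_out(X, y, StubBackend, folds=3) == 100.0

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out(np.ones((1, 4)), ["a"], StubBackend)


class TestSummaries:
    def test_reference_cohort_summaries(self):
        df = load_reference_scores()
        non_fad = summarize(results_from_scores(df[df.cohort == "non_fad"]))
        by = {s.group_label: s for s in non_fad}
        assert by["normal"].n_correct == 8 and by["normal"].accuracy == 100.0
        assert round(by["normal"].mean_score, 1) == 89.2
        assert by["dementia"].n_correct == 8
        assert round(by["dementia"].accuracy, 1) == 88.9
        assert round(by["dementia"].mean_score, 1) == 72.0
        assert round(by["overall"].accuracy) == 94

    def test_fad_cohort_summaries(self):
        df = load_reference_scores()
        fad = summarize(results_from_scores(df[df.cohort == "fad"]))
        by = {s.group_label: s for s in fad}
        assert by["fad_neg"].accuracy == 100.0 and by["fad_neg"].mean_score == 91.25
        assert by["fad_pos"].accuracy == 80.0 and by["fad_pos"].mean_score == 80.0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
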