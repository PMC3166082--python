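"""Forest learner, bootstrap validation, beam search and Y-scrambling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fiasma._forest import _HAVE_CYTHON, RandomForest
from fiasma.errors import PipelineError, ValidationError
from fiasma.learner import (
    ForestSpec,
    beam_search,
    bootstrap_validate,
    candidate_pool,
    fit_forest,
    train_model,
    variance_filter,
    weight_features,
    y_scramble,
    youden,
    zero_rule,
)


def separable_matrix(n=120, seed=0):
    """Two informative axes with a clear margin around the class boundary."""
    rng = np.random.default_rng(seed)
    x1, x2 = [], []
    while len(x1) < n:
        a, b = rng.normal(size=2)
        if abs(a + b) > 0.6:  # margin makes the classes cleanly separable
            x1.append(a)
            x2.append(b)
    x1, x2 = np.array(x1), np.array(x2)
    y = (x1 + x2 > 0).astype(int)
    m = pd.DataFrame({"a": x1, "b": x2, "junk": rng.normal(size=n)})
    return m, pd.Series(y)


class TestYouden:
    @pytest.mark.parametrize(
        "tp, fp, tn, fn, expected",
        [
            (10, 0, 20, 0, 1.0),
            (5, 10, 10, 5, 0.0),
            (72, 0, 204, 0, 1.0),  # a perfectly separated 72/204 panel
            (0, 0, 20, 10, -0.0),
        ],
    )
    def test_values(self, tp, fp, tn, fn, expected):
        assert youden(tp, fp, tn, fn) == pytest.approx(expected)

    def test_equals_sens_plus_spec_minus_one_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            j = youden(tp, fp, tn, fn)
            sens, spec = tp / (tp + fn), tn / (tn + fp)
            assert j == pytest.approx(sens + spec - 1.0)
            # swapping class labels together with predictions negates nothing:
            # J is invariant (tn<->tp, fn<->fp)
            assert youden(tn, fn, tp, fp) == pytest.approx(j)

    def test_empty_truth_class_is_error(self):
        with pytest.raises(ValidationError):
            youden(0, 5, 10, 0)


class TestZeroRule:
    def test_study_class_balance(self):
        labels = [0] * 204 + [1] * 72
        assert zero_rule(labels) == pytest.approx(0.7391, abs=5e-5)

    @pytest.mark.parametrize(
        "labels, expected", [([1, 1, 1], 1.0), ([0, 1, 0, 1], 0.5)]
    )
    def test_degenerate(self, labels, expected):
        assert zero_rule(labels) == expected


class TestVarianceFilter:
    def test_constant_column_removed_binary_retained(self):
        m = pd.DataFrame(
            {
                "const": np.ones(100),
                "binary": np.array([0, 1] * 50),
                "cont": np.linspace(0, 1, 100),
            }
        )
        kept = variance_filter(m)
        assert "const" not in kept and {"binary", "cont"} <= set(kept)

    def test_all_removed_is_error(self):
        with pytest.raises(PipelineError):
            variance_filter(pd.DataFrame({"c": np.ones(10)}))


class TestWeighting:
    def test_label_copy_is_maximal_under_all_methods(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        m = pd.DataFrame({"copy": y.astype(float), "noise": rng.normal(size=200)})
        for method in ("correlation", "information_gain", "relief"):
            w = weight_features(m, y, method)
            assert w["copy"] > w["noise"], method

    def test_duplicated_column_gets_equal_weight(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 150)
        sig = y + rng.normal(0, 0.5, 150)
        m = pd.DataFrame({"s1": sig, "s2": sig.copy()})
        for method in ("correlation", "information_gain"):
            w = weight_features(m, y, method)
            assert w["s1"] == pytest.approx(w["s2"])

    def test_noise_weight_near_permutation_null(self):
        # correlation weight of pure noise should sit inside the null band
        # obtained by permuting the labels
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        noise = rng.normal(size=n)
        m = pd.DataFrame({"noise": noise})
        observed = weight_features(m, y, "correlation")["noise"]
        null = [
            weight_features(m, rng.permutation(y), "correlation")["noise"]
            for _ in range(200)
        ]
        assert observed <= np.quantile(null, 0.999)

    def test_single_class_rejected(self):
        m = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValidationError):
            weight_features(m, np.zeros(10, dtype=int), "correlation")


class TestForest:
    def test_separable_training_accuracy(self):
        m, y = separable_matrix()
        forest = fit_forest(m[["a", "b"]], y, ForestSpec(seed=5))
        assert (forest.predict(m[["a", "b"]].to_numpy()) == y.to_numpy()).mean() == 1.0

    def test_determinism_same_seed_same_predictions(self):
        m, y = separable_matrix()
        x = m.to_numpy()
        p1 = fit_forest(m, y, ForestSpec(seed=9)).predict_proba(x)
        p2 = fit_forest(m, y, ForestSpec(seed=9)).predict_proba(x)
        assert (p1 == p2).all()
        p3 = fit_forest(m, y, ForestSpec(seed=10)).predict_proba(x)
        assert not (p1 == p3).all()  # different seed, different vote fractions

    def test_single_class_rejected(self):
        m, _ = separable_matrix()
        with pytest.raises(ValueError):
            fit_forest(m, np.zeros(len(m), dtype=int), ForestSpec())

    @pytest.mark.skipif(not _HAVE_CYTHON, reason="compiled tree backend unavailable")
    def test_backends_agree(self):
        m, y = separable_matrix(n=150, seed=4)
        x = m.to_numpy()
        kwargs = dict(ntree=25, nodesize=1, mtry=2, maxdepth=8, seed=77)
        fast = RandomForest(backend="cython", **kwargs).fit(x, y.to_numpy())
        slow = RandomForest(backend="sklearn", **kwargs).fit(x, y.to_numpy())
        agreement = (fast.predict(x) == slow.predict(x)).mean()
        assert agreement > 0.95

    def test_random_labels_oob_youden_near_zero(self):
        rng = np.random.default_rng(0)
        js = []
        for seed in range(10):
            x = rng.normal(size=(200, 4))
            y = rng.integers(0, 2, 200)
            rep = bootstrap_validate(x, y, ForestSpec(), n_resamples=20, seed=seed)
            js.append(rep.youden_mean)
        assert abs(np.mean(js)) < 0.15


class TestBootstrapValidate:
    def test_separable_set_scores_near_one(self):
        m, y = separable_matrix(n=200)
        rep = bootstrap_validate(m[["a", "b"]], y, n_resamples=60, seed=0)
        assert rep.youden_mean > 0.9
        assert 0.0 <= rep.accuracy_mean <= 1.0
        assert rep.youden_sd >= 0.0

    def test_bitwise_reproducible_under_fixed_seed(self):
        m, y = separable_matrix(n=150, seed=8)
        r1 = bootstrap_validate(m, y, n_resamples=30, seed=123)
        r2 = bootstrap_validate(m, y, n_resamples=30, seed=123)
        assert (r1.youden_values == r2.youden_values).all()
        assert (r1.accuracy_values == r2.accuracy_values).all()

    def test_permuted_labels_score_near_zero(self):
        m, y = separable_matrix(n=276, seed=6)
        perm = pd.Series(np.random.default_rng(0).permutation(y.to_numpy()))
        rep = bootstrap_validate(m, perm, n_resamples=60, seed=1)
        assert abs(rep.youden_mean) < 0.12


class TestBeamSearch:
    def test_joint_signal_pair_is_recovered(self):
        rng = np.random.default_rng(11)
        n = 250
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = pd.Series(((a + b) > 0).astype(int))
        m = pd.DataFrame(
            {"a": a, "b": b,
             **{f"n{i}": rng.normal(size=n) for i in range(4)}}
        )
        res = beam_search(m, y, beam_width=4, max_size=2, seed=0, score_resamples=30)
        assert set(res[2].combination) == {"a", "b"}

    def test_width_at_least_pool_matches_exhaustive_at_size_one(self):
        m, y = separable_matrix(n=150, seed=2)
        wide = beam_search(m, y, beam_width=len(m.columns), max_size=1, seed=3,
                           score_resamples=25)
        narrow = beam_search(m, y, beam_width=1, max_size=1, seed=3,
                             score_resamples=25)
        assert wide[1].combination == narrow[1].combination

    def test_empty_pool_rejected(self):
        m, y = separable_matrix()
        with pytest.raises(PipelineError):
            beam_search(m, y, candidates=[], seed=0)


class TestYScramble:
    def test_informative_set_far_above_null(self):
        m, y = separable_matrix(n=200, seed=5)
        res = y_scramble(m, y, ["a", "b"], n_permutations=12, seed=4, n_resamples=20)
        assert res.reference.youden_mean > res.null_youden_mean + 5 * res.null_youden_sd
        assert abs(res.null_youden_mean) < 0.1

    def test_null_accuracy_below_zero_rule_on_imbalanced_labels(self):
        rng = np.random.default_rng(9)
        n = 240
        x1 = rng.normal(size=n)
        y = pd.Series((x1 + rng.normal(0, 0.5, n) > 0.7).astype(int))  # ~1:3
        m = pd.DataFrame({"a": x1, "b": rng.normal(size=n)})
        res = y_scramble(m, y, ["a", "b"], n_permutations=12, seed=2, n_resamples=20)
        assert res.null_accuracy_mean < zero_rule(y)


class TestModelArtifact:
    def test_save_load_predict_round_trip(self, tmp_path, labeled):
        matrix, labels = labeled
        model = train_model(matrix, labels)
        path = tmp_path / "model.pkl"
        model.save(path)
        from fiasma.learner import ModelArtifact

        back = ModelArtifact.load(path)
        assert (back.predict(matrix) == model.predict(matrix)).all()

    def test_missing_descriptor_column_rejected(self, trained_model):
        with pytest.raises(ValidationError):
            trained_model.predict(pd.DataFrame({"mw": [100.0]}))


class TestDot632Estimator:
    def test_blended_estimate_exceeds_oob_on_separable_data(self):
        m, y = separable_matrix(n=150, seed=3)
        oob = bootstrap_validate(m[["a", "b"]], y, n_resamples=30, seed=6)
        blended = bootstrap_validate(
            m[["a", "b"]], y, n_resamples=30, seed=6, estimator=".632"
        )
        # resubstitution is optimistic, so the blend sits at or above OOB
        assert blended.youden_mean >= oob.youden_mean
        assert blended.accuracy_mean <= 1.0

    def test_unknown_estimator_rejected(self):
        m, y = separable_matrix()
        with pytest.raises(ValidationError):
            bootstrap_validate(m, y, n_resamples=5, seed=0, estimator="jackknife")
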