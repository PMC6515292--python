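"""Laplacian-corrected NB weights, closed-form LOO, ROC, and enrichment."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from tox21sig.bayes import (
    NBModel,
    enrichment,
    loo_cv_scores,
    randomized_control,
    roc_auc,
    train_nb,
)
from tox21sig.datamodel import ValidationError


def _random_problem(rng, n, n_features=40, p_active=0.4):
    features = [
        frozenset(rng.choice(n_features, size=rng.integers(2, 10), replace=False).tolist())
        for _ in range(n)
    ]
    labels = (rng.random(n) < p_active).astype(int)
    # ensure two per class so no degenerate folds
    labels[:2] = 1
    labels[2:4] = 0
    return features, labels


class TestTrainNB:
    def test_weight_examples(self):
        # 4 compounds, 2 active; feature f present in the 2 actives only
        features = [frozenset({"f"}), frozenset({"f"}), frozenset({"g"}), frozenset({"g"})]
        labels = np.array([1, 1, 0, 0])
        model = train_nb(features, labels)
        assert model.p_base == 0.5
        assert model.weight("f") == pytest.approx(math.log(3 / 2))
        assert model.weight("g") == pytest.approx(math.log(1 / 2))  # inactives only, < 0
        assert model.weight("unseen") == 0.0

    def test_unseen_feature_never_changes_scores(self):
        features = [frozenset({"a"}), frozenset({"a", "b"}), frozenset({"b"})]
        labels = np.array([1, 0, 0])
        model = train_nb(features, labels)
        assert model.score({"a", "b"}) == pytest.approx(model.score({"a", "b", "zzz"}))

    def test_single_class_is_error_naming_category(self):
        with pytest.raises(ValidationError, match="my_cat"):
            train_nb([frozenset({"a"}), frozenset({"b"})], np.array([1, 1]), category="my_cat")

    def test_weight_tends_to_log_enrichment_ratio(self):
        """With fixed enrichment ratio r = P(active|f)/p_base, the weight
        approaches ln(r) as counts grow."""
        r = 2.0
        p = 0.25
        prev_gap = None
        for scale in (10, 100, 10_000):
            t = scale
            a = int(r * p * t)
            w = math.log((a + 1) / (t * p + 1))
            gap = abs(w - math.log(r))
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 1e-3


class TestLeaveOneOut:
    def test_matches_naive_retraining(self):
        """Count-decrement LOO is identical to retraining without each
        compound."""
        rng = np.random.default_rng(42)
        features, labels = _random_problem(rng, 30)
        fast = loo_cv_scores(features, labels)
        for i in range(len(labels)):
            rest_f = features[:i] + features[i + 1:]
            rest_y = np.delete(labels, i)
            model = train_nb(rest_f, rest_y)
            assert fast[i] == pytest.approx(model.score(features[i]), abs=1e-10)

    def test_identical_compounds_identical_scores(self):
        features = [frozenset({"a", "b"})] * 2 + [frozenset({"c"}), frozenset({"d"})]
        labels = np.array([1, 1, 0, 0])
        scores = loo_cv_scores(features, labels)
        assert scores[0] == pytest.approx(scores[1])

    def test_minimum_size(self):
        features = [frozenset({"a"}), frozenset({"b"}), frozenset({"a", "b"})]
        scores = loo_cv_scores(features, np.array([1, 0, 1]))
        assert len(scores) == 3
        with pytest.raises(ValidationError):
            loo_cv_scores(features[:2], np.array([1, 0]))

    def test_degenerate_prior_guard(self):
        """Holding out the single active still yields finite scores."""
        features = [frozenset({"a"}), frozenset({"b"}), frozenset({"c"}), frozenset({"a", "c"})]
        labels = np.array([1, 0, 0, 0])
        scores = loo_cv_scores(features, labels)
        assert np.isfinite(scores).all()


class TestRoc:
    def test_examples(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_pair_statistic_equals_trapezoidal_curve(self):
        """Mann-Whitney formulation agrees with curve integration (sklearn)
        on random score vectors including heavy ties."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(10, 60)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)  # ties likely
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestEnrichment:
    def test_perfect_ranking(self):
        scores = np.concatenate([np.linspace(2, 3, 10), np.zeros(90)])
        labels = np.array([1] * 10 + [0] * 90)
        assert enrichment(scores, labels, 0.10) == pytest.approx(10.0)

    def test_full_fraction_is_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0] = 1
        assert enrichment(scores, labels, 1.0) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValidationError):
            enrichment([1.0, 2.0], [0, 0], 0.5)
        with pytest.raises(ValidationError):
            enrichment([1.0, 2.0], [1, 0], 0.0)


class TestRandomizedControl:
    def test_reproducible_and_preserves_active_count(self):
        rng = np.random.default_rng(9)
        features, labels = _random_problem(rng, 40)
        a = randomized_control(features, labels, reps=3, seed=5)
        b = randomized_control(features, labels, reps=3, seed=5)
        assert a.per_rep.tolist() == b.per_rep.tolist()
        assert len(a.per_rep) == 3
        # permutation preserves the active fraction: ROC remains defined
        assert np.isfinite(a.per_rep).all()

    def test_permutation_preserves_count_directly(self):
        rng = np.random.default_rng(2)
        y = np.array([1, 1, 0, 0, 0, 0, 1, 0])
        for _ in range(20):
            assert rng.permutation(y).sum() == y.sum()
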