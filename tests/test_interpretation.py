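"""Saliency gradients (closed form + finite differences), rule ablation,
and the external-corpus screening audit."""

import numpy as np
import pytest

from capscreen.encoders import RuleLexicon, apply_tfidf, fit_tfidf
from capscreen.interpretation import (
    external_corpus_screen,
    rule_loo_sensitivity,
    saliency_frequency_map,
    word_saliency,
)
from capscreen.modeling import (
    ArchitectureSpec,
    TrainedModel,
    TrainParams,
    _MLP,
    train_mlp,
)
from capscreen.preprocess import CleanCorpus


def linear_sigmoid_model(weights, bias=0.0):
    """One 'hidden' pass-through layer is avoided: build a net whose first
    layer is identity-sized and whose output reproduces sigmoid(w.x + b)."""
    n = len(weights)
    net = _MLP(ArchitectureSpec("lin", (n,)), n, np.random.default_rng(0))
    net.W[0] = np.eye(n)
    net.b[0] = np.full(n, 100.0)  # keep every ReLU strictly active
    net.W[1] = np.asarray(weights, dtype=float).reshape(-1, 1)
    net.b[1] = np.array([bias - 100.0 * float(np.sum(weights))])
    return TrainedModel(net, 1, {"val_accuracy": [1.0]}, "lin", 0, np.array([0]))


def finite_difference_gradient(net, x, step=1e-4):
    grad = np.zeros_like(x, dtype=float)
    for i in range(len(x)):
        hi, lo = x.copy().astype(float), x.copy().astype(float)
        hi[i] += step
        lo[i] -= step
        grad[i] = (
            net.predict_proba(hi[None, :])[0] - net.predict_proba(lo[None, :])[0]
        ) / (2 * step)
    return grad


class TestWordSaliency:
    def test_linear_model_closed_form(self):
        w = np.array([2.0, -1.0, 0.0])
        model = linear_sigmoid_model(w)
        x = np.array([0.5, 0.3, 0.7])
        p = model.net.predict_proba(x[None, :])[0]
        sal = word_saliency(model, x, ["alpha", "beta", "gamma"])
        for i, word in enumerate(["alpha", "beta", "gamma"]):
            assert sal[word] == pytest.approx(abs(w[i]) * p * (1 - p), rel=1e-9)

    def test_zero_weight_word_has_zero_saliency(self):
        model = linear_sigmoid_model([1.0, 0.0])
        sal = word_saliency(model, np.array([0.4, 0.4]), ["a", "b"])
        assert sal["b"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_words_not_reported(self):
        model = linear_sigmoid_model([1.0, 1.0, 1.0])
        sal = word_saliency(model, np.array([0.5, 0.0, 0.2]), ["a", "b", "c"])
        assert set(sal) == {"a", "c"}

    def test_agrees_with_central_finite_differences(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 8))
            arch = ArchitectureSpec(
                f"t{trial}", tuple(rng.integers(2, 6, size=rng.integers(1, 3)))
            )
            net = _MLP(arch, n, np.random.default_rng(trial))
            x = rng.normal(size=n)
            analytic = net.input_gradient(x)
            numeric = finite_difference_gradient(net, x)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.allclose(analytic, numeric, atol=1e-3 * scale)

    def test_width_mismatch_rejected(self):
        model = linear_sigmoid_model([1.0, 2.0])
        with pytest.raises(ValueError):
            word_saliency(model, np.array([1.0, 2.0, 3.0]), ["a", "b", "c"])


class TestSaliencyFrequencyMap:
    def _setup(self):
        corpora = [
            CleanCorpus("p1", ["alpha", "gamma", "beta"]),
            CleanCorpus("p2", ["alpha", "gamma", "delta"]),
        ]
        tfidf = fit_tfidf(corpora)
        # saliency order is driven by |output weight|
        weights = {"alpha": 0.5, "beta": 0.1, "gamma": 0.3, "delta": 0.0}
        model = linear_sigmoid_model([weights[w] for w in tfidf.vocabulary])
        return model, tfidf, corpora

    def test_top_k_selection_and_frequencies(self):
        model, tfidf, corpora = self._setup()
        report = saliency_frequency_map(model, tfidf, corpora, [1, 1], k=2)
        assert report.per_record == [["alpha", "gamma"], ["alpha", "gamma"]]
        assert report.positive_counts == {"alpha": 2, "gamma": 2}
        assert report.negative_counts == {}

    def test_shortfall_record_contributes_what_it_has(self):
        model, tfidf, _ = self._setup()
        report = saliency_frequency_map(
            model, tfidf, [CleanCorpus("p", ["beta"])], [0], k=50
        )
        assert report.per_record == [["beta"]]

    def test_classes_grouped_by_ground_truth(self):
        model, tfidf, corpora = self._setup()
        report = saliency_frequency_map(model, tfidf, corpora, [1, 0], k=1)
        assert report.positive_counts == {"alpha": 1}
        assert report.negative_counts == {"alpha": 1}

    def test_empty_test_set_rejected(self):
        model, tfidf, _ = self._setup()
        with pytest.raises(ValueError):
            saliency_frequency_map(model, tfidf, [], [], k=2)

    def test_injected_phrase_recovered_on_synthetic_cohort(self, small_cohort):
        from capscreen.pipeline import prepare_cohort

        prep = prepare_cohort(small_cohort.records)
        tfidf = fit_tfidf(prep.corpora, max_features=150)
        X = np.array([apply_tfidf(tfidf, c) for c in prep.corpora])
        model = train_mlp(
            X, prep.labels, ArchitectureSpec("w16", (16,)),
            TrainParams(epochs=25, learning_rate=3e-3, seed=2),
        )
        report = saliency_frequency_map(
            model, tfidf, prep.corpora, prep.labels, k=10
        )
        top_pos = {w for w, _ in report.top_positive[:10]}
        phrase_tokens = set(small_cohort.config.lexicon.phrase_tokens())
        assert phrase_tokens & top_pos, (
            "inserted phrase tokens should rank among the most frequently "
            "salient words for positive patients"
        )


class TestRuleAblation:
    def _rule_detector_model(self):
        """Net that outputs ~0.9 iff rule 0 == 1, else ~0.1."""
        net = _MLP(ArchitectureSpec("det", (1,)), 2, np.random.default_rng(0))
        net.W[0] = np.array([[1.0], [0.0]])
        net.b[0] = np.array([0.0])  # relu(x0): 1 when rule present, else 0
        net.W[1] = np.array([[4.39444915]])  # logit(0.9) - logit(0.1)
        net.b[1] = np.array([-2.19722458])  # logit(0.1)
        return TrainedModel(net, 1, {"val_accuracy": [1.0]}, "det", 0,
                            np.array([0]))

    def test_dominant_rule_delta_and_zero_impact_partition(self):
        model = self._rule_detector_model()
        X = np.array([[1.0, -1.0]] * 10 + [[-1.0, -1.0]] * 10)
        y = np.array([1] * 10 + [0] * 10)
        report = rule_loo_sensitivity(model, X, y, rule_names=["dominant", "inert"])
        assert report.baseline_accuracy == 1.0
        assert report.deltas[0] == pytest.approx(-0.5)
        assert report.deltas[1] == 0.0
        assert report.zero_impact == ["inert"]

    def test_invalidating_an_all_absent_column_is_a_no_op(self):
        model = self._rule_detector_model()
        X = np.array([[1.0, -1.0], [-1.0, -1.0]])
        y = np.array([1, 0])
        report = rule_loo_sensitivity(model, X, y)
        assert report.deltas[1] == 0.0

    def test_pure_function_baseline_reproducible(self):
        model = self._rule_detector_model()
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        y = np.array([1, 0, 1, 0])
        first = rule_loo_sensitivity(model, X, y)
        second = rule_loo_sensitivity(model, X, y)
        assert first.baseline_accuracy == second.baseline_accuracy
        assert np.array_equal(first.deltas, second.deltas)
        assert np.array_equal(X, np.array([[1.0, 1.0], [-1.0, 1.0],
                                           [1.0, -1.0], [-1.0, -1.0]]))


class TestExternalScreen:
    def _trained_rb(self):
        lexicon = RuleLexicon.from_raw(
            ["rib fracture", "domestic violence"], ["positive", "positive"]
        )
        rng = np.random.default_rng(0)
        X = np.where(rng.random((120, 2)) < 0.5, 1.0, -1.0)
        y = (X[:, 0] == 1).astype(int)
        model = train_mlp(
            X, y, ArchitectureSpec("w4", (4,)),
            TrainParams(epochs=60, learning_rate=1e-2, seed=1),
        )
        internal = [
            CleanCorpus("i1", ["rib", "fracture", "seen", "today"]),
            CleanCorpus("i2", ["well", "child", "visit", "today"]),
            CleanCorpus("i3", ["domestic", "violence", "history", "noted"]),
            CleanCorpus("i4", ["routine", "immunization", "visit", "done"]),
        ]
        return model, lexicon, internal

    def test_length_filter(self):
        model, lexicon, internal = self._trained_rb()
        texts = [" ".join(["word"] * n) for n in (4, 6, 8)]
        report = external_corpus_screen(
            model, lexicon, texts, internal, lexicon, (5, 7)
        )
        assert report.n_screened == 1

    def test_prevalence_ratio_definition(self):
        model, lexicon, internal = self._trained_rb()
        # phrase 0 in 2/4 external, 1/4 internal -> ratio 2.0
        texts = [
            "rib fracture noted today overnight",
            "rib fracture suspected again today",
            "quiet night nothing acute noted",
            "stable overnight improving steadily now",
        ]
        report = external_corpus_screen(
            model, lexicon, texts, internal, lexicon, (1, 10)
        )
        assert report.prevalence_ratio["rib fracture"] == pytest.approx(2.0)
        assert report.prevalence_ratio["domestic violence"] == pytest.approx(0.0)

    def test_zero_over_zero_reported_as_undefined(self):
        model, lexicon, _ = self._trained_rb()
        internal = [CleanCorpus("i", ["nothing", "relevant", "here"])]
        report = external_corpus_screen(
            model, lexicon, ["benign text only here"], internal, lexicon, (1, 10)
        )
        assert np.isnan(report.prevalence_ratio["rib fracture"])

    def test_empty_retained_set_rejected(self):
        model, lexicon, internal = self._trained_rb()
        with pytest.raises(ValueError):
            external_corpus_screen(
                model, lexicon, ["too short"], internal, lexicon, (50, 60)
            )

    def test_shifted_positive_phrases_raise_positive_rate(self):
        model, lexicon, internal = self._trained_rb()
        shifted = ["rib fracture documented again today"] * 30
        benign = ["quiet stable night no concerns"] * 30
        high = external_corpus_screen(
            model, lexicon, shifted, internal, lexicon, (1, 10)
        )
        low = external_corpus_screen(
            model, lexicon, benign, internal, lexicon, (1, 10)
        )
        assert high.positive_rate > low.positive_rate + 0.5
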