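"""Model-interpretation analyses: gradient saliency, leave-one-out rule
ablation, and the external-corpus (dataset-shift) false-positive audit.

Saliency of a word for a record is the magnitude of the analytic gradient
of the positive-class probability with respect to that word's bag-of-words
feature, evaluated at the record's own encoding; it is reported only for
words actually present in the record.  Rule ablation invalidates one rule
column at a time (set to -1 for every record) at inference — no retraining —
and measures the accuracy change.  The external audit freezes the encoder
fitted on internal data, screens out-of-domain texts of comparable length,
and reports both the positive-classification rate and per-rule prevalence
ratios (external / internal), the diagnostics for why a context-specific
screen misfires off-domain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoders import RuleLexicon, TfidfModel, apply_tfidf, encode_rules
from .evaluation import compute_metrics
from .modeling import TrainedModel, predict
from .preprocess import CleanCorpus, clean_text

__all__ = [
    "SaliencyReport",
    "AblationReport",
    "ExternalScreenReport",
    "word_saliency",
    "saliency_frequency_map",
    "rule_loo_sensitivity",
    "external_corpus_screen",
]


@dataclass
class SaliencyReport:
    """Top-k salient words per record and per-class frequency tables."""

    per_record: list[list[str]]
    positive_counts: dict[str, int]
    negative_counts: dict[str, int]
    top_positive: list[tuple[str, int]]
    top_negative: list[tuple[str, int]]
    k: int


@dataclass
class AblationReport:
    baseline_accuracy: float
    rule_names: list[str]
    deltas: np.ndarray  # accuracy(with rule j invalidated) - baseline
    zero_impact: list[str]


@dataclass
class ExternalScreenReport:
    n_screened: int
    positive_rate: float
    prevalence_ratio: dict[str, float]  # external / internal; NaN when 0/0


def word_saliency(
    model: TrainedModel,
    feature_vector: Sequence[float],
    vocabulary: Sequence[str],
) -> dict[str, float]:
    """|d p / d feature| for every word with a nonzero feature value."""
    x = np.asarray(feature_vector, dtype=float)
    if x.shape != (len(vocabulary),):
        raise ValueError("feature vector does not align with vocabulary")
    grad = np.abs(model.net.input_gradient(x))
    return {vocabulary[i]: float(grad[i]) for i in np.flatnonzero(x != 0)}


def saliency_frequency_map(
    model: TrainedModel,
    tfidf: TfidfModel,
    corpora: Sequence[CleanCorpus],
    labels: Sequence[int],
    k: int = 50,
    top_n: int = 50,
) -> SaliencyReport:
    """Per-record top-k salient words, tallied by ground-truth class.

    Ties in saliency break alphabetically; a record with fewer than ``k``
    distinct present words contributes them all.  ``top_n`` most frequent
    words are reported per class (count ties alphabetical).
    """
    if len(corpora) == 0:
        raise ValueError("empty test set")
    if len(corpora) != len(labels):
        raise ValueError("corpora and labels must align")
    per_record: list[list[str]] = []
    pos_counts: Counter[str] = Counter()
    neg_counts: Counter[str] = Counter()
    for corpus, label in zip(corpora, labels):
        sal = word_saliency(model, apply_tfidf(tfidf, corpus), tfidf.vocabulary)
        top = [w for w, _ in sorted(sal.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]
        per_record.append(top)
        (pos_counts if label == 1 else neg_counts).update(top)

    def ranked(counts: Counter[str]) -> list[tuple[str, int]]:
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]

    return SaliencyReport(
        per_record=per_record,
        positive_counts=dict(pos_counts),
        negative_counts=dict(neg_counts),
        top_positive=ranked(pos_counts),
        top_negative=ranked(neg_counts),
        k=k,
    )


def rule_loo_sensitivity(
    model: TrainedModel,
    rule_features: np.ndarray,
    labels: Sequence[int],
    threshold: float = 0.5,
    rule_names: Sequence[str] | None = None,
) -> AblationReport:
    """Invalidate each rule in turn (column := -1) and track accuracy change.

    Model weights are untouched; ablation happens at inference only.
    """
    X = np.asarray(rule_features, dtype=float)
    y = np.asarray(labels)
    names = (
        list(rule_names)
        if rule_names is not None
        else [f"rule_{j}" for j in range(X.shape[1])]
    )
    if len(names) != X.shape[1]:
        raise ValueError("rule names do not align with feature columns")
    baseline = compute_metrics(predict(model, X), y, threshold).accuracy
    deltas = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        ablated = X.copy()
        ablated[:, j] = -1.0
        deltas[j] = (
            compute_metrics(predict(model, ablated), y, threshold).accuracy
            - baseline
        )
    zero = [names[j] for j in range(X.shape[1]) if deltas[j] == 0.0]
    return AblationReport(
        baseline_accuracy=baseline, rule_names=names,
        deltas=deltas, zero_impact=zero,
    )


def _phrase_presence(
    lexicon: RuleLexicon, corpora: Sequence[CleanCorpus]
) -> np.ndarray:
    """Fraction of corpora containing each phrase (any polarity)."""
    if len(corpora) == 0:
        return np.full(len(lexicon), np.nan)
    present = np.array([encode_rules(lexicon, c) != -1 for c in corpora])
    return present.mean(axis=0)


def external_corpus_screen(
    model: TrainedModel,
    encoder_state: TfidfModel | RuleLexicon,
    external_texts: Sequence[str],
    internal_corpora: Sequence[CleanCorpus],
    lexicon: RuleLexicon,
    length_range: tuple[int, int],
    stop_list: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> ExternalScreenReport:
    """Screen out-of-domain texts with a frozen encoder and trained model.

    Texts are cleaned with the same pipeline as the internal cohort; only
    those whose cleaned word counts fall inside ``length_range`` are
    encoded and scored.  ``encoder_state`` selects the encoding: a fitted
    :class:`TfidfModel` (bag of words) or a :class:`RuleLexicon` (rules).
    """
    lo, hi = length_range
    cleaned = [
        CleanCorpus(f"ext{i:05d}", clean_text(t, stop_list))
        for i, t in enumerate(external_texts)
    ]
    retained = [c for c in cleaned if lo <= c.word_count <= hi]
    if not retained:
        raise ValueError("no external texts inside the length range")
    if isinstance(encoder_state, TfidfModel):
        X = np.array([apply_tfidf(encoder_state, c) for c in retained])
    elif isinstance(encoder_state, RuleLexicon):
        X = np.array(
            [encode_rules(encoder_state, c) for c in retained], dtype=float
        )
    else:
        raise TypeError(f"unsupported encoder state {type(encoder_state)!r}")
    probs = predict(model, X)
    ext_prev = _phrase_presence(lexicon, retained)
    int_prev = _phrase_presence(lexicon, internal_corpora)
    ratios: dict[str, float] = {}
    for j, phrase in enumerate(lexicon.phrases):
        name = " ".join(phrase)
        if ext_prev[j] == 0 and int_prev[j] == 0:
            ratios[name] = float("nan")  # 0/0: phrase absent everywhere
        elif int_prev[j] == 0:
            ratios[name] = float("inf")
        else:
            ratios[name] = float(ext_prev[j] / int_prev[j])
    return ExternalScreenReport(
        n_screened=len(retained),
        positive_rate=float(np.mean(probs >= threshold)),
        prevalence_ratio=ratios,
    )
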