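"""End-to-end convenience layer: cohort records in, cross-validated
screening results out.

These helpers wire the stage modules together in the canonical order —
truncate at the first CAP-team note, clean and merge into per-patient
corpora, apply the exclusion filters, encode, cross-validate — so that
scripts and tests exercise the exact pipeline a study analysis would run.
Encoders that fit statistics (TF-IDF) are fitted inside each training fold
and frozen before touching its test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .encoders import (
    RuleLexicon,
    TfidfModel,
    apply_tfidf,
    encode_corpora_rules,
    fit_tfidf,
)
from .evaluation import MetricsReport, compute_metrics
from .modeling import (
    ArchitectureSpec,
    CVConfig,
    CVEntry,
    CVResult,
    TrainParams,
    TrainingError,
    _repetition_seed,
    make_folds,
    predict,
    train_mlp,
)
from .preprocess import (
    CleanCorpus,
    ExclusionReport,
    PatientRecord,
    filter_cohort,
    truncate_at_cap,
)

__all__ = [
    "PreparedCohort",
    "prepare_cohort",
    "cross_validate_pipeline",
    "pooled_metrics",
    "per_split_metrics",
]


@dataclass
class PreparedCohort:
    corpora: list[CleanCorpus]
    labels: np.ndarray
    report: ExclusionReport


def prepare_cohort(
    records: Sequence[PatientRecord],
    stop_list: Iterable[str] | None = None,
    min_notes: int = 2,
    word_cap: int = 100_000,
) -> PreparedCohort:
    """Truncate at the CAP note, clean, and apply exclusion filters."""
    truncated = [truncate_at_cap(r) for r in records]
    corpora, labels, report = filter_cohort(
        truncated, stop_list=stop_list, min_notes=min_notes, word_cap=word_cap
    )
    return PreparedCohort(corpora, np.asarray(labels), report)


def cross_validate_pipeline(
    prepared: PreparedCohort,
    encoder: Literal["bow", "rules"],
    cv: CVConfig,
    params: TrainParams,
    archs: Sequence[ArchitectureSpec],
    lexicon: RuleLexicon | None = None,
    max_features: int | None = None,
) -> CVResult:
    """Cross-validate MLPs over a prepared cohort.

    For ``encoder="bow"`` a TF-IDF model is fitted on each training fold
    only, so test documents never contribute to vocabulary or document
    frequencies.  ``encoder="rules"`` needs a ``lexicon``; the rules
    encoding has no fitted state, so it is computed once.
    """
    y = prepared.labels
    fold_of = make_folds(y, cv)
    entries: list[CVEntry] = []
    rules_X: np.ndarray | None = None
    if encoder == "rules":
        if lexicon is None:
            raise ValueError("rules encoding requires a lexicon")
        rules_X = encode_corpora_rules(lexicon, prepared.corpora).toarray()
    elif encoder != "bow":
        raise ValueError(f"unknown encoder {encoder!r}")

    n_features = -1
    for split in range(cv.n_splits):
        train_idx = np.flatnonzero(fold_of != split)
        test_idx = np.flatnonzero(fold_of == split)
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise TrainingError(f"fold {split} contains a single class")
        if encoder == "bow":
            tfidf = fit_tfidf(
                [prepared.corpora[i] for i in train_idx], max_features
            )
            X_train = np.array(
                [apply_tfidf(tfidf, prepared.corpora[i]) for i in train_idx]
            )
            X_test = np.array(
                [apply_tfidf(tfidf, prepared.corpora[i]) for i in test_idx]
            )
        else:
            assert rules_X is not None
            X_train, X_test = rules_X[train_idx], rules_X[test_idx]
        n_features = X_train.shape[1]
        for arch in archs:
            for rep in range(cv.n_repetitions):
                p = replace(params,
                            seed=_repetition_seed(cv.master_seed, split, rep))
                model = train_mlp(X_train, y[train_idx], arch, p)
                probs = predict(model, X_test)
                entries.append(
                    CVEntry(
                        split=split, repetition=rep,
                        architecture_id=arch.id, model=model,
                        test_indices=test_idx, probabilities=probs,
                        metrics=compute_metrics(probs, y[test_idx]),
                    )
                )
    return CVResult(
        fold_of=fold_of, entries=entries,
        architecture_ids=[a.id for a in archs], n_features=n_features,
    )


def pooled_metrics(
    cv_result: CVResult,
    labels: Sequence[int],
    architecture_id: str | None = None,
    repetition: int = 0,
) -> MetricsReport:
    """Metrics on test predictions pooled over all splits (one model per
    split: the given repetition of the given architecture)."""
    y = np.asarray(labels)
    arch = architecture_id or cv_result.architecture_ids[0]
    probs = np.full(len(y), np.nan)
    for e in cv_result.entries:
        if e.architecture_id == arch and e.repetition == repetition:
            probs[e.test_indices] = e.probabilities
    if np.any(np.isnan(probs)):
        raise ValueError("pooled predictions do not cover the cohort")
    return compute_metrics(probs, y)


def per_split_metrics(
    cv_result: CVResult,
    architecture_id: str | None = None,
    repetition: int = 0,
) -> list[MetricsReport]:
    arch = architecture_id or cv_result.architecture_ids[0]
    out = [
        e.metrics
        for e in sorted(cv_result.entries, key=lambda e: e.split)
        if e.architecture_id == arch and e.repetition == repetition
    ]
    if not out:
        raise ValueError(f"no entries for architecture {arch!r}")
    return out
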