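"""Synthetic EMR cohorts with the statistical structure the analysis assumes.

Real pre-referral abuse-screening data are protected and cannot ship with a
package, so every stage of the pipeline is exercised against generated
cohorts whose structure mirrors the study design:

* one record per patient: several pre-referral notes, then a first
  CAP-team-authored note, then zero or more later notes;
* a binary abuse label drawn at ~55/45 prevalence;
* per-patient indicator-phrase presence drawn Bernoulli per phrase with
  class-conditional probabilities, phrases inserted verbatim into the
  pre-referral text;
* heavy-tailed note counts (negative binomial) and log-normal note lengths
  (defaults give corpora with median on the order of a few thousand words);
* a ``leakage_token`` injected *only* at or after the CAP note, so tests can
  grep for truncation failures;
* an unlabeled "external ICU-like" corpus generator with shifted phrase
  prevalence for the dataset-shift audit.

Background vocabulary, lexicon phrase tokens and the leakage token are drawn
from disjoint reserved pools, so a phrase can occur in a corpus only where
the generator put it — the recorded truth indicators are exact.

:func:`bayes_reference_auc` scores the generative model itself with the
exact log-likelihood ratio and returns the achievable (Bayes) AUC, the
yardstick against which trained classifiers are judged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.stats import mannwhitneyu

from .encoders import RuleLexicon
from .preprocess import PatientRecord, RawNote

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_lexicon",
    "generate_cohort",
    "generate_external_corpus",
    "bayes_reference_auc",
]

_PRE_ROLES = ("RN", "MD", "SW")
_CAP_ROLES = ("CAP-MD", "CAP-NP")
_ALL_ROLES = _PRE_ROLES + _CAP_ROLES

_ALPHA = "abcdefghijklmnopqrstuvwxyz"


def _base26(i: int, width: int = 3) -> str:
    out = []
    for _ in range(width):
        out.append(_ALPHA[i % 26])
        i //= 26
    return "".join(reversed(out))


def _background_vocab(size: int) -> list[str]:
    # Prefix "bg" keeps the pool disjoint from lexicon tokens ("zq...") and
    # stop words, and every token survives the cleaning pipeline.
    return ["bg" + _base26(i) for i in range(size)]


def _lexicon_token_pool(size: int) -> list[str]:
    return ["zq" + _base26(i) for i in range(size)]


def generate_lexicon(n_positive: int, n_negative: int, seed: int) -> RuleLexicon:
    """Draw a lexicon of distinct 2–3-token phrases from a reserved pool.

    No token is shared between phrases, so any contiguous occurrence of a
    phrase in generated text is attributable to a deliberate insertion.
    """
    if n_positive < 1 or n_negative < 0:
        raise ValueError("need n_positive >= 1 and n_negative >= 0")
    total = n_positive + n_negative
    rng = np.random.default_rng(seed)
    pool = rng.permutation(_lexicon_token_pool(3 * total + 8))
    rules: list[tuple[tuple[str, ...], str]] = []
    cursor = 0
    for k in range(total):
        length = int(rng.integers(2, 4))
        phrase = tuple(str(t) for t in pool[cursor : cursor + length])
        cursor += length
        rules.append((phrase, "positive" if k < n_positive else "negative"))
    return RuleLexicon(rules)  # type: ignore[arg-type]


@dataclass
class CohortConfig:
    """Generative description of a synthetic screening cohort.

    ``p_present_pos[j]`` / ``p_present_neg[j]`` are the per-phrase Bernoulli
    presence probabilities given a positive / negative label; when omitted
    they default to (0.6, 0.15) for positive-polarity rules and (0.15, 0.5)
    for negative-polarity ones.  ``phrase_location`` moves all phrase signal
    to the CAP-and-later notes, which a correctly truncating pipeline must
    then be blind to.
    """

    n_patients: int
    lexicon: RuleLexicon
    prevalence: float = 0.55
    p_present_pos: Sequence[float] | None = None
    p_present_neg: Sequence[float] | None = None
    notes_per_patient: tuple[float, float] = (2.0, 0.15)  # neg. binomial (r, p)
    words_per_note: tuple[float, float] = (500.0, 0.8)  # log-normal (median, sigma)
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.3
    n_post_cap_notes: float = 2.0  # Poisson mean
    leakage_token: str = "postreferralmarker"
    phrase_location: Literal["pre_cap", "post_cap"] = "pre_cap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        R = len(self.lexicon)
        if self.p_present_pos is None:
            self.p_present_pos = [
                0.6 if pol == "positive" else 0.15 for pol in self.lexicon.polarities
            ]
        if self.p_present_neg is None:
            self.p_present_neg = [
                0.15 if pol == "positive" else 0.5 for pol in self.lexicon.polarities
            ]
        for name, probs in (
            ("p_present_pos", self.p_present_pos),
            ("p_present_neg", self.p_present_neg),
        ):
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (R,):
                raise ValueError(f"{name} must give one probability per phrase")
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        phrase_tokens = self.lexicon.phrase_tokens()
        background = set(_background_vocab(self.background_vocab_size))
        if background & phrase_tokens or self.leakage_token in background:
            raise ValueError("background vocabulary must be disjoint from "
                             "lexicon tokens and the leakage token")
        if self.leakage_token in phrase_tokens:
            raise ValueError("leakage token collides with a lexicon token")

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_patients": self.n_patients,
            "prevalence": self.prevalence,
            "lexicon": [
                [" ".join(p), pol] for p, pol in self.lexicon.rules
            ],
            "p_present_pos": [float(x) for x in np.asarray(self.p_present_pos)],
            "p_present_neg": [float(x) for x in np.asarray(self.p_present_neg)],
            "notes_per_patient": list(self.notes_per_patient),
            "words_per_note": list(self.words_per_note),
            "background_vocab_size": self.background_vocab_size,
            "zipf_exponent": self.zipf_exponent,
            "n_post_cap_notes": self.n_post_cap_notes,
            "leakage_token": self.leakage_token,
            "phrase_location": self.phrase_location,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        lexicon = RuleLexicon(
            [(tuple(p.split()), pol) for p, pol in data.pop("lexicon")]
        )
        return cls(lexicon=lexicon, **{
            k: tuple(v) if k in ("notes_per_patient", "words_per_note") else v
            for k, v in data.items()
        })


@dataclass
class SyntheticCohort:
    """Generated records plus the exact phrase-presence truth indicators."""

    records: list[PatientRecord]
    truth: np.ndarray  # (n_patients, n_rules) boolean presence indicators
    config: CohortConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == "positive" else 0 for r in self.records])


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    p = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return p / p.sum()


def _insert_phrases(
    rng: np.random.Generator,
    notes: list[list[str]],
    phrases: list[tuple[str, ...]],
) -> None:
    """Overwrite non-overlapping random slices of the notes with phrases.

    Each present phrase is copied into *every* note with free space —
    clinical notes are highly redundant (findings are restated and copied
    forward from note to note), and this redundancy is what gives a present
    indicator phrase a non-negligible term frequency in the merged corpus.
    Replacing a slice (rather than splicing in) keeps each note's length
    intact, so the configured length distribution is unaffected by phrase
    load.  A phrase that fits nowhere at all raises: its truth indicator
    could not be honoured.
    """
    occupancy = [np.zeros(len(n), dtype=bool) for n in notes]
    for phrase in phrases:
        m = len(phrase)
        placed = 0
        for t, note in enumerate(notes):
            if len(note) < m:
                continue
            csum = np.concatenate(([0], np.cumsum(occupancy[t])))
            free_starts = np.flatnonzero(
                csum[m : len(note) + 1] - csum[: len(note) - m + 1] == 0
            )
            if len(free_starts) == 0:
                continue
            start = int(free_starts[rng.integers(len(free_starts))])
            note[start : start + m] = list(phrase)
            occupancy[t][start : start + m] = True
            placed += 1
        if placed == 0:
            raise RuntimeError(
                f"could not place phrase {' '.join(phrase)!r}: no free slot"
            )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a labeled cohort (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    vocab = np.array(_background_vocab(config.background_vocab_size))
    probs = _zipf_probs(config.background_vocab_size, config.zipf_exponent)
    p1 = np.asarray(config.p_present_pos, dtype=float)
    p0 = np.asarray(config.p_present_neg, dtype=float)
    r_nb, p_nb = config.notes_per_patient
    median_w, sigma_w = config.words_per_note
    base_time = datetime(2016, 1, 1)

    records: list[PatientRecord] = []
    truth = np.zeros((config.n_patients, len(config.lexicon)), dtype=bool)
    for i in range(config.n_patients):
        positive = rng.random() < config.prevalence
        x = rng.random(len(config.lexicon)) < (p1 if positive else p0)
        truth[i] = x
        n_pre = 1 + int(rng.negative_binomial(r_nb, p_nb))
        n_post = int(rng.poisson(config.n_post_cap_notes))

        def draw_note() -> list[str]:
            length = max(5, int(rng.lognormal(np.log(median_w), sigma_w)))
            return list(vocab[rng.choice(config.background_vocab_size,
                                         size=length, p=probs)])

        pre_notes = [draw_note() for _ in range(n_pre)]
        later_notes = [draw_note() for _ in range(1 + n_post)]  # CAP + post
        present = [config.lexicon.phrases[j] for j in np.flatnonzero(x)]
        if config.phrase_location == "pre_cap":
            _insert_phrases(rng, pre_notes, present)
        else:
            _insert_phrases(rng, later_notes, present)
        for note in later_notes:
            note.append(config.leakage_token)

        notes: list[RawNote] = []
        stamp = base_time + timedelta(days=int(rng.integers(0, 1200)))
        for k, toks in enumerate(pre_notes + later_notes):
            if k < n_pre:
                role = str(rng.choice(_PRE_ROLES))
            elif k == n_pre:
                role = str(rng.choice(_CAP_ROLES))
            else:
                role = str(rng.choice(_ALL_ROLES))
            notes.append(RawNote(role, stamp + timedelta(hours=k), " ".join(toks)))
        label = "positive" if positive else "negative"
        records.append(PatientRecord(f"pt{i:05d}", label, notes))
    return SyntheticCohort(records, truth, config)


def generate_external_corpus(
    config: CohortConfig,
    shift: Sequence[float],
    length_range: tuple[int, int],
    n: int,
    seed: int,
) -> list[str]:
    """Unlabeled external texts with shifted phrase prevalence.

    Emulates screening an out-of-domain corpus: word counts are drawn
    uniformly from ``length_range`` (counts are preserved by the cleaning
    pipeline because every generated token survives it), and phrase *j* is
    present with probability ``shift[j]`` regardless of any label.  Like
    the internal records, each external text is a merged multi-note corpus:
    it is built from segments of roughly the configured note length and a
    present phrase is copied into each segment, so per-record phrase
    frequency is comparable between domains.
    """
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"infeasible length_range ({lo} > {hi})")
    shift_arr = np.asarray(shift, dtype=float)
    if shift_arr.shape != (len(config.lexicon),):
        raise ValueError("shift must give one probability per lexicon phrase")
    rng = np.random.default_rng(seed)
    vocab = np.array(_background_vocab(config.background_vocab_size))
    probs = _zipf_probs(config.background_vocab_size, config.zipf_exponent)
    median_w = config.words_per_note[0]
    texts: list[str] = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        n_seg = max(1, round(length / median_w))
        bounds = np.linspace(0, length, n_seg + 1).astype(int)
        segments = [
            list(vocab[rng.choice(config.background_vocab_size,
                                  size=b - a, p=probs)])
            for a, b in zip(bounds[:-1], bounds[1:])
            if b > a
        ]
        x = rng.random(len(config.lexicon)) < shift_arr
        present = [config.lexicon.phrases[j] for j in np.flatnonzero(x)]
        _insert_phrases(rng, segments, present)
        texts.append(" ".join(t for seg in segments for t in seg))
    return texts


def bayes_reference_auc(
    config: CohortConfig, n_mc: int = 20_000, seed: int = 0
) -> float:
    """Achievable AUC of the cohort's own generative model.

    Each presence-indicator vector is scored with the exact log-likelihood
    ratio ``sum_j x_j ln(p1j/p0j) + (1-x_j) ln((1-p1j)/(1-p0j))`` and the
    concordance probability between class-conditional score distributions is
    returned (ties counted half).  For lexica of at most two phrases the
    result is computed by exhaustive enumeration; otherwise by Monte Carlo
    with ``n_mc`` draws per class.
    """
    p1 = np.asarray(config.p_present_pos, dtype=float)
    p0 = np.asarray(config.p_present_neg, dtype=float)
    if np.any((p1 <= 0) | (p1 >= 1) | (p0 <= 0) | (p0 >= 1)):
        raise ValueError("presence probabilities of 0 or 1 give infinite "
                         "log-likelihood ratios")
    w_present = np.log(p1 / p0)
    w_absent = np.log((1 - p1) / (1 - p0))

    def score(x: np.ndarray) -> np.ndarray:
        return x @ w_present + (1 - x) @ w_absent

    R = len(p1)
    if R <= 2:
        patterns = np.array(list(itertools.product([0, 1], repeat=R)), dtype=float)
        s = score(patterns)
        lik1 = np.prod(np.where(patterns == 1, p1, 1 - p1), axis=1)
        lik0 = np.prod(np.where(patterns == 1, p0, 1 - p0), axis=1)
        gt = s[:, None] > s[None, :] + 1e-12
        eq = np.abs(s[:, None] - s[None, :]) <= 1e-12
        return float(lik1 @ (gt + 0.5 * eq) @ lik0)
    rng = np.random.default_rng(seed)
    x1 = (rng.random((n_mc, R)) < p1).astype(float)
    x0 = (rng.random((n_mc, R)) < p0).astype(float)
    u = mannwhitneyu(score(x1), score(x0)).statistic
    return float(u / (n_mc * n_mc))
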