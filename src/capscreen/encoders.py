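"""Three numeric encodings of cleaned patient corpora.

* **BOW-TFIDF** — bag of words with smoothed inverse document frequency,
  ``tf(w, d) * (ln((1 + N) / (1 + df(w))) + 1)``, L2-normalised per row.
  Vocabulary and document frequencies are fitted on the training split only
  and frozen, so test documents never leak into the statistics.
* **Word embeddings** — a pre-trained word → vector table in word2vec text
  format; a document is the mean (or sum) of its token vectors, with
  out-of-vocabulary tokens mapped to deterministic pseudo-random vectors
  keyed by ``(word, oov_seed)``.
* **Rules-based (RB)** — a clinician lexicon of polarised phrases; rule *j*
  scores 1 when a positive-concern phrase occurs as a contiguous token run,
  0 when a negative-concern phrase occurs, and -1 when the phrase is absent
  (absence of a worrying phrase is *not* evidence of its negation).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .preprocess import CleanCorpus, clean_text

logger = logging.getLogger(__name__)

__all__ = [
    "TfidfModel",
    "EmbeddingTable",
    "EmbeddingFormatError",
    "RuleLexicon",
    "FeatureMatrix",
    "fit_tfidf",
    "apply_tfidf",
    "encode_corpora_tfidf",
    "load_embedding",
    "encode_embedding",
    "encode_rules",
    "encode_corpora_rules",
]

Polarity = Literal["positive", "negative"]


@dataclass
class RuleLexicon:
    """Ordered list of (cleaned phrase, polarity) clinician rules."""

    rules: list[tuple[tuple[str, ...], Polarity]]

    def __post_init__(self) -> None:
        if len(self.rules) < 1:
            raise ValueError("lexicon must contain at least one rule")
        phrases = [p for p, _ in self.rules]
        if len(set(phrases)) != len(phrases):
            raise ValueError("lexicon phrases must be distinct after cleaning")
        if any(len(p) == 0 for p in phrases):
            raise ValueError("lexicon contains a phrase that cleans to nothing")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def phrases(self) -> list[tuple[str, ...]]:
        return [p for p, _ in self.rules]

    @property
    def polarities(self) -> list[Polarity]:
        return [pol for _, pol in self.rules]

    def phrase_tokens(self) -> frozenset[str]:
        return frozenset(t for p, _ in self.rules for t in p)

    @classmethod
    def from_raw(
        cls,
        phrases: Sequence[str],
        polarities: Sequence[Polarity],
        stop_list: Iterable[str] | None = None,
    ) -> "RuleLexicon":
        """Build a lexicon from raw phrase strings, cleaning each phrase
        with the same pipeline applied to corpora (so e.g. "history of
        domestic violence" matches the cleaned run "history domestic
        violence")."""
        if len(phrases) != len(polarities):
            raise ValueError("phrases and polarities must align")
        return cls(
            [
                (tuple(clean_text(p, stop_list)), pol)
                for p, pol in zip(phrases, polarities)
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for phrase, pol in self.rules:
                fh.write(f"{' '.join(phrase)}\t{'pos' if pol == 'positive' else 'neg'}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RuleLexicon":
        rules: list[tuple[tuple[str, ...], Polarity]] = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            phrase, pol = line.split("\t")
            rules.append(
                (tuple(phrase.split()), "positive" if pol == "pos" else "negative")
            )
        return cls(rules)


@dataclass
class FeatureMatrix:
    """Encoded cohort: one row per patient, column semantics per encoder."""

    values: np.ndarray | scipy.sparse.spmatrix
    patient_ids: list[str]
    feature_names: list[str]
    encoder: str

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.patient_ids):
            raise ValueError("row count does not match patient id count")

    def toarray(self) -> np.ndarray:
        if scipy.sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def save(self, prefix: str | Path) -> None:
        """Persist as Matrix Market (values) + JSON sidecar (row/col names)."""
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.csr_matrix(self.values))
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "patient_ids": self.patient_ids,
                    "feature_names": self.feature_names,
                    "encoder": self.encoder,
                }
            )
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        values = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).tocsr()
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(values, meta["patient_ids"], meta["feature_names"], meta["encoder"])


# ---------------------------------------------------------------------------
# BOW-TFIDF
# ---------------------------------------------------------------------------

@dataclass
class TfidfModel:
    vocabulary: list[str]
    document_frequency: np.ndarray  # aligned with vocabulary
    n_documents: int
    max_features: int | None = None
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicates")
        if np.any(self.document_frequency < 1):
            raise ValueError("document frequencies must be >= 1")
        self.index = {w: i for i, w in enumerate(self.vocabulary)}

    def idf(self) -> np.ndarray:
        return np.log((1 + self.n_documents) / (1 + self.document_frequency)) + 1.0


def fit_tfidf(
    train_corpora: Sequence[CleanCorpus], max_features: int | None = None
) -> TfidfModel:
    """Fit vocabulary and document frequencies on training corpora only.

    When ``max_features`` is given the vocabulary is truncated to the top
    words by total collection frequency, ties broken alphabetically; the
    retained vocabulary is stored in alphabetical order.
    """
    if not train_corpora or all(c.word_count == 0 for c in train_corpora):
        raise ValueError("cannot fit TF-IDF: all training corpora are empty")
    df: dict[str, int] = {}
    cf: dict[str, int] = {}
    for corpus in train_corpora:
        seen = set()
        for tok in corpus.tokens:
            cf[tok] = cf.get(tok, 0) + 1
            seen.add(tok)
        for tok in seen:
            df[tok] = df.get(tok, 0) + 1
    vocab = sorted(df)
    if max_features is not None and len(vocab) > max_features:
        kept = sorted(vocab, key=lambda w: (-cf[w], w))[:max_features]
        vocab = sorted(kept)
    return TfidfModel(
        vocabulary=vocab,
        document_frequency=np.array([df[w] for w in vocab], dtype=np.int64),
        n_documents=len(train_corpora),
        max_features=max_features,
    )


def apply_tfidf(model: TfidfModel, corpus: CleanCorpus) -> np.ndarray:
    """Encode one corpus under a fitted model; never mutates the model.

    Out-of-vocabulary tokens are ignored.  A corpus with no in-vocabulary
    tokens encodes to the zero vector (returned unnormalised).
    """
    vec = np.zeros(len(model.vocabulary))
    for tok in corpus.tokens:
        i = model.index.get(tok)
        if i is not None:
            vec[i] += 1.0
    vec *= model.idf()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def encode_corpora_tfidf(
    model: TfidfModel, corpora: Sequence[CleanCorpus]
) -> FeatureMatrix:
    rows = np.array([apply_tfidf(model, c) for c in corpora])
    return FeatureMatrix(
        values=rows,
        patient_ids=[c.patient_id for c in corpora],
        feature_names=list(model.vocabulary),
        encoder="bow-tfidf",
    )


# ---------------------------------------------------------------------------
# Word embeddings
# ---------------------------------------------------------------------------

class EmbeddingFormatError(ValueError):
    """Raised for malformed word2vec-style embedding files."""


@dataclass
class EmbeddingTable:
    dimension: int
    vectors: dict[str, np.ndarray]
    oov_seed: int = 0

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise EmbeddingFormatError(
                    f"vector for {w!r} has length {v.shape[0]}, expected {self.dimension}"
                )


def load_embedding(path: str | Path, oov_seed: int = 0) -> EmbeddingTable:
    """Load a word2vec text-format table (optional ``count dim`` header).

    Duplicate words keep their first occurrence (a warning is logged);
    inconsistent vector lengths or an empty file raise
    :class:`EmbeddingFormatError`.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmbeddingFormatError(f"embedding file {path} is empty")
    start = 0
    header = lines[0].split()
    if len(header) == 2 and all(p.lstrip("-").isdigit() for p in header):
        start = 1
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    for ln in lines[start:]:
        parts = ln.split()
        word, vals = parts[0], parts[1:]
        if dim is None:
            dim = len(vals)
            if dim == 0:
                raise EmbeddingFormatError(f"no vector components on line {ln!r}")
        elif len(vals) != dim:
            raise EmbeddingFormatError(
                f"inconsistent dimension for {word!r}: {len(vals)} != {dim}"
            )
        if word in vectors:
            logger.warning("duplicate embedding entry %r: keeping first", word)
            continue
        vectors[word] = np.array([float(v) for v in vals])
    if dim is None:
        raise EmbeddingFormatError(f"embedding file {path} has no vector lines")
    return EmbeddingTable(dimension=dim, vectors=vectors, oov_seed=oov_seed)


def _oov_vector(word: str, dimension: int, oov_seed: int) -> np.ndarray:
    # Keyed by (word, seed) so every run maps an unseen word identically.
    digest = hashlib.blake2b(
        f"{word}\x00{oov_seed}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    half = 0.5 / dimension
    return rng.uniform(-half, half, size=dimension)


def encode_embedding(
    table: EmbeddingTable,
    corpus: CleanCorpus,
    pooling: Literal["mean", "sum"] = "mean",
) -> tuple[np.ndarray, float]:
    """Pool token vectors into a document vector; report table coverage.

    Coverage is the fraction of tokens found in the table (multiplicity
    counted); an empty corpus yields a zero vector and coverage 0.
    """
    if corpus.word_count == 0:
        logger.warning("empty corpus %r: zero vector, coverage 0", corpus.patient_id)
        return np.zeros(table.dimension), 0.0
    total = np.zeros(table.dimension)
    hits = 0
    for tok in corpus.tokens:
        vec = table.vectors.get(tok)
        if vec is None:
            vec = _oov_vector(tok, table.dimension, table.oov_seed)
        else:
            hits += 1
        total += vec
    if pooling == "mean":
        total /= corpus.word_count
    elif pooling != "sum":
        raise ValueError(f"unknown pooling {pooling!r}")
    return total, hits / corpus.word_count


# ---------------------------------------------------------------------------
# Rules-based encoding
# ---------------------------------------------------------------------------

def encode_rules(lexicon: RuleLexicon, corpus: CleanCorpus) -> np.ndarray:
    """Score each rule on one corpus: 1 / 0 / -1.

    A phrase counts as present only when its cleaned tokens occur as a
    contiguous run in the cleaned corpus.
    """
    lengths = {len(p) for p in lexicon.phrases}
    grams: dict[int, set[tuple[str, ...]]] = {}
    toks = corpus.tokens
    for m in lengths:
        grams[m] = {tuple(toks[i : i + m]) for i in range(len(toks) - m + 1)}
    out = np.empty(len(lexicon), dtype=np.int8)
    for j, (phrase, pol) in enumerate(lexicon.rules):
        if phrase in grams[len(phrase)]:
            out[j] = 1 if pol == "positive" else 0
        else:
            out[j] = -1
    return out


def encode_corpora_rules(
    lexicon: RuleLexicon, corpora: Sequence[CleanCorpus]
) -> FeatureMatrix:
    rows = np.array([encode_rules(lexicon, c) for c in corpora], dtype=np.float64)
    return FeatureMatrix(
        values=rows,
        patient_ids=[c.patient_id for c in corpora],
        feature_names=[" ".join(p) for p in lexicon.phrases],
        encoder="rules",
    )
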