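"""Record truncation, text cleaning and cohort exclusion filters.

The unit of analysis is a patient: an ordered stream of authored free-text
notes plus a screening label assigned by a Child Abuse Pediatrics (CAP)
team.  Because the goal is a *pre-referral* screen, every note at or after
the first CAP-team-authored note is discarded before any text is seen by a
model; the surviving notes are merged into one per-patient corpus, cleaned,
and passed through the cohort exclusion filters.

Cleaning pipeline (order matters and is fixed):

1. every punctuation character is replaced by a space;
2. the text is lowercased and split on whitespace;
3. tokens containing any digit are dropped (``10mg``, ``3am``);
4. single-character tokens are dropped;
5. stop-list tokens are dropped (default: :data:`DEFAULT_STOP_WORDS`,
   which keeps the negations ``no``/``not``/``nor``).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

from ._stopwords import DEFAULT_STOP_WORDS, NLTK_ENGLISH

__all__ = [
    "RawNote",
    "PatientRecord",
    "CleanCorpus",
    "ExclusionReport",
    "DEFAULT_STOP_WORDS",
    "NLTK_ENGLISH",
    "clean_text",
    "truncate_at_cap",
    "build_corpus",
    "filter_cohort",
    "read_cohort_jsonl",
    "write_cohort_jsonl",
    "read_stop_list",
]

Label = Literal["positive", "negative", "unclassified"]

#: Author roles whose first note defines the truncation point, by prefix.
CAP_ROLE_PREFIX = "CAP-"


@dataclass(frozen=True)
class RawNote:
    """A single free-text note with its author role and timestamp."""

    author_role: str
    timestamp: datetime
    text: str


@dataclass
class PatientRecord:
    """Time-ordered notes for one patient plus the CAP-team label.

    ``label`` is ``"unclassified"`` when the CAP team did not reach a
    determination; such records are dropped by :func:`filter_cohort`.
    """

    patient_id: str
    label: Label
    notes: list[RawNote] = field(default_factory=list)

    def __post_init__(self) -> None:
        stamps = [n.timestamp for n in self.notes]
        if stamps != sorted(stamps):
            raise ValueError(
                f"notes of patient {self.patient_id!r} are not time-ordered"
            )


@dataclass
class CleanCorpus:
    """Cleaned, order-preserving token sequence for one patient."""

    patient_id: str
    tokens: list[str]

    @property
    def word_count(self) -> int:
        return len(self.tokens)


@dataclass
class ExclusionReport:
    """Tally of cohort exclusions; counts always sum to the input size."""

    retained: int = 0
    excluded_unclassified: int = 0
    excluded_few_notes: int = 0
    excluded_over_cap: int = 0
    excluded_empty: int = 0
    word_cap: int = 100_000
    min_notes: int = 2

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.excluded_unclassified
            + self.excluded_few_notes
            + self.excluded_over_cap
            + self.excluded_empty
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def clean_text(text: str, stop_list: Iterable[str] | None = None) -> list[str]:
    """Apply the full cleaning pipeline to a piece of free text."""
    stop = DEFAULT_STOP_WORDS if stop_list is None else frozenset(stop_list)
    tokens = text.translate(_PUNCT_TABLE).lower().split()
    return [
        t
        for t in tokens
        if len(t) > 1
        and not any(c.isdigit() for c in t)
        and t not in stop
    ]


def truncate_at_cap(
    record: PatientRecord, cap_roles: Iterable[str] | None = None
) -> PatientRecord:
    """Drop the first CAP-team note and everything after it.

    ``cap_roles`` names the author roles that mark CAP-team involvement;
    when omitted, any role starting with ``"CAP-"`` counts.  If no note
    matches, the record is returned unchanged (already pre-referral).
    """
    roles = None if cap_roles is None else frozenset(cap_roles)

    def is_cap(role: str) -> bool:
        return role.startswith(CAP_ROLE_PREFIX) if roles is None else role in roles

    kept: list[RawNote] = []
    for note in record.notes:
        if is_cap(note.author_role):
            break
        kept.append(note)
    else:
        return record
    return PatientRecord(record.patient_id, record.label, kept)


def build_corpus(
    record: PatientRecord, stop_list: Iterable[str] | None = None
) -> CleanCorpus:
    """Merge a (truncated) record's notes in time order and clean them."""
    merged = " ".join(note.text for note in record.notes)
    return CleanCorpus(record.patient_id, clean_text(merged, stop_list))


def filter_cohort(
    records: Sequence[PatientRecord],
    stop_list: Iterable[str] | None = None,
    min_notes: int = 2,
    word_cap: int = 100_000,
) -> tuple[list[CleanCorpus], list[int], ExclusionReport]:
    """Apply the cohort exclusion filters to already-truncated records.

    Exclusion rules are checked in a fixed order and each record is counted
    once, under the first rule it trips:

    1. label ``unclassified``;
    2. fewer than ``min_notes`` notes remaining after truncation;
    3. cleaned corpus longer than ``word_cap`` words;
    4. cleaned corpus empty.

    Returns retained corpora, their binary labels (1 = positive), and an
    :class:`ExclusionReport`.
    """
    stop = DEFAULT_STOP_WORDS if stop_list is None else frozenset(stop_list)
    report = ExclusionReport(word_cap=word_cap, min_notes=min_notes)
    corpora: list[CleanCorpus] = []
    labels: list[int] = []
    for record in records:
        if record.label == "unclassified":
            report.excluded_unclassified += 1
            continue
        if len(record.notes) < min_notes:
            report.excluded_few_notes += 1
            continue
        corpus = build_corpus(record, stop)
        if corpus.word_count > word_cap:
            report.excluded_over_cap += 1
            continue
        if corpus.word_count == 0:
            report.excluded_empty += 1
            continue
        report.retained += 1
        corpora.append(corpus)
        labels.append(1 if record.label == "positive" else 0)
    return corpora, labels, report


# ---------------------------------------------------------------------------
# JSONL cohort IO (one object per patient)
# ---------------------------------------------------------------------------

def write_cohort_jsonl(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "id": rec.patient_id,
                        "label": rec.label,
                        "notes": [
                            {
                                "role": n.author_role,
                                "timestamp": n.timestamp.isoformat(),
                                "text": n.text,
                            }
                            for n in rec.notes
                        ],
                    }
                )
                + "\n"
            )


def read_cohort_jsonl(path: str | Path) -> list[PatientRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                PatientRecord(
                    patient_id=str(obj["id"]),
                    label=obj["label"],
                    notes=[
                        RawNote(
                            author_role=n["role"],
                            timestamp=datetime.fromisoformat(n["timestamp"]),
                            text=n["text"],
                        )
                        for n in obj["notes"]
                    ],
                )
            )
    return records


def read_stop_list(path: str | Path) -> frozenset[str]:
    """Read a stop list: one word per line, ``#`` comments and blanks ignored."""
    words = set()
    for line in Path(path).read_text().splitlines():
        word = line.strip().lower()
        if word and not word.startswith("#"):
            words.add(word)
    return frozenset(words)
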