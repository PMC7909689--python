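"""English stop-word lists used by the cleaning pipeline.

``NLTK_ENGLISH`` is the standard 179-word English stop list distributed with
the Natural Language Toolkit, vendored here as a plain tuple so the package
has no runtime dependency on NLTK data downloads.

``DEFAULT_STOP_WORDS`` is the list actually applied by default: the same set
minus the negation words {"no", "not", "nor"}.  Negations carry diagnostic
meaning in clinical notes ("no acute distress", "not consistent with
mechanism"), and downstream saliency analyses rely on "no" surviving
cleaning; the stop list is a parameter everywhere, so callers who want the
unmodified list can pass ``NLTK_ENGLISH``.
"""

from __future__ import annotations

NLTK_ENGLISH: frozenset[str] = frozenset((
    "i", "me", "my", "myself", "we", "our", "ours", "ourselves", "you",
    "you're", "you've", "you'll", "you'd", "your", "yours", "yourself",
    "yourselves", "he", "him", "his", "himself", "she", "she's", "her",
    "hers", "herself", "it", "it's", "its", "itself", "they", "them",
    "their", "theirs", "themselves", "what", "which", "who", "whom", "this",
    "that", "that'll", "these", "those", "am", "is", "are", "was", "were",
    "be", "been", "being", "have", "has", "had", "having", "do", "does",
    "did", "doing", "a", "an", "the", "and", "but", "if", "or", "because",
    "as", "until", "while", "of", "at", "by", "for", "with", "about",
    "against", "between", "into", "through", "during", "before", "after",
    "above", "below", "to", "from", "up", "down", "in", "out", "on", "off",
    "over", "under", "again", "further", "then", "once", "here", "there",
    "when", "where", "why", "how", "all", "any", "both", "each", "few",
    "more", "most", "other", "some", "such", "no", "nor", "not", "only",
    "own", "same", "so", "than", "too", "very", "s", "t", "can", "will",
    "just", "don", "don't", "should", "should've", "now", "d", "ll", "m",
    "o", "re", "ve", "y", "ain", "aren", "aren't", "couldn", "couldn't",
    "didn", "didn't", "doesn", "doesn't", "hadn", "hadn't", "hasn",
    "hasn't", "haven", "haven't", "isn", "isn't", "ma", "mightn",
    "mightn't", "mustn", "mustn't", "needn", "needn't", "shan", "shan't",
    "shouldn", "shouldn't", "wasn", "wasn't", "weren", "weren't", "won",
    "won't", "wouldn", "wouldn't",
))

#: Default list applied by :func:`capscreen.preprocess.build_corpus`:
#: negations are retained because their removal inverts clinical meaning.
DEFAULT_STOP_WORDS: frozenset[str] = NLTK_ENGLISH - {"no", "not", "nor"}
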