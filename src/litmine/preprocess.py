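"""Corpus cleaning, stopword removal, stemming and tokenization.

The cleaning procedure mirrors the three-step normalisation that is standard
for abstract mining: (1) noise removal — lowercasing, dropping tokens outside
the English alphabet (URLs, e-mails, numbers, hyphenated compounds), stripping
punctuation, removing generic and user-defined stopwords, and a word-length
filter; (2) stemming with the Porter algorithm; (3) tokenization into an
ordered list of stems per document.

Stopword removal and the length filter apply to the *unstemmed* word; both
stopword lists ship in the package as plain-text files (one word per line).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from ._porter import porter_stem
from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "StopwordPolicy",
    "TokenizedDoc",
    "clean_text",
    "stem",
    "preprocess_corpus",
    "load_stopwords",
    "default_policy",
]

# Characters that mark a whitespace token as "not an English word" once
# surrounding punctuation is stripped: digits, e-mail/URL characters and
# hyphens (hyphenated compounds are dropped whole, not split).
_NON_ALPHA_MARKERS = re.compile(r"[0-9@/.\-_~%+=&#]")
_STRIP_EDGES = re.compile(r"^[^A-Za-z0-9@/.\-_~%+=&#]+|[^A-Za-z]+$")
_LETTER_RUNS = re.compile(r"[a-z]+")


def load_stopwords(name_or_path: str) -> frozenset[str]:
    """Load a one-word-per-line stopword file.

    ``name_or_path`` is either the name of a packaged list
    (``"stopwords_english"`` or ``"custom_stopwords"``) or a filesystem path.
    """
    packaged = resources.files("litmine.data").joinpath(f"{name_or_path}.txt")
    if packaged.is_file():
        text = packaged.read_text(encoding="utf-8")
    else:
        with open(name_or_path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


@dataclass(frozen=True)
class StopwordPolicy:
    """Which words are removed before stemming.

    ``min_len``/``max_len`` bound the length of a kept (unstemmed) word,
    inclusive: words of fewer than ``min_len`` or more than ``max_len``
    letters are discarded.
    """

    generic_stopwords: frozenset[str] = field(default_factory=frozenset)
    custom_stopwords: frozenset[str] = field(default_factory=frozenset)
    min_len: int = 2
    max_len: int = 21

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len <= self.min_len:
            raise ValueError("max_len must exceed min_len")
        for words in (self.generic_stopwords, self.custom_stopwords):
            bad = [w for w in words if w != w.lower()]
            if bad:
                raise ValueError(f"stopwords must be lowercase: {bad[:5]}")


def default_policy(extra_custom: Iterable[str] = ()) -> StopwordPolicy:
    """The packaged policy: frozen generic English list plus the custom list
    of boilerplate section words ("abstract", "background", ...)."""
    return StopwordPolicy(
        generic_stopwords=load_stopwords("stopwords_english"),
        custom_stopwords=load_stopwords("custom_stopwords")
        | frozenset(w.lower() for w in extra_custom),
    )


@dataclass(frozen=True)
class TokenizedDoc:
    """A document reduced to its ordered list of stems."""

    id: str
    tokens: tuple[str, ...]


def clean_text(raw: str, policy: StopwordPolicy) -> list[str]:
    """Clean one free-text string into a list of lowercase words.

    Applied in order: lowercase; strip punctuation from token edges; drop
    whole tokens still containing non-alphabet characters (URLs, e-mails,
    numbers, hyphenated compounds); split what remains on non-letter runs;
    remove generic then custom stopwords; apply the word-length filter.
    Word order is preserved.  Idempotent on its own (re-joined) output.
    """
    if not isinstance(raw, str):
        raise ValueError("clean_text expects a string")
    out: list[str] = []
    for token in raw.lower().split():
        if not token.isascii():
            continue
        token = _STRIP_EDGES.sub("", token)
        if not token:
            continue
        if _NON_ALPHA_MARKERS.search(token):
            continue
        for word in _LETTER_RUNS.findall(token):
            if word in policy.generic_stopwords:
                continue
            if word in policy.custom_stopwords:
                continue
            if not policy.min_len <= len(word) <= policy.max_len:
                continue
            out.append(word)
    return out


def stem(word: str) -> str:
    """Porter stem of a lowercase alphabetic word."""
    if not word:
        raise ValueError("cannot stem an empty word")
    return porter_stem(word)


def preprocess_corpus(
    corpus: Corpus | Sequence, policy: StopwordPolicy | None = None
) -> list[TokenizedDoc]:
    """Clean and stem every document; one :class:`TokenizedDoc` per document,
    in corpus order.  Documents that clean down to nothing are retained with
    an empty token list (they become zero rows downstream) and logged."""
    if policy is None:
        policy = default_policy()
    docs = list(corpus)
    if not docs:
        raise ValueError("cannot preprocess an empty corpus")
    out = []
    n_empty = 0
    for doc in docs:
        words = clean_text(doc.text, policy)
        if not words:
            n_empty += 1
        out.append(TokenizedDoc(id=doc.id, tokens=tuple(stem(w) for w in words)))
    if n_empty:
        logger.warning("%d document(s) have no tokens after cleaning", n_empty)
    return out
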