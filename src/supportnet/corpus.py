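"""Corpus ingestion and text preprocessing.

Reads post corpora (JSONL/CSV), splits posts into sentences, and tokenizes
sentences into the word units that become network nodes: lowercased unigrams
plus underscore-joined multi-word units (MWUs), with stopwords, punctuation,
numerals and single-character tokens removed.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CorpusFormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "Post",
    "TokenizedSentence",
    "read_posts",
    "split_sentences",
    "tokenize_sentence",
    "tokenize_posts",
    "load_wordlist",
    "default_stopwords",
    "default_mwu_lexicon",
]


@dataclass(frozen=True)
class Post:
    """A single forum post: identifier, group label, free text."""

    post_id: str
    group: str
    text: str


@dataclass(frozen=True)
class TokenizedSentence:
    """One preprocessed sentence of a post.

    ``ordinal`` is the 0-based sentence index within the post; ``tokens`` are
    the surviving word units in original order (duplicates retained).
    """

    post_id: str
    group: str
    ordinal: int
    tokens: tuple[str, ...]


_REQUIRED_FIELDS = ("post_id", "group", "text")


def load_wordlist(path: str | Path) -> list[str]:
    """Read a UTF-8 word/phrase list, one entry per line, '#' comments allowed."""
    entries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            entries.append(line.lower())
    return entries


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """Packaged default English stopword list."""
    text = resources.files("supportnet.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@lru_cache(maxsize=1)
def default_mwu_lexicon() -> tuple[str, ...]:
    """Packaged default multi-word-unit lexicon (domain phrases)."""
    text = resources.files("supportnet.data").joinpath("mwu_lexicon.txt").read_text("utf-8")
    return tuple(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def read_posts(
    path: str | Path,
    format: str | None = None,
    groups: Iterable[str] | None = None,
) -> list[Post]:
    """Read a corpus file into Posts, preserving record order.

    Parameters
    ----------
    path:
        Corpus file. JSONL (one object per line with keys post_id, group,
        text) or CSV with a header row containing those columns.
    format:
        "jsonl" or "csv"; inferred from the file suffix when omitted.
    groups:
        Optional configured label set; records with a group outside it raise
        :class:`CorpusFormatError`.

    Records whose text is empty after whitespace stripping are skipped with a
    logged warning. A missing required field raises an error naming the
    offending record.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".jsonl", ".ndjson", ".json"):
            format = "jsonl"
        elif suffix in (".csv",):
            format = "csv"
        else:
            raise UsageError(f"cannot infer corpus format from suffix {suffix!r}")
    if format not in ("jsonl", "csv"):
        raise UsageError(f"unknown corpus format {format!r} (expected jsonl or csv)")

    group_set = set(groups) if groups is not None else None
    posts: list[Post] = []
    for recno, record in _iter_records(path, format):
        for field in _REQUIRED_FIELDS:
            if field not in record or record[field] is None:
                raise CorpusFormatError(
                    f"{path.name}: record {recno} is missing required field {field!r}"
                )
        text = str(record["text"])
        if not text.strip():
            logger.warning("%s: record %d has empty text; skipped", path.name, recno)
            continue
        group = str(record["group"])
        if group_set is not None and group not in group_set:
            raise CorpusFormatError(
                f"{path.name}: record {recno} has group {group!r} outside the "
                f"configured label set"
            )
        posts.append(Post(post_id=str(record["post_id"]), group=group, text=text))
    return posts


def _iter_records(path: Path, format: str):
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(
                        f"{path.name}: line {lineno} is not valid JSON: {exc}"
                    ) from exc
                if not isinstance(obj, dict):
                    raise CorpusFormatError(
                        f"{path.name}: line {lineno} is not a JSON object"
                    )
                yield lineno, obj
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for field in _REQUIRED_FIELDS:
                if field not in header:
                    raise CorpusFormatError(
                        f"{path.name}: CSV header is missing column {field!r}"
                    )
            for recno, row in enumerate(reader, start=1):
                yield recno, row


# Sentence splitting: terminal punctuation with an abbreviation exception
# list. The token immediately preceding a candidate boundary is compared,
# minus its trailing periods, against this set.
_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "rev", "sr", "jr", "st",
        "vs", "e.g", "i.e", "cf", "al", "approx", "fig", "dept",
    }
)
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def split_sentences(post: Post | str) -> list[str]:
    """Split a post's text into raw sentence strings.

    Boundaries are runs of terminal punctuation (. ! ?) followed by
    whitespace or end-of-text, except after known abbreviations ("Dr.",
    "e.g.", ...). Text with no terminal punctuation yields one sentence.
    Joining the result with single spaces reconstructs the text modulo
    whitespace.
    """
    text = post.text if isinstance(post, Post) else post
    boundaries: list[int] = []
    for match in _BOUNDARY_RE.finditer(text):
        prefix = text[: match.start()]
        word = re.search(r"(\S*)$", prefix).group(1)
        if word.lower().rstrip(".") in _ABBREVIATIONS:
            continue
        boundaries.append(match.end())
    sentences = []
    start = 0
    for end in boundaries:
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


_TOKEN_RE = re.compile(r"[\w']+")
_ALPHA_RE = re.compile(r"[a-z]")


def tokenize_sentence(
    sentence: str,
    stopwords: frozenset[str] | set[str] | None = None,
    mwu_lexicon: Sequence[str] | None = None,
) -> list[str]:
    """Tokenize one raw sentence into network-ready word units.

    Lowercases, strips punctuation, replaces longest-match multi-word units
    from the lexicon with underscore-joined tokens *before* stopword removal,
    then drops stopwords, numerals and single-character tokens. Duplicate
    tokens are retained in sequence; a sentence may reduce to zero tokens.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    if mwu_lexicon is None:
        mwu_lexicon = default_mwu_lexicon()

    raw = [t.strip("'") for t in _TOKEN_RE.findall(sentence.lower())]
    raw = [t for t in raw if t]

    # Longest-match, left-to-right MWU concatenation.
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for phrase in mwu_lexicon:
        words = tuple(phrase.split())
        if len(words) >= 2:
            by_first.setdefault(words[0], []).append(words)
    for cands in by_first.values():
        cands.sort(key=len, reverse=True)

    merged: list[str] = []
    i = 0
    while i < len(raw):
        token = raw[i]
        matched = False
        for phrase in by_first.get(token, ()):
            if tuple(raw[i : i + len(phrase)]) == phrase:
                merged.append("_".join(phrase))
                i += len(phrase)
                matched = True
                break
        if not matched:
            merged.append(token)
            i += 1

    stop = {w.lower() for w in stopwords}
    return [
        t
        for t in merged
        if t not in stop and len(t) > 1 and _ALPHA_RE.search(t)
    ]


def tokenize_posts(
    posts: Iterable[Post],
    stopwords: frozenset[str] | set[str] | None = None,
    mwu_lexicon: Sequence[str] | None = None,
) -> list[TokenizedSentence]:
    """Split and tokenize every post; sentences that reduce to zero tokens
    are kept (downstream network construction ignores them)."""
    out: list[TokenizedSentence] = []
    for post in posts:
        for ordinal, raw in enumerate(split_sentences(post)):
            tokens = tokenize_sentence(raw, stopwords, mwu_lexicon)
            out.append(
                TokenizedSentence(
                    post_id=post.post_id,
                    group=post.group,
                    ordinal=ordinal,
                    tokens=tuple(tokens),
                )
            )
    return out
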