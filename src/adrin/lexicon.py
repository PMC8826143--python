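"""Term resources: search-term sets, non-ADR keywords, ADR dictionary.

Three kinds of term lists steer identification: thresholded *search
terms* (medication, ADR and general-ADR categories) that seed the
embedding-similarity expansion; a flat *non-ADR keyword* list of words
that, immediately next to a medication, signal a dose change rather
than a reaction; and a flat *dictionary* of ADR terms (standing in for
MedDRA Lowest Level Terms) matched by exact token-sequence string
matching.

All entries are normalized with the same rules as note text, so lexicon
and note tokens live in one space.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Sequence

from .preprocess import ProcessedNote, normalize_text, tokenize

__all__ = [
    "CATEGORIES",
    "SearchTerm",
    "SearchTermSet",
    "NonAdrKeywordList",
    "DictionaryLexicon",
    "load_search_terms",
    "load_keywords",
    "load_dictionary",
    "contains_non_adr_keyword",
    "dictionary_match",
    "builtin_path",
]

CATEGORIES = ("medication", "adr", "general_adr")


@dataclass(frozen=True)
class SearchTerm:
    term: str
    category: str
    threshold: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(
                f"threshold for {self.term!r} must lie in (0, 1], "
                f"got {self.threshold}"
            )
        if self.term != normalize_text(self.term):
            raise ValueError(f"term {self.term!r} is not normalized")


class SearchTermSet:
    """Ordered, duplicate-free search terms of a single category."""

    def __init__(self, terms: Iterable[SearchTerm]):
        terms = list(terms)
        cats = {t.category for t in terms}
        if len(cats) > 1:
            raise ValueError(f"mixed categories in one set: {sorted(cats)}")
        seen: set[str] = set()
        for t in terms:
            if t.term in seen:
                raise ValueError(f"duplicate search term {t.term!r}")
            seen.add(t.term)
        self.terms: tuple[SearchTerm, ...] = tuple(terms)
        self.category: str | None = next(iter(cats)) if cats else None

    def __iter__(self) -> Iterator[SearchTerm]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


class NonAdrKeywordList:
    """Words flagging a medication change/extension (increase, double...)."""

    def __init__(self, words: Iterable[str]):
        self.words = frozenset(normalize_text(w) for w in words)

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


class DictionaryLexicon:
    """Flat ADR dictionary for exact multi-token string matching."""

    def __init__(self, entries: Iterable[Sequence[str]]):
        self.entries: frozenset[tuple[str, ...]] = frozenset(
            tuple(e) for e in entries if len(e) >= 1
        )
        self.max_len: int = max((len(e) for e in self.entries), default=0)

    def __contains__(self, entry: Sequence[str]) -> bool:
        return tuple(entry) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_search_terms(path, category: str) -> SearchTermSet:
    """Load the rows of one category from a ``term\\tcategory\\tthreshold``
    TSV file, validating thresholds and duplicates."""
    terms: list[SearchTerm] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: row {i + 1}: expected 3 tab-separated fields"
                )
            term, cat, thr = parts
            if cat != category:
                continue
            try:
                threshold = float(thr)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {i + 1}: bad threshold {thr!r}"
                ) from exc
            try:
                terms.append(
                    SearchTerm(
                        term=normalize_text(term),
                        category=cat,
                        threshold=threshold,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    try:
        return SearchTermSet(terms)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def load_keywords(path) -> NonAdrKeywordList:
    with open(path, encoding="utf-8") as fh:
        words = [w.strip() for w in fh if w.strip() and not w.startswith("#")]
    return NonAdrKeywordList(words)


def load_dictionary(path) -> DictionaryLexicon:
    """Load a flat dictionary (one term per line), tokenizing each entry
    with the note preprocessing rules so matching is token-exact."""
    entries: list[tuple[str, ...]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens, _ = tokenize(normalize_text(line))
            if tokens:
                entries.append(tuple(tokens))
    return DictionaryLexicon(entries)


def builtin_path(name: str):
    """Context manager yielding the path of a shipped fixture file."""
    return resources.as_file(resources.files("adrin.data").joinpath(name))


def contains_non_adr_keyword(
    note: ProcessedNote,
    anchor_index: int,
    keywords: NonAdrKeywordList,
    radius: int = 1,
) -> bool:
    """True iff a keyword sits within ``radius`` tokens of the anchor.

    The default radius of 1 reads "immediately before or after the
    medication" literally: only the two adjacent tokens are inspected.
    """
    if not 0 <= anchor_index < len(note):
        raise IndexError(f"anchor index {anchor_index} out of bounds")
    lo = max(0, anchor_index - radius)
    hi = min(len(note) - 1, anchor_index + radius)
    return any(
        note.tokens[i] in keywords
        for i in range(lo, hi + 1)
        if i != anchor_index
    )


def dictionary_match(
    note: ProcessedNote,
    span: tuple[int, int],
    dictionary: DictionaryLexicon,
) -> list[tuple[int, tuple[str, ...]]]:
    """All dictionary entries matching consecutive note tokens inside
    ``span`` (inclusive index range).

    At each start position the longest matching entry wins (a shorter
    entry nested at the same start is suppressed); matches starting at
    different positions may overlap and are all reported.
    """
    lo, hi = span
    if lo < 0 or hi >= len(note) or lo > hi:
        raise IndexError(f"span {span} out of bounds for note of "
                         f"length {len(note)}")
    matches: list[tuple[int, tuple[str, ...]]] = []
    for start in range(lo, hi + 1):
        longest = min(dictionary.max_len, hi - start + 1)
        for length in range(longest, 0, -1):
            cand = tuple(note.tokens[start:start + length])
            if cand in dictionary:
                matches.append((start, cand))
                break
    return matches
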