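"""Text preprocessing for clinical notes.

Raw note text passes through five steps before any similarity matching:
lowercasing + transliteration, dose removal, greedy word tokenization
(with sentence-boundary bookkeeping), number normalization, and
vocabulary filtering against the unigram embedding model.  Sentence
boundaries are recorded as per-token segment indices rather than as
tokens, so the embedding view of a note never contains punctuation while
the search-area logic can still respect it.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

__all__ = [
    "ProcessedNote",
    "NumberLexicon",
    "normalize_text",
    "tokenize",
    "strip_doses",
    "normalize_numbers",
    "filter_to_vocabulary",
    "preprocess_note",
    "DEFAULT_BOUNDARY_CHARS",
    "DEFAULT_DOSE_UNITS",
]

#: Characters that end a sentence segment.  Commas are deliberately not
#: included: short clinical notes use commas as soft separators within a
#: clause, and treating them as hard boundaries would shred most notes
#: into one-token segments.
DEFAULT_BOUNDARY_CHARS = frozenset(".;!?")

#: Units recognized by the dose grammar (post-transliteration, so µg has
#: already become ug).
DEFAULT_DOSE_UNITS = ("mg", "mcg", "ug", "g", "ml", "ie")

# Transliterations that NFKD decomposition alone does not produce.
_TRANSLIT_SPECIAL = str.maketrans(
    {
        "ß": "ss",
        "æ": "ae",
        "œ": "oe",
        "ø": "o",
        "đ": "d",
        "ð": "d",
        "þ": "th",
        "ł": "l",
        "µ": "u",
        "μ": "u",
    }
)

_WORD_RE = re.compile(r"[a-z0-9]+")
_DIGITS_RE = re.compile(r"[0-9]+")


def normalize_text(text: str) -> str:
    """Lowercase and transliterate ``text`` to plain ASCII.

    Accented letters are decomposed (NFKD) and their combining marks
    dropped; a handful of letters without a decomposition (ß, ø, µ, ...)
    are mapped explicitly.  Remaining non-ASCII characters are removed.
    The function is idempotent.
    """
    text = text.lower().translate(_TRANSLIT_SPECIAL)
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return text.encode("ascii", "ignore").decode("ascii").lower()


def tokenize(
    text: str, boundary_chars: Iterable[str] = DEFAULT_BOUNDARY_CHARS
) -> tuple[list[str], list[int]]:
    """Greedy word tokenization with sentence-segment tracking.

    Tokens are maximal runs of ``[a-z0-9]`` in the normalized text.  Each
    character from ``boundary_chars`` increments the segment counter, so
    the returned ``sentence_ids`` (one per token, non-decreasing) tell
    which segment every token belongs to.  Boundary characters themselves
    never appear as tokens.
    """
    boundary = frozenset(boundary_chars)
    tokens: list[str] = []
    sentence_ids: list[int] = []
    segment = 0
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in boundary:
            segment += 1
            i += 1
            continue
        m = _WORD_RE.match(text, i)
        if m:
            tokens.append(m.group(0))
            sentence_ids.append(segment)
            i = m.end()
        else:
            i += 1
    return tokens, sentence_ids


def _dose_pattern(units: Sequence[str]) -> re.Pattern[str]:
    alts = "|".join(sorted(units, key=len, reverse=True))
    # number, optional space, unit (e.g. "50 mg", "12.5mg"); and
    # frequency shorthand such as "1dd1" / "2 dd 1" (times-daily codes).
    return re.compile(
        r"\b\d+(?:[.,]\d+)?\s*(?:%s)\b"
        r"|\b\d+\s*dd\s*\d*(?:[.,]\d+)?\b" % alts
    )


def strip_doses(text: str, units: Sequence[str] = DEFAULT_DOSE_UNITS) -> str:
    """Remove dose expressions (``50 mg``, ``1dd1``) from normalized text.

    Doses are removed before number normalization so that the digits of a
    dose never survive as written-out number words; bare numbers without
    a unit (years, counts) are left alone.
    """
    return _dose_pattern(units).sub(" ", text)


@dataclass(frozen=True)
class NumberLexicon:
    """Mapping from digit strings to their written form for one language.

    Lookups outside the domain (large numbers, leading zeros) fall back
    to digit-wise spelling, so every all-digit token has a written form.
    """

    language: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        words = list(self.mapping.values())
        if len(set(words)) != len(words):
            raise ValueError("number lexicon mapping must be injective")
        for d in "0123456789":
            if d not in self.mapping:
                raise ValueError(
                    f"number lexicon for {self.language!r} must cover single "
                    f"digits (missing {d!r}) to support digit-wise fallback"
                )

    def to_words(self, token: str) -> list[str]:
        """Written form of an all-digit token (one or more word tokens)."""
        if token in self.mapping:
            return [self.mapping[token]]
        return [self.mapping[d] for d in token]

    @classmethod
    def from_tsv(cls, path, language: str = "custom") -> "NumberLexicon":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                digits, word = line.split("\t")
                mapping[digits] = word
        return cls(language=language, mapping=mapping)

    @classmethod
    def _builtin(cls, name: str) -> "NumberLexicon":
        ref = resources.files("adrin.data").joinpath(f"numbers_{name}.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, language=name)

    @classmethod
    def dutch(cls) -> "NumberLexicon":
        return cls._builtin("nl")

    @classmethod
    def english(cls) -> "NumberLexicon":
        return cls._builtin("en")


def normalize_numbers(
    tokens: Sequence[str], lexicon: NumberLexicon
) -> list[str]:
    """Replace every all-digit token by its written form.

    A token may expand to several word tokens under the digit-wise
    fallback; non-numeric tokens pass through untouched.
    """
    out: list[str] = []
    for tok in tokens:
        if tok.isdigit():
            out.extend(lexicon.to_words(tok))
        else:
            out.append(tok)
    return out


def filter_to_vocabulary(
    tokens: Sequence[str], vocab
) -> tuple[list[str], list[int]]:
    """Order-preserving subsequence of ``tokens`` present in ``vocab``.

    Returns the kept tokens and their indices in the input sequence so
    that per-token annotations (sentence ids) can be carried through.
    """
    kept: list[str] = []
    positions: list[int] = []
    for i, tok in enumerate(tokens):
        if tok in vocab:
            kept.append(tok)
            positions.append(i)
    return kept, positions


@dataclass(frozen=True)
class ProcessedNote:
    """A note after preprocessing: aligned tokens, segments, positions.

    ``source_positions`` index into the pre-filter token sequence (after
    tokenization and number normalization, before vocabulary filtering).
    """

    note_id: str
    tokens: tuple[str, ...]
    sentence_ids: tuple[int, ...]
    source_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.tokens)
            == len(self.sentence_ids)
            == len(self.source_positions)
        ):
            raise ValueError("parallel token annotations differ in length")
        if any(
            b < a
            for a, b in zip(self.sentence_ids, self.sentence_ids[1:])
        ):
            raise ValueError("sentence_ids must be non-decreasing")

    def __len__(self) -> int:
        return len(self.tokens)


def preprocess_note(
    raw,
    vocab=None,
    number_lexicon: Optional[NumberLexicon] = None,
    boundary_chars: Iterable[str] = DEFAULT_BOUNDARY_CHARS,
    dose_units: Sequence[str] = DEFAULT_DOSE_UNITS,
) -> ProcessedNote:
    """Full preprocessing composition for one note.

    normalize_text -> strip_doses -> tokenize -> normalize_numbers ->
    filter_to_vocabulary.  ``raw`` is anything with ``note_id`` and
    ``text`` attributes (or a plain string, in which case the note id is
    empty).  ``vocab=None`` skips the vocabulary filter; a missing number
    lexicon leaves digit tokens as they are (useful when the embedding
    model was itself trained on digit tokens).
    """
    if isinstance(raw, str):
        note_id, text = "", raw
    else:
        note_id, text = raw.note_id, raw.text

    text = strip_doses(normalize_text(text), dose_units)
    tokens, sentence_ids = tokenize(text, boundary_chars)

    if number_lexicon is not None:
        expanded: list[str] = []
        expanded_ids: list[int] = []
        for tok, sid in zip(tokens, sentence_ids):
            words = (
                number_lexicon.to_words(tok) if tok.isdigit() else [tok]
            )
            expanded.extend(words)
            expanded_ids.extend([sid] * len(words))
        tokens, sentence_ids = expanded, expanded_ids

    if vocab is not None:
        kept, positions = filter_to_vocabulary(tokens, vocab)
        kept_ids = [sentence_ids[p] for p in positions]
    else:
        kept, positions, kept_ids = (
            list(tokens),
            list(range(len(tokens))),
            list(sentence_ids),
        )

    return ProcessedNote(
        note_id=note_id,
        tokens=tuple(kept),
        sentence_ids=tuple(kept_ids),
        source_positions=tuple(positions),
    )
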