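"""The identification pipeline: medication anchoring, windowed search
areas, non-ADR keyword filtering, and ADR identification.

Each note runs through three steps:

1. *Medication anchoring.*  Every note token is compared (cosine
   similarity in the unigram embedding space) against the medication
   search terms; tokens strictly above a term's threshold become
   medication anchors.  If no anchor is found, a fallback search with
   general ADR words ("bijwerking", ...) decides whether the note is a
   general ADR mention or a definite negative.
2. *Search area.*  Around each anchor a window of ``s`` tokens per side
   (or the whole note) is taken and, when the version respects
   punctuation, clipped to the anchor's sentence segment.  An anchor
   whose immediate neighbour is a non-ADR keyword (``increase``,
   ``double``...) signals a dose change and is skipped entirely.
3. *ADR identification.*  Inside the area, two sequential routes fire:
   exact dictionary string matching (versions "A") and embedding
   similarity against the ADR search terms.  Every (anchor, ADR) hit
   becomes a medication-ADR pair.

Twelve versions (the grid: search area all/10/5 x punctuation on/off x
dictionary on/off) parameterize the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .embedding import VectorStore, matches_above_threshold
from .io import RawNote
from .lexicon import (
    DictionaryLexicon,
    NonAdrKeywordList,
    SearchTermSet,
    contains_non_adr_keyword,
    dictionary_match,
)
from .preprocess import (
    DEFAULT_BOUNDARY_CHARS,
    NumberLexicon,
    ProcessedNote,
    preprocess_note,
)

__all__ = [
    "VERSION_TABLE",
    "PipelineConfig",
    "Mention",
    "MedAdrPair",
    "NoteResult",
    "SearchArea",
    "make_version",
    "find_medications",
    "find_general_adr",
    "build_search_area",
    "identify_adrs_in_area",
    "run_note",
    "run_corpus",
]

logger = logging.getLogger(__name__)

#: Version grid: number -> (search area in words per side or None for
#: the whole note, respect punctuation).  Suffix A adds the dictionary
#: route, suffix B omits it.
VERSION_TABLE: dict[str, tuple[Optional[int], bool]] = {
    "1": (None, True),
    "2": (None, False),
    "3": (10, True),
    "4": (10, False),
    "5": (5, True),
    "6": (5, False),
}


@dataclass(frozen=True)
class PipelineConfig:
    """One pipeline version plus its term resources."""

    search_area: Optional[int]  # tokens per side; None = whole note
    respect_punctuation: bool
    use_dictionary: bool
    med_terms: SearchTermSet = field(default_factory=lambda: SearchTermSet([]))
    adr_terms: SearchTermSet = field(default_factory=lambda: SearchTermSet([]))
    general_adr_terms: SearchTermSet = field(
        default_factory=lambda: SearchTermSet([])
    )
    non_adr_keywords: NonAdrKeywordList = field(
        default_factory=lambda: NonAdrKeywordList([])
    )
    dictionary: Optional[DictionaryLexicon] = None
    version_label: str = ""
    keyword_radius: int = 1
    boundary_chars: frozenset[str] = DEFAULT_BOUNDARY_CHARS

    def __post_init__(self) -> None:
        if self.search_area is not None and self.search_area < 1:
            raise ValueError("search_area must be >= 1 or None (whole note)")
        if self.use_dictionary and self.dictionary is None:
            raise ValueError(
                "use_dictionary requires a dictionary lexicon"
            )
        if self.version_label:
            num, suffix = self.version_label[:-1], self.version_label[-1]
            expect = VERSION_TABLE.get(num)
            if expect is not None and suffix in "AB":
                area, punct = expect
                if (
                    area != self.search_area
                    or punct != self.respect_punctuation
                    or (suffix == "A") != self.use_dictionary
                ):
                    raise ValueError(
                        f"settings inconsistent with version label "
                        f"{self.version_label!r}"
                    )

    def with_resources(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def make_version(version_label: str, **resources) -> PipelineConfig:
    """Build the config skeleton for one of the twelve versions.

    ``"3B"`` -> search area 10 words per side, punctuation respected, no
    dictionary.  Term resources can be attached immediately via keyword
    arguments or later with :meth:`PipelineConfig.with_resources`.
    """
    label = version_label.strip().upper()
    if len(label) != 2 or label[0] not in VERSION_TABLE or label[1] not in "AB":
        raise ValueError(
            f"unknown pipeline version {version_label!r}; expected one of "
            "1A..6A, 1B..6B"
        )
    area, punct = VERSION_TABLE[label[0]]
    return PipelineConfig(
        search_area=area,
        respect_punctuation=punct,
        use_dictionary=label[1] == "A",
        version_label=label,
        **resources,
    )


@dataclass(frozen=True)
class Mention:
    """One extracted medication or ADR span."""

    kind: str  # medication | adr | general_adr
    token_index: int
    length: int
    surface: str
    matched_term: str
    similarity: float
    route: str  # embedding | dictionary

    def __post_init__(self) -> None:
        if self.kind not in ("medication", "adr", "general_adr"):
            raise ValueError(f"unknown mention kind {self.kind!r}")
        if self.route not in ("embedding", "dictionary"):
            raise ValueError(f"unknown route {self.route!r}")

    @property
    def indices(self) -> range:
        return range(self.token_index, self.token_index + self.length)


@dataclass(frozen=True)
class MedAdrPair:
    medication: Mention
    adr: Mention


@dataclass(frozen=True)
class NoteResult:
    """Pipeline output for one note."""

    note_id: str
    has_adr: bool
    medications: tuple[Mention, ...]
    adrs: tuple[Mention, ...]
    pairs: tuple[MedAdrPair, ...]
    termination: str
    # no_medication_no_general_adr | general_adr_only | paired |
    # medication_no_adr


@dataclass(frozen=True)
class SearchArea:
    """Inclusive token-index window around an anchor (anchor excluded
    from ADR candidacy)."""

    lo: int
    hi: int
    anchor: int

    def indices(self) -> list[int]:
        return [i for i in range(self.lo, self.hi + 1) if i != self.anchor]

    def __contains__(self, index: int) -> bool:
        return self.lo <= index <= self.hi and index != self.anchor


def _scan(note: ProcessedNote, store: VectorStore, terms: SearchTermSet,
          kind: str) -> list[Mention]:
    mentions: list[Mention] = []
    for i, tok in enumerate(note.tokens):
        if tok not in store:
            continue
        hit = matches_above_threshold(store, tok, terms)
        if hit is not None:
            term, sim = hit
            mentions.append(
                Mention(
                    kind=kind,
                    token_index=i,
                    length=1,
                    surface=tok,
                    matched_term=term,
                    similarity=sim,
                    route="embedding",
                )
            )
    return mentions


def find_medications(
    note: ProcessedNote, cfg: PipelineConfig, store: VectorStore
) -> list[Mention]:
    """Step 1: every token above a medication term's threshold.

    A token identical to a search term always matches (its
    self-similarity 1.0 strictly exceeds any threshold in (0, 1)).
    """
    return _scan(note, store, cfg.med_terms, "medication")


def find_general_adr(
    note: ProcessedNote, cfg: PipelineConfig, store: VectorStore
) -> list[Mention]:
    """Fallback of step 1: general ADR words when no medication anchors.

    An empty result means the note is automatically labeled as not
    containing an ADR.
    """
    return _scan(note, store, cfg.general_adr_terms, "general_adr")


def build_search_area(
    note: ProcessedNote, anchor_index: int, cfg: PipelineConfig
) -> SearchArea:
    """Step 2: the token window searched for ADRs around one anchor.

    ``search_area=None`` takes the whole note; otherwise ``s`` tokens on
    each side of the anchor, clipped to the note.  When the version
    respects punctuation the window is additionally clipped to the
    anchor's sentence segment.
    """
    if not 0 <= anchor_index < len(note):
        raise IndexError(f"anchor index {anchor_index} out of bounds")
    if cfg.search_area is None:
        lo, hi = 0, len(note) - 1
    else:
        lo = max(0, anchor_index - cfg.search_area)
        hi = min(len(note) - 1, anchor_index + cfg.search_area)
    if cfg.respect_punctuation:
        seg = note.sentence_ids[anchor_index]
        while lo < anchor_index and note.sentence_ids[lo] != seg:
            lo += 1
        while hi > anchor_index and note.sentence_ids[hi] != seg:
            hi -= 1
    return SearchArea(lo=lo, hi=hi, anchor=anchor_index)


def identify_adrs_in_area(
    note: ProcessedNote,
    area: SearchArea,
    cfg: PipelineConfig,
    store: VectorStore,
) -> list[Mention]:
    """Step 3: dictionary matches first (if enabled), then embedding
    matches over the remaining area tokens.

    A token covered by a dictionary match is not re-reported by the
    embedding route; mentions overlapping the anchor are discarded.
    """
    mentions: list[Mention] = []
    occupied: set[int] = set()
    if cfg.use_dictionary and cfg.dictionary is not None and len(cfg.dictionary):
        for start, entry in dictionary_match(
            note, (area.lo, area.hi), cfg.dictionary
        ):
            span = range(start, start + len(entry))
            if area.anchor in span or span[-1] > area.hi:
                continue
            mentions.append(
                Mention(
                    kind="adr",
                    token_index=start,
                    length=len(entry),
                    surface=" ".join(entry),
                    matched_term=" ".join(entry),
                    similarity=1.0,
                    route="dictionary",
                )
            )
            occupied.update(span)
    for i in area.indices():
        if i in occupied:
            continue
        tok = note.tokens[i]
        if tok not in store:
            continue
        hit = matches_above_threshold(store, tok, cfg.adr_terms)
        if hit is not None:
            term, sim = hit
            mentions.append(
                Mention(
                    kind="adr",
                    token_index=i,
                    length=1,
                    surface=tok,
                    matched_term=term,
                    similarity=sim,
                    route="embedding",
                )
            )
    mentions.sort(key=lambda m: (m.token_index, m.route))
    return mentions


def _resegment_with_phrases(
    note: ProcessedNote, store: VectorStore
) -> ProcessedNote:
    """Greedily merge adjacent tokens whose ``a_b`` join is a phrase in
    the (bigram) store's vocabulary."""
    tokens: list[str] = []
    sids: list[int] = []
    pos: list[int] = []
    i = 0
    while i < len(note):
        if (
            i + 1 < len(note)
            and note.tokens[i] + "_" + note.tokens[i + 1] in store
        ):
            tokens.append(note.tokens[i] + "_" + note.tokens[i + 1])
            sids.append(note.sentence_ids[i])
            pos.append(note.source_positions[i])
            i += 2
        else:
            tokens.append(note.tokens[i])
            sids.append(note.sentence_ids[i])
            pos.append(note.source_positions[i])
            i += 1
    return ProcessedNote(
        note_id=note.note_id,
        tokens=tuple(tokens),
        sentence_ids=tuple(sids),
        source_positions=tuple(pos),
    )


def run_note(
    raw: RawNote | ProcessedNote,
    cfg: PipelineConfig,
    store: VectorStore,
    bigram_store: Optional[VectorStore] = None,
    number_lexicon: Optional[NumberLexicon] = None,
) -> NoteResult:
    """Run the full three-step identification on one note.

    ``raw`` may be a :class:`RawNote` (preprocessed here against the
    unigram store's vocabulary) or an already-processed note.  If a
    bigram store is supplied, the token stream is re-segmented with its
    phrase table and matching uses the bigram space; the unigram-only
    path is the default.
    """
    if isinstance(raw, ProcessedNote):
        note = raw
    else:
        note = preprocess_note(
            raw,
            vocab=store,
            number_lexicon=number_lexicon,
            boundary_chars=cfg.boundary_chars,
        )
    match_store = store
    if bigram_store is not None:
        note = _resegment_with_phrases(note, bigram_store)
        match_store = bigram_store

    medications = find_medications(note, cfg, match_store)
    if not medications:
        general = find_general_adr(note, cfg, match_store)
        if general:
            return NoteResult(
                note_id=note.note_id,
                has_adr=True,
                medications=(),
                adrs=tuple(general),
                pairs=(),
                termination="general_adr_only",
            )
        return NoteResult(
            note_id=note.note_id,
            has_adr=False,
            medications=(),
            adrs=(),
            pairs=(),
            termination="no_medication_no_general_adr",
        )

    pairs: list[MedAdrPair] = []
    adrs: list[Mention] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_adrs: set[tuple[int, int]] = set()
    for med in medications:
        if contains_non_adr_keyword(
            note, med.token_index, cfg.non_adr_keywords, cfg.keyword_radius
        ):
            continue  # dose change, not a reaction: skip this anchor
        area = build_search_area(note, med.token_index, cfg)
        for adr in identify_adrs_in_area(note, area, cfg, match_store):
            key = (adr.token_index, adr.length)
            if key not in seen_adrs:
                seen_adrs.add(key)
                adrs.append(adr)
            pair_key = (med.surface, adr.surface)
            if pair_key not in seen_pairs:
                seen_pairs.add(pair_key)
                pairs.append(MedAdrPair(medication=med, adr=adr))

    return NoteResult(
        note_id=note.note_id,
        has_adr=bool(pairs),
        medications=tuple(medications),
        adrs=tuple(adrs),
        pairs=tuple(pairs),
        termination="paired" if pairs else "medication_no_adr",
    )


def run_corpus(
    notes: Iterable[RawNote],
    cfg: PipelineConfig,
    store: VectorStore,
    bigram_store: Optional[VectorStore] = None,
    number_lexicon: Optional[NumberLexicon] = None,
) -> list[NoteResult]:
    """Order-preserving map of :func:`run_note` over the corpus.

    Notes with empty text are excluded (their count is logged), matching
    how empty records are dropped from a test set rather than scored.
    """
    results: list[NoteResult] = []
    n_empty = 0
    for raw in notes:
        if isinstance(raw, RawNote) and raw.is_empty:
            n_empty += 1
            continue
        results.append(
            run_note(
                raw,
                cfg,
                store,
                bigram_store=bigram_store,
                number_lexicon=number_lexicon,
            )
        )
    if n_empty:
        logger.info("excluded %d empty note(s) from the corpus", n_empty)
    return results
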