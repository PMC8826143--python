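import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrin.io import RawNote
from adrin.preprocess import (
    NumberLexicon,
    filter_to_vocabulary,
    normalize_numbers,
    normalize_text,
    preprocess_note,
    strip_doses,
    tokenize,
)
from adrin.synthetic import SyntheticParams, generate_corpus


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Oedeem Bèta", "oedeem beta"),
        ("oedeem beta", "oedeem beta"),
        ("", ""),
        ("Duizélig ß µg", "duizelig ss ug"),
        ("café naïve", "cafe naive"),
    ],
)
def test_normalize_text(raw, expected):
    assert normalize_text(raw) == expected


@given(st.text(max_size=80))
@settings(max_examples=200, deadline=None)
def test_normalize_text_idempotent_and_ascii(text):
    once = normalize_text(text)
    assert normalize_text(once) == once
    assert once == once.lower()
    once.encode("ascii")


@pytest.mark.parametrize(
    "text, tokens, sids",
    [
        (
            "stopt metoprolol; duizelig",
            ["stopt", "metoprolol", "duizelig"],
            [0, 0, 1],
        ),
        ("geen klachten vandaag", ["geen", "klachten", "vandaag"], [0, 0, 0]),
        ("a.b", ["a", "b"], [0, 1]),
        ("a..b", ["a", "b"], [0, 2]),
        ("", [], []),
    ],
)
def test_tokenize(text, tokens, sids):
    got_tokens, got_sids = tokenize(text)
    assert got_tokens == tokens
    assert got_sids == sids


@pytest.mark.parametrize(
    "text, expected_tokens",
    [
        ("metoprolol 50 mg gestopt", ["metoprolol", "gestopt"]),
        ("sinds 2016 klachten", ["sinds", "2016", "klachten"]),
        ("simvastatine 1dd1", ["simvastatine"]),
        ("metoprolol 12,5mg 2dd", ["metoprolol"]),
        ("drinkt 2 liter water", ["drinkt", "2", "liter", "water"]),
    ],
)
def test_strip_doses(text, expected_tokens):
    assert tokenize(strip_doses(text))[0] == expected_tokens


def test_normalize_numbers_english_and_fallback():
    lex = NumberLexicon.english()
    assert normalize_numbers(["16", "and", "18"], lex) == [
        "sixteen",
        "and",
        "eighteen",
    ]
    assert normalize_numbers(["abc"], lex) == ["abc"]
    # outside the lexicon domain: digit-wise spelling
    assert normalize_numbers(["016"], lex) == ["zero", "one", "six"]
    assert normalize_numbers(["1984"], lex) == ["one", "nine", "eight", "four"]


def test_number_lexicon_requires_digits():
    with pytest.raises(ValueError, match="single"):
        NumberLexicon("broken", {"1": "one"})


def test_filter_to_vocabulary():
    vocab = {"metoprolol", "duizelig"}
    assert filter_to_vocabulary(["foo", "metoprolol"], vocab) == (
        ["metoprolol"],
        [1],
    )
    assert filter_to_vocabulary(["metoprolol", "duizelig"], vocab) == (
        ["metoprolol", "duizelig"],
        [0, 1],
    )
    assert filter_to_vocabulary(["x", "y"], vocab) == ([], [])


def test_preprocess_note_composition(dutch_numbers):
    note = RawNote("n1", "p1", __import__("datetime").date(2016, 1, 1),
                   "Stopt Metoprolol 50 mg; duizelig sinds 3 dagen.")
    vocab = {"stopt", "metoprolol", "duizelig", "sinds", "drie", "dagen"}
    out = preprocess_note(note, vocab=vocab, number_lexicon=dutch_numbers)
    assert list(out.tokens) == [
        "stopt", "metoprolol", "duizelig", "sinds", "drie", "dagen",
    ]
    assert list(out.sentence_ids) == [0, 0, 1, 1, 1, 1]
    assert len(out.tokens) == len(out.source_positions)


def test_preprocess_note_empty_and_oov(dutch_numbers):
    import datetime

    empty = RawNote("n1", "p1", datetime.date(2016, 1, 1), "")
    assert len(preprocess_note(empty, vocab={"a"})) == 0
    oov = RawNote("n2", "p1", datetime.date(2016, 1, 1), "volledig onbekend")
    assert len(preprocess_note(oov, vocab={"a"})) == 0


_DOSE_RE = re.compile(r"^\d+(mg|mcg|ug|g|ml|ie)$|^\d+dd\d*$")


def test_no_digits_or_doses_survive_on_synthetic_corpus(dutch_numbers):
    """Across 1,000 generated notes, full preprocessing leaves no
    all-digit token and no dose-grammar remnant."""
    notes, _ = generate_corpus(
        params=SyntheticParams(n_notes=1000, seed=17)
    )
    for note in notes:
        out = preprocess_note(note, number_lexicon=dutch_numbers)
        assert list(out.sentence_ids) == sorted(out.sentence_ids)
        for tok in out.tokens:
            assert not tok.isdigit()
            assert not _DOSE_RE.match(tok)


@given(st.text(max_size=120))
@settings(max_examples=150, deadline=None)
def test_preprocess_invariants_random_text(text):
    out = preprocess_note(normalize_text(text))
    filtered = preprocess_note(
        normalize_text(text), vocab=set(out.tokens[::2])
    )
    assert len(filtered) <= len(out)
    assert list(filtered.sentence_ids) == sorted(filtered.sentence_ids)
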