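import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrin.evaluate import (
    ConfusionCounts,
    compute_metrics,
    evaluate_grid,
    interobserver_agreement,
    score_binary,
    score_mentions,
)
from adrin.io import GoldAnnotation
from adrin.pipeline import MedAdrPair, Mention, NoteResult
from reference import optimal_matching_count


def mention(surface, kind="adr", idx=0, route="embedding"):
    return Mention(
        kind=kind,
        token_index=idx,
        length=1,
        surface=surface,
        matched_term=surface,
        similarity=0.9,
        route=route,
    )


def result(note_id, pairs=(), has_adr=None, extra_adrs=()):
    pair_objs = tuple(
        MedAdrPair(
            medication=mention(m, kind="medication"), adr=mention(a)
        )
        for m, a in pairs
    )
    adrs = tuple(mention(a) for _, a in pairs) + tuple(
        mention(a) for a in extra_adrs
    )
    meds = tuple(mention(m, kind="medication") for m, _ in pairs)
    return NoteResult(
        note_id=note_id,
        has_adr=bool(pairs) if has_adr is None else has_adr,
        medications=meds,
        adrs=adrs,
        pairs=pair_objs,
        termination="paired" if pairs else "no_medication_no_general_adr",
    )


def gold(note_id, pairs=()):
    return GoldAnnotation(
        note_id=note_id,
        has_adr=bool(pairs),
        medications=tuple(m for m, _ in pairs),
        adrs=tuple(a for _, a in pairs),
        pairs=tuple(pairs),
    )


# -- metric arithmetic -------------------------------------------------

def test_metrics_on_reconstructed_binary_table():
    """A 988-note binary table with 237 gold positives and 80 false
    negatives (so tp=157, fp=78, tn=673) gives accuracy 0.84 and
    F1 0.67 at two decimals."""
    m = compute_metrics(ConfusionCounts(tp=157, fp=78, fn=80, tn=673))
    assert m.accuracy == pytest.approx(0.840081, abs=1e-6)
    assert m.f1 == pytest.approx(0.665254, abs=1e-6)
    assert round(m.accuracy, 2) == 0.84
    assert round(m.f1, 2) == 0.67


def test_metrics_zero_denominators_are_undefined():
    m = compute_metrics(ConfusionCounts(0, 0, 0, 10))
    assert m.accuracy == 1.0
    assert m.precision is None  # not silently 0
    assert m.sensitivity is None
    m = compute_metrics(ConfusionCounts(1, 1, 1, 1))
    assert m.accuracy == 0.5
    assert m.f1 == 0.5


counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500),
    st.integers(0, 500), st.integers(0, 500),
)


@given(counts_strategy)
@settings(max_examples=500, deadline=None)
def test_metric_identities(raw):
    tp, fp, fn, tn = raw
    c = ConfusionCounts(tp, fp, fn, tn)
    m = compute_metrics(c)
    n = tp + fp + fn + tn

    def check(value, num, den):
        if den == 0:
            assert value is None
        else:
            assert value == pytest.approx(num / den)

    check(m.accuracy, tp + tn, n)
    check(m.sensitivity, tp, tp + fn)
    check(m.specificity, tn, tn + fp)
    check(m.precision, tp, tp + fp)
    check(m.npv, tn, tn + fn)
    check(m.detection_rate, tp, n)
    check(m.detection_prevalence, tp + fp, n)
    assert m.recall == m.sensitivity
    if m.sensitivity is not None and m.specificity is not None:
        assert m.balanced_accuracy == pytest.approx(
            (m.sensitivity + m.specificity) / 2
        )
    if m.precision is not None and m.recall is not None:
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )


@given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
@settings(max_examples=200, deadline=None)
def test_balanced_accuracy_equals_accuracy_on_balanced_counts(tp, fn, fp):
    # choose tn so that positives (tp+fn) equal negatives (fp+tn)
    tn = tp + fn - fp
    if tn < 0 or tp + fn == 0:
        return
    m = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
    assert m.balanced_accuracy == pytest.approx(m.accuracy)


# -- scoring -----------------------------------------------------------

def test_score_binary_examples():
    golds = [gold(f"n{i}", [("m", "a")] if i < 3 else []) for i in range(10)]
    perfect = [
        result(f"n{i}", [("m", "a")] if i < 3 else []) for i in range(10)
    ]
    c = score_binary(perfect, golds)
    assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 7)
    all_neg = [result(f"n{i}") for i in range(10)]
    c = score_binary(all_neg, golds)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 3, 7)


def test_score_binary_id_mismatch():
    with pytest.raises(ValueError, match="differ"):
        score_binary([result("n1")], [gold("n2")])


def test_score_mentions_examples():
    g = [gold("n1", [("metoprolol", "duizeligheid")])]
    c = score_mentions(
        [result("n1", [("metoprolol", "duizeligheid")])], g, "pair"
    )
    assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 0)
    # both components must match
    c = score_mentions([result("n1", [("metoprolol", "moe")])], g, "pair")
    assert (c.tp, c.fp, c.fn) == (0, 1, 1)
    # notes clean on both sides are the mention-level true negatives
    c = score_mentions(
        [result("n1", [("metoprolol", "duizeligheid")]), result("n2")],
        g + [gold("n2")],
        "pair",
    )
    assert (c.tp, c.tn) == (1, 1)


def test_score_mentions_one_to_one_matching():
    g = [gold("n1", [("m", "a")])]
    r = NoteResult(
        note_id="n1",
        has_adr=True,
        medications=(mention("m", "medication"),),
        adrs=(mention("a"), mention("a", idx=5)),
        pairs=(
            MedAdrPair(mention("m", "medication", 0), mention("a", idx=2)),
            MedAdrPair(mention("m", "medication", 9), mention("a", idx=5)),
        ),
        termination="paired",
    )
    c = score_mentions([r], g, "pair")
    # duplicate identical predictions: one matches, the other is a FP
    assert (c.tp, c.fp, c.fn) == (1, 1, 0)


def test_greedy_matching_is_optimal_for_distinct_strings():
    rng = np.random.default_rng(3)
    universe = [f"t{i}" for i in range(8)]
    for _ in range(200):
        k_pred = int(rng.integers(0, 5))
        k_gold = int(rng.integers(0, 5))
        preds = list(
            rng.choice(universe, size=k_pred, replace=False)
        )
        golds = list(
            rng.choice(universe, size=k_gold, replace=False)
        )
        g = [
            GoldAnnotation(
                "n1",
                bool(golds),
                medications=("m",) if golds else (),
                adrs=tuple(golds),
                pairs=(),
            )
        ]
        r = result("n1", has_adr=bool(preds), extra_adrs=preds)
        c = score_mentions([r], g, "adr")
        assert c.tp == optimal_matching_count(preds, golds)


def test_interobserver_agreement():
    a = [True] * 237 + [False] * 751
    b = list(a)
    for i in range(80):
        b[i] = not b[i]
    assert interobserver_agreement(a, b) == pytest.approx(
        100 * 908 / 988, abs=1e-9
    )
    assert round(interobserver_agreement(a, b), 1) == 91.9
    assert interobserver_agreement(a, a) == 100.0
    assert interobserver_agreement(a, [not x for x in a]) == 0.0
    with pytest.raises(ValueError, match="length"):
        interobserver_agreement([True], [True, False])


# -- version grid ------------------------------------------------------

def test_evaluate_grid_shape_and_determinism(
    oracle_store, resources, small_corpus, dutch_numbers
):
    notes, golds = small_corpus
    notes = notes[:80]
    versions = [f"{n}{s}" for n in "123456" for s in "AB"]
    t1 = evaluate_grid(notes, golds, versions, oracle_store, resources,
                       number_lexicon=dutch_numbers)
    assert len(t1) == 48  # 12 versions x 4 tasks
    assert set(t1["task"]) == {"binary", "medication", "adr", "pair"}
    t2 = evaluate_grid(notes, golds, versions, oracle_store, resources,
                       number_lexicon=dutch_numbers)
    assert t1.to_csv(sep="\t") == t2.to_csv(sep="\t")
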