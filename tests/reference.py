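"""Independent brute-force reference implementations used as oracles.

Everything here re-derives expected behaviour directly from the stated
rules (nested loops, exhaustive enumeration) without sharing code with
the package's implementations, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import itertools


def brute_force_join(records, notes):
    """All (discontinued record, same-patient same-stop-date note) pairs."""
    out = []
    for rec in records:
        if rec.stop_date is None:
            continue
        for note in notes:
            if note.patient_id == rec.patient_id and note.date == rec.stop_date:
                out.append((rec, note))
    return out


def brute_force_threshold_curve(store, term, grid):
    """Match counts by direct all-pairs cosine scan."""
    counts = []
    for g in grid:
        c = 0
        for other in store.tokens:
            if other == term:
                continue
            if store.similarity(term, other) >= g:
                c += 1
        counts.append(c)
    return counts


def brute_force_dictionary_match(tokens, span, entries):
    """Longest-entry-at-each-start scan over an inclusive span."""
    lo, hi = span
    out = []
    for start in range(lo, hi + 1):
        best = None
        for entry in entries:
            stop = start + len(entry)
            if stop - 1 > hi:
                continue
            if tuple(tokens[start:stop]) == tuple(entry):
                if best is None or len(entry) > len(best):
                    best = tuple(entry)
        if best is not None:
            out.append((start, best))
    return out


def _best_term(store, token, terms):
    """Argmax search term strictly above threshold (ties: lexicographic)."""
    best = None
    for st in terms:
        if st.term not in store:
            continue
        sim = store.similarity(token, st.term)
        if sim > st.threshold:
            if best is None or (-sim, st.term) < best:
                best = (-sim, st.term)
    return None if best is None else best[1]


def brute_force_note(note, cfg, store):
    """Direct rule enumeration of the three identification steps.

    Returns (has_adr, termination, set of (med surface, adr surface)
    pairs); written against the stated rules, not the pipeline code.
    """
    toks = note.tokens
    sids = note.sentence_ids
    med_idx = [
        i for i, t in enumerate(toks)
        if t in store and _best_term(store, t, cfg.med_terms) is not None
    ]
    if not med_idx:
        general = [
            t for t in toks
            if t in store
            and _best_term(store, t, cfg.general_adr_terms) is not None
        ]
        if general:
            return True, "general_adr_only", set()
        return False, "no_medication_no_general_adr", set()

    def in_window(j, i):
        """Token j lies in the search window of anchor i (anchor itself
        included; its exclusion from candidacy is applied afterwards)."""
        if cfg.search_area is not None and abs(j - i) > cfg.search_area:
            return False
        if cfg.respect_punctuation and sids[j] != sids[i]:
            return False
        return True

    pairs = set()
    for i in med_idx:
        neighbours = [k for k in (i - 1, i + 1) if 0 <= k < len(toks)]
        if any(toks[k] in cfg.non_adr_keywords for k in neighbours):
            continue
        covered = set()
        if cfg.use_dictionary and cfg.dictionary is not None:
            for start in range(len(toks)):
                # longest entry at this start fully inside the window;
                # only afterwards is an anchor-overlapping match dropped
                best = None
                for entry in cfg.dictionary.entries:
                    span = range(start, start + len(entry))
                    if not span or span[-1] >= len(toks):
                        continue
                    if any(not in_window(j, i) for j in span):
                        continue
                    if tuple(toks[j] for j in span) == entry:
                        if best is None or len(entry) > len(best):
                            best = entry
                if best is not None and i not in range(
                    start, start + len(best)
                ):
                    pairs.add((toks[i], " ".join(best)))
                    covered.update(range(start, start + len(best)))
        for j, t in enumerate(toks):
            if (
                j == i
                or not in_window(j, i)
                or j in covered
                or t not in store
            ):
                continue
            if _best_term(store, t, cfg.adr_terms) is not None:
                pairs.add((toks[i], t))
    if pairs:
        return True, "paired", pairs
    return False, "medication_no_adr", pairs


def optimal_matching_count(preds, golds):
    """Maximum one-to-one matching size by exhaustive permutation."""
    best = 0
    if len(preds) <= len(golds):
        small, large = preds, golds
    else:
        small, large = golds, preds
    for perm in itertools.permutations(range(len(large)), len(small)):
        matched = sum(
            1 for a, b in zip(small, (large[i] for i in perm)) if a == b
        )
        best = max(best, matched)
    return best
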