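# adrin — adverse drug reaction identification in clinical notes

`adrin` extracts **adverse drug reactions (ADRs) and the medications
that triggered them** from short, informal free-text clinical notes —
the kind a physician types after a consultation ("stopt metoprolol
wegens duizeligheid"). ADRs are chronically under-reported in
structured registries; the free text written on a drug's stop date
often holds the reason, but it is noisy, abbreviated and full of
spelling variants. This package is aimed at pharmacovigilance and
clinical-NLP researchers who want a transparent, fully configurable
baseline that needs **no labeled training data**: only a corpus of
unlabeled notes to train word embeddings on, plus small user-editable
term lists.

## Method

Identification runs in three steps per note, after light preprocessing
(lowercasing + transliteration, dose stripping, greedy word
tokenization, number normalization, vocabulary filtering):

1. **Medication anchoring.** Every token *w* is compared against a
   lexicon of medication search terms *t* by cosine similarity in a
   skip-gram embedding space, `cos(v_w, v_t) = v_w·v_t / (|v_w||v_t|)`.
   A token strictly above a term's threshold becomes an anchor; because
   embeddings place misspellings, brand names and synonyms near the
   canonical term, a ~40-term lexicon covers a far larger surface
   vocabulary. If no anchor is found, a fallback search with general
   ADR words ("bijwerking", …) decides between *general ADR mention*
   and *definite negative*.
2. **Search area.** A window of *s* tokens per side (s ∈ {5, 10, ∞}) is
   taken around each anchor, optionally clipped to the anchor's
   sentence. An anchor flanked by a *non-ADR keyword* ("verhoogd",
   "verdubbeld", …) signals a dose change, not a reaction, and is
   skipped.
3. **ADR identification.** Inside the area, two sequential routes fire:
   exact token-sequence string matching against a flat ADR dictionary
   (a stand-in for MedDRA Lowest Level Terms), and embedding similarity
   against ADR search terms. Each hit yields a medication–ADR pair.

The 2 × 3 × 2 grid of settings (dictionary on/off × area × punctuation)
defines twelve pipeline versions `1A … 6B`. The embeddings are
skip-gram with negative sampling (d = 200, window 5, 5 epochs,
vocabulary = tokens occurring ≥ 2 times), trained by the package's own
numba-compiled trainer; a bigram model merges adjacent pairs
co-occurring > 5 times into phrase tokens. An evaluation harness scores
four tasks (binary ADR presence, medication extraction, ADR extraction,
exact pair extraction) with the full metric panel (accuracy, balanced
accuracy, sensitivity/recall, specificity, PPV/precision, NPV, F1,
detection rate, detection prevalence), and a synthetic-corpus generator
with planted co-occurrence clusters makes every stage testable without
clinical data.

## Worked example

```python
import datetime
from adrin import default_resources, make_version, run_note
from adrin.io import RawNote
from adrin.preprocess import NumberLexicon
from adrin.synthetic import default_clusters, make_oracle_store

store = make_oracle_store(default_clusters(), within_sim=0.81)
cfg = make_version("3B", **default_resources(use_dictionary=False))
note = RawNote("n1", "p1", datetime.date(2016, 3, 1),
               "Stopt met metoprolol 50 mg wegens veel last van "
               "duizellig. Controle over 3 maanden.")
res = run_note(note, cfg, store, number_lexicon=NumberLexicon.dutch())
print("has_adr:", res.has_adr)
for p in res.pairs:
    print(f"pair: {p.medication.surface} -> {p.adr.surface} "
          f"(term {p.adr.matched_term!r}, cosine {p.adr.similarity:.2f}, "
          f"{p.adr.route})")
```

prints

```
has_adr: True
pair: metoprolol -> duizellig (term 'duizelig', cosine 0.81, embedding)
```

The dose (`50 mg`) is stripped, the misspelled *duizellig* is matched
to the search term *duizelig* at cosine 0.81 (the misspelling sits in
the same embedding cluster), and version 3B's 10-word
punctuation-respecting window pairs it with the anchored *metoprolol*.
The same flow scales to corpora via `run_corpus` / `evaluate_grid`, or
from the shell:

```bash
adrin simulate --n-notes 2000 --seed 1 --out-notes notes.jsonl --out-gold gold.jsonl
adrin train-embeddings --notes notes.jsonl --out vecs.txt
adrin run --notes notes.jsonl --version 3B --unigram vecs.txt --out results.jsonl
adrin evaluate --results results.jsonl --gold gold.jsonl --out metrics.tsv
adrin grid --notes notes.jsonl --gold gold.jsonl --unigram vecs.txt --out grid.tsv
```

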