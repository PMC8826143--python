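# Methods

## Scope and model

`adrin` treats ADR extraction as a lexicon-anchored matching problem in
a learned similarity space, not as supervised sequence labeling. The
operating assumptions are:

* an ADR, for this tool, is an unwanted event that led to
  discontinuation of a prescribed drug, and the note written on the
  stop date mentions both the drug and the event;
* patients take what is prescribed (compliance), so a drug mention is a
  valid anchor for an event search;
* spelling variants, brand names and synonyms of a term occupy nearby
  points in a skip-gram embedding space trained on a large unlabeled
  corpus of the same register, so a short curated search-term list plus
  a per-term cosine threshold expands to the realistic surface
  vocabulary;
* negation is *not* modeled: "geen bijwerkingen" counts as a general
  ADR mention. This is a deliberate fidelity choice, not an oversight.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `search_area` | 10 (version 3/4) | tokens on **each** side of the anchor; `None` = whole note. "s words around the medication" is read symmetrically; a total-width reading can be emulated by halving. |
| `respect_punctuation` | version-dependent | clip the window to the anchor's sentence segment. Boundary set `{. ; ! ?}`; commas are soft separators in this register and do not break segments. |
| `use_dictionary` | A-versions | exact token-sequence matching against a flat ADR dictionary, run *before* the embedding route; on a token matched by both, the dictionary route wins. |
| term thresholds | 0.60 | per-term cosine cut-offs, strict inequality ("above the threshold"). The shipped fixtures use a uniform 0.6; per-term values belong in the TSV. |
| `keyword_radius` | 1 | "immediately before or after the medication" read literally: only the two adjacent tokens can veto an anchor. |
| embedding | d=200, window 5, 5 epochs | skip-gram/negative sampling; vocabulary keeps tokens with corpus frequency ≥ 2 ("more than once"); phrase pairs merge at co-occurrence ≥ 6 ("more than five times"). Negative samples (5), subsampling (1e-3) and the linear learning-rate schedule (0.025 → 1e-4) are standard defaults recorded in `EmbeddingConfig`. |

Design decisions where the contract was genuinely open:

* **General-ADR fallback semantics.** Only the negative branch is fully
  determined (no medication and no general term ⇒ automatic negative).
  When general terms *are* found without a medication the note is
  marked positive with termination `general_adr_only` and no pairs —
  otherwise the fallback step would have no effect at all. This touches
  only the binary task.
* **Multiple anchors** are processed independently; the non-ADR keyword
  veto silences one anchor, not the note. Duplicate pairs are
  deduplicated on (medication surface, ADR surface).
* **Unigram vs bigram store at identification time.** Preprocessing
  filters against the unigram vocabulary and matching runs in the
  unigram space by default. If a bigram store is supplied, the token
  stream is greedily re-segmented with its phrase table and matching
  moves to that space; this path exists but is not the tested default,
  since how the two models were combined in the original prototype is
  underdetermined.
* **Tie-breaking** everywhere is argmax by similarity, then
  lexicographic by term, so runs are exactly reproducible.
* **A/B decomposition.** Removing the dictionary (B versions) removes
  exactly the dictionary-routed mentions, with one nuance: a token
  matched by *both* routes is reported as dictionary-route in A and as
  embedding-route in B. The decomposition test therefore checks
  set-inclusion in both directions with that collision rule, not naive
  set difference.
* **Threshold curves** use ≥ on the grid (so the −1 endpoint counts the
  whole vocabulary) while identification uses strict >; the asymmetry
  is intentional and documented at both call sites.

## Evaluation

Binary scoring is a plain note-level 2×2. For the mention tasks
(medication / ADR / pair), predictions are matched to gold strings
greedily, one-to-one, in note order, by exact normalized-string
equality (pairs need both components); tp/fp come from predictions, fn
from unmatched gold, and **tn counts notes clean on both sides**. A 2×2
table for an extraction task is not canonical; this reconstruction is
the module's stated contract and is what the property tests pin down
(greedy = optimal when strings within a note are distinct). Ratios with
zero denominators are *undefined* and serialize as `NA`, never 0.
Interobserver agreement is raw percent agreement, no chance correction.

## Synthetic data

The generator emulates the statistical shape of stop-date cardiology
notes: log-normal record lengths (median 43 tokens, IQR ≈ 26–70), ~24%
positive rate, doses ("50 mg", "1dd1") and digit tokens injected at
realistic rates, and an informal sentence-chunk structure joined by
periods and commas.

Lexical structure is planted through **clusters** (canonical term +
misspellings/brands/synonyms) and **slot-substitution templates**: any
member can fill its cluster's slot, so members share context
distributions and skip-gram training pulls them together. Each ADR
cluster additionally owns two companion words, which keeps symptom
clusters apart; medication clusters deliberately *share* their context
templates, so drug names of different groups may blur together — which
is harmless here, because an anchor is an anchor regardless of which
medication term identified it, and it mirrors how drug names co-occur
in real prescription talk. Dose-change keywords also appear in
non-medication contexts ("bloeddruk verhoogd gemeten") so their vectors
do not collapse onto the drug direction. A small color/symptom
demonstration cluster ("rood" co-occurring with irritation words, other
colors among themselves) exercises the domain-specificity of the
embeddings.

Positive notes plant one medication→ADR event at a sampled signed token
offset (default distribution concentrated on 1–8, 10% crossing a
sentence boundary); confounder notes plant a keyword flanking the
medication plus a nearby bare symptom word, gold-negative. The
medication never sits at a chunk boundary, so neighbouring chunks
cannot accidentally veto an anchor.

`make_oracle_store` replaces training entirely for deterministic tests:
member vectors are explicit combinations of orthonormal cluster and
member bases, giving *exact* within-cluster cosine (0.81 by default,
between the 0.6 threshold and self-similarity 1) and exactly orthogonal
clusters. With it, every planted event whose offset fits the active
search area is recovered with precision = recall = 1.0 by
construction — the pipeline's logic, not the embedding quality, is
what's under test. Recovery runs use an offset distribution bounded by
the 5-word area and no cross-sentence events, which is the stated
condition of that check.

What the generator does **not** emulate — and hence what passing tests
do not show about real notes: abbreviation conventions, free spelling
variation outside the planted variants, negation and speculation,
multi-drug polypharmacy interactions, longitudinal patient structure,
and genuinely out-of-lexicon ADRs. Numbers obtained on synthetic
corpora characterize the machinery, not expected clinical performance.

## Numerical choices

* Training is single-threaded and bit-reproducible for a fixed seed
  (one linear-congruential stream inside the compiled loop; sigmoid via
  a 1000-entry table clipped at ±6, as is conventional for this model
  family). Vectors are float32; similarity queries upcast to float64.
* Degenerate inputs: empty notes yield an empty `ProcessedNote` and a
  negative result with termination `no_medication_no_general_adr`;
  corpora with empty notes drop them with a logged count; zero vectors
  are rejected at store construction; out-of-vocabulary search terms
  are skipped rather than raised, since fixture lexicons may exceed a
  small trained vocabulary.
* Problem sizes in the test and acceptance runs (20,000-note training
  corpus, 2,000-note recovery corpus, 1,000-note audits) were chosen as
  the smallest scales at which skip-gram statistics are stable; the
  full suite runs in well under two minutes.

## Known limitations

Misses concentrate where the paper trail predicts them: events whose
offset exceeds the active window, events across sentence boundaries
under punctuation-respecting versions, and variants whose trained
similarity lands under the threshold. The dictionary route matches
exact token sequences only — misspellings are the embedding route's
job. General-ADR terms absent from the embedding vocabulary silently
disable the fallback. Mention-level false positives include companion
words that legitimately embed near symptom terms; the binary task is
robust to them, the pair task is not.
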