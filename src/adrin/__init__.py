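"""adrin: adverse drug reaction identification in free-text clinical notes.

A configurable pipeline that finds medications and the adverse drug
reactions (ADRs) they triggered in short free-text notes, using cosine
similarity in skip-gram word-embedding space against expandable search
term lists, windowed search areas around medication anchors, non-ADR
keyword filtering, and optional dictionary string matching — plus the
evaluation harness (four tasks, full metric panel) and a synthetic
corpus generator that makes every stage testable without clinical data.
"""

from .embedding import (
    EmbeddingConfig,
    ThresholdCurve,
    VectorStore,
    calibrate_threshold,
    cosine_similarity,
    matches_above_threshold,
    most_similar,
    train_bigram,
    train_unigram,
)
from .evaluate import (
    ConfusionCounts,
    MetricSet,
    compute_metrics,
    evaluate_grid,
    interobserver_agreement,
    score_binary,
    score_mentions,
    score_task,
)
from .io import (
    FormatError,
    GoldAnnotation,
    MedicationRecord,
    RawNote,
    join_stops_to_notes,
    read_gold,
    read_medication_records,
    read_notes,
    read_vector_store,
    write_gold,
    write_notes,
    write_vector_store,
)
from .lexicon import (
    DictionaryLexicon,
    NonAdrKeywordList,
    SearchTerm,
    SearchTermSet,
    contains_non_adr_keyword,
    dictionary_match,
    load_dictionary,
    load_keywords,
    load_search_terms,
)
from .pipeline import (
    MedAdrPair,
    Mention,
    NoteResult,
    PipelineConfig,
    build_search_area,
    find_general_adr,
    find_medications,
    identify_adrs_in_area,
    make_version,
    run_corpus,
    run_note,
)
from .preprocess import (
    NumberLexicon,
    ProcessedNote,
    filter_to_vocabulary,
    normalize_numbers,
    normalize_text,
    preprocess_note,
    strip_doses,
    tokenize,
)
from .synthetic import (
    ClusterSpec,
    SyntheticParams,
    corpus_stats,
    default_clusters,
    generate_corpus,
    load_clusters,
    make_oracle_store,
)

__version__ = "0.1.0"


def default_resources(use_dictionary: bool = True) -> dict:
    """The shipped term resources, ready for :func:`make_version`."""
    from .lexicon import builtin_path

    res: dict = {}
    with builtin_path("med_terms.tsv") as p:
        res["med_terms"] = load_search_terms(p, "medication")
    with builtin_path("adr_terms.tsv") as p:
        res["adr_terms"] = load_search_terms(p, "adr")
    with builtin_path("general_terms.tsv") as p:
        res["general_adr_terms"] = load_search_terms(p, "general_adr")
    with builtin_path("non_adr_keywords.txt") as p:
        res["non_adr_keywords"] = load_keywords(p)
    if use_dictionary:
        with builtin_path("dictionary.txt") as p:
            res["dictionary"] = load_dictionary(p)
    return res
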