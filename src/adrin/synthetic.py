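"""Synthetic clinical-note corpora with known gold annotations.

Real discharge-style cardiology notes are short, informal and private;
this module emulates their statistical shape (median ~43 tokens, IQR
26-70 per record) with fully known ground truth, so that embeddings can
be trained, thresholds calibrated and the whole pipeline validated
without clinical data.

Two mechanisms matter:

* **Co-occurrence by slot substitution.**  Tokens are organized in
  clusters (a canonical drug or symptom name plus misspellings, brand
  names and synonyms).  Sentence templates carry one slot per cluster
  role; any member can fill its slot, so members of a cluster share
  context distributions and a skip-gram model draws them together.
  ADR clusters additionally get two cluster-specific companion words,
  which keeps different symptom clusters apart in embedding space.
* **Planted events.**  A positive note contains a medication member and
  an ADR member at a sampled token offset (optionally across a sentence
  boundary); the gold annotation records the pair.  Confounder notes
  plant a non-ADR keyword (dose-change word) immediately next to the
  medication plus a nearby ADR-cluster word, with gold ``has_adr =
  false``.  Doses and digit tokens are injected at configurable rates.

:func:`make_oracle_store` builds an *analytic* embedding table over the
same clusters (exact within-cluster cosine, orthogonal across clusters)
for deterministic pipeline tests that do not depend on training noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .embedding import VectorStore
from .io import GoldAnnotation, RawNote
from .preprocess import NumberLexicon, normalize_text, tokenize

__all__ = [
    "ROLES",
    "ClusterSpec",
    "SyntheticParams",
    "default_clusters",
    "load_clusters",
    "generate_corpus",
    "make_oracle_store",
    "corpus_stats",
    "template_vocabulary",
]

ROLES = (
    "medication",
    "adr",
    "non_adr_keyword",
    "filler",
    "number",
    "demo",
)


@dataclass(frozen=True)
class ClusterSpec:
    """A token cluster: canonical member first, then variants."""

    cluster_id: str
    members: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if self.role not in ROLES:
            raise ValueError(f"unknown cluster role {self.role!r}")
        if len(self.members) < 1:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(
                f"cluster {self.cluster_id!r} has duplicate members"
            )

    @property
    def canonical(self) -> str:
        return self.members[0]

    @property
    def variants(self) -> tuple[str, ...]:
        return self.members[1:]


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters; the defaults emulate the target corpus.

    ``p_adr_note`` mirrors the ~24% positive rate of a labeled stop-date
    test set; note lengths are log-normal with median 43 tokens and a
    log-sigma that reproduces the 26-70 interquartile range.
    """

    n_notes: int = 1000
    p_adr_note: float = 0.24
    adr_distance_distribution: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.18, 2: 0.18, 3: 0.14, 4: 0.12, 5: 0.10, 6: 0.08,
            7: 0.05, 8: 0.05, -1: 0.04, -2: 0.03, -3: 0.02, -4: 0.01,
        }
    )
    p_cross_sentence: float = 0.10
    p_non_adr_confounder: float = 0.10
    p_misspelling: float = 0.15
    dose_rate: float = 0.30
    note_length_median: float = 43.0
    note_length_log_sigma: float = 0.735
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        for name in (
            "p_adr_note",
            "p_cross_sentence",
            "p_non_adr_confounder",
            "p_misspelling",
            "dose_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_adr_note + self.p_non_adr_confounder > 1.0:
            raise ValueError(
                "p_adr_note + p_non_adr_confounder must not exceed 1"
            )
        dist = self.adr_distance_distribution
        if not dist:
            raise ValueError("adr_distance_distribution is empty")
        if any(d == 0 for d in dist):
            raise ValueError("offset 0 is not a valid planting distance")
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(
                f"adr_distance_distribution must sum to 1, sums to {total}"
            )
        if self.note_length_median <= 0 or self.note_length_log_sigma < 0:
            raise ValueError("invalid note-length distribution parameters")


# ---------------------------------------------------------------------
# Template library (Dutch-like token inventory)
# ---------------------------------------------------------------------

# Shared medication-context words: every medication cluster uses the
# same templates, which is deliberate — drug names of different groups
# are allowed to blur together (the pipeline matches whichever term
# identifies them), while ADR clusters must stay separable.
_MED_PRE = (
    ("gestart", "met"),
    ("stopt", "met"),
    ("gestopt", "met"),
    ("staakt",),
)
_MED_ONLY_CHUNKS = (
    ("gestart", "met", "{MED}"),
    ("{MED}", "gestopt"),
    ("gebruikt", "{MED}", "dagelijks"),
    ("medicatie", "{MED}", "gecontinueerd"),
    ("recept", "{MED}", "meegegeven"),
)
_MED_POST = (("gestopt",), ("gestaakt",), ("op", "verzoek"))

# Words allowed between a planted medication and its ADR.
_GAP_POOL = (
    "wegens", "vanwege", "door", "klachten", "last", "van", "veel",
    "erg", "nu", "sinds", "kort", "toenemend", "hinder", "bij", "na",
    "en", "ook", "nog",
)

# Companion-word pool for ADR clusters (two per cluster, assigned in
# order); these give each symptom cluster its own context signature.
_COMPANION_POOL = (
    "opstaan", "houding", "maag", "eetlust", "prikkelend", "keel",
    "enkels", "vochtophoping", "voorhoofd", "drukkend", "futloos",
    "energie", "aanhoudend", "wisselend", "fors", "gering",
)

_FILLER_CHUNKS = (
    ("patient", "komt", "voor", "controle"),
    ("voelt", "zich", "goed"),
    ("bloeddruk", "goed", "gereguleerd"),
    ("ecg", "geen", "afwijkingen"),
    ("vervolg", "over", "{NUM}", "maanden"),
    ("telefonisch", "consult", "gepland"),
    ("uitslag", "besproken", "en", "akkoord"),
    ("sinds", "{YEAR}", "bekend", "bij", "cardioloog"),
    ("conditie", "stabiel", "nog"),
    ("geen", "nieuwe", "klachten", "nu"),
    ("labwaarden", "binnen", "norm"),
    ("afspraak", "poli", "cardiologie"),
    ("echo", "laat", "goede", "functie", "zien"),
    # dose-change words in non-medication contexts: keeps their vectors
    # from collapsing onto the drug-name direction
    ("bloeddruk", "verhoogd", "gemeten"),
    ("cholesterol", "verlaagd", "bij", "controle"),
    ("frequentie", "verdubbeld", "na", "overleg"),
    ("medicatie", "afgebouwd", "geleidelijk"),
    ("dosis", "gehalveerd", "eerder"),
    ("beleid", "opgehoogd", "stapsgewijs"),
)

_NUM_TOKENS = ("2", "3", "6", "12")
_YEAR_TOKENS = ("2014", "2015", "2016", "2017", "2018")
_DOSE_AMOUNTS = ("5", "10", "25", "40", "50", "80", "100")
_DOSE_UNITS = ("mg", "ml")

_RED_CHUNKS = (
    ("huid", "{SYM}", "rood", "{SYM}"),
    ("rood", "en", "{SYM}"),
    ("{SYM}", "rood", "bij", "inspanning"),
)
_COLOR_CHUNKS = (
    ("verkleuring", "{COL}", "{COL}", "{COL}"),
    ("{COL}", "en", "{COL}", "plek"),
)

_P_DEMO_RED = 0.04
_P_DEMO_COLOR = 0.04
# negative-note subtype mix: medication-only / symptom-only / pure filler
_NEG_MIX = (0.25, 0.15, 0.60)


def template_vocabulary() -> set[str]:
    """Every non-cluster token the generator can emit (written numbers
    included), i.e. the filler vocabulary of the synthetic language."""
    vocab: set[str] = set()
    for group in (
        _MED_PRE,
        _MED_ONLY_CHUNKS,
        _MED_POST,
        _FILLER_CHUNKS,
        _RED_CHUNKS,
        _COLOR_CHUNKS,
    ):
        for chunk in group:
            for tok in chunk:
                if not tok.startswith("{"):
                    vocab.add(tok)
    vocab.update(_GAP_POOL)
    vocab.update(_COMPANION_POOL)
    return vocab


def _number_words() -> set[str]:
    lex = NumberLexicon.dutch()
    words: set[str] = set()
    for tok in _NUM_TOKENS + _YEAR_TOKENS + _DOSE_AMOUNTS:
        words.update(lex.to_words(tok))
    return words


def load_clusters(path) -> list[ClusterSpec]:
    """Load cluster specs from YAML (list of {cluster_id, members, role})."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [
        ClusterSpec(
            cluster_id=c["cluster_id"],
            members=tuple(c["members"]),
            role=c["role"],
        )
        for c in raw
    ]


def default_clusters(include_support: bool = True) -> list[ClusterSpec]:
    """The shipped Dutch-like cluster fixture.

    Content clusters (drugs, symptoms, dose-change keywords, color/
    symptom demo) come from the packaged ``clusters.yaml``; with
    ``include_support`` the template vocabulary and written numbers are
    appended as ``filler`` / ``number`` clusters so that an oracle store
    built from the result covers every token the generator emits.
    """
    ref = resources.files("adrin.data").joinpath("clusters.yaml")
    with resources.as_file(ref) as path:
        clusters = load_clusters(path)
    if include_support:
        content = {m for c in clusters for m in c.members}
        filler = sorted(template_vocabulary() - content)
        numbers = sorted(_number_words() - content)
        clusters.append(
            ClusterSpec("filler", tuple(filler), "filler")
        )
        clusters.append(
            ClusterSpec("numbers", tuple(numbers), "number")
        )
    return clusters


def _check_clusters(clusters: Sequence[ClusterSpec]) -> None:
    seen: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            if m in seen:
                raise ValueError(
                    f"member {m!r} appears in clusters {seen[m]!r} "
                    f"and {c.cluster_id!r}"
                )
            seen[m] = c.cluster_id
    roles = {c.role for c in clusters}
    if "medication" not in roles or "adr" not in roles:
        raise ValueError(
            "clusters must contain at least one medication and one adr "
            "cluster"
        )


def _companions(adr_clusters: Sequence[ClusterSpec]) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    pool = _COMPANION_POOL
    for i, c in enumerate(adr_clusters):
        a = pool[(2 * i) % len(pool)]
        b = pool[(2 * i + 1) % len(pool)]
        out[c.cluster_id] = (a, b)
    return out


class _NoteBuilder:
    """Assembles one note from sentence chunks and renders raw text."""

    def __init__(self, rng: np.random.Generator, params: SyntheticParams):
        self.rng = rng
        self.params = params

    def _pick(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def _member(self, cluster: ClusterSpec) -> str:
        if cluster.variants and self.rng.random() < self.params.p_misspelling:
            return self._pick(cluster.variants)
        return cluster.canonical

    def _fill(self, chunk: Sequence[str], symptoms=None, colors=None
              ) -> list[str]:
        out: list[str] = []
        for tok in chunk:
            if tok == "{NUM}":
                out.append(self._pick(_NUM_TOKENS))
            elif tok == "{YEAR}":
                out.append(self._pick(_YEAR_TOKENS))
            elif tok == "{SYM}":
                out.append(self._member(symptoms))
            elif tok == "{COL}":
                out.append(self._member(colors))
            else:
                out.append(tok)
        return out

    def _dose(self) -> list[str]:
        return [self._pick(_DOSE_AMOUNTS), self._pick(_DOSE_UNITS)]

    def med_chunk(self, med: str) -> list[str]:
        chunk = [med if t == "{MED}" else t
                 for t in self._pick(_MED_ONLY_CHUNKS)]
        if self.rng.random() < self.params.dose_rate:
            i = chunk.index(med)
            chunk[i + 1:i + 1] = self._dose()
        return chunk

    def event_chunk(
        self, med: str, adr: str, offset: int, cross_sentence: bool,
        companions: tuple[str, str],
    ) -> list[str]:
        """Medication and ADR mention at the given token offset.

        ``offset`` is the signed token distance ADR - medication in the
        note's word-token stream (doses do not count: they are stripped
        before tokens are formed).  The medication never sits at a chunk
        boundary, so a neighbouring chunk can never plant an accidental
        keyword next to it.
        """
        gap = [self._pick(_GAP_POOL) for _ in range(abs(offset) - 1)]
        if cross_sentence:
            gap.insert(len(gap) // 2, ".")
        if offset > 0:
            chunk = list(self._pick(_MED_PRE)) + [med] + gap + [adr]
            if self.rng.random() < 0.5:
                chunk.append(self._pick(companions))
        else:
            chunk = [self._pick(companions), adr] + gap + [med]
            chunk += list(self._pick(_MED_POST))
        if self.rng.random() < self.params.dose_rate:
            i = chunk.index(med)
            chunk[i + 1:i + 1] = self._dose()
        return chunk

    def adr_chunk(self, adr: str, companions: tuple[str, str]) -> list[str]:
        c1, c2 = companions
        patterns = (
            [c1, adr, c2],
            [adr, c1],
            [c2, adr],
            ["last", "van", adr, c1],
        )
        return list(self._pick(patterns))

    def confounder_chunk(
        self, med: str, keyword: str, adr: str
    ) -> list[str]:
        """Keyword immediately next to the medication, ADR word nearby."""
        if self.rng.random() < 0.5:
            head = [keyword, med]
        else:
            head = [med, keyword]
        gap = [self._pick(("na", "bij", "en", "ook", "nog"))
               for _ in range(int(self.rng.integers(1, 3)))]
        return head + gap + [adr]

    def filler_chunk(self) -> list[str]:
        return self._fill(self._pick(_FILLER_CHUNKS))

    def render(self, chunks: list[list[str]]) -> str:
        parts = []
        for chunk in chunks:
            text = " ".join(chunk).replace(" .", ".")
            parts.append(text)
        out = parts[0]
        for p in parts[1:]:
            sep = ". " if self.rng.random() < 0.7 else ", "
            out += sep + p
        return out + "."


def generate_corpus(
    clusters: Optional[Sequence[ClusterSpec]] = None,
    params: SyntheticParams = SyntheticParams(),
) -> tuple[list[RawNote], list[GoldAnnotation]]:
    """Generate ``params.n_notes`` notes with gold annotations.

    Deterministic given ``params.seed``.  Positive notes carry one
    planted medication->ADR event; confounder notes a keyword-guarded
    medication plus a bare symptom word (gold negative); the remaining
    notes mention a drug only, a symptom only, or neither.
    """
    if clusters is None:
        clusters = default_clusters()
    clusters = list(clusters)
    _check_clusters(clusters)

    med_clusters = [c for c in clusters if c.role == "medication"]
    adr_clusters = [c for c in clusters if c.role == "adr"]
    kw_clusters = [c for c in clusters if c.role == "non_adr_keyword"]
    demo = {c.cluster_id: c for c in clusters if c.role == "demo"}
    symptoms = demo.get("demo_symptoms")
    colors = demo.get("demo_colors")
    companions = _companions(adr_clusters)

    rng = np.random.default_rng(params.seed)
    builder = _NoteBuilder(rng, params)

    offsets = sorted(params.adr_distance_distribution)
    offset_p = np.array(
        [params.adr_distance_distribution[o] for o in offsets]
    )
    offset_p = offset_p / offset_p.sum()

    mu = math.log(params.note_length_median)
    base_date = date(2016, 1, 1)

    notes: list[RawNote] = []
    gold: list[GoldAnnotation] = []
    for i in range(params.n_notes):
        note_id = f"n{i:06d}"
        patient_id = f"p{int(rng.integers(1, 80000)):05d}"
        note_date = base_date + timedelta(days=int(rng.integers(0, 1000)))

        target = int(
            rng.lognormal(mean=mu, sigma=params.note_length_log_sigma)
        )
        target = max(target, 5)

        u = rng.random()
        required: Optional[list[str]] = None
        annotation: GoldAnnotation
        if u < params.p_adr_note:
            med_cluster = builder._pick(med_clusters)
            adr_cluster = builder._pick(adr_clusters)
            med = builder._member(med_cluster)
            adr = builder._member(adr_cluster)
            offset = offsets[
                int(rng.choice(len(offsets), p=offset_p))
            ]
            cross = rng.random() < params.p_cross_sentence
            required = builder.event_chunk(
                med, adr, offset, cross, companions[adr_cluster.cluster_id]
            )
            annotation = GoldAnnotation(
                note_id=note_id,
                has_adr=True,
                medications=(med,),
                adrs=(adr,),
                pairs=((med, adr),),
            )
        elif u < params.p_adr_note + params.p_non_adr_confounder and kw_clusters:
            med = builder._member(builder._pick(med_clusters))
            keyword = builder._pick(builder._pick(kw_clusters).members)
            adr = builder._member(builder._pick(adr_clusters))
            required = builder.confounder_chunk(med, keyword, adr)
            annotation = GoldAnnotation(note_id=note_id, has_adr=False)
        else:
            v = rng.random()
            if v < _NEG_MIX[0]:
                med = builder._member(builder._pick(med_clusters))
                required = builder.med_chunk(med)
            elif v < _NEG_MIX[0] + _NEG_MIX[1]:
                adr_cluster = builder._pick(adr_clusters)
                required = builder.adr_chunk(
                    builder._member(adr_cluster),
                    companions[adr_cluster.cluster_id],
                )
            annotation = GoldAnnotation(note_id=note_id, has_adr=False)

        chunks: list[list[str]] = []
        n_tokens = len(required) if required else 0
        while n_tokens < target:
            chunk = builder.filler_chunk()
            chunks.append(chunk)
            n_tokens += len(chunk)
        if symptoms is not None and rng.random() < _P_DEMO_RED:
            chunks.append(builder._fill(builder._pick(_RED_CHUNKS),
                                        symptoms=symptoms))
        if colors is not None and rng.random() < _P_DEMO_COLOR:
            chunks.append(builder._fill(builder._pick(_COLOR_CHUNKS),
                                        colors=colors))
        if required is not None:
            pos = int(rng.integers(0, len(chunks) + 1))
            chunks.insert(pos, required)
        if not chunks:
            chunks.append(builder.filler_chunk())

        notes.append(
            RawNote(
                note_id=note_id,
                patient_id=patient_id,
                date=note_date,
                text=builder.render(chunks),
            )
        )
        gold.append(annotation)
    return notes, gold


def make_oracle_store(
    clusters: Sequence[ClusterSpec],
    within_sim: float = 0.81,
    cross_sim: float = 0.0,
    dim: Optional[int] = None,
) -> VectorStore:
    """Analytic embedding table with exact cluster geometry.

    Every member vector is ``sqrt(cross) * e0 + sqrt(within - cross) *
    e_cluster + sqrt(1 - within) * e_member`` over orthonormal bases, so
    same-cluster cosines equal ``within_sim`` exactly, cross-cluster
    cosines equal ``cross_sim``, and self-similarity is 1.  ``dim=None``
    uses the smallest dimension that hosts the required bases.
    """
    if not (0.0 <= cross_sim < within_sim <= 1.0):
        raise ValueError(
            "need 0 <= cross_sim < within_sim <= 1, got "
            f"cross={cross_sim}, within={within_sim}"
        )
    _check_clusters(clusters)
    n_members = sum(len(c.members) for c in clusters)
    needed = len(clusters) + n_members + (1 if cross_sim > 0 else 0)
    if dim is None:
        dim = needed
    if dim < needed:
        raise ValueError(
            f"dim={dim} too small: {needed} orthogonal bases required "
            f"for {len(clusters)} clusters with {n_members} members"
        )

    a0 = math.sqrt(cross_sim)
    a1 = math.sqrt(within_sim - cross_sim)
    a2 = math.sqrt(1.0 - within_sim)
    tokens: list[str] = []
    vectors = np.zeros((n_members, dim), dtype=np.float32)
    axis = 1 if cross_sim > 0 else 0
    row = 0
    member_axis = axis + len(clusters)
    for ci, cluster in enumerate(clusters):
        for m in cluster.members:
            v = np.zeros(dim, dtype=np.float32)
            if cross_sim > 0:
                v[0] = a0
            v[axis + ci] = a1
            v[member_axis] = a2
            member_axis += 1
            tokens.append(m)
            vectors[row] = v
            row += 1
    return VectorStore(tokens, vectors)


def corpus_stats(notes: Sequence[RawNote]) -> dict[str, float]:
    """Descriptive statistics of a corpus (token counts per record).

    Tokens are counted on the normalized, tokenized text (no vocabulary
    filtering), matching how record lengths are usually reported.
    """
    if not notes:
        raise ValueError("cannot summarize an empty corpus")
    lengths = []
    vocab: set[str] = set()
    for n in notes:
        toks, _ = tokenize(normalize_text(n.text))
        lengths.append(len(toks))
        vocab.update(toks)
    arr = np.array(lengths, dtype=np.float64)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n_records": len(notes),
        "unique_tokens": len(vocab),
        "tokens_mean": float(arr.mean()),
        "tokens_sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "tokens_median": float(med),
        "tokens_q1": float(q1),
        "tokens_q3": float(q3),
    }
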