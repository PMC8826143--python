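"""Scoring pipeline output against gold annotations.

Four tasks are scored: (1) binary note-level ADR presence, (2)
extraction of the triggering medication, (3) extraction of the ADR, and
(4) exact extraction of the medication-ADR pair.  Mention-level tasks
use greedy one-to-one matching of predicted surfaces to gold strings by
exact normalized equality; their true negatives are counted at note
level (a note clean on both sides), which is stated here as this
package's reconstruction of a 2x2 table for an extraction task.

Every ratio with a zero denominator is *undefined* (serialized "NA"),
never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import GoldAnnotation
from .pipeline import NoteResult, PipelineConfig
from .preprocess import normalize_text

__all__ = [
    "TASKS",
    "ConfusionCounts",
    "MetricSet",
    "score_binary",
    "score_mentions",
    "score_task",
    "compute_metrics",
    "interobserver_agreement",
    "evaluate_grid",
]

TASKS = ("binary", "medication", "adr", "pair")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The full metric panel; ``None`` marks an undefined (0/0) ratio."""

    accuracy: Optional[float]
    balanced_accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    detection_rate: Optional[float]
    detection_prevalence: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Metric panel from a 2x2 table.

    precision is the positive predictive value; recall equals
    sensitivity; detection rate = tp/n and detection prevalence =
    (tp+fp)/n.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.n
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    balanced = (
        (sensitivity + specificity) / 2
        if sensitivity is not None and specificity is not None
        else None
    )
    f1 = (
        _ratio(2 * precision * sensitivity, precision + sensitivity)
        if precision is not None and sensitivity is not None
        else None
    )
    return MetricSet(
        accuracy=_ratio(tp + tn, n),
        balanced_accuracy=balanced,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        npv=npv,
        recall=sensitivity,
        f1=f1,
        detection_rate=_ratio(tp, n),
        detection_prevalence=_ratio(tp + fp, n),
    )


def _index_results(
    results: Sequence[NoteResult], gold: Sequence[GoldAnnotation]
) -> list[tuple[NoteResult, GoldAnnotation]]:
    by_id = {g.note_id: g for g in gold}
    missing = [r.note_id for r in results if r.note_id not in by_id]
    extra = set(by_id) - {r.note_id for r in results}
    if missing or extra:
        raise ValueError(
            "note ids of results and gold differ; "
            f"unannotated: {sorted(missing)[:10]}, "
            f"unpredicted: {sorted(extra)[:10]}"
        )
    return [(r, by_id[r.note_id]) for r in results]


def score_binary(
    results: Sequence[NoteResult], gold: Sequence[GoldAnnotation]
) -> ConfusionCounts:
    """Note-level 2x2 of predicted vs annotated ADR presence."""
    tp = fp = fn = tn = 0
    for r, g in _index_results(results, gold):
        if r.has_adr and g.has_adr:
            tp += 1
        elif r.has_adr:
            fp += 1
        elif g.has_adr:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def _predicted_items(result: NoteResult, task: str) -> list[str | tuple]:
    if task == "medication":
        # medications that fed at least one pair (the triggering drug),
        # deduplicated by surface in note order
        out: list[str] = []
        for p in result.pairs:
            if p.medication.surface not in out:
                out.append(p.medication.surface)
        return out
    if task == "adr":
        out = []
        for m in result.adrs:
            if m.kind == "adr" and m.surface not in out:
                out.append(m.surface)
        return out
    if task == "pair":
        return [(p.medication.surface, p.adr.surface) for p in result.pairs]
    raise ValueError(f"unknown mention task {task!r}")


def _gold_items(g: GoldAnnotation, task: str) -> list[str | tuple]:
    if task == "medication":
        return [normalize_text(m) for m in g.medications]
    if task == "adr":
        return [normalize_text(a) for a in g.adrs]
    if task == "pair":
        return [
            (normalize_text(m), normalize_text(a)) for m, a in g.pairs
        ]
    raise ValueError(f"unknown mention task {task!r}")


def score_mentions(
    results: Sequence[NoteResult],
    gold: Sequence[GoldAnnotation],
    task: str,
) -> ConfusionCounts:
    """Mention-level 2x2 for the medication / adr / pair task.

    Within each note, predictions are matched greedily (in note order)
    one-to-one to gold items by exact normalized-string equality; a pair
    matches only if both components match.  tp = matched predictions,
    fp = unmatched predictions, fn = unmatched gold items; tn counts
    notes with neither gold nor predicted items of the task's type.
    """
    tp = fp = fn = tn = 0
    for r, g in _index_results(results, gold):
        preds = _predicted_items(r, task)
        golds = _gold_items(g, task)
        if not preds and not golds:
            tn += 1
            continue
        remaining = list(golds)
        for p in preds:
            if p in remaining:
                remaining.remove(p)
                tp += 1
            else:
                fp += 1
        fn += len(remaining)
    return ConfusionCounts(tp, fp, fn, tn)


def score_task(
    results: Sequence[NoteResult],
    gold: Sequence[GoldAnnotation],
    task: str,
) -> ConfusionCounts:
    if task == "binary":
        return score_binary(results, gold)
    return score_mentions(results, gold, task)


def interobserver_agreement(
    labels_a: Sequence[bool] | Mapping[str, bool],
    labels_b: Sequence[bool] | Mapping[str, bool],
) -> float:
    """Percent of items labeled identically by two annotators."""
    if isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping):
        if set(labels_a) != set(labels_b):
            raise ValueError("annotators labeled different note ids")
        keys = sorted(labels_a)
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        a, b = list(labels_a), list(labels_b)
        if len(a) != len(b):
            raise ValueError(
                f"label vectors differ in length ({len(a)} vs {len(b)})"
            )
    if not a:
        raise ValueError("no labels to compare")
    agree = sum(1 for x, y in zip(a, b) if bool(x) == bool(y))
    return 100.0 * agree / len(a)


def evaluate_grid(
    notes,
    gold: Sequence[GoldAnnotation],
    versions: Iterable[str],
    store,
    resources: Mapping[str, object],
    number_lexicon=None,
) -> pd.DataFrame:
    """Run every requested version on the corpus and score all four
    tasks, returning a long-format table (one row per version x task).

    ``resources`` holds the term resources passed to
    :func:`adrin.pipeline.make_version` (med_terms, adr_terms, ...).
    """
    from .pipeline import make_version, run_corpus

    rows = []
    gold_by_id = {g.note_id: g for g in gold}
    for label in versions:
        cfg: PipelineConfig = make_version(label, **resources)
        results = run_corpus(
            notes, cfg, store, number_lexicon=number_lexicon
        )
        scored_gold = [gold_by_id[r.note_id] for r in results]
        for task in TASKS:
            counts = score_task(results, scored_gold, task)
            metrics = compute_metrics(counts)
            rows.append(
                {
                    "version": label,
                    "task": task,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    **metrics.as_dict(),
                }
            )
    return pd.DataFrame(rows)
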