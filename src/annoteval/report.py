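"""Consolidated evaluation reports and multi-pipeline agreement partitions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .classify import (
    DEFECT_OUTCOMES,
    MATCH_OUTCOMES,
    ClassifierThresholds,
    FeatureTally,
    GeneClassification,
    classify_genes,
    labels_by_reference,
    match_transcripts,
    tally_subfeatures,
)
from .model import AnnotationSet
from .refset import GoldStandardSet
from .stats import LEVELS, confusion_counts, sn_pr_f1

logger = logging.getLogger(__name__)


@dataclass
class AgreementPartition:
    """Reference genes partitioned by the subset of pipelines matching them.

    ``match_cells`` maps each non-empty frozenset of pipeline labels to the
    number of reference genes matched (exact or inexact) by exactly those
    pipelines; ``unmatched_by_all`` counts genes matched by none; the cells
    plus ``unmatched_by_all`` sum to ``total_reference_genes``.
    ``defect_cells`` is the parallel partition over defective outcomes
    (merged/fragmented/missing).
    """

    match_cells: dict[frozenset, int]
    defect_cells: dict[frozenset, int]
    unmatched_by_all: int
    total_reference_genes: int

    def per_1000(self) -> dict[frozenset, float]:
        t = self.total_reference_genes
        return {k: 1000.0 * v / t for k, v in self.match_cells.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pipelines": "+".join(sorted(cell)), "n_pipelines": len(cell),
             "matched": n, "per_1000": 1000.0 * n / self.total_reference_genes}
            for cell, n in sorted(self.match_cells.items(),
                                  key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(
            rows, columns=["pipelines", "n_pipelines", "matched", "per_1000"])


def agreement_partition(
    prediction_sets: dict[str, AnnotationSet],
    references: AnnotationSet,
    thresholds: ClassifierThresholds | None = None,
) -> AgreementPartition:
    """Partition reference genes by which pipelines match them.

    Each prediction set is classified against the references independently; a
    reference gene falls in the cell of the exact/inexact-matching pipeline
    subset.  Pipelines lacking whole contigs simply contribute 'missing' for
    genes there (a warning is logged).
    """
    if len(prediction_sets) < 2:
        raise ValueError("agreement needs at least 2 prediction sets")
    ref_contigs = references.contigs()
    outcome_maps: dict[str, dict[str, str]] = {}
    for label, preds in prediction_sets.items():
        absent = ref_contigs - preds.contigs()
        if absent:
            logger.warning(
                "pipeline %s lacks contigs %s; reference genes there count "
                "as missing", label, sorted(absent))
        outcome_maps[label] = labels_by_reference(
            classify_genes(preds, references, thresholds))
    match_cells: dict[frozenset, int] = {}
    defect_cells: dict[frozenset, int] = {}
    unmatched = 0
    for gene in references:
        matching = frozenset(
            label for label, omap in outcome_maps.items()
            if omap.get(gene.id) in MATCH_OUTCOMES)
        if matching:
            match_cells[matching] = match_cells.get(matching, 0) + 1
        else:
            unmatched += 1
        defective = frozenset(
            label for label, omap in outcome_maps.items()
            if omap.get(gene.id, "missing") in DEFECT_OUTCOMES)
        if defective:
            defect_cells[defective] = defect_cells.get(defective, 0) + 1
    return AgreementPartition(
        match_cells, defect_cells, unmatched, len(references))


@dataclass
class EvaluationReport:
    """Everything one prediction-vs-reference comparison produces."""

    classifications: list[GeneClassification]
    outcome_counts: dict[str, int]
    tallies: dict[str, FeatureTally]
    accuracy: dict[str, object]          # level -> AccuracyStats
    per_gene_f1: dict[str, float]        # reference gene id -> F1
    f1_level: str
    summary: dict = field(default_factory=dict)

    def classification_frame(self) -> pd.DataFrame:
        rows = [
            {"outcome": c.outcome,
             "reference_ids": ",".join(c.reference_ids),
             "prediction_ids": ",".join(c.prediction_ids),
             "coverages": ";".join(
                 f"{p}->{r}:{v:.4f}"
                 for (p, r), v in sorted(c.coverage_fractions.items()))}
            for c in self.classifications
        ]
        return pd.DataFrame(
            rows, columns=["outcome", "reference_ids", "prediction_ids",
                           "coverages"])

    def tally_frame(self) -> pd.DataFrame:
        rows = []
        for level, t in self.tallies.items():
            rows.append({"level": level, "position_class": "all",
                         "matched": t.matched, "missing": t.missing,
                         "false_positive": t.false_positive,
                         "exact_matched": t.exact_matched})
            for cls, counts in sorted(t.exon_position_breakdown.items()):
                rows.append({"level": level, "position_class": cls,
                             "matched": counts["matched"],
                             "missing": counts["missing"],
                             "false_positive": counts["false_positive"],
                             "exact_matched": ""})
        return pd.DataFrame(rows)

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"level": lvl, "Sn": s.Sn, "Pr": s.Pr, "F1": s.F1}
             for lvl, s in self.accuracy.items()])


def _per_gene_f1(
    classifications: list[GeneClassification],
    predictions: AnnotationSet,
    references: AnnotationSet,
) -> dict[str, float]:
    """Nucleotide-stringency F1 per reference gene against its matched group."""
    scores: dict[str, float] = {}
    for c in classifications:
        if not c.reference_ids:
            continue
        pred_sub = predictions.subset(c.prediction_ids)
        for rid in c.reference_ids:
            ref_sub = references.subset([rid])
            counts = confusion_counts(pred_sub, ref_sub, "nucleotide")
            scores[rid] = sn_pr_f1(counts).F1
    return scores


def aggregate_tallies(
    classifications: list[GeneClassification],
    predictions: AnnotationSet,
    references: AnnotationSet,
) -> dict[str, FeatureTally]:
    """Transcript/exon/intron tallies accumulated over all classified groups."""
    totals = {lvl: FeatureTally(lvl) for lvl in ("transcript", "exon", "intron")}
    for c in classifications:
        pred_genes = [predictions[p] for p in c.prediction_ids]
        ref_genes = [references[r] for r in c.reference_ids]
        if not pred_genes and not ref_genes:
            continue
        assignment = match_transcripts(pred_genes, ref_genes)
        for lvl, t in tally_subfeatures(assignment).items():
            totals[lvl].add(t)
    return totals


def evaluate_report(
    predictions: AnnotationSet,
    references: AnnotationSet,
    gold_standard: GoldStandardSet | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> EvaluationReport:
    """Classify, tally, and score one prediction set against a reference.

    When a gold standard is given, the reference set is restricted to its
    member genes first (an empty restriction is an error); this equals
    evaluating against a pre-filtered annotation set.  Per-gene F1 scores are
    computed at nucleotide stringency.
    """
    if gold_standard is not None:
        wanted = set(gold_standard.members) & set(references.genes)
        if not wanted:
            raise ValueError("gold standard restriction leaves no reference "
                             "genes")
        references = references.subset(wanted)
    classifications = classify_genes(predictions, references, thresholds)
    outcome_counts: dict[str, int] = {}
    for c in classifications:
        if c.reference_ids:
            outcome_counts[c.outcome] = (
                outcome_counts.get(c.outcome, 0) + len(c.reference_ids))
        else:
            outcome_counts["unassigned_prediction"] = (
                outcome_counts.get("unassigned_prediction", 0) + 1)
    tallies = aggregate_tallies(classifications, predictions, references)
    accuracy = {lvl: sn_pr_f1(confusion_counts(predictions, references, lvl))
                for lvl in LEVELS}
    per_gene = _per_gene_f1(classifications, predictions, references)
    summary = {
        "n_reference_genes": len(references),
        "n_prediction_genes": len(predictions),
        "outcome_counts": outcome_counts,
        "accuracy": {lvl: {"Sn": s.Sn, "Pr": s.Pr, "F1": s.F1}
                     for lvl, s in accuracy.items()},
        "tallies": {lvl: {"matched": t.matched, "missing": t.missing,
                          "false_positive": t.false_positive,
                          "exact_matched": t.exact_matched}
                    for lvl, t in tallies.items()},
        "per_gene_f1_level": "nucleotide",
        "mean_per_gene_f1": (sum(per_gene.values()) / len(per_gene)
                             if per_gene else None),
    }
    return EvaluationReport(
        classifications, outcome_counts, tallies, accuracy, per_gene,
        "nucleotide", summary)
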