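"""Coordinate-based classification of gene-prediction outcomes.

Each reference gene receives exactly one outcome from {exact, inexact,
missing, merged, fragmented}; predictions that never participate are reported
under the separate ``unassigned_prediction`` outcome.  The procedure is
strand-aware and purely coordinate-based:

1. *merged* — one prediction whose span covers two or more reference spans,
   each by more than ``merged_ref_coverage`` of the reference length (the
   signature of an intergenic region mistaken for an intron);
2. *fragmented* — one remaining reference overlapped by two or more remaining
   predictions, each lying at least ``fragment_pred_coverage`` of its own span
   inside the reference and pairwise (near-)disjoint (an intron mistaken for
   an intergenic region);
3. the remaining overlapping pairs are resolved one-to-one by maximum-weight
   assignment on span overlap — *exact* when spans coincide, else *inexact*;
4. leftovers are *missing* (references) or *unassigned_prediction*.

Earlier steps consume their participants, so the outcomes partition the
reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.optimize import linear_sum_assignment

from .model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    overlap_length,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("exact", "inexact", "missing", "merged", "fragmented",
            "unassigned_prediction")
MATCH_OUTCOMES = frozenset({"exact", "inexact"})
DEFECT_OUTCOMES = frozenset({"missing", "merged", "fragmented"})


def coverage_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``b`` covered by ``a``; 0 when disjoint.

    Both intervals must lie on the same contig (strand is not checked here;
    callers restrict comparisons to one strand).
    """
    if a.contig != b.contig:
        raise ValueError(f"intervals on different contigs: {a.contig} vs {b.contig}")
    return overlap_length(a, b) / len(b)


@dataclass
class ClassifierThresholds:
    """Coverage thresholds of the defect rules.

    ``merged_ref_coverage`` is a strict lower bound (>) on the fraction of
    each reference covered by a merged prediction; ``fragment_pred_coverage``
    is a non-strict bound (>=) on the fraction of each fragment lying inside
    the reference; ``fragment_mutual_overlap_max`` bounds pairwise fragment
    overlap as a fraction of the shorter fragment (0 = fragments must be
    disjoint).  ``merged_use_footprint`` switches the merged test's
    denominator from the reference span to its CDS footprint.
    """

    merged_ref_coverage: float = 0.5
    fragment_pred_coverage: float = 0.5
    fragment_mutual_overlap_max: float = 0.0
    merged_use_footprint: bool = False

    def __post_init__(self):
        for name in ("merged_ref_coverage", "fragment_pred_coverage",
                     "fragment_mutual_overlap_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GeneClassification:
    """One classified locus: an outcome plus its participating gene IDs."""

    outcome: str
    reference_ids: list[str] = field(default_factory=list)
    prediction_ids: list[str] = field(default_factory=list)
    coverage_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    contig: str = ""
    strand: str = "+"


def _ref_coverage_denominator(ref: GeneModel, thresholds: ClassifierThresholds) -> int:
    if thresholds.merged_use_footprint:
        return sum(len(iv) for iv in ref.footprint())
    return len(ref.span)


def _ref_covered_length(pred: GeneModel, ref: GeneModel,
                        thresholds: ClassifierThresholds) -> int:
    if thresholds.merged_use_footprint:
        return sum(overlap_length(pred.span, iv) for iv in ref.footprint())
    return overlap_length(pred.span, ref.span)


def classify_genes(
    predictions: AnnotationSet,
    references: AnnotationSet,
    thresholds: ClassifierThresholds | None = None,
) -> list[GeneClassification]:
    """Classify every reference gene (and leftover prediction) on shared strands.

    Returns one :class:`GeneClassification` per outcome group; every reference
    gene appears in exactly one classification, predictions in at most one
    (plus one ``unassigned_prediction`` record per leftover prediction).
    """
    thresholds = thresholds or ClassifierThresholds()
    results: list[GeneClassification] = []
    keys = sorted(set(predictions.index()) | set(references.index()))
    for contig, strand in keys:
        preds = predictions.genes_on(contig, strand)
        refs = references.genes_on(contig, strand)
        _warn_internal_overlaps(refs, "reference", contig, strand)
        _warn_internal_overlaps(preds, "prediction", contig, strand)
        results.extend(
            _classify_on_strand(preds, refs, thresholds, contig, strand)
        )
    return results


def _warn_internal_overlaps(genes, label, contig, strand):
    for a, b in zip(genes, genes[1:]):
        if b.span.start <= a.span.end:
            logger.info(
                "overlapping %s genes %s/%s on %s%s", label, a.id, b.id,
                contig, strand,
            )


def _classify_on_strand(preds, refs, thresholds, contig, strand):
    # pairwise span overlaps via an interval tree over reference spans
    tree = IntervalTree()
    for j, r in enumerate(refs):
        tree.addi(r.span.lo, r.span.hi, j)
    overlaps: dict[int, dict[int, int]] = {}  # pred idx -> {ref idx: span ov}
    for i, p in enumerate(preds):
        hits = {}
        for node in tree.overlap(p.span.lo, p.span.hi):
            hits[node.data] = overlap_length(p.span, refs[node.data].span)
        if hits:
            overlaps[i] = hits

    consumed_p: set[int] = set()
    consumed_r: set[int] = set()
    out: list[GeneClassification] = []

    # step 1: merged predictions
    for i, p in enumerate(preds):
        hits = overlaps.get(i, {})
        covered = []
        for j in sorted(hits):
            if j in consumed_r:
                continue
            denom = _ref_coverage_denominator(refs[j], thresholds)
            cov = _ref_covered_length(p, refs[j], thresholds) / denom
            if cov > thresholds.merged_ref_coverage:
                covered.append((j, cov))
        if len(covered) >= 2:
            consumed_p.add(i)
            consumed_r.update(j for j, _ in covered)
            out.append(GeneClassification(
                "merged",
                reference_ids=[refs[j].id for j, _ in covered],
                prediction_ids=[p.id],
                coverage_fractions={(p.id, refs[j].id): c for j, c in covered},
                contig=contig, strand=strand,
            ))

    # step 2: fragmented references
    pred_hits_by_ref: dict[int, list[int]] = {}
    for i, hits in overlaps.items():
        for j in hits:
            pred_hits_by_ref.setdefault(j, []).append(i)
    for j, r in enumerate(refs):
        if j in consumed_r:
            continue
        candidates = []
        for i in sorted(pred_hits_by_ref.get(j, [])):
            if i in consumed_p:
                continue
            frac = overlaps[i][j] / len(preds[i].span)
            if frac >= thresholds.fragment_pred_coverage:
                candidates.append((i, frac))
        # greedy left-to-right maximal pairwise-compatible subset
        chosen: list[tuple[int, float]] = []
        for i, frac in candidates:
            ok = True
            for k, _ in chosen:
                shorter = min(len(preds[i].span), len(preds[k].span))
                mutual = overlap_length(preds[i].span, preds[k].span) / shorter
                if mutual > thresholds.fragment_mutual_overlap_max:
                    ok = False
                    break
            if ok:
                chosen.append((i, frac))
        if len(chosen) >= 2:
            consumed_r.add(j)
            consumed_p.update(i for i, _ in chosen)
            out.append(GeneClassification(
                "fragmented",
                reference_ids=[r.id],
                prediction_ids=[preds[i].id for i, _ in chosen],
                coverage_fractions={(preds[i].id, r.id): f for i, f in chosen},
                contig=contig, strand=strand,
            ))

    # step 3: one-to-one maximum-weight assignment on span overlap
    free_p = [i for i in range(len(preds)) if i not in consumed_p]
    free_r = [j for j in range(len(refs)) if j not in consumed_r]
    weight = np.zeros((len(free_p), len(free_r)), dtype=np.int64)
    col_of = {j: b for b, j in enumerate(free_r)}
    for a, i in enumerate(free_p):
        for j, ov in overlaps.get(i, {}).items():
            if j in col_of:
                weight[a, col_of[j]] = ov
    if weight.size and weight.any():
        rows, cols = linear_sum_assignment(weight, maximize=True)
        for a, b in zip(rows, cols):
            if weight[a, b] <= 0:
                continue
            i, j = free_p[a], free_r[b]
            consumed_p.add(i)
            consumed_r.add(j)
            p, r = preds[i], refs[j]
            outcome = "exact" if (p.span.start == r.span.start
                                  and p.span.end == r.span.end) else "inexact"
            out.append(GeneClassification(
                outcome,
                reference_ids=[r.id], prediction_ids=[p.id],
                coverage_fractions={
                    (p.id, r.id): coverage_fraction(p.span, r.span)},
                contig=contig, strand=strand,
            ))

    # step 4: leftovers
    for j, r in enumerate(refs):
        if j not in consumed_r:
            out.append(GeneClassification(
                "missing", reference_ids=[r.id],
                contig=contig, strand=strand,
            ))
    for i, p in enumerate(preds):
        if i not in consumed_p:
            out.append(GeneClassification(
                "unassigned_prediction", prediction_ids=[p.id],
                contig=contig, strand=strand,
            ))
    return out


def labels_by_reference(classifications: list[GeneClassification]) -> dict[str, str]:
    """Outcome per reference gene (merged/fragmented groups expand)."""
    labels: dict[str, str] = {}
    for c in classifications:
        for rid in c.reference_ids:
            if rid in labels:
                raise ValueError(f"reference {rid} classified twice")
            labels[rid] = c.outcome
    return labels


# ---------------------------------------------------------------------------
# transcript-level matching


@dataclass
class TranscriptAssignment:
    """One-to-one transcript matching maximizing summed CDS overlap."""

    pairs: dict[str, str]                 # prediction tid -> reference tid
    total_overlap: int
    missing_refs: list[str]
    false_positive_preds: list[str]
    pair_objects: list[tuple[TranscriptModel, TranscriptModel]] = field(
        default_factory=list, repr=False)
    missing_ref_objects: list[TranscriptModel] = field(
        default_factory=list, repr=False)
    fp_pred_objects: list[TranscriptModel] = field(
        default_factory=list, repr=False)


def transcript_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Shared nucleotides between two transcripts' CDS footprints.

    Segments within a transcript are non-overlapping, so the footprint
    intersection is the sum of pairwise segment overlaps.
    """
    if a.contig != b.contig or a.strand != b.strand:
        return 0
    total = 0
    for sa in a.segments:
        for sb in b.segments:
            total += overlap_length(sa.interval, sb.interval)
    return total


def _optimal_assignment(
    weight: np.ndarray,
) -> list[tuple[int, int]]:
    """Maximum-weight one-to-one assignment excluding zero-weight pairs.

    Ties between equal-total assignments are broken toward lexicographically
    smallest (row, column) index pairs: inputs are pre-sorted by coordinate,
    and each pair gets an integer bonus small enough never to trade against
    one unit of real weight.
    """
    if weight.size == 0 or not weight.any():
        return []
    n, m = weight.shape
    cells = n * m
    scale = min(n, m) * cells + 1
    bonus = np.arange(cells, 0, -1, dtype=np.int64).reshape(n, m)
    adjusted = weight.astype(np.int64) * scale + np.where(weight > 0, bonus, 0)
    rows, cols = linear_sum_assignment(adjusted, maximize=True)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if weight[r, c] > 0]


def match_transcripts(
    prediction_genes: list[GeneModel],
    reference_genes: list[GeneModel],
) -> TranscriptAssignment:
    """Match transcripts of a classified gene group one-to-one.

    The assignment maximizes the total number of shared CDS nucleotides
    (optimal, not greedy); transcripts left unmatched are missing (reference
    side) or false positives (prediction side).
    """
    if not prediction_genes and not reference_genes:
        raise ValueError("both gene groups are empty")
    pred_ts = sorted(
        (t for g in prediction_genes for t in g.transcripts),
        key=lambda t: (t.span.start, t.span.end, t.id))
    ref_ts = sorted(
        (t for g in reference_genes for t in g.transcripts),
        key=lambda t: (t.span.start, t.span.end, t.id))
    weight = np.zeros((len(ref_ts), len(pred_ts)), dtype=np.int64)
    for i, r in enumerate(ref_ts):
        for j, p in enumerate(pred_ts):
            weight[i, j] = transcript_overlap(p, r)
    chosen = _optimal_assignment(weight)
    pairs = {pred_ts[j].id: ref_ts[i].id for i, j in chosen}
    matched_r = {i for i, _ in chosen}
    matched_p = {j for _, j in chosen}
    return TranscriptAssignment(
        pairs=pairs,
        total_overlap=int(sum(weight[i, j] for i, j in chosen)),
        missing_refs=[t.id for i, t in enumerate(ref_ts) if i not in matched_r],
        false_positive_preds=[t.id for j, t in enumerate(pred_ts)
                              if j not in matched_p],
        pair_objects=[(pred_ts[j], ref_ts[i]) for i, j in chosen],
        missing_ref_objects=[t for i, t in enumerate(ref_ts)
                             if i not in matched_r],
        fp_pred_objects=[t for j, t in enumerate(pred_ts) if j not in matched_p],
    )


# ---------------------------------------------------------------------------
# exon / intron tallies


@dataclass
class FeatureTally:
    """Matched / missing / false-positive counts at one feature level."""

    level: str
    matched: int = 0
    missing: int = 0
    false_positive: int = 0
    exact_matched: int = 0
    exon_position_breakdown: dict[str, dict[str, int]] = field(
        default_factory=dict)

    def add(self, other: "FeatureTally") -> None:
        assert self.level == other.level
        self.matched += other.matched
        self.missing += other.missing
        self.false_positive += other.false_positive
        self.exact_matched += other.exact_matched
        for cls, counts in other.exon_position_breakdown.items():
            mine = self.exon_position_breakdown.setdefault(
                cls, {"matched": 0, "missing": 0, "false_positive": 0})
            for k, v in counts.items():
                mine[k] += v


def _interval_assignment(
    pred_ivs: list, ref_ivs: list
) -> list[tuple[int, int]]:
    weight = np.zeros((len(ref_ivs), len(pred_ivs)), dtype=np.int64)
    for i, r in enumerate(ref_ivs):
        for j, p in enumerate(pred_ivs):
            weight[i, j] = overlap_length(p, r)
    return _optimal_assignment(weight)


def _breakdown_bucket(tally: FeatureTally, cls: str) -> dict[str, int]:
    return tally.exon_position_breakdown.setdefault(
        cls, {"matched": 0, "missing": 0, "false_positive": 0})


def tally_subfeatures(assignment: TranscriptAssignment) -> dict[str, FeatureTally]:
    """Exon and intron matched/missing/false-positive tallies for one group.

    Within each matched transcript pair, exons (CDS segments) are matched
    one-to-one by maximum overlap, introns likewise; features of unmatched
    reference transcripts all count missing and features of false-positive
    transcripts all count false positive.  Exon tallies carry a breakdown by
    position class (matched and missing classed by the reference segment,
    false positives by the prediction segment).  ``exact_matched`` counts the
    subset of matches with identical coordinates.
    """
    tx = FeatureTally("transcript",
                      matched=len(assignment.pairs),
                      missing=len(assignment.missing_refs),
                      false_positive=len(assignment.false_positive_preds))
    exon = FeatureTally("exon")
    intron = FeatureTally("intron")

    for pred_t, ref_t in assignment.pair_objects:
        if pred_t.chain == ref_t.chain:
            tx.exact_matched += 1
        # exons
        p_segs, r_segs = pred_t.segments, ref_t.segments
        chosen = _interval_assignment(
            [s.interval for s in p_segs], [s.interval for s in r_segs])
        matched_r = {i for i, _ in chosen}
        matched_p = {j for _, j in chosen}
        for i, j in chosen:
            exon.matched += 1
            _breakdown_bucket(exon, r_segs[i].position_class)["matched"] += 1
            if r_segs[i].interval == p_segs[j].interval:
                exon.exact_matched += 1
        for i, s in enumerate(r_segs):
            if i not in matched_r:
                exon.missing += 1
                _breakdown_bucket(exon, s.position_class)["missing"] += 1
        for j, s in enumerate(p_segs):
            if j not in matched_p:
                exon.false_positive += 1
                _breakdown_bucket(exon, s.position_class)["false_positive"] += 1
        # introns
        p_int, r_int = pred_t.introns, ref_t.introns
        chosen_i = _interval_assignment(p_int, r_int)
        intron.matched += len(chosen_i)
        intron.exact_matched += sum(
            1 for i, j in chosen_i if r_int[i] == p_int[j])
        intron.missing += len(r_int) - len(chosen_i)
        intron.false_positive += len(p_int) - len(chosen_i)

    for t in assignment.missing_ref_objects:
        exon.missing += len(t.segments)
        for s in t.segments:
            _breakdown_bucket(exon, s.position_class)["missing"] += 1
        intron.missing += len(t.introns)
    for t in assignment.fp_pred_objects:
        exon.false_positive += len(t.segments)
        for s in t.segments:
            _breakdown_bucket(exon, s.position_class)["false_positive"] += 1
        intron.false_positive += len(t.introns)

    return {"transcript": tx, "exon": exon, "intron": intron}


# ---------------------------------------------------------------------------
# evidence concordance (2-of-3 selector)


def select_concordant(
    source_a: AnnotationSet,
    source_b: AnnotationSet,
    source_c: AnnotationSet,
    min_agree: int = 2,
) -> AnnotationSet:
    """Select gene models agreed by at least ``min_agree`` of three sources.

    Two gene models are concordant when their (contig, strand, ordered CDS
    coordinate chain) signatures are identical.  One representative per
    concordant structure is returned (taken from the first supporting source
    in argument order); the returned set carries a ``provenance`` attribute
    mapping gene id to the tuple of supporting source labels.
    """
    if not 1 <= min_agree <= 3:
        raise ValueError(f"min_agree must be in 1..3, got {min_agree}")
    sources = [("a", source_a), ("b", source_b), ("c", source_c)]
    support: dict[tuple, dict[str, GeneModel]] = {}
    for name, annot in sources:
        label = annot.source_label or name
        for g in annot:
            support.setdefault(g.chain_signature, {}).setdefault(label, g)
    selected = AnnotationSet(source_label="concordant")
    provenance: dict[str, tuple[str, ...]] = {}
    reps = []
    for sig, backers in support.items():
        if len(backers) >= min_agree:
            rep = next(iter(backers.values()))
            reps.append((sig[0], rep.span.start, rep, tuple(backers)))
    used_ids: set[str] = set()
    for _, _, rep, backers in sorted(reps, key=lambda x: (x[0], x[1], x[2].id)):
        gid = rep.id
        while gid in used_ids:
            gid += "_alt"
        used_ids.add(gid)
        gene = rep if gid == rep.id else GeneModel(gid, rep.transcripts)
        selected.add(gene)
        provenance[gid] = backers
    selected.provenance = provenance
    return selected
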