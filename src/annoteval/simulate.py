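"""Synthetic annotation generator with controlled defect injection.

Builds reference annotations with realistic exon/intron length structure on
linear contigs, then derives a prediction set from them by injecting the five
gene-level outcome classes (exact copies, boundary-jittered inexact models,
missing genes, merges of adjacent gene pairs, fragment splits at introns)
plus transcript-level spurious isoforms — together with a truth-label table
recording every injected outcome.  Because genes are placed with guaranteed
intergenic gaps and jitter is bounded against them, the injected labels are
unambiguous under the classifier's default thresholds, which is what makes
label-recovery a meaningful end-to-end check.

All sampling is driven by a single seeded NumPy generator, so outputs are
byte-identical across runs for a given parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (
    AnnotationSet,
    CdsSegment,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


class CapacityError(ValueError):
    """Requested genes do not fit in the configured contig length."""


@dataclass
class GenomeParams:
    """Parameters of the synthetic reference genome annotation.

    Defaults emulate a compact eukaryotic (fungal/protist-like) gene
    structure: 1–8 coding exons of 50–300 nt separated by short introns of
    40–400 nt, genes packed on both strands with at least
    ``min_intergenic_gap`` nt between consecutive gene spans.

    ``exon_count_distribution`` is either an int (fixed count) or a tuple
    ``("uniform", lo, hi)`` / ``("geometric", p, cap)``.
    """

    n_genes: int = 100
    n_contigs: int = 1
    contig_length: int = 600_000
    exon_count_distribution: tuple | int = ("uniform", 1, 8)
    exon_length_range: tuple[int, int] = (50, 300)
    intron_length_range: tuple[int, int] = (40, 400)
    min_intergenic_gap: int = 200
    strand_probability: float = 0.5
    isoform_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.min_intergenic_gap < 4:
            raise ValueError("min_intergenic_gap must be >= 4")
        if self.n_genes < 1 or self.n_contigs < 1:
            raise ValueError("n_genes and n_contigs must be positive")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")


@dataclass
class PerturbationSpec:
    """How many of each defect to inject.

    Integer values are absolute counts; float values below 1 are fractions of
    the reference gene count.  ``merged`` counts merged *pairs* (each consumes
    two adjacent same-strand reference genes); genes not claimed by any
    defect are emitted as exact copies.  ``jitter_magnitude`` bounds the
    boundary shift of inexact genes as a fraction of gene length (further
    clamped so a jittered gene can never reach half-way into a flanking
    intergenic gap).
    """

    inexact: int | float = 0
    missing: int | float = 0
    merged: int | float = 0
    fragmented: int | float = 0
    jitter_magnitude: float = 0.1
    spurious_transcript_rate: float = 0.0
    dropped_transcript_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.jitter_magnitude <= 1:
            raise ValueError("jitter_magnitude must be in (0, 1]")
        for name in ("spurious_transcript_rate", "dropped_transcript_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthLabels:
    """Injected outcome per reference gene, and role per prediction gene."""

    reference_outcomes: dict[str, str] = field(default_factory=dict)
    prediction_roles: dict[str, str] = field(default_factory=dict)
    spurious_transcripts: list[str] = field(default_factory=list)
    dropped_transcripts: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["#kind\tid\tlabel"]
        for rid, outcome in self.reference_outcomes.items():
            lines.append(f"reference_gene\t{rid}\t{outcome}")
        for pid, role in self.prediction_roles.items():
            lines.append(f"prediction_gene\t{pid}\t{role}")
        for tid in self.spurious_transcripts:
            lines.append(f"prediction_transcript\t{tid}\tspurious")
        for tid in self.dropped_transcripts:
            lines.append(f"reference_transcript\t{tid}\tdropped")
        return "\n".join(lines) + "\n"


def _sample_exon_count(rng: np.random.Generator, dist) -> int:
    if isinstance(dist, int):
        return dist
    kind = dist[0]
    if kind == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    if kind == "geometric":
        return int(min(rng.geometric(dist[1]), dist[2]))
    raise ValueError(f"unknown exon count distribution {dist!r}")


def generate_reference(params: GenomeParams) -> AnnotationSet:
    """Generate a deterministic multi-gene reference annotation.

    Genes are placed left-to-right per contig with intergenic gaps sampled in
    ``[min_intergenic_gap, 2*min_intergenic_gap]``; each gene gets one
    transcript, plus (with ``isoform_probability``) an isoform skipping one
    internal exon.  Raises :class:`CapacityError` when the requested genes do
    not fit.
    """
    rng = np.random.default_rng(params.seed)
    annotation = AnnotationSet(source_label="synthetic-reference")
    per_contig = int(np.ceil(params.n_genes / params.n_contigs))
    gene_no = 0
    for ci in range(params.n_contigs):
        contig = f"contig_{ci + 1}"
        pos = 0  # last occupied coordinate
        n_here = min(per_contig, params.n_genes - gene_no)
        for _ in range(n_here):
            gap = int(rng.integers(params.min_intergenic_gap,
                                   2 * params.min_intergenic_gap + 1))
            start = pos + gap + 1
            k = _sample_exon_count(rng, params.exon_count_distribution)
            exon_lens = rng.integers(params.exon_length_range[0],
                                     params.exon_length_range[1] + 1, size=k)
            intron_lens = rng.integers(params.intron_length_range[0],
                                       params.intron_length_range[1] + 1,
                                       size=max(0, k - 1))
            strand = "+" if rng.random() < params.strand_probability else "-"
            segments, cursor = [], start
            for i, el in enumerate(exon_lens):
                iv = GenomicInterval(contig, cursor, cursor + int(el) - 1, strand)
                segments.append(CdsSegment(iv, 0))
                cursor = iv.end + 1
                if i < k - 1:
                    cursor += int(intron_lens[i])
            end = segments[-1].interval.end
            if end > params.contig_length:
                raise CapacityError(
                    f"gene {gene_no + 1} would end at {end} on {contig} "
                    f"(capacity {params.contig_length}); increase "
                    f"contig_length or n_contigs")
            gene_no += 1
            gid = f"g{gene_no:05d}"
            transcripts = [TranscriptModel(f"{gid}.t1", gid, segments)]
            if k >= 3 and rng.random() < params.isoform_probability:
                skip = int(rng.integers(1, k - 1))
                iso = [s for i, s in enumerate(segments) if i != skip]
                transcripts.append(TranscriptModel(f"{gid}.t2", gid, iso))
            annotation.add(GeneModel(gid, transcripts))
            pos = end
    return annotation


def _resolve_count(value, n: int) -> int:
    if isinstance(value, bool):
        raise ValueError("defect counts must be numbers")
    if isinstance(value, int):
        return value
    if isinstance(value, float):
        if 0 <= value < 1:
            return int(round(value * n))
        raise ValueError(f"fractional defect value must be in [0, 1): {value}")
    raise ValueError(f"cannot interpret defect count {value!r}")


def _copy_transcript(t: TranscriptModel, tid: str, gid: str) -> TranscriptModel:
    return TranscriptModel(tid, gid, list(t.segments))


def _jitter_gene(gene: GeneModel, gid: str, rng: np.random.Generator,
                 jitter: float, room_left: int, room_right: int) -> GeneModel:
    """Shift both span boundaries by at least 1 nt, staying unambiguous.

    Outward shifts are capped at just under half the flanking gap; inward
    shifts at one less than the shortest boundary exon among transcripts
    anchored there.
    """
    span = gene.span
    base = max(1, int(jitter * len(span)))

    def pick_delta(side: str) -> int:
        if side == "start":
            anchored = [t for t in gene.transcripts
                        if t.segments[0].interval.start == span.start]
            in_cap = min(len(t.segments[0].interval) - 1 for t in anchored)
            out_cap = max(0, room_left // 2 - 1)
        else:
            anchored = [t for t in gene.transcripts
                        if t.segments[-1].interval.end == span.end]
            in_cap = min(len(t.segments[-1].interval) - 1 for t in anchored)
            out_cap = max(0, room_right // 2 - 1)
        outward = rng.random() < 0.5
        cap = out_cap if outward else in_cap
        if cap < 1:  # fall back to the feasible direction
            outward = not outward
            cap = out_cap if outward else in_cap
        if cap < 1:
            return 0
        mag = int(rng.integers(1, min(base, cap) + 1))
        if side == "start":
            return -mag if outward else mag
        return mag if outward else -mag

    d_start = pick_delta("start")
    d_end = pick_delta("end")
    if d_start == 0 and d_end == 0:  # degenerate locus; cannot happen with
        d_end = 1                    # default gaps, kept as a safety net
    transcripts = []
    for t in gene.transcripts:
        segs = list(t.segments)
        first, last = segs[0], segs[-1]
        if first.interval.start == span.start and d_start:
            iv = first.interval
            segs[0] = CdsSegment(
                GenomicInterval(iv.contig, iv.start + d_start, iv.end,
                                iv.strand),
                first.phase, first.position_class)
        if last.interval.end == span.end and d_end:
            iv = segs[-1].interval
            segs[-1] = CdsSegment(
                GenomicInterval(iv.contig, iv.start, iv.end + d_end,
                                iv.strand),
                last.phase, last.position_class)
        transcripts.append(
            TranscriptModel(t.id.replace(gene.id, gid, 1), gid, segs))
    return GeneModel(gid, transcripts)


def _spurious_isoform(gene: GeneModel, rng: np.random.Generator
                      ) -> TranscriptModel | None:
    primary = gene.transcripts[0]
    segs = primary.segments
    existing = {t.chain for t in gene.transcripts}
    if len(segs) >= 3:
        skip = int(rng.integers(1, len(segs) - 1))
        cand = [s for i, s in enumerate(segs) if i != skip]
    elif len(segs[-1].interval) >= 20:
        iv = segs[-1].interval
        cand = list(segs[:-1]) + [CdsSegment(
            GenomicInterval(iv.contig, iv.start, iv.end - 10, iv.strand),
            segs[-1].phase, segs[-1].position_class)]
    else:
        return None
    tid = f"{gene.id}.spur"
    iso = TranscriptModel(tid, gene.id, cand)
    if iso.chain in existing:
        return None
    return iso


def inject_defects(
    reference: AnnotationSet, spec: PerturbationSpec
) -> tuple[AnnotationSet, TruthLabels]:
    """Derive a prediction set from a reference by injecting labelled defects.

    Defects are assigned to disjoint gene subsets in the fixed order merged,
    fragmented, missing, inexact; the remainder is copied exactly.  Merges
    join *adjacent same-strand* gene pairs into one model whose intergenic
    gap becomes an intron; fragment splits cut one multi-exon gene at an
    intron into two disjoint predictions lying fully inside the reference
    span.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(reference)
    n = len(genes)
    n_merged = _resolve_count(spec.merged, n)
    n_frag = _resolve_count(spec.fragmented, n)
    n_missing = _resolve_count(spec.missing, n)
    n_inexact = _resolve_count(spec.inexact, n)
    if 2 * n_merged + n_frag + n_missing + n_inexact > n:
        raise ValueError("defect demands exceed the reference gene count")

    used: set[str] = set()
    labels = TruthLabels()

    # merged: adjacent same-strand pairs, both genes unused
    pair_pool = []
    for bucket in reference.index().values():
        pair_pool.extend(zip(bucket, bucket[1:]))
    order = rng.permutation(len(pair_pool))
    merged_pairs: list[tuple[GeneModel, GeneModel]] = []
    for idx in order:
        if len(merged_pairs) == n_merged:
            break
        a, b = pair_pool[idx]
        if a.id in used or b.id in used:
            continue
        merged_pairs.append((a, b))
        used.update((a.id, b.id))
    if len(merged_pairs) < n_merged:
        raise ValueError(
            f"only {len(merged_pairs)} disjoint adjacent same-strand pairs "
            f"available for {n_merged} requested merges")

    def draw(candidates: list[GeneModel], count: int, what: str
             ) -> list[GeneModel]:
        pool = [g for g in candidates if g.id not in used]
        if len(pool) < count:
            raise ValueError(
                f"only {len(pool)} genes available for {count} {what}")
        picked = [pool[i] for i in rng.choice(len(pool), size=count,
                                              replace=False)] if count else []
        used.update(g.id for g in picked)
        return picked

    frag_genes = draw([g for g in genes if len(g.transcripts[0].segments) >= 2],
                      n_frag, "fragment splits")
    missing_genes = {g.id for g in draw(genes, n_missing, "missing genes")}
    inexact_genes = {g.id for g in draw(genes, n_inexact, "inexact genes")}

    frag_ids = {g.id for g in frag_genes}
    merged_left = {a.id: (a, b) for a, b in merged_pairs}
    merged_member = {g.id for pair in merged_pairs for g in pair}

    # intergenic room per gene, for jitter bounds (neighbours on the contig,
    # either strand, in placement order)
    by_contig: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.span.start)):
        by_contig.setdefault(g.contig, []).append(g)
    room: dict[str, tuple[int, int]] = {}
    for contig, ordered in by_contig.items():
        for i, g in enumerate(ordered):
            left = (g.span.start - ordered[i - 1].span.end - 1
                    if i else g.span.start - 1)
            right = (ordered[i + 1].span.start - g.span.end - 1
                     if i + 1 < len(ordered) else len(ordered) * 10**6)
            room[g.id] = (left, right)

    predictions = AnnotationSet(source_label="synthetic-predictions")
    merged_no = 0
    for gene in genes:
        gid = gene.id
        if gid in missing_genes:
            labels.reference_outcomes[gid] = "missing"
            continue
        if gid in merged_member:
            labels.reference_outcomes[gid] = "merged"
            if gid not in merged_left:
                continue  # emitted with the left partner
            a, b = merged_left[gid]
            merged_no += 1
            pid = f"p_merged{merged_no:04d}"
            segments = list(a.transcripts[0].segments) + \
                list(b.transcripts[0].segments)
            predictions.add(GeneModel(
                pid, [TranscriptModel(f"{pid}.t1", pid, segments)]))
            labels.prediction_roles[pid] = "merged"
            continue
        if gid in frag_ids:
            labels.reference_outcomes[gid] = "fragmented"
            segs = gene.transcripts[0].segments
            cut = int(rng.integers(1, len(segs)))
            for part, chunk in (("f1", segs[:cut]), ("f2", segs[cut:])):
                pid = f"p_{gid}_{part}"
                predictions.add(GeneModel(
                    pid, [TranscriptModel(f"{pid}.t1", pid, list(chunk))]))
                labels.prediction_roles[pid] = "fragment"
            continue
        pid = f"p_{gid}"
        if gid in inexact_genes:
            labels.reference_outcomes[gid] = "inexact"
            left, right = room[gid]
            pred = _jitter_gene(gene, pid, rng, spec.jitter_magnitude,
                                left, right)
            labels.prediction_roles[pid] = "inexact"
        else:
            labels.reference_outcomes[gid] = "exact"
            pred = GeneModel(pid, [
                _copy_transcript(t, t.id.replace(gid, pid, 1), pid)
                for t in gene.transcripts])
            labels.prediction_roles[pid] = "exact"
        if spec.dropped_transcript_rate and len(pred.transcripts) > 1 \
                and rng.random() < spec.dropped_transcript_rate:
            dropped = pred.transcripts.pop()
            ref_tid = dropped.id.replace(pid, gid, 1)
            labels.dropped_transcripts.append(ref_tid)
        if spec.spurious_transcript_rate \
                and rng.random() < spec.spurious_transcript_rate:
            iso = _spurious_isoform(pred, rng)
            if iso is not None:
                pred.transcripts.append(iso)
                labels.spurious_transcripts.append(iso.id)
        predictions.add(pred)
    return predictions, labels


def params_json(params: GenomeParams, spec: PerturbationSpec | None = None
                ) -> dict:
    """JSON-serializable record of the generation parameters."""
    out = {"genome": asdict(params)}
    if spec is not None:
        out["perturbation"] = asdict(spec)
    return out
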