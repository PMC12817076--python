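"""Hierarchical gene-annotation model and GFF3 I/O.

The object universe is the three-level hierarchy gene -> mRNA -> CDS used
throughout coordinate-based annotation comparison: a :class:`GeneModel` owns
one or more :class:`TranscriptModel` objects, each an ordered chain of coding
segments (:class:`CdsSegment`).  Exons here are *strictly coding* coordinates;
UTRs are never modelled, and a gene's span is the extent of its CDS extrema.
Introns are derived, not stored: the gap between consecutive CDS segments of
one transcript.

Coordinates follow the GFF3 convention externally (1-based, inclusive).
Interval arithmetic goes through the 0-based half-open ``lo``/``hi`` view so
overlap math never needs a ``+1``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

POSITION_CLASSES = ("initial", "internal", "terminal", "single")


class AnnotationError(Exception):
    """Base class for annotation structure and parse errors."""


class GffParseError(AnnotationError):
    """A located GFF3 parse error; ``line`` is the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class MalformedRecordError(GffParseError):
    """Wrong column count or unparseable row."""


class CoordinateError(GffParseError):
    """end < start, start < 1, or other coordinate violations."""


class UnknownParentError(GffParseError):
    """mRNA with unknown gene parent, or CDS with unknown transcript parent."""


class DuplicateIdError(GffParseError):
    """A gene ID occurring more than once in one file."""


class StructureError(AnnotationError):
    """Invalid in-memory structure (overlapping CDS, mixed strands, ...)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval on one strand of a contig (1-based, inclusive)."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise StructureError(f"invalid strand {self.strand!r}")

    @property
    def lo(self) -> int:
        """0-based half-open lower bound."""
        return self.start - 1

    @property
    def hi(self) -> int:
        """0-based half-open upper bound."""
        return self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared nucleotides between two intervals on the same contig."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.hi, b.hi) - max(a.lo, b.lo))


@dataclass(frozen=True)
class CdsSegment:
    """One coding segment (exon, coding part only) of a transcript."""

    interval: GenomicInterval
    phase: int | None = None
    position_class: str = "single"

    def __post_init__(self):
        if self.phase is not None and self.phase not in (0, 1, 2):
            raise StructureError(f"invalid phase {self.phase}")
        if self.position_class not in POSITION_CLASSES:
            raise StructureError(f"invalid position class {self.position_class!r}")


def _classify_positions(
    intervals: list[GenomicInterval], strand: str
) -> list[str]:
    """Position class of each (sorted) segment in transcription direction.

    The 5'-most segment in transcription direction is ``initial``: first by
    coordinate on '+', last on '-'.
    """
    n = len(intervals)
    if n == 1:
        return ["single"]
    classes = ["internal"] * n
    if strand == "+":
        classes[0], classes[-1] = "initial", "terminal"
    else:
        classes[0], classes[-1] = "terminal", "initial"
    return classes


def derive_introns(
    segments: list[CdsSegment], min_intron_length: int = 1
) -> list[GenomicInterval]:
    """Introns as gaps between consecutive CDS segments.

    For consecutive segments (a, b) the intron is ``[a.end+1, b.start-1]``,
    emitted only when its length is at least ``min_intron_length`` (so
    zero-length gaps — abutting segments — never produce one).  Segments must
    be sorted and non-overlapping.
    """
    introns: list[GenomicInterval] = []
    for a, b in zip(segments, segments[1:]):
        if b.interval.start <= a.interval.end:
            raise StructureError(
                f"overlapping CDS segments {a.interval} / {b.interval}"
            )
        gap = b.interval.start - a.interval.end - 1
        if gap >= min_intron_length:
            introns.append(
                GenomicInterval(
                    a.interval.contig,
                    a.interval.end + 1,
                    b.interval.start - 1,
                    a.interval.strand,
                )
            )
    return introns


@dataclass
class TranscriptModel:
    """An mRNA: ordered, non-overlapping chain of CDS segments on one strand."""

    id: str
    gene_id: str
    segments: list[CdsSegment]

    def __post_init__(self):
        if not self.segments:
            raise StructureError(f"transcript {self.id} has no CDS segments")
        self.segments = sorted(self.segments, key=lambda s: s.interval.start)
        contigs = {s.interval.contig for s in self.segments}
        strands = {s.interval.strand for s in self.segments}
        if len(contigs) > 1 or len(strands) > 1:
            raise StructureError(
                f"transcript {self.id} mixes contigs/strands: {contigs} {strands}"
            )
        # also validates non-overlap
        self._introns = derive_introns(self.segments)
        classes = _classify_positions(
            [s.interval for s in self.segments], self.strand
        )
        self.segments = [
            CdsSegment(s.interval, s.phase, c)
            for s, c in zip(self.segments, classes)
        ]

    @property
    def contig(self) -> str:
        return self.segments[0].interval.contig

    @property
    def strand(self) -> str:
        return self.segments[0].interval.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        return list(self._introns)

    @property
    def coding_length(self) -> int:
        return sum(len(s.interval) for s in self.segments)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig,
            self.segments[0].interval.start,
            self.segments[-1].interval.end,
            self.strand,
        )

    @property
    def chain(self) -> tuple[tuple[int, int], ...]:
        """The ordered CDS coordinate chain — the transcript's identity."""
        return tuple((s.interval.start, s.interval.end) for s in self.segments)


@dataclass
class GeneModel:
    """A gene locus: non-empty set of transcripts sharing contig and strand."""

    id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise StructureError(f"gene {self.id} has no transcripts")
        contigs = {t.contig for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(contigs) > 1 or len(strands) > 1:
            raise StructureError(f"gene {self.id} mixes contigs/strands")

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """CDS extrema over all transcripts (UTRs are out of scope)."""
        start = min(t.segments[0].interval.start for t in self.transcripts)
        end = max(t.segments[-1].interval.end for t in self.transcripts)
        return GenomicInterval(self.contig, start, end, self.strand)

    @property
    def chain_signature(self) -> tuple:
        """Canonical identity of the gene's full CDS structure."""
        return (self.contig, self.strand, tuple(sorted(t.chain for t in self.transcripts)))

    def footprint(self) -> list[GenomicInterval]:
        """Merged union of CDS intervals over all transcripts."""
        ivs = sorted(
            (s.interval for t in self.transcripts for s in t.segments),
            key=lambda i: i.start,
        )
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end + 1:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(
                        last.contig, last.start, iv.end, last.strand
                    )
            else:
                merged.append(iv)
        return merged


class AnnotationSet:
    """A collection of gene models with a per-(contig, strand) sorted index."""

    def __init__(self, genes: Iterable[GeneModel] = (), source_label: str = ""):
        self.source_label = source_label
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.id in self._genes:
            raise DuplicateIdError(f"duplicate gene ID {gene.id!r}")
        self._genes[gene.id] = gene
        self._index = None

    _index: dict[tuple[str, str], list[GeneModel]] | None = None

    @property
    def genes(self) -> dict[str, GeneModel]:
        return self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def index(self) -> dict[tuple[str, str], list[GeneModel]]:
        """Genes grouped by (contig, strand), sorted by span start."""
        if self._index is None:
            buckets: dict[tuple[str, str], list[GeneModel]] = {}
            for g in self._genes.values():
                buckets.setdefault((g.contig, g.strand), []).append(g)
            for bucket in buckets.values():
                bucket.sort(key=lambda g: (g.span.start, g.span.end, g.id))
            self._index = buckets
        return self._index

    def genes_on(self, contig: str, strand: str) -> list[GeneModel]:
        return list(self.index().get((contig, strand), []))

    def contigs(self) -> set[str]:
        return {g.contig for g in self}

    def subset(self, gene_ids: Iterable[str], source_label: str | None = None) -> "AnnotationSet":
        wanted = set(gene_ids)
        return AnnotationSet(
            (g for g in self if g.id in wanted),
            source_label=source_label if source_label is not None else self.source_label,
        )

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.transcripts

    def structurally_equal(self, other: "AnnotationSet") -> bool:
        """Equality of gene IDs and full CDS coordinate structure."""
        if set(self._genes) != set(other._genes):
            return False
        return all(
            self._genes[i].chain_signature == other._genes[i].chain_signature
            and [t.id for t in self._genes[i].transcripts]
            == [t.id for t in other._genes[i].transcripts]
            for i in self._genes
        )


# ---------------------------------------------------------------------------
# GFF3 I/O


def _as_stream(source) -> TextIO:
    if isinstance(source, str) and "\n" not in source and "\t" not in source:
        return open(source)
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_gff3(
    source,
    lenient: bool = False,
    source_label: str = "",
) -> AnnotationSet:
    """Parse a GFF3 gene -> mRNA -> CDS hierarchy into an :class:`AnnotationSet`.

    Parameters
    ----------
    source:
        Path, GFF3 text, or open text stream.
    lenient:
        When True, features on strand '.' are skipped with a warning instead
        of raising; transcripts without CDS are silently dropped either way.

    Raises located errors (:class:`MalformedRecordError`,
    :class:`CoordinateError`, :class:`UnknownParentError`,
    :class:`DuplicateIdError`) naming the offending line.
    """
    stream = _as_stream(source)
    gene_lines: list[tuple[int, str, GenomicInterval]] = []  # (line, id, span)
    mrna_parent: dict[str, str] = {}
    mrna_order: list[str] = []
    cds_by_parent: dict[str, list[CdsSegment]] = {}
    seen_gene_ids: set[str] = set()

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise MalformedRecordError(
                f"expected 9 tab-separated columns, got {len(cols)}", line_no
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # pragma: no cover - defensive
            raise MalformedRecordError(str(exc), line_no) from exc
        ftype = feat.featuretype
        if ftype not in ("gene", "mRNA", "transcript", "CDS"):
            continue
        if feat.end < feat.start or feat.start < 1:
            raise CoordinateError(
                f"end < start ({feat.start}..{feat.end})", line_no
            )
        if feat.strand not in ("+", "-"):
            if lenient:
                logger.warning(
                    "line %d: skipping %s feature with strand %r",
                    line_no, ftype, feat.strand,
                )
                continue
            raise CoordinateError(
                f"unstranded {ftype} feature (strand {feat.strand!r}); "
                "use lenient=True to skip", line_no
            )
        interval = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        attrs = feat.attributes
        if ftype == "gene":
            gid = (attrs.get("ID") or [None])[0]
            if gid is None:
                raise MalformedRecordError("gene feature without ID", line_no)
            if gid in seen_gene_ids:
                raise DuplicateIdError(f"duplicate gene ID {gid!r}", line_no)
            seen_gene_ids.add(gid)
            gene_lines.append((line_no, gid, interval))
        elif ftype in ("mRNA", "transcript"):
            tid = (attrs.get("ID") or [None])[0]
            parents = attrs.get("Parent") or []
            if tid is None:
                raise MalformedRecordError("mRNA feature without ID", line_no)
            if not parents:
                raise UnknownParentError(
                    f"mRNA {tid!r} has no Parent attribute", line_no
                )
            if parents[0] not in seen_gene_ids:
                raise UnknownParentError(
                    f"mRNA {tid!r} references unknown gene {parents[0]!r}",
                    line_no,
                )
            mrna_parent[tid] = parents[0]
            mrna_order.append(tid)
        else:  # CDS
            parents = attrs.get("Parent") or []
            if not parents:
                raise UnknownParentError("CDS without Parent attribute", line_no)
            phase = None
            if feat.frame in ("0", "1", "2"):
                phase = int(feat.frame)
            for parent in parents:
                if parent not in mrna_parent:
                    raise UnknownParentError(
                        f"CDS references unknown transcript {parent!r}", line_no
                    )
                cds_by_parent.setdefault(parent, []).append(
                    CdsSegment(interval, phase)
                )
    if stream is not source:
        stream.close()

    transcripts_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid in mrna_order:
        segs = cds_by_parent.get(tid)
        if not segs:
            continue  # coding model required; CDS-less transcripts are dropped
        gid = mrna_parent[tid]
        transcripts_by_gene.setdefault(gid, []).append(
            TranscriptModel(tid, gid, segs)
        )

    annotation = AnnotationSet(source_label=source_label)
    for _, gid, _ in gene_lines:
        if gid in transcripts_by_gene:
            annotation.add(GeneModel(gid, transcripts_by_gene[gid]))
    return annotation


def write_gff3(annotation: AnnotationSet) -> str:
    """Serialize an :class:`AnnotationSet` as GFF3 text.

    Rows are deterministically ordered by (contig, start, gene id), so
    ``parse_gff3(write_gff3(a))`` is structurally equal to ``a``.
    """
    src = annotation.source_label or "annoteval"
    out = ["##gff-version 3"]
    genes = sorted(annotation, key=lambda g: (g.contig, g.span.start, g.id))
    for g in genes:
        span = g.span
        out.append(
            f"{g.contig}\t{src}\tgene\t{span.start}\t{span.end}\t.\t"
            f"{g.strand}\t.\tID={g.id}"
        )
        for t in g.transcripts:
            ts = t.span
            out.append(
                f"{g.contig}\t{src}\tmRNA\t{ts.start}\t{ts.end}\t.\t"
                f"{g.strand}\t.\tID={t.id};Parent={g.id}"
            )
            for s in t.segments:
                phase = "." if s.phase is None else str(s.phase)
                out.append(
                    f"{g.contig}\t{src}\tCDS\t{s.interval.start}\t"
                    f"{s.interval.end}\t.\t{g.strand}\t{phase}\tParent={t.id}"
                )
    return "\n".join(out) + "\n"


def read_id_list(source) -> set[str]:
    """Read a plain-text identifier list: one ID per line, '#' comments."""
    stream = _as_stream(source)
    ids = set()
    for raw in stream:
        line = raw.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    if stream is not source:
        stream.close()
    return ids
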