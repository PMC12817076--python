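"""Gold-standard reference-set extension from BUSCO assessments.

Curated (Swiss-Prot-backed) reference genes are scarce outside a handful of
model organisms.  The extension strategy: run BUSCO on the translated
reference genes, and supplement the curated set with uncurated genes whose
proteins BUSCO reports as complete.  Two statistics validate the supplement —
a two-proportion z-test of fragmented-to-complete rates between curated and
uncurated groups, and (upstream of this module) a DTS comparison of per-gene
F1 ECDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GffParseError, _as_stream
from .stats import two_proportion_ztest

BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")
DEFAULT_COMPLETE_CLASS = frozenset({"Complete", "Duplicated"})


class BuscoParseError(GffParseError):
    """Located error in a BUSCO full_table.tsv file."""


@dataclass(frozen=True)
class BuscoRecord:
    busco_id: str
    status: str
    sequence_id: str | None = None
    score: float | None = None
    length: int | None = None


@dataclass
class GoldStandardSet:
    """Curated genes plus BUSCO-complete uncurated genes, with provenance."""

    members: dict[str, str] = field(default_factory=dict)  # id -> provenance
    organism_label: str = ""

    @property
    def curated_count(self) -> int:
        return sum(1 for p in self.members.values() if p in ("curated", "both"))

    @property
    def added_count(self) -> int:
        return sum(1 for p in self.members.values() if p == "busco_complete")

    @property
    def percent_increase(self) -> float | None:
        """100 * added / curated; None when there are no curated genes."""
        if self.curated_count == 0:
            return None
        return 100.0 * self.added_count / self.curated_count

    def summary(self) -> dict:
        return {
            "organism": self.organism_label,
            "total": len(self.members),
            "curated": self.curated_count,
            "busco_complete_added": self.added_count,
            "percent_increase": self.percent_increase,
        }


def parse_busco_table(source) -> list[BuscoRecord]:
    """Parse a BUSCO ``full_table.tsv``.

    Expected tab-separated columns: busco id, status, sequence, score,
    length; '#'-prefixed lines are comments; trailing columns are tolerated;
    Missing rows carry no sequence.  Unknown statuses and short rows raise a
    located :class:`BuscoParseError`.
    """
    stream = _as_stream(source)
    records: list[BuscoRecord] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise BuscoParseError(
                f"expected at least 2 columns, got {len(cols)}", line_no)
        busco_id, status = cols[0].strip(), cols[1].strip()
        if status not in BUSCO_STATUSES:
            raise BuscoParseError(
                f"unknown BUSCO status {status!r} "
                f"(expected one of {BUSCO_STATUSES})", line_no)
        if status == "Missing":
            records.append(BuscoRecord(busco_id, status))
            continue
        if len(cols) < 3 or not cols[2].strip():
            raise BuscoParseError(
                f"{status} row without a sequence identifier", line_no)
        score = _opt_float(cols, 3)
        length = _opt_int(cols, 4)
        records.append(
            BuscoRecord(busco_id, status, cols[2].strip(), score, length))
    if stream is not source:
        stream.close()
    return records


def _opt_float(cols, i):
    try:
        return float(cols[i]) if len(cols) > i and cols[i].strip() else None
    except ValueError:
        return None


def _opt_int(cols, i):
    try:
        return int(float(cols[i])) if len(cols) > i and cols[i].strip() else None
    except ValueError:
        return None


def partition_by_curation(
    records: list[BuscoRecord], curated_ids: set[str]
) -> tuple[list[BuscoRecord], list[BuscoRecord]]:
    """Split records into (curated, uncurated) by sequence id membership.

    Missing-status records carry no gene and belong to neither group.
    """
    curated, uncurated = [], []
    for rec in records:
        if rec.status == "Missing" or rec.sequence_id is None:
            continue
        (curated if rec.sequence_id in curated_ids else uncurated).append(rec)
    return curated, uncurated


def fragmented_complete_ztest(
    group_1: list[BuscoRecord],
    group_2: list[BuscoRecord],
    complete_statuses: frozenset = DEFAULT_COMPLETE_CLASS,
) -> tuple[float, float, tuple[float, float]]:
    """z-test of the fragmented proportion between two BUSCO record groups.

    Successes are Fragmented records; trials are Fragmented plus
    complete-class records.  Returns (z, two-sided p, (ratio_1, ratio_2)).
    """
    def frag_trials(group):
        frag = sum(1 for r in group if r.status == "Fragmented")
        comp = sum(1 for r in group if r.status in complete_statuses)
        return frag, frag + comp

    f1, t1 = frag_trials(group_1)
    f2, t2 = frag_trials(group_2)
    if t1 == 0 or t2 == 0:
        raise ValueError("each group needs at least one fragmented or "
                         "complete-class record")
    z, p = two_proportion_ztest(f1, t1, f2, t2)
    return z, p, (f1 / t1, f2 / t2)


def build_gold_standard(
    records: list[BuscoRecord],
    curated_ids: set[str],
    complete_statuses: frozenset = DEFAULT_COMPLETE_CLASS,
    organism_label: str = "",
) -> GoldStandardSet:
    """Extend a curated gene list with uncurated BUSCO-complete genes.

    Curated genes are included regardless of their BUSCO status (curation is
    the higher evidence tier); uncurated genes enter when any of their
    records has a complete-class status.  Provenance is ``both`` for curated
    genes that BUSCO also reports complete.
    """
    members: dict[str, str] = {gid: "curated" for gid in sorted(curated_ids)}
    for rec in records:
        if rec.sequence_id is None or rec.status not in complete_statuses:
            continue
        if rec.sequence_id in curated_ids:
            members[rec.sequence_id] = "both"
        elif rec.sequence_id not in members:
            members[rec.sequence_id] = "busco_complete"
    return GoldStandardSet(members, organism_label)
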