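"""Accuracy statistics and distribution tests for annotation comparison.

Implements the Burset–Guigó-style sensitivity/precision/F1 statistics at
nucleotide, exon, intron, and transcript stringencies, plus two hypothesis
tests used to validate extended reference sets: a variance-weighted
two-sample ECDF statistic (DTS) with permutation significance, and the pooled
two-proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import AnnotationSet

LEVELS = ("nucleotide", "exon", "intron", "transcript")


@dataclass(frozen=True)
class ConfusionCounts:
    level: str
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class AccuracyStats:
    """Sensitivity TP/(TP+FN), precision TP/(TP+FP) and their harmonic mean.

    All 0/0 cases resolve to 0, so an empty comparison scores zero rather
    than raising.
    """

    Sn: float
    Pr: float
    F1: float


@dataclass
class EcdfSample:
    """A labelled sample of per-gene scores for ECDF comparison."""

    values: list[float]
    label: str = ""


def _merged_intervals(annotation: AnnotationSet) -> dict[tuple[str, str], np.ndarray]:
    """Union of CDS coverage per (contig, strand) as merged (lo, hi) pairs."""
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gene in annotation:
        key = (gene.contig, gene.strand)
        bucket = raw.setdefault(key, [])
        for t in gene.transcripts:
            for s in t.segments:
                bucket.append((s.interval.lo, s.interval.hi))
    out = {}
    for key, ivs in raw.items():
        ivs.sort()
        merged = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out[key] = np.asarray(merged, dtype=np.int64)
    return out


def _intersection_length(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap between two merged, sorted half-open interval arrays."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def _feature_sets(annotation: AnnotationSet, level: str) -> set:
    feats = set()
    for gene in annotation:
        for t in gene.transcripts:
            if level == "exon":
                for s in t.segments:
                    feats.add((gene.contig, gene.strand,
                               s.interval.start, s.interval.end))
            elif level == "intron":
                for iv in t.introns:
                    feats.add((gene.contig, gene.strand, iv.start, iv.end))
            else:  # transcript
                feats.add((gene.contig, gene.strand, t.chain))
    return feats


def confusion_counts(
    prediction: AnnotationSet,
    reference: AnnotationSet,
    level: str,
) -> ConfusionCounts:
    """TP/FP/FN between two annotation sets at the given stringency.

    ``nucleotide`` compares per-base CDS membership on each strand;
    ``exon``/``intron`` count exact-coordinate feature matches (distinct
    coordinates, so isoform-shared features count once); ``transcript``
    counts exact CDS-chain matches.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "nucleotide":
        pred_cov = _merged_intervals(prediction)
        ref_cov = _merged_intervals(reference)
        tp = fp = fn = 0
        for key in set(pred_cov) | set(ref_cov):
            p = pred_cov.get(key, np.empty((0, 2), dtype=np.int64))
            r = ref_cov.get(key, np.empty((0, 2), dtype=np.int64))
            inter = _intersection_length(p, r)
            tp += inter
            fp += int((p[:, 1] - p[:, 0]).sum()) - inter
            fn += int((r[:, 1] - r[:, 0]).sum()) - inter
        return ConfusionCounts("nucleotide", tp, fp, fn)
    pred_feats = _feature_sets(prediction, level)
    ref_feats = _feature_sets(reference, level)
    tp = len(pred_feats & ref_feats)
    return ConfusionCounts(level, tp, len(pred_feats) - tp, len(ref_feats) - tp)


def sn_pr_f1(counts: ConfusionCounts) -> AccuracyStats:
    """Sensitivity, precision, F1 from a confusion triple (0/0 -> 0)."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    pr = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * sn * pr / (sn + pr) if sn + pr else 0.0
    return AccuracyStats(sn, pr, f1)


# ---------------------------------------------------------------------------
# DTS two-sample ECDF test


def _values(sample) -> np.ndarray:
    vals = np.asarray(
        sample.values if isinstance(sample, EcdfSample) else sample,
        dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("sample must be a non-empty 1-d collection")
    return vals


def _dts_from_masks(x_sorted: np.ndarray, masks: np.ndarray,
                    n: int, m: int) -> np.ndarray:
    """DTS for each row-mask (True where the sorted pooled value is group A).

    At tied pooled values the spacing term is zero, so cumulative counts by
    sorted position equal the ECDFs wherever a term contributes.
    """
    total = n + m
    dx = np.diff(x_sorted)                        # (total-1,)
    k = np.arange(1, total)
    h = k / total
    w = np.sqrt(h * (1.0 - h))                    # >0 for k in 1..total-1
    cum_a = np.cumsum(masks, axis=1)[:, :-1]
    f = cum_a / n
    g = (k[None, :] - cum_a) / m
    return (np.abs(f - g) * dx[None, :] / w[None, :]).sum(axis=1)


def dts_statistic(sample_a, sample_b) -> float:
    """Variance-weighted integrated ECDF difference of two samples.

    Sums |F(x) - G(x)| * dx / sqrt(H(x) (1 - H(x))) over the pooled sorted
    values, where H is the pooled ECDF; symmetric in its arguments and zero
    when the two multisets coincide.  Scaling both samples by c > 0 scales
    the statistic by c (through the spacing term).
    """
    a, b = _values(sample_a), _values(sample_b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    mask = (np.arange(pooled.size) < a.size)[order][None, :]
    return float(_dts_from_masks(pooled[order], mask, a.size, b.size)[0])


def dts_test(
    sample_a,
    sample_b,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation two-sample test on the DTS statistic.

    Pooled values are re-split into groups of the original sizes
    ``n_permutations`` times; the p-value uses the add-one estimator
    ``(1 + #{permuted >= observed}) / (n_permutations + 1)``, so it can never
    be exactly zero.  Deterministic for a fixed seed.
    """
    a, b = _values(sample_a), _values(sample_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    x_sorted = pooled[order]
    n, m = a.size, b.size
    obs_mask = (np.arange(pooled.size) < n)[order][None, :]
    observed = float(_dts_from_masks(x_sorted, obs_mask, n, m)[0])

    rng = np.random.default_rng(seed)
    stats = np.empty(n_permutations)
    # vectorized in blocks: each row is a uniformly random n-subset mask
    block = 256
    done = 0
    while done < n_permutations:
        size = min(block, n_permutations - done)
        ranks = np.argsort(rng.random((size, n + m)), axis=1)
        masks = ranks < n
        stats[done:done + size] = _dts_from_masks(x_sorted, masks, n, m)
        done += size
    p = (1.0 + np.count_nonzero(stats >= observed)) / (n_permutations + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# two-proportion z-test


def two_proportion_ztest(
    successes_1: int, n_1: int, successes_2: int, n_2: int
) -> tuple[float, float]:
    """Pooled two-sample z-test of proportions, two-sided, no continuity
    correction.

    Degenerate pooled proportions (0 or 1) have zero variance; the test is
    then vacuous and returns (0, 1).
    """
    if n_1 < 1 or n_2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= successes_1 <= n_1 and 0 <= successes_2 <= n_2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = successes_1 / n_1, successes_2 / n_2
    pooled = (successes_1 + successes_2) / (n_1 + n_2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_1 + 1.0 / n_2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))
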