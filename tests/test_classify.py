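"""Gene outcome classification, transcript matching, tallies, concordance."""

import itertools

import numpy as np
import pytest

import annoteval as av
from annoteval.classify import transcript_overlap

from conftest import make_gene, make_set


def iv(s, e, strand="+", contig="chr1"):
    return av.GenomicInterval(contig, s, e, strand)


class TestCoverageFraction:
    def test_half_coverage(self):
        assert av.coverage_fraction(iv(101, 200), iv(151, 250)) == 0.5

    def test_identity(self):
        assert av.coverage_fraction(iv(101, 200), iv(101, 200)) == 1.0

    def test_disjoint(self):
        assert av.coverage_fraction(iv(1, 50), iv(100, 200)) == 0.0

    def test_different_contigs_error(self):
        with pytest.raises(ValueError):
            av.coverage_fraction(iv(1, 50), iv(1, 50, contig="chr2"))


def outcomes_of(classifications):
    return av.labels_by_reference(classifications)


class TestClassifyGenes:
    def test_identical_sets_all_exact(self, synthetic_pair):
        ref, _, _ = synthetic_pair
        renamed = make_set(
            [av.GeneModel(f"p_{g.id}", g.transcripts) for g in ref])
        labels = outcomes_of(av.classify_genes(renamed, ref))
        assert set(labels.values()) == {"exact"}

    def test_merged_rule(self):
        refs = make_set([make_gene("A", [(1100, 1500)]),
                         make_gene("B", [(2000, 2800)])])
        preds = make_set([make_gene("P", [(1000, 3000)])])
        (c,) = [c for c in av.classify_genes(preds, refs)
                if c.outcome == "merged"]
        assert sorted(c.reference_ids) == ["A", "B"]
        assert c.coverage_fractions[("P", "A")] == 1.0

    def test_merged_needs_majority_coverage_of_each_reference(self):
        # B is covered by only ~19% of its span: not a merge
        refs = make_set([make_gene("A", [(1100, 1500)]),
                         make_gene("B", [(2000, 3600)])])
        preds = make_set([make_gene("P", [(1000, 2300)])])
        labels = outcomes_of(av.classify_genes(preds, refs))
        assert labels == {"A": "inexact", "B": "missing"}

    def test_fragmented_rule(self):
        refs = make_set([make_gene("R", [(1000, 3000)])])
        preds = make_set([make_gene("P1", [(1000, 1800)]),
                          make_gene("P2", [(2200, 3000)])])
        (c,) = av.classify_genes(preds, refs)
        assert c.outcome == "fragmented"
        assert sorted(c.prediction_ids) == ["P1", "P2"]

    def test_overlapping_fragments_fall_back_to_inexact_match(self):
        # P1 and P2 share [1700, 1800]; with mutual overlap capped at 0 the
        # fragments are not "separate portions" -> best-overlap prediction
        # matches inexactly, the other is unassigned.
        refs = make_set([make_gene("R", [(1000, 3000)])])
        preds = make_set([make_gene("P1", [(1000, 1800)]),
                          make_gene("P2", [(1700, 3000)])])
        by_outcome = {c.outcome: c for c in av.classify_genes(preds, refs)}
        assert set(by_outcome) == {"inexact", "unassigned_prediction"}
        assert by_outcome["inexact"].prediction_ids == ["P2"]  # larger overlap
        assert by_outcome["unassigned_prediction"].prediction_ids == ["P1"]

    def test_unmatched_reference_is_missing(self):
        refs = make_set([make_gene("R", [(1000, 2000)])])
        labels = outcomes_of(av.classify_genes(make_set([]), refs))
        assert labels == {"R": "missing"}

    def test_strand_reversal_zeroes_all_matches(self, synthetic_pair):
        ref, _, _ = synthetic_pair
        pred = make_set(
            [av.GeneModel(f"p_{g.id}", g.transcripts) for g in ref])
        flipped = make_set([
            av.GeneModel(g.id, [
                av.TranscriptModel(t.id, g.id, [
                    av.CdsSegment(av.GenomicInterval(
                        s.interval.contig, s.interval.start, s.interval.end,
                        "-" if s.interval.strand == "+" else "+"))
                    for s in t.segments])
                for t in g.transcripts])
            for g in pred])
        labels = outcomes_of(av.classify_genes(flipped, ref))
        assert set(labels.values()) == {"missing"}

    def test_reference_partition_no_double_counting(self, synthetic_pair):
        ref, pred, _ = synthetic_pair
        labels = outcomes_of(av.classify_genes(pred, ref))  # raises on dups
        assert set(labels) == set(ref.genes)

    def test_threshold_monotonicity(self, synthetic_pair):
        ref, pred, _ = synthetic_pair
        merged_counts, frag_counts = [], []
        for th in (0.3, 0.5, 0.7):
            cls_m = av.classify_genes(
                pred, ref, av.ClassifierThresholds(merged_ref_coverage=th))
            merged_counts.append(
                sum(1 for c in cls_m if c.outcome == "merged"))
            cls_f = av.classify_genes(
                pred, ref, av.ClassifierThresholds(fragment_pred_coverage=th))
            frag_counts.append(
                sum(1 for c in cls_f if c.outcome == "fragmented"))
        assert merged_counts == sorted(merged_counts, reverse=True)
        assert frag_counts == sorted(frag_counts, reverse=True)

    def test_thresholds_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            av.ClassifierThresholds(merged_ref_coverage=1.5)


class TestMatchTranscripts:
    def test_identity_pair(self):
        ref = make_gene("R", [(100, 200), (300, 400)])
        pred = make_gene("P", [(100, 200), (300, 400)])
        a = av.match_transcripts([pred], [ref])
        assert a.pairs == {"P.t1": "R.t1"}
        assert a.total_overlap == ref.transcripts[0].coding_length
        assert not a.missing_refs and not a.false_positive_preds

    def test_optimal_beats_greedy(self):
        # overlaps: P1.R1=100, P1.R2=90, P2.R1=95, P2.R2=0
        ref = av.GeneModel("R", [
            av.TranscriptModel("R1", "R", [av.CdsSegment(iv(1, 195))]),
            av.TranscriptModel("R2", "R", [av.CdsSegment(iv(300, 389))]),
        ])
        pred = av.GeneModel("P", [
            av.TranscriptModel("P1", "P", [av.CdsSegment(iv(96, 195)),
                                           av.CdsSegment(iv(300, 389))]),
            av.TranscriptModel("P2", "P", [av.CdsSegment(iv(1, 95))]),
        ])
        w = {(p.id, r.id): transcript_overlap(p, r)
             for p in pred.transcripts for r in ref.transcripts}
        assert w == {("P1", "R1"): 100, ("P1", "R2"): 90,
                     ("P2", "R1"): 95, ("P2", "R2"): 0}
        a = av.match_transcripts([pred], [ref])
        assert a.total_overlap == 185
        assert a.pairs == {"P1": "R2", "P2": "R1"}

    def test_surplus_prediction_is_false_positive(self):
        ref = make_gene("R", [(100, 400)])
        pred = av.GeneModel("P", [
            av.TranscriptModel("P.t1", "P", [av.CdsSegment(iv(100, 400))]),
            av.TranscriptModel("P.t2", "P", [av.CdsSegment(iv(100, 250))]),
        ])
        a = av.match_transcripts([pred], [ref])
        assert len(a.pairs) == 1
        assert a.false_positive_preds == ["P.t2"]

    def test_zero_overlap_pairs_never_created(self):
        ref = make_gene("R", [(100, 200)])
        pred = make_gene("P", [(900, 950)])
        a = av.match_transcripts([pred], [ref])
        assert a.pairs == {}
        assert a.missing_refs == ["R.t1"]
        assert a.false_positive_preds == ["P.t1"]

    def test_both_groups_empty_is_an_error(self):
        with pytest.raises(ValueError):
            av.match_transcripts([], [])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(40):
            n, m = rng.integers(1, 5, size=2)
            refs = [_random_transcript_gene(rng, f"R{i}") for i in range(n)]
            preds = [_random_transcript_gene(rng, f"P{j}") for j in range(m)]
            a = av.match_transcripts(preds, refs)
            assert a.total_overlap == _brute_force_best(preds, refs)


def _random_transcript_gene(rng, gid):
    start = int(rng.integers(1, 600))
    exons, cursor = [], start
    for _ in range(int(rng.integers(1, 4))):
        length = int(rng.integers(20, 120))
        exons.append((cursor, cursor + length - 1))
        cursor += length + int(rng.integers(2, 80))
    return make_gene(gid, exons)


def _brute_force_best(pred_genes, ref_genes):
    preds = [t for g in pred_genes for t in g.transcripts]
    refs = [t for g in ref_genes for t in g.transcripts]
    if len(refs) > len(preds):
        preds, refs = refs, preds
    best = 0
    for perm in itertools.permutations(range(len(preds)), len(refs)):
        best = max(best, sum(
            transcript_overlap(preds[j], refs[i])
            for i, j in enumerate(perm)))
    return best


class TestTallySubfeatures:
    def tally(self, pred_gene, ref_gene):
        return av.tally_subfeatures(
            av.match_transcripts([pred_gene], [ref_gene]))

    def test_identical_three_exon_pair(self):
        ref = make_gene("R", [(100, 200), (300, 400), (500, 600)])
        pred = make_gene("P", [(100, 200), (300, 400), (500, 600)])
        t = self.tally(pred, ref)
        assert (t["exon"].matched, t["exon"].missing,
                t["exon"].false_positive) == (3, 0, 0)
        assert t["exon"].exact_matched == 3
        assert (t["intron"].matched, t["intron"].missing,
                t["intron"].false_positive) == (2, 0, 0)

    def test_missing_terminal_exon(self):
        ref = make_gene("R", [(100, 200), (300, 400), (500, 600)])
        pred = make_gene("P", [(100, 200), (300, 400)])
        t = self.tally(pred, ref)
        assert (t["exon"].matched, t["exon"].missing,
                t["exon"].false_positive) == (2, 1, 0)
        assert t["exon"].exon_position_breakdown["terminal"]["missing"] == 1
        assert (t["intron"].matched, t["intron"].missing,
                t["intron"].false_positive) == (1, 1, 0)

    def test_extra_exon_splitting_reference_exon(self):
        ref = make_gene("R", [(100, 400), (500, 600)])
        pred = make_gene("P", [(100, 200), (300, 400), (500, 600)])
        t = self.tally(pred, ref)
        assert t["exon"].false_positive >= 1
        assert t["intron"].false_positive >= 1
        # tally identities
        assert t["exon"].matched + t["exon"].missing == 2
        assert t["exon"].matched + t["exon"].false_positive == 3

    def test_unassigned_transcript_features_count_wholesale(self, synthetic_pair):
        ref, pred, _ = synthetic_pair
        for c in av.classify_genes(pred, ref):
            pg = [pred[p] for p in c.prediction_ids]
            rg = [ref[r] for r in c.reference_ids]
            if not pg and not rg:
                continue
            t = av.tally_subfeatures(av.match_transcripts(pg, rg))
            n_ref_tx = sum(len(g.transcripts) for g in rg)
            n_pred_tx = sum(len(g.transcripts) for g in pg)
            assert t["transcript"].matched + t["transcript"].missing == n_ref_tx
            assert (t["transcript"].matched
                    + t["transcript"].false_positive) == n_pred_tx
            n_ref_ex = sum(len(t_.segments) for g in rg
                           for t_ in g.transcripts)
            n_pred_ex = sum(len(t_.segments) for g in pg
                            for t_ in g.transcripts)
            assert t["exon"].matched + t["exon"].missing == n_ref_ex
            assert t["exon"].matched + t["exon"].false_positive == n_pred_ex


class TestSelectConcordant:
    def chains(self, annot):
        return {g.chain_signature for g in annot}

    def test_unanimous_chain_selected_with_full_support(self):
        g = make_gene("x", [(100, 200), (300, 400)])
        sources = [make_set([make_gene(f"x{i}", [(100, 200), (300, 400)])],
                            label=l) for i, l in enumerate("abc")]
        out = av.select_concordant(*sources)
        assert len(out) == 1
        (support,) = out.provenance.values()
        assert sorted(support) == ["a", "b", "c"]
        assert self.chains(out) == {g.chain_signature}

    def test_single_source_chain_excluded(self):
        a = make_set([make_gene("x", [(100, 200)])], label="a")
        b = make_set([], label="b")
        c = make_set([], label="c")
        assert len(av.select_concordant(a, b, c)) == 0

    def test_majority_chain_wins_at_shared_locus(self):
        x = [(100, 200), (300, 400)]
        y = [(100, 250), (300, 400)]
        a = make_set([make_gene("ga", x)], label="a")
        b = make_set([make_gene("gb", x)], label="b")
        c = make_set([make_gene("gc", y)], label="c")
        out = av.select_concordant(a, b, c)
        assert self.chains(out) == {make_gene("ga", x).chain_signature}

    def test_min_agree_bounds(self):
        a = make_set([], label="a")
        with pytest.raises(ValueError):
            av.select_concordant(a, a, a, min_agree=0)
        with pytest.raises(ValueError):
            av.select_concordant(a, a, a, min_agree=4)
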