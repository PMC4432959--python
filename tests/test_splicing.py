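"""Alternative-splicing classification: definitional cases, recovery, summary."""

import numpy as np
import pytest

from reannot.model import AnnotationError, Gene, Interval, Transcript
from reannot.splicing import (AS_CLASSES, EventFilterParams, ASEvent,
                              classify_annotation, classify_gene,
                              filter_events, pairwise_events,
                              summarize_counts, summarize_events)


def _tx(tid, exon_pairs, strand="+", scaffold="s", gene="g"):
    return Transcript(id=tid, gene_id=gene,
                      exons=[Interval(scaffold, s, e, strand)
                             for s, e in exon_pairs])


CANON = [(0, 100), (200, 300), (400, 500), (600, 700)]


class TestPairwiseDefinitional:
    def test_identical_chains_no_events(self):
        assert pairwise_events(_tx("c", CANON), _tx("a", CANON)) == []

    def test_different_strands_error(self):
        with pytest.raises(AnnotationError):
            pairwise_events(_tx("c", CANON), _tx("a", CANON, strand="-"))

    def test_intron_retention(self):
        alt = [(0, 100), (200, 500), (600, 700)]  # reads through intron 2
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("IntRt", 300, 400)]

    def test_alt_acceptor_plus_strand(self):
        alt = [(0, 100), (230, 300), (400, 500), (600, 700)]  # acceptor +30
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("AltAc", 200, 230)]

    def test_alt_donor_plus_strand(self):
        alt = [(0, 80), (200, 300), (400, 500), (600, 700)]  # donor -20
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("AltDo", 80, 100)]

    def test_donor_acceptor_swap_on_minus_strand(self):
        # same genomic change as the AltAc(+) case is AltDo on '-'
        alt = [(0, 100), (230, 300), (400, 500), (600, 700)]
        events = pairwise_events(_tx("c", CANON, strand="-"),
                                 _tx("a", alt, strand="-"))
        assert [e.event_class for e in events] == ["AltDo"]

    def test_exon_skipping(self):
        alt = [(0, 100), (400, 500), (600, 700)]  # exon 2 skipped
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("ExSk", 200, 300)]

    def test_alternative_terminal_exon(self):
        # last exon replaced by a novel exon inside the last intron
        alt = [(0, 100), (200, 300), (400, 500), (520, 580)]
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("AltTEx", 520, 580)]

    def test_intronic_start(self):
        alt = [(150, 300), (400, 500), (600, 700)]  # starts inside intron 1
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("IntSt", 100, 200)]

    def test_intronic_end(self):
        alt = [(0, 100), (200, 300), (400, 550)]  # ends inside intron 3
        events = pairwise_events(_tx("c", CANON), _tx("a", alt))
        assert [(e.event_class, e.footprint.start, e.footprint.end)
                for e in events] == [("IntEnd", 500, 600)]

    def test_translation_invariance(self):
        shift = 10_000
        alt = [(0, 100), (200, 500), (600, 700)]
        base = pairwise_events(_tx("c", CANON), _tx("a", alt))
        moved = pairwise_events(
            _tx("c", [(s + shift, e + shift) for s, e in CANON]),
            _tx("a", [(s + shift, e + shift) for s, e in alt]))
        assert [(e.event_class, e.footprint.start - shift,
                 e.footprint.end - shift) for e in moved] == \
            [(e.event_class, e.footprint.start, e.footprint.end)
             for e in base]

    def test_strand_mirror_invariance(self):
        L = 10_000

        def mirror(pairs):
            return sorted((L - e, L - s) for s, e in pairs)

        for alt in ([(0, 100), (200, 500), (600, 700)],        # IntRt
                    [(0, 100), (400, 500), (600, 700)],        # ExSk
                    [(0, 100), (230, 300), (400, 500), (600, 700)]):  # AltAc
            base = pairwise_events(_tx("c", CANON), _tx("a", alt))
            mirrored = pairwise_events(
                _tx("c", mirror(CANON), strand="-"),
                _tx("a", mirror(alt), strand="-"))
            assert sorted(e.event_class for e in base) == \
                sorted(e.event_class for e in mirrored)
            assert sorted((L - e.footprint.end, L - e.footprint.start)
                          for e in base) == \
                sorted((e.footprint.start, e.footprint.end)
                       for e in mirrored)


class TestClassifyGene:
    def test_single_isoform_gene(self):
        gene = Gene("g", [_tx("c", CANON)])
        assert classify_gene(gene, "c") == []

    def test_three_supporters_merged_into_one_event(self):
        alt = [(0, 100), (200, 500), (600, 700)]
        gene = Gene("g", [_tx("c", CANON)] +
                    [_tx(f"a{i}", alt) for i in range(3)])
        events = classify_gene(gene, "c")
        assert len(events) == 1
        assert events[0].event_class == "IntRt"
        assert events[0].supporting == {"a0", "a1", "a2"}
        assert events[0].supporting.isdisjoint(events[0].reference)

    def test_two_distinct_events_disjoint_supporters(self):
        ret = [(0, 100), (200, 500), (600, 700)]
        skip = [(0, 100), (400, 500), (600, 700)]
        gene = Gene("g", [_tx("c", CANON), _tx("r1", ret), _tx("s1", skip)])
        events = classify_gene(gene, "c")
        assert sorted(e.event_class for e in events) == ["ExSk", "IntRt"]
        sup = [e.supporting for e in events]
        assert sup[0].isdisjoint(sup[1])


class TestFilterEvents:
    def _ev(self, n):
        return ASEvent("IntRt", "g", Interval("s", 0, 10),
                       frozenset(f"t{i}" for i in range(n)), frozenset({"c"}))

    def test_min_three_rule(self):
        events = [self._ev(3), self._ev(2), self._ev(5)]
        kept = filter_events(events)
        assert [len(e.supporting) for e in kept] == [3, 5]

    def test_empty_and_identity(self):
        assert filter_events([]) == []
        events = [self._ev(1), self._ev(2)]
        assert filter_events(events, EventFilterParams(min_support=1)) == events


class TestSummarize:
    # published per-class event and transcript tallies, used as a fixed
    # arithmetic check of the summary percentage columns
    EVENTS = dict(zip(AS_CLASSES, [12610, 6191, 4843, 3562, 513, 148, 132]))
    TRANSCRIPTS = dict(zip(AS_CLASSES, [8643, 4442, 4163, 3175, 500, 148, 132]))

    def test_percent_of_events_column(self):
        s = summarize_counts(self.EVENTS, self.TRANSCRIPTS, 47_895)
        assert s.pct_of_events("IntRt") == 45.0
        assert s.pct_of_events("AltTEx") == 22.1
        assert s.pct_of_events("ExSk") == 1.8

    def test_percent_of_all_transcripts_column(self):
        s = summarize_counts(self.EVENTS, self.TRANSCRIPTS, 47_895)
        assert s.pct_of_all_transcripts("IntRt") == 18.0
        assert s.pct_of_all_transcripts("AltDo") == 6.6

    def test_event_percentages_sum_to_100(self):
        s = summarize_counts(self.EVENTS, self.TRANSCRIPTS, 47_895)
        total = sum(s.pct_of_events(c) for c in AS_CLASSES)
        assert abs(total - 100.0) <= 0.4

    def test_single_event_single_transcript(self):
        ev = ASEvent("IntRt", "g", Interval("s", 0, 10),
                     frozenset({"t1"}), frozenset({"c"}))
        s = summarize_events([ev], total_transcripts=10)
        assert s.pct_of_events("IntRt") == 100.0
        assert s.pct_of_all_transcripts("IntRt") == 10.0
        assert s.pct_of_as_transcripts("IntRt") == 100.0

    def test_no_events_no_division_error(self):
        s = summarize_events([], total_transcripts=100)
        assert s.total_events == 0
        assert all(s.pct_of_events(c) == 0.0 for c in AS_CLASSES)


class TestRecoveryFromTruth:
    def test_precision_recall_one_per_class(self, iso_sim):
        _, genome, iso, _, as_truth = iso_sim
        events = classify_annotation(iso, genome=genome)
        pred = {(e.gene_id, e.event_class, e.footprint) for e in events}
        true = {(e.gene_id, e.event_class, e.footprint)
                for e in as_truth.as_events}
        assert pred == true

    def test_random_isoform_pairs_match_truth_labels(self, iso_sim):
        _, _, iso, truth, as_truth = iso_sim
        by_gene = {e.gene_id: e for e in as_truth.as_events}
        checked = 0
        for gene in iso:
            if gene.id not in by_gene:
                continue
            ev = by_gene[gene.id]
            canonical = gene.transcript(truth.canonical[gene.id])
            for tid in ev.isoform_ids:
                got = pairwise_events(canonical, gene.transcript(tid))
                assert [e.event_class for e in got] == [ev.event_class]
                assert got[0].footprint == ev.footprint
                checked += 1
        assert checked >= 50

    def test_low_support_events_removed(self, sim):
        _, genome, ann, _ = sim
        from reannot.simulate import spawn_isoforms
        iso, truth = spawn_isoforms(ann, {"IntRt": 1.0}, seed=33,
                                    n_low_support=8, genome=genome)
        events = classify_annotation(iso, genome=genome)
        got = {(e.gene_id, e.event_class) for e in events}
        for ev in truth.as_events:
            if ev.n_support == 2:
                assert (ev.gene_id, ev.event_class) not in got
            else:
                assert (ev.gene_id, ev.event_class) in got

    def test_supporters_contain_alternative_form_intron_retention(self, sim):
        """Independent region-content check: retained intronic bases are
        exonic in every supporter and intronic in the canonical isoform."""
        _, genome, ann, _ = sim
        from reannot.simulate import spawn_isoforms
        iso, _ = spawn_isoforms(ann, {"IntRt": 1.0}, seed=41, genome=genome)
        events = classify_annotation(iso, genome=genome)
        assert events
        for ev in events:
            gene = iso.genes[ev.gene_id]
            fp = ev.footprint
            for tid in ev.supporting:
                t = gene.transcript(tid)
                assert any(e.start <= fp.start and fp.end <= e.end
                           for e in t.exons)
            for tid in ev.reference:
                t = gene.transcript(tid)
                assert fp in t.introns()
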