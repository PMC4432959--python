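"""Tag clustering and 3'-end extension: thresholds, oracles, invariants."""

import copy

import numpy as np
import pytest

from reannot.extension import (ExtensionParams, ReadAlignment, TagCluster,
                               cluster_reads, extend_three_prime,
                               merge_sample_clusters, read_bed6, write_bed6)
from reannot.model import (AnnotationSet, Gene, Genome, Interval, Transcript,
                           write_gff3, read_gff3)
from reannot.simulate import simulate_3prime_tags


def _reads(triples, strand="+", sample="s1", scaffold="chr"):
    return [ReadAlignment(Interval(scaffold, s, e, strand), sample)
            for s, e in triples]


class TestClusterReads:
    def test_ten_overlapping_reads_retained(self):
        reads = _reads([(i, i + 50) for i in range(0, 100, 10)])
        clusters = cluster_reads(reads)
        assert len(clusters) == 1
        assert clusters[0].read_count == 10
        assert (clusters[0].interval.start, clusters[0].interval.end) == (0, 140)

    def test_nine_reads_discarded(self):
        reads = _reads([(i, i + 50) for i in range(0, 90, 10)])
        assert cluster_reads(reads) == []

    def test_stranded_split_below_threshold(self):
        reads = _reads([(i, i + 50) for i in range(0, 60, 10)], strand="+") + \
            _reads([(i, i + 50) for i in range(0, 60, 10)], strand="-")
        assert cluster_reads(reads) == []

    def test_abutting_reads_do_not_merge(self):
        reads = _reads([(0, 50)] * 10 + [(50, 100)] * 10)
        clusters = cluster_reads(reads)
        assert [(c.interval.start, c.interval.end) for c in clusters] == \
            [(0, 50), (50, 100)]

    def test_matches_union_find_oracle_on_random_reads(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 5_000, size=1_000)
        lens = rng.integers(20, 80, size=1_000)
        strands = rng.choice(["+", "-"], size=1_000)
        reads = [ReadAlignment(Interval("c", int(s), int(s + l), str(st)))
                 for s, l, st in zip(starts, lens, strands)]
        params = ExtensionParams(min_cluster_reads=1)
        clusters = cluster_reads(reads, params)

        # oracle: connected components of the pairwise-overlap graph
        def components(items):
            n = len(items)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = items[i].interval, items[j].interval
                    if a.strand == b.strand and a.overlap_len(b) > 0:
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(n):
                comps.setdefault(find(i), []).append(items[i].interval)
            return sorted(
                (min(iv.start for iv in g), max(iv.end for iv in g),
                 g[0].strand, len(g))
                for g in comps.values())

        expected = components(reads)
        got = sorted((c.interval.start, c.interval.end, c.interval.strand,
                      c.read_count) for c in clusters)
        assert got == expected


class TestMergeSampleClusters:
    def test_single_sample_identity(self):
        cl = [TagCluster(Interval("c", 0, 100), 12, frozenset({"s1"}))]
        assert merge_sample_clusters([cl]) == cl

    def test_identical_clusters_sum_counts(self):
        c1 = [TagCluster(Interval("c", 0, 100), 12, frozenset({"s1"}))]
        c2 = [TagCluster(Interval("c", 0, 100), 15, frozenset({"s2"}))]
        merged = merge_sample_clusters([c1, c2])
        assert len(merged) == 1
        assert merged[0].read_count == 27
        assert merged[0].samples == frozenset({"s1", "s2"})

    def test_matches_pooled_union_find(self):
        rng = np.random.default_rng(8)
        per_sample = []
        for sample in ("s1", "s2", "s3"):
            ivs = []
            for _ in range(50):
                s = int(rng.integers(0, 3_000))
                ivs.append(TagCluster(Interval("c", s, s + int(rng.integers(30, 120))),
                                      int(rng.integers(10, 40)),
                                      frozenset({sample})))
            per_sample.append(ivs)
        merged = merge_sample_clusters(per_sample)
        pooled = [c for group in per_sample for c in group]
        # oracle on the pooled set
        n = len(pooled)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = pooled[i].interval, pooled[j].interval
                if a.strand == b.strand and a.overlap_len(b) > 0:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(pooled[i])
        expected = sorted(
            (min(c.interval.start for c in g), max(c.interval.end for c in g),
             sum(c.read_count for c in g))
            for g in comps.values())
        got = sorted((c.interval.start, c.interval.end, c.read_count)
                     for c in merged)
        assert got == expected


def _one_gene_annotation(strand="+"):
    """Two-exon gene on chr:100-1000 with an annotated 3' UTR."""
    if strand == "+":
        exons = [Interval("chr", 100, 300, "+"), Interval("chr", 900, 1000, "+")]
        cds = [Interval("chr", 150, 300, "+"), Interval("chr", 900, 950, "+")]
    else:
        exons = [Interval("chr", 100, 200, "-"), Interval("chr", 800, 1000, "-")]
        cds = [Interval("chr", 150, 200, "-"), Interval("chr", 800, 950, "-")]
    t = Transcript("t1", "g1", exons=exons, cds=cds)
    t.derive_utrs()
    ann = AnnotationSet(name="toy")
    ann.add(Gene("g1", [t]))
    return ann


class TestExtendThreePrime:
    def test_plus_strand_direct_rule(self):
        ann = _one_gene_annotation()
        clusters = [TagCluster(Interval("chr", 950, 1100, "+"), 12)]
        out, report = extend_three_prime(ann, clusters)
        t = out.genes["g1"].transcripts[0]
        assert t.end == 1100
        assert t.utr3[-1].end == 1100
        assert report.records[0].delta == 100
        # original untouched
        assert ann.genes["g1"].transcripts[0].end == 1000

    def test_nine_bp_overlap_not_enough(self):
        ann = _one_gene_annotation()
        clusters = [TagCluster(Interval("chr", 995, 1104, "+"), 12)]
        out, report = extend_three_prime(ann, clusters)
        assert out.genes == ann.genes
        assert report.records == []

    def test_cluster_inside_gene_no_extension(self):
        ann = _one_gene_annotation()
        clusters = [TagCluster(Interval("chr", 900, 990, "+"), 12)]
        out, report = extend_three_prime(ann, clusters)
        assert out.genes == ann.genes

    def test_no_annotated_utr3_untouched(self):
        ann = _one_gene_annotation()
        t = ann.genes["g1"].transcripts[0]
        t.cds, t.utr3, t.utr5 = [], [], []
        clusters = [TagCluster(Interval("chr", 950, 1100, "+"), 12)]
        out, report = extend_three_prime(ann, clusters)
        assert report.records == []
        assert out.genes == ann.genes

    def test_minus_strand_extension(self):
        ann = _one_gene_annotation(strand="-")
        clusters = [TagCluster(Interval("chr", 20, 120, "-"), 12)]
        out, report = extend_three_prime(ann, clusters)
        t = out.genes["g1"].transcripts[0]
        assert t.start == 20
        assert t.utr3[0].start == 20
        assert report.records[0].delta == 80

    def test_farthest_qualifying_cluster_wins(self):
        ann = _one_gene_annotation()
        clusters = [TagCluster(Interval("chr", 950, 1050, "+"), 12),
                    TagCluster(Interval("chr", 960, 1200, "+"), 11)]
        out, _ = extend_three_prime(ann, clusters)
        assert out.genes["g1"].transcripts[0].end == 1200

    def test_clamped_to_scaffold_end(self):
        ann = _one_gene_annotation()
        genome = Genome({"chr": "A" * 1050})
        clusters = [TagCluster(Interval("chr", 950, 1100, "+"), 12)]
        out, report = extend_three_prime(ann, clusters, genome=genome)
        assert out.genes["g1"].transcripts[0].end == 1050

    def test_idempotent_and_monotone(self, sim):
        cfg, genome, ann, _ = sim
        reads, _ = simulate_3prime_tags(ann, cfg, seed=13, genome=genome)
        per_sample = {}
        for r in reads:
            per_sample.setdefault(r.sample, []).append(r)
        clusters = merge_sample_clusters(
            [cluster_reads(rs) for rs in per_sample.values()])
        once, rep1 = extend_three_prime(ann, clusters, genome=genome)
        twice, rep2 = extend_three_prime(once, clusters, genome=genome)
        assert rep2.records == []
        assert twice.genes == once.genes
        # monotone: no coordinate moves inward; 5' end and CDS untouched
        for gid, gene in ann.genes.items():
            for t_old, t_new in zip(gene.transcripts,
                                    once.genes[gid].transcripts):
                assert t_new.cds == t_old.cds
                assert t_new.five_prime_end == t_old.five_prime_end
                if t_old.strand == "+":
                    assert t_new.end >= t_old.end
                    assert t_new.start == t_old.start
                else:
                    assert t_new.start <= t_old.start
                    assert t_new.end == t_old.end

    def test_strand_mirror_symmetry(self):
        """Reflecting coordinates and flipping strands commutes with extension."""
        L = 2_000
        ann = _one_gene_annotation()
        clusters = [TagCluster(Interval("chr", 950, 1100, "+"), 12)]

        def mirror_iv(iv):
            return Interval(iv.scaffold, L - iv.end, L - iv.start,
                            "-" if iv.strand == "+" else "+")

        m_t = Transcript("t1", "g1",
                         exons=sorted(mirror_iv(e) for e in
                                      ann.genes["g1"].transcripts[0].exons),
                         cds=sorted(mirror_iv(c) for c in
                                    ann.genes["g1"].transcripts[0].cds))
        m_t.derive_utrs()
        m_ann = AnnotationSet(name="mirror")
        m_ann.add(Gene("g1", [m_t]))
        m_clusters = [TagCluster(mirror_iv(clusters[0].interval), 12)]

        out, _ = extend_three_prime(ann, clusters)
        m_out, _ = extend_three_prime(m_ann, m_clusters)
        got = m_out.genes["g1"].transcripts[0]
        want = out.genes["g1"].transcripts[0]
        assert sorted(mirror_iv(e) for e in want.exons) == got.exons

    def test_parameter_recovery_on_simulated_tags(self, sim):
        cfg, genome, ann, _ = sim
        reads, truth = simulate_3prime_tags(ann, cfg, seed=17, genome=genome)
        per_sample = {}
        for r in reads:
            per_sample.setdefault(r.sample, []).append(r)
        clusters = merge_sample_clusters(
            [cluster_reads(rs) for rs in per_sample.values()])
        out, report = extend_three_prime(ann, clusters, genome=genome)
        recovered = {r.transcript_id: (r.old_end, r.new_end)
                     for r in report.records}
        assert recovered == truth.three_prime_ends

    def test_noise_only_changes_nothing(self, sim):
        cfg, genome, ann, _ = sim
        cfg2 = copy.deepcopy(cfg)
        cfg2.celseq.reads_per_end = 0
        cfg2.celseq.noise_clusters = 30
        reads, _ = simulate_3prime_tags(ann, cfg2, seed=19, genome=genome)
        assert reads  # noise present, but every pileup is sub-threshold
        clusters = merge_sample_clusters([cluster_reads(reads)])
        assert clusters == []
        out, report = extend_three_prime(ann, clusters, genome=genome)
        assert report.records == []
        assert out.genes == ann.genes


def test_bed6_round_trip(tmp_path):
    reads = _reads([(0, 50), (40, 90)], sample="dev1") + \
        _reads([(100, 150)], strand="-", sample="dev2")
    p = tmp_path / "r.bed"
    write_bed6(reads, p)
    assert read_bed6(p) == reads
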