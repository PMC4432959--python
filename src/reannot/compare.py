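"""Hierarchical comparison of competing annotation sets and gene-structure stats.

Two annotation sets are compared by base-level coverage: a query gene
counts as present in a target set when at least ``coverage_threshold``
(default 0.8) of its exonic bases are covered by same-strand exonic bases
of the target.  With more than two sets, genes are assigned to Venn-diagram
regions hierarchically under a fixed precedence order, so that only the
reference (first) set keeps its original cardinality.
"""

from __future__ import annotations

import bisect
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import AnnotationSet, Gene, Genome, Interval


@dataclass
class CompareParams:
    coverage_threshold: float = 0.8
    stranded: bool = True
    mode: str = "exon"  # "exon" (spliced bases) or "span" (whole gene span)

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.mode not in ("exon", "span"):
            raise ValueError("mode must be 'exon' or 'span'")


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs.sort()
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gene_intervals(gene: Gene, mode: str) -> list[tuple[int, int]]:
    if mode == "span":
        sp = gene.span
        return [(sp.start, sp.end)]
    return _merge_intervals(
        [(e.start, e.end) for t in gene.transcripts for e in t.exons])


class CoverageIndex:
    """Merged per-(scaffold, strand) base intervals of an annotation set."""

    def __init__(self, annotation: AnnotationSet, params: CompareParams):
        self.params = params
        raw: dict[tuple, list[tuple[int, int]]] = {}
        for g in annotation:
            key = (g.scaffold, g.strand if params.stranded else ".")
            raw.setdefault(key, []).extend(_gene_intervals(g, params.mode))
        self._starts: dict[tuple, list[int]] = {}
        self._ends: dict[tuple, list[int]] = {}
        for key, ivs in raw.items():
            merged = _merge_intervals(ivs)
            self._starts[key] = [s for s, _ in merged]
            self._ends[key] = [e for _, e in merged]

    def covered_bases(self, scaffold: str, strand: str, start: int, end: int
                      ) -> int:
        key = (scaffold, strand if self.params.stranded else ".")
        starts = self._starts.get(key)
        if not starts:
            return 0
        ends = self._ends[key]
        i = bisect.bisect_right(ends, start)
        total = 0
        while i < len(starts) and starts[i] < end:
            total += min(end, ends[i]) - max(start, starts[i])
            i += 1
        return total


def coverage_fraction(query: Gene, targets: AnnotationSet,
                      params: Optional[CompareParams] = None,
                      index: Optional[CoverageIndex] = None) -> float:
    """Fraction of the query gene's bases covered by the target set.

    Coverage is over exonic bases by default (``params.mode == "exon"``);
    a span-based mode is available.  Same-strand coverage only unless
    ``params.stranded`` is off.
    """
    params = params or CompareParams()
    if index is None:
        index = CoverageIndex(targets, params)
    ivs = _gene_intervals(query, params.mode)
    total = sum(e - s for s, e in ivs)
    if total == 0:
        return 0.0
    covered = sum(
        index.covered_bases(query.scaffold, query.strand, s, e)
        for s, e in ivs)
    return covered / total


@dataclass
class VennCounts:
    """Hierarchically assigned gene counts per Venn-diagram region.

    ``regions`` maps a frozenset of set names to a gene count;
    ``assignments`` records the region of every counted gene as
    (set name, gene id) -> region.
    """

    order: list[str]
    regions: dict = field(default_factory=dict)
    assignments: dict = field(default_factory=dict)

    def count(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k, key=self.order.index)), "genes": v}
            for k, v in sorted(self.regions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["region", "genes"])


def hierarchical_assign(sets: Sequence[AnnotationSet],
                        params: Optional[CompareParams] = None) -> VennCounts:
    """Assign genes of competing annotation sets to Venn regions.

    The first set is the reference: each of its genes lands in the region
    named by the lower-precedence sets that cover it at the threshold, so
    reference-region counts always sum to the reference set size.  A gene
    of a non-reference set is only counted (in its own region, determined
    against lower-precedence sets) if no higher-precedence set covers it.
    """
    params = params or CompareParams()
    if len(sets) < 2:
        raise ValueError("need at least two annotation sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("annotation set names must be unique")
    indexes = [CoverageIndex(s, params) for s in sets]
    venn = VennCounts(order=list(names))

    def covered_by(gene: Gene, j: int) -> bool:
        return coverage_fraction(gene, sets[j], params,
                                 index=indexes[j]) >= params.coverage_threshold

    for i, aset in enumerate(sets):
        for gene in aset:
            if any(covered_by(gene, j) for j in range(i)):
                continue  # represented through a higher-precedence set
            region = frozenset(
                [names[i]] + [names[j] for j in range(i + 1, len(sets))
                              if covered_by(gene, j)])
            venn.regions[region] = venn.regions.get(region, 0) + 1
            venn.assignments[(names[i], gene.id)] = region
    return venn


def gene_correspondence(query: AnnotationSet, target: AnnotationSet,
                        params: Optional[CompareParams] = None
                        ) -> pd.DataFrame:
    """Many-to-one correspondences: target genes covering each query gene.

    Reports, per query gene passing the coverage threshold against the
    whole target set, the ids of individual target genes overlapping it —
    the raw material for spotting fragmented or merged gene models.
    """
    params = params or CompareParams()
    index = CoverageIndex(target, params)
    by_scaffold: dict[str, list[Gene]] = {}
    for g in target:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    rows = []
    for q in query:
        frac = coverage_fraction(q, target, params, index=index)
        if frac < params.coverage_threshold:
            continue
        partners = [
            t.id for t in by_scaffold.get(q.scaffold, [])
            if t.span.overlaps(q.span, stranded=params.stranded)
        ]
        rows.append({"query_gene": q.id, "coverage": round(frac, 4),
                     "n_target_genes": len(partners),
                     "target_genes": ",".join(sorted(partners))})
    return pd.DataFrame(rows, columns=["query_gene", "coverage",
                                       "n_target_genes", "target_genes"])


# ---------------------------------------------------------------------------
# gene-structure statistics
# ---------------------------------------------------------------------------

@dataclass
class StructureStats:
    """Annotation-wide gene-structure statistics.

    Gene lengths include introns and exons (span lengths); genome coverage
    is the union of gene spans over the genome length.  Exon and intron
    tallies run over all transcripts, with per-gene averages taken over
    genes.  ORF statistics are over each gene's representative
    (longest-ORF) isoform and require a genome.
    """

    total_genes: int = 0
    total_gene_length: int = 0
    pct_genome: float = 0.0
    mean_gene_length: float = 0.0
    min_gene_length: int = 0
    max_gene_length: int = 0
    total_isoforms: int = 0
    total_exons: int = 0
    mean_exon_length: float = 0.0
    mean_exons_per_gene: float = 0.0
    max_exons_per_gene: int = 0
    total_introns: int = 0
    mean_intron_length: float = 0.0
    orf_total_length: int = 0
    orf_mean_length: float = 0.0
    orf_max_length: int = 0
    utr5_count: int = 0
    utr5_total_length: int = 0
    utr5_mean_length: float = 0.0
    utr5_max_length: int = 0
    utr3_count: int = 0
    utr3_total_length: int = 0
    utr3_mean_length: float = 0.0
    utr3_max_length: int = 0
    median_intergenic_distance: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in self.__dataclass_fields__]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def structure_stats(annotation: AnnotationSet,
                    genome: Optional[Genome] = None) -> StructureStats:
    from .model import find_longest_orf, select_representative

    st = StructureStats()
    st.total_genes = len(annotation)
    if st.total_genes == 0:
        return st

    gene_lengths = [g.span.length for g in annotation]
    st.total_gene_length = sum(gene_lengths)
    st.mean_gene_length = st.total_gene_length / st.total_genes
    st.min_gene_length = min(gene_lengths)
    st.max_gene_length = max(gene_lengths)
    st.total_isoforms = annotation.n_transcripts

    if genome is not None:
        spans: dict[str, list[tuple[int, int]]] = {}
        for g in annotation:
            spans.setdefault(g.scaffold, []).append((g.span.start, g.span.end))
        union = sum(
            sum(e - s for s, e in _merge_intervals(ivs))
            for ivs in spans.values())
        st.pct_genome = 100.0 * union / genome.total_length

    exon_lengths = []
    intron_lengths = []
    exons_per_gene = []
    utr5_lens, utr3_lens = [], []
    for g in annotation:
        gene_exons = 0
        for t in g.transcripts:
            gene_exons += len(t.exons)
            exon_lengths.extend(e.length for e in t.exons)
            intron_lengths.extend(i.length for i in t.introns())
            if t.utr5:
                utr5_lens.append(sum(u.length for u in t.utr5))
            if t.utr3:
                utr3_lens.append(sum(u.length for u in t.utr3))
        exons_per_gene.append(gene_exons)
    st.total_exons = len(exon_lengths)
    st.mean_exon_length = sum(exon_lengths) / st.total_exons
    st.mean_exons_per_gene = st.total_exons / st.total_genes
    st.max_exons_per_gene = max(exons_per_gene)
    st.total_introns = len(intron_lengths)
    if intron_lengths:
        st.mean_intron_length = sum(intron_lengths) / st.total_introns

    if utr5_lens:
        st.utr5_count = len(utr5_lens)
        st.utr5_total_length = sum(utr5_lens)
        st.utr5_mean_length = st.utr5_total_length / st.utr5_count
        st.utr5_max_length = max(utr5_lens)
    if utr3_lens:
        st.utr3_count = len(utr3_lens)
        st.utr3_total_length = sum(utr3_lens)
        st.utr3_mean_length = st.utr3_total_length / st.utr3_count
        st.utr3_max_length = max(utr3_lens)

    if genome is not None:
        orf_lens = []
        for g in annotation:
            rep = g.transcript(select_representative(g, genome))
            orf = find_longest_orf(rep.spliced_sequence(genome))
            orf_lens.append(orf.length if orf else 0)
        st.orf_total_length = sum(orf_lens)
        st.orf_mean_length = st.orf_total_length / len(orf_lens)
        st.orf_max_length = max(orf_lens)

    _, st.median_intergenic_distance = intergenic_distances(annotation)
    return st


def intergenic_distances(annotation: AnnotationSet
                         ) -> tuple[list[int], Optional[float]]:
    """Distances between consecutive gene spans, strand-ignored.

    Per scaffold, gene spans are sorted by start; each gap is
    ``next.start - prev.end`` clamped at 0 for overlapping genes.  Returns
    the distances and their median, or ``None`` when no pair of genes
    shares a scaffold.
    """
    by_scaffold: dict[str, list[Interval]] = {}
    for g in annotation:
        by_scaffold.setdefault(g.scaffold, []).append(g.span)
    distances: list[int] = []
    for spans in by_scaffold.values():
        spans.sort(key=lambda iv: (iv.start, iv.end))
        for a, b in zip(spans, spans[1:]):
            distances.append(max(0, b.start - a.end))
    if not distances:
        return [], None
    return distances, float(statistics.median(distances))
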