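"""3'-end refinement of gene models from stranded 3'-end tag pileups.

3'-end-biased protocols (e.g. CEL-Seq) produce read pileups at and beyond
annotated transcript ends.  Reads are single-linkage clustered per sample,
per scaffold and per strand; clusters with at least ``min_cluster_reads``
reads survive, per-sample clusters are then union-merged across samples,
and any transcript with an annotated 3' UTR whose last exon overlaps a
cluster by at least ``min_overlap_bp`` has its 3' end moved outward to the
cluster's far boundary — never inward.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotationSet, Genome, Interval, Transcript


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned 3'-end read reduced to its reference interval."""

    interval: Interval
    sample: str = "sample1"


@dataclass(frozen=True)
class TagCluster:
    """A merged pileup of same-strand overlapping reads."""

    interval: Interval
    read_count: int
    samples: frozenset = frozenset()

    @property
    def far_boundary(self) -> int:
        """Downstream-most boundary in transcript orientation."""
        return self.interval.end if self.interval.strand == "+" else self.interval.start


@dataclass
class ExtensionParams:
    min_cluster_reads: int = 10
    min_overlap_bp: int = 10
    require_annotated_utr3: bool = True

    def __post_init__(self) -> None:
        if self.min_cluster_reads < 1 or self.min_overlap_bp < 1:
            raise ValueError("thresholds must be >= 1")


@dataclass(frozen=True)
class ExtensionRecord:
    gene_id: str
    transcript_id: str
    old_end: int
    new_end: int
    delta: int
    cluster: Interval
    cluster_reads: int


@dataclass
class ExtensionReport:
    records: list[ExtensionRecord] = field(default_factory=list)

    @property
    def n_extended_transcripts(self) -> int:
        return len(self.records)

    @property
    def n_extended_genes(self) -> int:
        return len({r.gene_id for r in self.records})

    @property
    def total_extended_bp(self) -> int:
        return sum(r.delta for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "transcript_id": r.transcript_id,
                    "old_end": r.old_end,
                    "new_end": r.new_end,
                    "delta_bp": r.delta,
                    "cluster": f"{r.cluster.scaffold}:{r.cluster.start}-"
                               f"{r.cluster.end}({r.cluster.strand})",
                    "cluster_reads": r.cluster_reads,
                }
                for r in self.records
            ],
            columns=["gene_id", "transcript_id", "old_end", "new_end",
                     "delta_bp", "cluster", "cluster_reads"],
        )


# ---------------------------------------------------------------------------
# BED6 / SAM input and output
# ---------------------------------------------------------------------------

def read_bed6(path) -> list[ReadAlignment]:
    """Read alignments from BED6 (name column = sample id, strand column 6)."""
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            reads.append(ReadAlignment(
                Interval(f[0], int(f[1]), int(f[2]), f[5]),
                sample=f[3] if len(f) > 3 else "sample1"))
    return reads


def write_bed6(reads: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{r.sample}\t0\t"
                     f"{iv.strand}\n")


def read_sam(path, sample: Optional[str] = None) -> list[ReadAlignment]:
    """Reduce SAM alignments to stranded reference intervals."""
    import pysam
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(ReadAlignment(
                Interval(aln.reference_name, aln.reference_start,
                         aln.reference_end, strand),
                sample=sample or (aln.get_tag("RG") if aln.has_tag("RG")
                                  else "sample1")))
    return reads


def write_clusters_bed(clusters: Iterable[TagCluster], path) -> None:
    """Clusters as BED6 with the read count in the score column."""
    with open(path, "w") as fh:
        for c in clusters:
            iv = c.interval
            name = ",".join(sorted(c.samples)) or "cluster"
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t"
                     f"{c.read_count}\t{iv.strand}\n")


def read_clusters_bed(path) -> list[TagCluster]:
    clusters = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            clusters.append(TagCluster(
                Interval(f[0], int(f[1]), int(f[2]), f[5]),
                read_count=int(f[4]),
                samples=frozenset(f[3].split(",")) if f[3] else frozenset()))
    return clusters


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _sweep_merge(items):
    """Single-linkage merge of (Interval, count, samples) triples.

    Items must share scaffold and strand and be sorted by start.  Abutting
    (zero-gap) intervals do not merge; merging requires >= 1 bp overlap.
    """
    merged = []
    cur_iv, cur_n, cur_s = None, 0, set()
    for iv, n, samples in items:
        if cur_iv is not None and iv.start < cur_iv.end:
            cur_iv = Interval(cur_iv.scaffold, cur_iv.start,
                              max(cur_iv.end, iv.end), cur_iv.strand)
            cur_n += n
            cur_s |= samples
        else:
            if cur_iv is not None:
                merged.append((cur_iv, cur_n, cur_s))
            cur_iv, cur_n, cur_s = iv, n, set(samples)
    if cur_iv is not None:
        merged.append((cur_iv, cur_n, cur_s))
    return merged


def cluster_reads(reads: Sequence[ReadAlignment],
                  params: Optional[ExtensionParams] = None) -> list[TagCluster]:
    """Single-linkage clusters of overlapping reads, per sample/scaffold/strand.

    Clusters with fewer than ``params.min_cluster_reads`` reads are
    discarded; survivors are returned sorted by (scaffold, start).
    """
    params = params or ExtensionParams()
    groups: dict[tuple, list[ReadAlignment]] = {}
    for r in reads:
        groups.setdefault(
            (r.sample, r.interval.scaffold, r.interval.strand), []).append(r)
    out: list[TagCluster] = []
    for (sample, _, _), rs in groups.items():
        rs.sort(key=lambda r: (r.interval.start, r.interval.end))
        merged = _sweep_merge(
            ((r.interval, 1, {sample}) for r in rs))
        for iv, n, samples in merged:
            if n >= params.min_cluster_reads:
                out.append(TagCluster(iv, n, frozenset(samples)))
    out.sort(key=lambda c: (c.interval.scaffold, c.interval.start,
                            c.interval.end, c.interval.strand))
    return out


def merge_sample_clusters(per_sample: Sequence[Sequence[TagCluster]]
                          ) -> list[TagCluster]:
    """Union-merge already-filtered per-sample clusters across samples.

    Same-strand overlapping clusters are merged with read counts summed and
    sample sets unioned.
    """
    pooled: dict[tuple, list[TagCluster]] = {}
    for clusters in per_sample:
        for c in clusters:
            pooled.setdefault(
                (c.interval.scaffold, c.interval.strand), []).append(c)
    out: list[TagCluster] = []
    for group in pooled.values():
        group.sort(key=lambda c: (c.interval.start, c.interval.end))
        merged = _sweep_merge(
            ((c.interval, c.read_count, set(c.samples)) for c in group))
        out.extend(TagCluster(iv, n, frozenset(s)) for iv, n, s in merged)
    out.sort(key=lambda c: (c.interval.scaffold, c.interval.start,
                            c.interval.end, c.interval.strand))
    return out


# ---------------------------------------------------------------------------
# 3' extension
# ---------------------------------------------------------------------------

def _last_exon(t: Transcript) -> Interval:
    return t.exons[-1] if t.strand == "+" else t.exons[0]


def extend_three_prime(annotation: AnnotationSet,
                       clusters: Sequence[TagCluster],
                       params: Optional[ExtensionParams] = None,
                       genome: Optional[Genome] = None,
                       ) -> tuple[AnnotationSet, ExtensionReport]:
    """Extend transcript 3' ends to tag-cluster far boundaries.

    For every transcript with an annotated 3' UTR, same-strand clusters
    overlapping its last exon by at least ``min_overlap_bp`` are collected;
    if the farthest cluster boundary (end on '+', start on '-') lies beyond
    the annotated 3' end, the last exon and terminal 3'-UTR piece are moved
    to that boundary.  CDS, internal exons and the 5' end are untouched.
    The input annotation is not modified; a deep copy is returned together
    with a per-transcript report of extensions.
    """
    params = params or ExtensionParams()
    trees: dict[tuple, IntervalTree] = {}
    for c in clusters:
        key = (c.interval.scaffold, c.interval.strand)
        trees.setdefault(key, IntervalTree()).addi(
            c.interval.start, c.interval.end, c)

    ann = copy.deepcopy(annotation)
    report = ExtensionReport()
    lengths = genome.lengths if genome is not None else None

    for gene in ann:
        for t in gene.transcripts:
            if params.require_annotated_utr3 and not t.utr3:
                continue
            last = _last_exon(t)
            tree = trees.get((t.scaffold, t.strand))
            if tree is None:
                continue
            best: Optional[TagCluster] = None
            for hit in tree.overlap(last.start, last.end):
                c: TagCluster = hit.data
                if c.interval.overlap_len(last) < params.min_overlap_bp:
                    continue
                if t.strand == "+" and c.far_boundary > t.end:
                    if best is None or c.far_boundary > best.far_boundary:
                        best = c
                elif t.strand == "-" and c.far_boundary < t.start:
                    if best is None or c.far_boundary < best.far_boundary:
                        best = c
            if best is None:
                continue
            new_bound = best.far_boundary
            if lengths is not None:
                scaf_len = lengths[t.scaffold]
                if t.strand == "+" and new_bound > scaf_len:
                    new_bound = scaf_len  # clamp at scaffold end
                elif t.strand == "-" and new_bound < 0:
                    new_bound = 0
            old_end = t.three_prime_end
            _apply_extension(t, new_bound)
            report.records.append(ExtensionRecord(
                gene_id=gene.id, transcript_id=t.id,
                old_end=old_end, new_end=new_bound,
                delta=abs(new_bound - old_end),
                cluster=best.interval, cluster_reads=best.read_count))
    return ann, report


def _apply_extension(t: Transcript, new_bound: int) -> None:
    if t.strand == "+":
        last = t.exons[-1]
        t.exons[-1] = Interval(last.scaffold, last.start, new_bound, last.strand)
        if t.utr3:
            u = t.utr3[-1]
            t.utr3[-1] = Interval(u.scaffold, u.start, new_bound, u.strand)
    else:
        first = t.exons[0]
        t.exons[0] = Interval(first.scaffold, new_bound, first.end, first.strand)
        if t.utr3:
            u = t.utr3[0]
            t.utr3[0] = Interval(u.scaffold, new_bound, u.end, u.strand)
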