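"""Seven-class alternative-splicing classification and summary.

Each alternative isoform of a gene is compared against the canonical
isoform (by default the one with the longest ORF) and every structural
difference is assigned to one of seven event classes:

====== ==========================================================
IntRt  intron retention — a canonical intron transcribed through
AltTEx alternative (first or last) terminal exon
AltAc  alternative acceptor (3' splice site) of a shared intron
AltDo  alternative donor (5' splice site) of a shared intron
ExSk   exon skipping — a canonical internal exon spliced out
IntSt  transcript start inside a canonical intron
IntEnd transcript end inside a canonical intron
====== ==========================================================

Operational rules (the class glossary names the classes but does not pin
down boundary cases):

* IntRt: every base of a canonical intron is exonic in the alternative
  isoform through a single exon that also reaches into both flanking
  canonical exons.  Footprint: the intron.
* ExSk: an alternative intron runs exactly from the start of one
  canonical intron to the end of a following one, with the canonical
  internal exon(s) in between entirely intronic.  Footprint: the skipped
  region.
* AltAc/AltDo: a canonical and an alternative intron share the donor
  (AltAc) or the acceptor (AltDo) but not the other splice site, *and*
  the exons flanking the differing site overlap each other.  The overlap
  requirement keeps genuinely novel terminal exons (which also share one
  splice site) out of this class.  Donor = the intron boundary nearer the
  transcript 5' end.  Footprint: the interval between the two competing
  splice-site coordinates.
* AltTEx: the alternative isoform's first or last exon does not overlap
  the corresponding canonical terminal exon, it is reached through a
  novel (non-shared) splice junction, and the isoforms share at least one
  splice site elsewhere.  Footprint: the alternative terminal exon.
* IntSt/IntEnd: the alternative transcript start (IntSt) or end (IntEnd)
  lies strictly inside a canonical intron, without a novel junction into
  the terminal exon (a read-through of a canonical exon).  Footprint:
  that canonical intron.

When one structural difference satisfies several rules the precedence
IntRt > ExSk > AltAc/AltDo > AltTEx > IntSt/IntEnd applies.

Events are supported by the transcripts exhibiting the alternative form;
events supported by fewer than ``min_support`` transcripts (default 3)
are discarded as lowly supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (AnnotationSet, AnnotationError, Gene, Genome, Interval,
                    Transcript, select_representative)

AS_CLASSES = ("IntRt", "AltTEx", "AltAc", "AltDo", "ExSk", "IntSt", "IntEnd")


@dataclass(frozen=True)
class ASEvent:
    event_class: str
    gene_id: str
    footprint: Interval
    supporting: frozenset
    reference: frozenset

    @property
    def key(self) -> tuple:
        return (self.event_class, self.footprint)


@dataclass
class EventFilterParams:
    min_support: int = 3

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------

def _covering_exon(exons: Sequence[Interval], start: int, end: int
                   ) -> Optional[Interval]:
    for e in exons:
        if e.start <= start and end <= e.end:
            return e
    return None


def _exon_left_of(exons: Sequence[Interval], pos: int) -> Optional[Interval]:
    for e in exons:
        if e.end == pos:
            return e
    return None


def _exon_right_of(exons: Sequence[Interval], pos: int) -> Optional[Interval]:
    for e in exons:
        if e.start == pos:
            return e
    return None


def pairwise_events(canonical: Transcript, alternative: Transcript
                    ) -> list[ASEvent]:
    """Classify the structural differences of one isoform pair.

    Coordinates are genomic; both transcripts must lie on the same
    scaffold and strand.
    """
    if canonical.strand != alternative.strand \
            or canonical.scaffold != alternative.scaffold:
        raise AnnotationError(
            f"{canonical.id}/{alternative.id}: different scaffold or strand")
    if canonical.exons == alternative.exons:
        return []

    strand = canonical.strand
    c_ex, a_ex = canonical.exons, alternative.exons
    c_in, a_in = canonical.introns(), alternative.introns()
    c_set, a_set = set(c_in), set(a_in)
    shared = c_set & a_set
    cu = [iv for iv in c_in if iv not in shared]
    au = [iv for iv in a_in if iv not in shared]
    used_c: set[Interval] = set()
    used_a: set[Interval] = set()
    found: list[tuple[str, Interval]] = []

    # intron retention
    for iv in cu:
        ex = _covering_exon(a_ex, iv.start, iv.end)
        if ex is not None and ex.start < iv.start and ex.end > iv.end:
            found.append(("IntRt", iv))
            used_c.add(iv)

    # exon skipping
    for a in au:
        left = next((c for c in cu if c not in used_c and c.start == a.start
                     and c.end < a.end), None)
        right = next((c for c in cu if c not in used_c and c.end == a.end
                      and c.start > a.start), None)
        if left is None or right is None:
            continue
        internal = c_ex[1:-1]
        skipped = [e for e in internal
                   if left.end <= e.start and e.end <= right.start]
        if not skipped:
            continue
        found.append(("ExSk", Interval(a.scaffold, skipped[0].start,
                                       skipped[-1].end, strand)))
        used_c.update((left, right))
        used_a.add(a)

    # alternative acceptor / donor
    for a in au:
        if a in used_a:
            continue
        for c in cu:
            if c in used_c:
                continue
            share_start = a.start == c.start
            share_end = a.end == c.end
            if share_start == share_end:
                continue
            if share_start:  # differ at the genomic-right splice site
                c_flank = _exon_right_of(c_ex, c.end)
                a_flank = _exon_right_of(a_ex, a.end)
                lo, hi = sorted((c.end, a.end))
            else:            # differ at the genomic-left splice site
                c_flank = _exon_left_of(c_ex, c.start)
                a_flank = _exon_left_of(a_ex, a.start)
                lo, hi = sorted((c.start, a.start))
            if c_flank is None or a_flank is None \
                    or not c_flank.overlaps(a_flank):
                continue
            donor_shared = share_start if strand == "+" else share_end
            cls = "AltAc" if donor_shared else "AltDo"
            found.append((cls, Interval(a.scaffold, lo, hi, strand)))
            used_c.add(c)
            used_a.add(a)
            break

    # alternative terminal exons (transcript orientation)
    c_sites = {p for iv in c_in for p in (iv.start, iv.end)}
    a_sites = {p for iv in a_in for p in (iv.start, iv.end)}
    shared_sites = c_sites & a_sites
    alt_tex_sides: set[str] = set()
    for side in ("first", "last"):
        genomic_left = (side == "first") == (strand == "+")
        a_term = a_ex[0] if genomic_left else a_ex[-1]
        c_term = c_ex[0] if genomic_left else c_ex[-1]
        if a_term.overlaps(c_term):
            continue
        if len(a_ex) < 2 or not shared_sites:
            continue
        adj = a_in[0] if genomic_left else a_in[-1]
        if adj in shared or adj in used_a:
            continue
        found.append(("AltTEx", a_term))
        used_a.add(adj)
        c_adj = c_in[0] if genomic_left else c_in[-1]
        used_c.add(c_adj)
        alt_tex_sides.add(side)

    # intronic start / end
    def _intron_containing(pos: int) -> Optional[Interval]:
        for iv in c_in:
            if iv.start < pos < iv.end:
                return iv
        return None

    if "first" not in alt_tex_sides:
        pos = alternative.five_prime_end
        host = _intron_containing(pos)
        if host is not None:
            found.append(("IntSt", host))
    if "last" not in alt_tex_sides:
        pos = alternative.three_prime_end
        host = _intron_containing(pos)
        if host is not None:
            found.append(("IntEnd", host))

    found.sort(key=lambda fc: (fc[1].start, fc[1].end, fc[0]))
    return [
        ASEvent(cls, canonical.gene_id, fp,
                supporting=frozenset({alternative.id}),
                reference=frozenset({canonical.id}))
        for cls, fp in found
    ]


# ---------------------------------------------------------------------------
# gene-level aggregation, filtering, summary
# ---------------------------------------------------------------------------

def classify_gene(gene: Gene, canonical: str) -> list[ASEvent]:
    """All AS events of a gene relative to its canonical isoform.

    Events with identical (class, footprint) found in several isoforms are
    merged with their supporting sets unioned.
    """
    ref = gene.transcript(canonical)
    merged: dict[tuple, ASEvent] = {}
    for t in gene.transcripts:
        if t.id == canonical:
            continue
        for ev in pairwise_events(ref, t):
            if ev.key in merged:
                prev = merged[ev.key]
                merged[ev.key] = ASEvent(
                    ev.event_class, ev.gene_id, ev.footprint,
                    supporting=prev.supporting | ev.supporting,
                    reference=prev.reference | ev.reference)
            else:
                merged[ev.key] = ev
    return sorted(merged.values(),
                  key=lambda e: (e.footprint.start, e.footprint.end,
                                 e.event_class))


def filter_events(events: Sequence[ASEvent],
                  params: Optional[EventFilterParams] = None) -> list[ASEvent]:
    """Drop events supported by fewer than ``min_support`` transcripts."""
    params = params or EventFilterParams()
    return [e for e in events if len(e.supporting) >= params.min_support]


def classify_annotation(annotation: AnnotationSet,
                        genome: Optional[Genome] = None,
                        canonical: Optional[Mapping[str, str]] = None,
                        params: Optional[EventFilterParams] = None
                        ) -> list[ASEvent]:
    """Classify and support-filter AS events for every multi-isoform gene.

    The canonical isoform per gene is taken from ``canonical`` when given,
    otherwise chosen as the longest-ORF isoform (requires ``genome``),
    falling back to the lexicographically smallest transcript id.
    """
    events: list[ASEvent] = []
    for gene in annotation:
        if len(gene.transcripts) < 2:
            continue
        if canonical is not None and gene.id in canonical:
            rep = canonical[gene.id]
        elif genome is not None:
            rep = select_representative(gene, genome)
        else:
            rep = min(t.id for t in gene.transcripts)
        events.extend(classify_gene(gene, rep))
    return filter_events(events, params)


@dataclass
class ASSummary:
    """Per-class event/transcript counts with the three percentage columns."""

    event_counts: dict
    transcript_counts: dict
    total_transcripts: int
    as_transcripts: Optional[int]

    @property
    def total_events(self) -> int:
        return sum(self.event_counts.values())

    def pct_of_events(self, cls: str) -> float:
        tot = self.total_events
        return round(100.0 * self.event_counts[cls] / tot, 1) if tot else 0.0

    def pct_of_as_transcripts(self, cls: str) -> Optional[float]:
        if not self.as_transcripts:
            return None
        return round(100.0 * self.transcript_counts[cls] / self.as_transcripts, 1)

    def pct_of_all_transcripts(self, cls: str) -> float:
        if not self.total_transcripts:
            return 0.0
        return round(100.0 * self.transcript_counts[cls] / self.total_transcripts, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in AS_CLASSES:
            rows.append({
                "class": cls,
                "as_events": self.event_counts[cls],
                "n_transcripts": self.transcript_counts[cls],
                "pct_of_as_events": self.pct_of_events(cls),
                "pct_of_as_transcripts": self.pct_of_as_transcripts(cls),
                "pct_of_all_transcripts": self.pct_of_all_transcripts(cls),
            })
        return pd.DataFrame(rows).set_index("class")


def summarize_counts(event_counts: Mapping[str, int],
                     transcript_counts: Mapping[str, int],
                     total_transcripts: int,
                     as_transcripts: Optional[int] = None) -> ASSummary:
    """Summary table from per-class event and transcript counts.

    ``as_transcripts`` (the number of distinct alternatively spliced
    transcripts, the denominator of the %-of-AS-transcripts column) is
    optional; the column is undefined without it.
    """
    ec = {cls: int(event_counts.get(cls, 0)) for cls in AS_CLASSES}
    tc = {cls: int(transcript_counts.get(cls, 0)) for cls in AS_CLASSES}
    return ASSummary(ec, tc, int(total_transcripts), as_transcripts)


def summarize_events(events: Sequence[ASEvent],
                     total_transcripts: int) -> ASSummary:
    """Summary table from classified events.

    Per class, the event count is the number of events and the transcript
    count the number of distinct supporting transcripts; percentages of AS
    transcripts use the distinct supporters over all classes, which may sum
    above 100% because one transcript can carry several event classes.
    """
    ec = {cls: 0 for cls in AS_CLASSES}
    tc_sets: dict[str, set] = {cls: set() for cls in AS_CLASSES}
    all_supporters: set = set()
    for ev in events:
        ec[ev.event_class] += 1
        tc_sets[ev.event_class].update(ev.supporting)
        all_supporters.update(ev.supporting)
    tc = {cls: len(s) for cls, s in tc_sets.items()}
    return ASSummary(ec, tc, int(total_transcripts),
                     len(all_supporters) if all_supporters else None)


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "class": e.event_class,
                "scaffold": e.footprint.scaffold,
                "start": e.footprint.start,
                "end": e.footprint.end,
                "strand": e.footprint.strand,
                "n_support": len(e.supporting),
                "supporting": ",".join(sorted(e.supporting)),
            }
            for e in events
        ],
        columns=["gene_id", "class", "scaffold", "start", "end", "strand",
                 "n_support", "supporting"],
    )
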