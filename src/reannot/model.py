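"""Coordinate-anchored genome and gene-annotation model with GFF3/FASTA I/O.

All internal coordinates are 0-based half-open intervals on a named
scaffold; GFF3 (1-based, fully closed) is converted at the I/O boundary
and nowhere else.  A :class:`Gene` owns one or more :class:`Transcript`
objects, each an ordered chain of exons with an optional CDS from which
5'/3' UTRs are derived when the source annotation does not state them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import gffutils

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations or malformed GFF3."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"bad interval {self.scaffold}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval", stranded: bool = False) -> bool:
        if self.scaffold != other.scaffold:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "Interval") -> int:
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class Genome:
    """Ordered collection of scaffold sequences (DNA, upper-case ACGTN)."""

    def __init__(self, scaffolds: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in scaffolds.items():
            if name in self._seqs:
                raise AnnotationError(f"duplicate scaffold id {name!r}")
            if len(seq) == 0:
                raise AnnotationError(f"empty scaffold {name!r}")
            self._seqs[name] = str(seq).upper()

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        path = Path(path)
        if path.suffix == ".gz":
            from Bio import SeqIO
            with gzip.open(path, "rt") as fh:
                return cls({r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")})
        import pyfaidx
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def sequence(self, iv: Interval, oriented: bool = True) -> str:
        """Sequence of ``iv``; reverse-complemented for '-' when oriented."""
        sub = self._seqs[iv.scaffold][iv.start:iv.end]
        if oriented and iv.strand == "-":
            return revcomp(sub)
        return sub


# ---------------------------------------------------------------------------
# transcripts and genes
# ---------------------------------------------------------------------------

def _check_chain(ivs: Sequence[Interval], what: str, tid: str) -> None:
    for a, b in zip(ivs, ivs[1:]):
        if a.scaffold != b.scaffold or a.strand != b.strand:
            raise AnnotationError(f"{tid}: {what} on mixed scaffold/strand")
        if b.start <= a.end:
            raise AnnotationError(
                f"{tid}: {what} not strictly separated at {a.end}/{b.start}")


@dataclass
class Transcript:
    """A spliced transcript: exon chain plus optional CDS and UTRs.

    ``exons``/``cds``/``utr5``/``utr3`` are genomic-coordinate sorted.
    UTRs are either read from the annotation or derived from the
    exon-minus-CDS difference (5' vs 3' resolved on the transcript strand).
    """

    id: str
    gene_id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.scaffold, self.start, self.end, self.strand)

    @property
    def five_prime_end(self) -> int:
        """Genomic boundary coordinate of the transcript 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_end(self) -> int:
        """Genomic boundary coordinate of the transcript 3' end."""
        return self.end if self.strand == "+" else self.start

    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.id}: transcript without exons")
        _check_chain(self.exons, "exons", self.id)
        _check_chain(self.cds, "CDS", self.id)
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise AnnotationError(f"{self.id}: CDS {c} outside exons")

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons (empty for single-exon)."""
        return [
            Interval(a.scaffold, a.end, b.start, a.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def derive_utrs(self) -> None:
        """Fill utr5/utr3 from the exon-minus-CDS difference (strand-aware)."""
        self.utr5, self.utr3 = [], []
        if not self.cds:
            return
        cs, ce = self.cds[0].start, self.cds[-1].end
        left: list[Interval] = []
        right: list[Interval] = []
        for e in self.exons:
            if e.start < cs:
                left.append(Interval(e.scaffold, e.start, min(e.end, cs), e.strand))
            if e.end > ce:
                right.append(Interval(e.scaffold, max(e.start, ce), e.end, e.strand))
        if self.strand == "+":
            self.utr5, self.utr3 = left, right
        else:
            self.utr5, self.utr3 = right, left

    def spliced_sequence(self, genome: Genome) -> str:
        """Exon sequences concatenated in transcript (5'→3') orientation."""
        parts = [genome.sequence(e, oriented=False) for e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


def infer_introns(transcript: Transcript) -> list[Interval]:
    """Introns of a transcript: the gaps between consecutive exons."""
    return transcript.introns()


@dataclass
class Gene:
    id: str
    transcripts: list[Transcript]

    @property
    def scaffold(self) -> str:
        return self.transcripts[0].scaffold

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return Interval(self.scaffold, start, end, self.strand)

    def validate(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.id}: gene without transcripts")
        sc, st = self.scaffold, self.strand
        for t in self.transcripts:
            t.validate()
            if t.scaffold != sc or t.strand != st:
                raise AnnotationError(f"{self.id}: transcripts on mixed scaffold/strand")

    def transcript(self, tid: str) -> Transcript:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


@dataclass
class AnnotationSet:
    """A named collection of genes anchored on a companion genome."""

    name: str = field(default="", compare=False)
    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise AnnotationError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[Transcript]:
        for g in self:
            yield from g.transcripts

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self)

    def validate(self, genome: Optional[Genome] = None) -> None:
        for g in self:
            g.validate()
            if genome is not None:
                if g.scaffold not in genome:
                    raise AnnotationError(f"{g.id}: unknown scaffold {g.scaffold}")
                if g.span.end > genome.lengths[g.scaffold]:
                    raise AnnotationError(f"{g.id}: extends past scaffold end")


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORF:
    """An open reading frame in transcript-local coordinates (half-open).

    ``end`` includes the stop codon when one terminates the frame.
    """

    frame: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def find_longest_orf(sequence: str, min_len: int = 30,
                     allow_open_end: bool = False) -> Optional[ORF]:
    """Longest sense-strand ATG→stop ORF; ties broken by smallest start.

    Parameters
    ----------
    sequence : DNA string over ACGTN.
    min_len : minimum ORF length in bp (including the stop codon).
    allow_open_end : accept an ORF running off the 3' end without an
        in-sequence stop codon ("open 3'" policy, default off).
    """
    seq = sequence.upper()
    best: Optional[ORF] = None
    for frame in range(3):
        atg: Optional[int] = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                if atg is not None:
                    cand = ORF(frame, atg, i + 3)
                    best = _better_orf(best, cand, min_len)
                    atg = None
            elif codon == START_CODON and atg is None:
                atg = i
            i += 3
        if allow_open_end and atg is not None and i - atg >= 3:
            best = _better_orf(best, ORF(frame, atg, i), min_len)
    return best


def _better_orf(best: Optional[ORF], cand: ORF, min_len: int) -> Optional[ORF]:
    if cand.length < min_len:
        return best
    if best is None or (-cand.length, cand.start) < (-best.length, best.start):
        return cand
    return best


def find_longest_orf_six_frame(sequence: str, min_len: int = 30,
                               allow_open_end: bool = False
                               ) -> Optional[tuple[ORF, str]]:
    """Six-frame variant for raw (unstranded) sequence; returns (ORF, strand)."""
    fwd = find_longest_orf(sequence, min_len, allow_open_end)
    rev = find_longest_orf(revcomp(sequence), min_len, allow_open_end)
    cands = [(o, s) for o, s in ((fwd, "+"), (rev, "-")) if o is not None]
    if not cands:
        return None
    return min(cands, key=lambda p: (-p[0].length, p[1], p[0].start))


def select_representative(gene: Gene, genome: Genome,
                          min_orf_len: int = 30) -> str:
    """Isoform id with the longest ORF (the gene's representative).

    Ties are broken by longest spliced transcript, then lexicographically
    smallest transcript id.
    """
    if genome is None:
        raise AnnotationError("select_representative requires a Genome")

    def key(t: Transcript):
        seq = t.spliced_sequence(genome)
        orf = find_longest_orf(seq, min_orf_len)
        return (-(orf.length if orf else 0), -len(seq), t.id)

    return min(gene.transcripts, key=key).id


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _gff3_text(path) -> str:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return fh.read()


def read_gff3(path, name: Optional[str] = None,
              genome: Optional[Genome] = None) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    Coordinates are converted to 0-based half-open.  UTRs are taken from
    five_prime_UTR/three_prime_UTR features when present, otherwise derived
    from the exon−CDS difference.  Feature line order is irrelevant; the
    gene/mRNA/exon hierarchy is resolved through ID/Parent attributes.
    """
    data = _gff3_text(path)
    db = gffutils.create_db(data, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    for f in db.all_features():
        for pid in f.attributes.get("Parent", []):
            try:
                db[pid]
            except gffutils.exceptions.FeatureNotFoundError:
                raise AnnotationError(
                    f"feature {f.id!r}: unknown Parent {pid!r}") from None

    ann = AnnotationSet(name=name if name is not None else Path(path).stem)
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for m in db.children(g, level=1):
            if m.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons, cds, utr5, utr3 = [], [], [], []
            for c in db.children(m, level=1):
                iv = Interval(c.seqid, c.start - 1, c.end, c.strand)
                if c.featuretype == "exon":
                    exons.append(iv)
                elif c.featuretype == "CDS":
                    cds.append(iv)
                elif c.featuretype == "five_prime_UTR":
                    utr5.append(iv)
                elif c.featuretype == "three_prime_UTR":
                    utr3.append(iv)
            if not exons:
                raise AnnotationError(f"transcript {m.id!r} has no exons")
            t = Transcript(id=m.id, gene_id=g.id,
                           exons=sorted(exons), cds=sorted(cds),
                           utr5=sorted(utr5), utr3=sorted(utr3))
            t.validate()
            if not t.utr5 and not t.utr3:
                t.derive_utrs()
            transcripts.append(t)
        if not transcripts:
            raise AnnotationError(f"gene {g.id!r} has no transcripts")
        transcripts.sort(key=lambda t: t.id)
        gene = Gene(id=g.id, transcripts=transcripts)
        gene.validate()
        genes.append(gene)
    genes.sort(key=lambda g: (g.scaffold, g.span.start, g.id))
    for gene in genes:
        ann.add(gene)
    if genome is not None:
        ann.validate(genome)
    return ann


def _gff3_line(scaffold, source, ftype, start, end, strand, phase, attrs) -> str:
    att = ";".join(f"{k}={v}" for k, v in attrs)
    return f"{scaffold}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t{phase}\t{att}"


def write_gff3(annotation: AnnotationSet, path, source: str = "reannot") -> None:
    """Serialize an AnnotationSet as GFF3 with stable, deterministic ordering.

    Genes are emitted sorted by (scaffold, start, id); within a transcript,
    exons, CDS (with computed phase) and UTR features follow the mRNA line.
    Two writes of the same model produce byte-identical files.
    """
    lines = ["##gff-version 3"]
    for gene in sorted(annotation, key=lambda g: (g.scaffold, g.span.start, g.id)):
        sp = gene.span
        lines.append(_gff3_line(sp.scaffold, source, "gene", sp.start, sp.end,
                                sp.strand, ".", [("ID", gene.id)]))
        for t in sorted(gene.transcripts, key=lambda t: t.id):
            lines.append(_gff3_line(t.scaffold, source, "mRNA", t.start, t.end,
                                    t.strand, ".",
                                    [("ID", t.id), ("Parent", gene.id)]))
            for i, e in enumerate(t.exons, 1):
                lines.append(_gff3_line(e.scaffold, source, "exon", e.start,
                                        e.end, e.strand, ".",
                                        [("ID", f"{t.id}.exon{i}"),
                                         ("Parent", t.id)]))
            cds_tx = t.cds if t.strand == "+" else list(reversed(t.cds))
            cum = 0
            phased = []
            for c in cds_tx:
                phased.append((c, (3 - cum % 3) % 3))
                cum += c.length
            for c, phase in sorted(phased, key=lambda p: p[0].start):
                lines.append(_gff3_line(c.scaffold, source, "CDS", c.start,
                                        c.end, c.strand, str(phase),
                                        [("ID", f"{t.id}.cds"),
                                         ("Parent", t.id)]))
            for ftype, ivs in (("five_prime_UTR", t.utr5),
                               ("three_prime_UTR", t.utr3)):
                for i, u in enumerate(ivs, 1):
                    lines.append(_gff3_line(u.scaffold, source, ftype, u.start,
                                            u.end, u.strand, ".",
                                            [("ID", f"{t.id}.{ftype}{i}"),
                                             ("Parent", t.id)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
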