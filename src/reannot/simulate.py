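"""Seeded synthetic genomes, annotations, isoforms, 3'-end tags and motifs.

The generators emulate a compact, gene-dense genome: small introns (mean
around 300 bp), about five exons per gene, and a median intergenic gap of
roughly 0.6 kb.  Every generator is a pure function of its configuration
and seed, and each returns ground-truth tables so that downstream stages
(3'-end extension, splice-event classification, motif profiling) can be
tested for exact parameter recovery without any real sequencing data.

Background sequence is i.i.d. uniform over ACGT, which keeps motif-
enrichment nulls analytically predictable (e.g. the expected AWTAAA rate
is 2/4**6 per position).  Two deliberate sequence edits depart from the
uniform background: each canonical CDS is written as a clean ORF (ATG,
stop-free codons, terminal stop) so the canonical isoform is always its
gene's longest-ORF representative, and an 11-mer carrying stop codons in
all three frames is written at the transcript-5' end of every intron so
that intron-retaining or read-through isoforms cannot out-score it.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .extension import ReadAlignment
from .model import (AnnotationSet, Gene, Genome, Interval, Transcript,
                    revcomp)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# stop codons in all three reading frames; spliced out of canonical isoforms
_INTRON_STOP_BLOCK = "TAGCTAGCTAG"
_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


@dataclass
class CelseqConfig:
    """3'-end tag simulation: pileups at true transcript ends plus noise."""

    reads_per_end: int = 12
    read_len: int = 50
    extension_range: tuple = (80, 160)   # bp beyond the annotated 3' end
    anchor_overlap: int = 30             # pileup overlap into the last exon
    noise_clusters: int = 20
    noise_reads_max: int = 9             # one below the retention threshold
    n_samples: int = 2


@dataclass
class MotifImplantConfig:
    """PAS and AT-rich motif implants in 3' UTRs, offsets relative to TTS."""

    pas_variants: tuple = ("AATAAA", "ATTAAA")   # DNA forms of AWUAAA
    pas_offset_range: tuple = (-40, -16)
    at_rich_motif: str = "ATTTATTT"
    at_offset_range: tuple = (-100, -68)


@dataclass
class SimConfig:
    """Genome/annotation simulation parameters.

    Length distributions are log-normal with (mu, sigma) on the log scale;
    defaults target a mean intron of ~330 bp, ~5 exons per gene, a mean
    exon of ~225 bp and a median intergenic gap of ~590 bp.
    """

    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len_range: tuple = (90_000, 110_000)
    n_genes: int = 50
    intron_len_lognorm: tuple = (5.665, 0.5)     # mean ~327 bp
    exon_len_lognorm: tuple = (5.236, 0.6)       # mean ~225 bp
    exon_count_mean: float = 5.2
    intergenic_lognorm: tuple = (6.375, 0.7)     # median ~587 bp
    utr5_mean: int = 114
    utr3_mean: int = 188
    utr3_presence_prob: float = 1.0
    min_exon_len: int = 60
    min_intron_len: int = 60
    min_utr3_len: int = 120
    min_cds_len: int = 303
    isoform_event_mix: dict = field(default_factory=lambda: {
        "IntRt": 0.45, "AltTEx": 0.221, "AltAc": 0.173, "AltDo": 0.127,
        "ExSk": 0.018, "IntSt": 0.005, "IntEnd": 0.005,
    })
    celseq: CelseqConfig = field(default_factory=CelseqConfig)
    motifs: MotifImplantConfig = field(default_factory=MotifImplantConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        celseq = CelseqConfig(**{k: _detuple(v) for k, v in
                                 raw.pop("celseq", {}).items()})
        motifs = MotifImplantConfig(**{k: _detuple(v) for k, v in
                                       raw.pop("motifs", {}).items()})
        cfg = cls(**{k: _detuple(v) for k, v in raw.items()},
                  celseq=celseq, motifs=motifs)
        return cfg


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass(frozen=True)
class TrueEvent:
    gene_id: str
    event_class: str
    footprint: Interval
    isoform_ids: tuple
    n_support: int


@dataclass(frozen=True)
class TrueMotifSite:
    transcript_id: str
    motif_name: str
    offset: int            # transcript-orientation offset of the first base
    genomic_start: int
    genomic_end: int
    strand: str


@dataclass
class TruthTables:
    """Ground truth emitted alongside synthetic data."""

    canonical: dict = field(default_factory=dict)       # gene -> transcript
    three_prime_ends: dict = field(default_factory=dict)  # tid -> (old,new)
    as_events: list = field(default_factory=list)       # TrueEvent
    motif_sites: list = field(default_factory=list)     # TrueMotifSite

    def merge(self, other: "TruthTables") -> "TruthTables":
        out = TruthTables()
        out.canonical = {**self.canonical, **other.canonical}
        out.three_prime_ends = {**self.three_prime_ends,
                                **other.three_prime_ends}
        out.as_events = self.as_events + other.as_events
        out.motif_sites = self.motif_sites + other.motif_sites
        return out

    def events_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tclass\tscaffold\tstart\tend\tstrand\t"
                     "n_support\tisoforms\n")
            for e in self.as_events:
                fp = e.footprint
                fh.write(f"{e.gene_id}\t{e.event_class}\t{fp.scaffold}\t"
                         f"{fp.start}\t{fp.end}\t{fp.strand}\t{e.n_support}\t"
                         f"{','.join(e.isoform_ids)}\n")

    def ends_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\told_end\tnew_end\n")
            for tid, (old, new) in sorted(self.three_prime_ends.items()):
                fh.write(f"{tid}\t{old}\t{new}\n")

    def motifs_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tmotif\toffset\tgenomic_start\t"
                     "genomic_end\tstrand\n")
            for m in self.motif_sites:
                fh.write(f"{m.transcript_id}\t{m.motif_name}\t{m.offset}\t"
                         f"{m.genomic_start}\t{m.genomic_end}\t{m.strand}\n")


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# genome + canonical annotation
# ---------------------------------------------------------------------------

def _lognorm_int(rng, mu, sigma, lo, hi=None) -> int:
    v = int(round(rng.lognormal(mu, sigma)))
    v = max(lo, v)
    return min(v, hi) if hi is not None else v


def _tx_positions(cds: Sequence[Interval], strand: str) -> list[int]:
    """Genomic positions of CDS bases in transcript (5'→3') order."""
    pos: list[int] = []
    for iv in cds:
        pos.extend(range(iv.start, iv.end))
    if strand == "-":
        pos.reverse()
    return pos


def _write_tx_seq(seq: np.ndarray, positions: Sequence[int], text: str,
                  strand: str) -> None:
    """Write ``text`` (transcript orientation) at genomic ``positions``."""
    if strand == "-":
        text = "".join("TGCA"["ACGT".index(b)] for b in text)  # complement
    for p, b in zip(positions, text):
        seq[p] = ord(b)


def generate_genome_annotation(config: SimConfig
                               ) -> tuple[Genome, AnnotationSet, TruthTables]:
    """A random gene-dense genome with one canonical isoform per gene.

    Genes are packed onto scaffolds with log-normal intergenic gaps and
    random strands; every gene has a clean implanted ORF, a 5' UTR and
    (with ``utr3_presence_prob``) a 3' UTR.  Identical config and seed
    give byte-identical FASTA and GFF3 output.

    Raises :class:`SimulationError` when the requested genes cannot be
    packed onto the configured scaffolds.
    """
    rng = np.random.default_rng(config.seed)
    lengths = [int(rng.integers(*config.scaffold_len_range))
               for _ in range(config.n_scaffolds)]
    seqs = [rng.choice(_BASES, size=n) for n in lengths]
    names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]

    ann = AnnotationSet(name="synthetic")
    truth = TruthTables()
    cursors = [0] * config.n_scaffolds
    tail_margin = 400  # room for 3'-tag extension beyond the last gene
    scaffold_idx = 0

    for gi in range(config.n_genes):
        placed = False
        for _ in range(config.n_scaffolds):
            si = scaffold_idx % config.n_scaffolds
            scaffold_idx += 1
            gap = _lognorm_int(rng, *config.intergenic_lognorm, lo=60)
            structure = _sample_gene_structure(rng, config)
            gene_len = sum(l for l, _ in structure["parts"])
            start = cursors[si] + gap
            if start + gene_len + tail_margin > lengths[si]:
                continue
            gene = _place_gene(f"g{gi + 1:05d}", names[si], start, structure,
                               rng, config, seqs[si])
            ann.add(gene)
            truth.canonical[gene.id] = gene.transcripts[0].id
            cursors[si] = gene.span.end
            placed = True
            break
        if not placed:
            raise SimulationError(
                "cannot pack genes onto scaffolds; reduce n_genes, shrink "
                "intergenic gaps or enlarge scaffold_len_range")

    genome = Genome({name: seq.tobytes().decode("ascii")
                     for name, seq in zip(names, seqs)})
    ann.validate(genome)
    return genome, ann, truth


def _sample_gene_structure(rng, config: SimConfig) -> dict:
    n_exons = 1 + int(rng.poisson(max(0.0, config.exon_count_mean - 1.0)))
    n_exons = min(n_exons, 15)
    exon_lens = [_lognorm_int(rng, *config.exon_len_lognorm,
                              lo=config.min_exon_len, hi=2000)
                 for _ in range(n_exons)]
    intron_lens = [_lognorm_int(rng, *config.intron_len_lognorm,
                                lo=config.min_intron_len, hi=1500)
                   for _ in range(n_exons - 1)]
    strand = "+" if rng.random() < 0.5 else "-"
    has_utr3 = rng.random() < config.utr3_presence_prob

    u5 = max(20, int(rng.normal(config.utr5_mean, 30)))
    u3 = max(config.min_utr3_len, int(rng.normal(config.utr3_mean, 40))) \
        if has_utr3 else 0

    # terminal exons must hold their UTR plus >= 20 bp of CDS
    first_i, last_i = (0, -1) if strand == "+" else (-1, 0)
    if exon_lens[first_i] < u5 + 20:
        exon_lens[first_i] = u5 + 20
    if has_utr3 and exon_lens[last_i] < u3 + 20:
        exon_lens[last_i] = u3 + 20
    cds_len = sum(exon_lens) - u5 - u3
    if cds_len < config.min_cds_len:
        exon_lens[first_i] += config.min_cds_len - cds_len
        cds_len = config.min_cds_len
    rem = cds_len % 3  # keep the CDS a codon multiple
    if has_utr3:
        u3 += rem
    else:
        u5 += rem
    cds_len -= rem

    parts: list[tuple[int, str]] = []
    for i, el in enumerate(exon_lens):
        parts.append((el, "exon"))
        if i < len(intron_lens):
            parts.append((intron_lens[i], "intron"))
    return {"parts": parts, "strand": strand, "u5": u5, "u3": u3}


def _place_gene(gene_id: str, scaffold: str, start: int, structure: dict,
                rng, config: SimConfig, seq: np.ndarray) -> Gene:
    strand = structure["strand"]
    exons: list[Interval] = []
    pos = start
    for length, kind in structure["parts"]:
        if kind == "exon":
            exons.append(Interval(scaffold, pos, pos + length, strand))
        pos += length

    u5, u3 = structure["u5"], structure["u3"]
    cds = _carve_cds(exons, strand, u5, u3)
    t = Transcript(id=f"{gene_id}.t1", gene_id=gene_id, exons=list(exons),
                   cds=cds)
    t.derive_utrs()
    t.validate()

    # write a clean ORF into the CDS: ATG, stop-free codons, terminal TAA
    positions = _tx_positions(cds, strand)
    n_codons = len(positions) // 3
    body = rng.choice(len(_SAFE_CODONS), size=max(0, n_codons - 2))
    text = "ATG" + "".join(_SAFE_CODONS[i] for i in body) + "TAA"
    _write_tx_seq(seq, positions, text, strand)

    # stop codons in all frames at the transcript-5' end of each intron and
    # of the 3' UTR, so altered isoforms cannot extend an ORF past them
    block = _INTRON_STOP_BLOCK
    for intron in t.introns():
        if strand == "+":
            ipos = list(range(intron.start, intron.start + len(block)))
        else:
            ipos = list(range(intron.end - 1,
                              intron.end - 1 - len(block), -1))
        _write_tx_seq(seq, ipos, block, strand)
    if t.utr3:
        upos = _tx_positions(t.utr3, strand)[:len(block)]
        if len(upos) == len(block):
            _write_tx_seq(seq, upos, block, strand)

    return Gene(id=gene_id, transcripts=[t])


def _carve_cds(exons: Sequence[Interval], strand: str, u5: int, u3: int
               ) -> list[Interval]:
    """CDS intervals left after trimming UTR bases off the transcript ends."""
    left = u5 if strand == "+" else u3
    right = u3 if strand == "+" else u5
    cds: list[Interval] = []
    total = sum(e.length for e in exons)
    lo, hi = left, total - right
    cum = 0
    for e in exons:
        s = max(lo, cum)
        t = min(hi, cum + e.length)
        if s < t:
            cds.append(Interval(e.scaffold, e.start + (s - cum),
                                e.start + (t - cum), e.strand))
        cum += e.length
    return cds


# ---------------------------------------------------------------------------
# alternative isoforms with known AS events
# ---------------------------------------------------------------------------

def _tx_first_last(exons: Sequence[Interval], strand: str):
    """(first, last) exon indices in transcript orientation."""
    return (0, len(exons) - 1) if strand == "+" else (len(exons) - 1, 0)


def _build_event(rng, exons: list[Interval], introns: list[Interval],
                 strand: str, cls: str) -> Optional[tuple[list[Interval],
                                                          Interval]]:
    """Alternative exon chain plus event footprint, or None if infeasible."""
    sc = exons[0].scaffold
    k = len(exons)
    if cls == "IntRt":
        if k < 2:
            return None
        j = int(rng.integers(0, k - 1))
        merged = Interval(sc, exons[j].start, exons[j + 1].end, strand)
        new = exons[:j] + [merged] + exons[j + 2:]
        return new, introns[j]
    if cls == "ExSk":
        if k < 3:
            return None
        j = int(rng.integers(1, k - 1))
        new = exons[:j] + exons[j + 1:]
        return new, exons[j]
    if cls in ("AltAc", "AltDo"):
        if k < 2:
            return None
        order = rng.permutation(k - 1)
        shrink_right = (cls == "AltAc") == (strand == "+")
        for j in map(int, order):
            delta = int(rng.integers(9, 31))
            if shrink_right:
                tgt = exons[j + 1]
                if tgt.length < delta + 20:
                    continue
                new_tgt = Interval(sc, tgt.start + delta, tgt.end, strand)
                fp = Interval(sc, tgt.start, tgt.start + delta, strand)
                new = exons[:j + 1] + [new_tgt] + exons[j + 2:]
            else:
                tgt = exons[j]
                if tgt.length < delta + 20:
                    continue
                new_tgt = Interval(sc, tgt.start, tgt.end - delta, strand)
                fp = Interval(sc, tgt.end - delta, tgt.end, strand)
                new = exons[:j] + [new_tgt] + exons[j + 1:]
            return new, fp
        return None
    if cls == "AltTEx":
        if k < 2:
            return None
        # replace the transcript-last exon with a novel exon strictly
        # inside the last intron (novel junction, shared donor)
        last_genomic = strand == "+"
        intron = introns[-1] if last_genomic else introns[0]
        ex_len, gap = 80, 20
        if intron.length < ex_len + gap + 2:
            return None
        if last_genomic:
            s = intron.start + gap
            novel = Interval(sc, s, s + ex_len, strand)
            new = exons[:-1] + [novel]
        else:
            e = intron.end - gap
            novel = Interval(sc, e - ex_len, e, strand)
            new = [novel] + exons[1:]
        return new, novel
    if cls == "IntSt":
        if k < 3:
            return None
        if strand == "+":
            intron = introns[0]
            p = intron.start + intron.length // 2
            new = [Interval(sc, p, exons[1].end, strand)] + exons[2:]
        else:
            intron = introns[-1]
            p = intron.start + intron.length // 2
            new = exons[:-2] + [Interval(sc, exons[-2].start, p, strand)]
        return new, intron
    if cls == "IntEnd":
        if k < 3:
            return None
        if strand == "+":
            intron = introns[-1]
            q = intron.start + intron.length // 2
            new = exons[:-2] + [Interval(sc, exons[-2].start, q, strand)]
        else:
            intron = introns[0]
            q = intron.start + intron.length // 2
            new = [Interval(sc, q, exons[1].end, strand)] + exons[2:]
        return new, intron
    raise ValueError(f"unknown event class {cls!r}")


def spawn_isoforms(annotation: AnnotationSet, mix: Mapping[str, float],
                   seed: int, support: int = 3, event_prob: float = 1.0,
                   n_low_support: int = 0, max_retries: int = 8,
                   genome: Optional[Genome] = None
                   ) -> tuple[AnnotationSet, TruthTables]:
    """Add alternative isoforms carrying known AS events.

    Per gene (with probability ``event_prob``) one event class is drawn
    from ``mix`` among the classes feasible for that gene's structure, and
    ``support`` identical isoforms exhibiting it are added (so the event
    survives the min-support filter).  The first ``n_low_support`` event
    genes instead receive only 2 supporting isoforms, to exercise the
    filter.  Infeasible draws are resampled up to ``max_retries`` times
    before the gene is skipped.

    When ``genome`` is given, drawn events whose alternative isoform would
    (by chance) carry an ORF at least as long as the canonical one are
    also resampled, keeping the canonical isoform the unambiguous
    longest-ORF representative that truth labels are defined against.

    Returns a deep-copied annotation plus the truth table of events.
    """
    from .model import find_longest_orf
    rng = np.random.default_rng(seed)
    ann = copy.deepcopy(annotation)
    truth = TruthTables()
    classes = [c for c, w in mix.items() if w > 0]
    weights = np.array([mix[c] for c in classes], dtype=float)
    if not classes:
        return ann, truth
    weights = weights / weights.sum()

    n_event_genes = 0
    for gene in ann:
        if rng.random() >= event_prob:
            continue
        canonical = gene.transcripts[0]
        exons, introns = canonical.exons, canonical.introns()
        ref_orf = None
        if genome is not None:
            orf = find_longest_orf(canonical.spliced_sequence(genome))
            ref_orf = orf.length if orf else 0
        built = None
        for _ in range(max_retries):
            cls = str(rng.choice(classes, p=weights))
            cand = _build_event(rng, list(exons), introns,
                                canonical.strand, cls)
            if cand is None:
                continue
            if ref_orf is not None:
                probe = Transcript(id="_probe", gene_id=gene.id,
                                   exons=list(cand[0]))
                alt = find_longest_orf(probe.spliced_sequence(genome))
                if alt is not None and alt.length >= ref_orf:
                    continue
            built = (cls, *cand)
            break
        if built is None:
            continue
        cls, new_exons, footprint = built
        n_event_genes += 1
        n_sup = 2 if n_event_genes <= n_low_support else support
        iso_ids = []
        for j in range(n_sup):
            tid = f"{gene.id}.t{j + 2}"
            t = Transcript(id=tid, gene_id=gene.id, exons=list(new_exons))
            t.validate()
            gene.transcripts.append(t)
            iso_ids.append(tid)
        truth.as_events.append(TrueEvent(
            gene_id=gene.id, event_class=cls, footprint=footprint,
            isoform_ids=tuple(iso_ids), n_support=n_sup))
    return ann, truth


# ---------------------------------------------------------------------------
# 3'-end tag pileups
# ---------------------------------------------------------------------------

def simulate_3prime_tags(annotation: AnnotationSet, config: SimConfig,
                         seed: int, genome: Genome
                         ) -> tuple[list[ReadAlignment], TruthTables]:
    """Stranded 3'-end read pileups at and beyond annotated transcript ends.

    Each transcript with an annotated 3' UTR receives ``reads_per_end``
    mutually overlapping reads in one sample, tiled from inside its last
    exon out to a sampled extension beyond the annotated end, so the
    resulting retained cluster's far boundary is exactly the true new 3'
    end.  Additional sub-threshold noise pileups (at most
    ``noise_reads_max`` reads) are scattered over intergenic space.
    """
    cs = config.celseq
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    reads: list[ReadAlignment] = []
    truth = TruthTables()

    forbidden: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        sp = g.span
        forbidden.setdefault(sp.scaffold, []).append(
            (sp.start - 300, sp.end + max(cs.extension_range) + 100))

    samples = [f"sample{i + 1}" for i in range(cs.n_samples)]
    if cs.reads_per_end > 0:
        for si, t in enumerate(sorted(annotation.transcripts(),
                                      key=lambda t: t.id)):
            if not t.utr3:
                continue
            ext = int(rng.integers(cs.extension_range[0],
                                   cs.extension_range[1] + 1))
            sample = samples[si % len(samples)]
            L = cs.read_len
            if t.strand == "+":
                new_end = min(t.end + ext, lengths[t.scaffold])
                lo = t.end - cs.anchor_overlap
                starts = np.linspace(lo, new_end - L,
                                     cs.reads_per_end).round().astype(int)
                for s in starts:
                    reads.append(ReadAlignment(
                        Interval(t.scaffold, int(s), int(s) + L, "+"), sample))
            else:
                new_end = max(t.start - ext, 0)
                hi = t.start + cs.anchor_overlap
                ends = np.linspace(hi, new_end + L,
                                   cs.reads_per_end).round().astype(int)
                for e in ends:
                    reads.append(ReadAlignment(
                        Interval(t.scaffold, int(e) - L, int(e), "-"), sample))
            truth.three_prime_ends[t.id] = (t.three_prime_end, int(new_end))

    placed_noise: dict[str, list[tuple[int, int]]] = {}
    for _ in range(cs.noise_clusters):
        for _attempt in range(50):
            scaffold = str(rng.choice(list(lengths)))
            pos = int(rng.integers(100, lengths[scaffold] - 200))
            span = (pos - 150, pos + 250)
            bad = forbidden.get(scaffold, []) + placed_noise.get(scaffold, [])
            if any(lo < span[1] and span[0] < hi for lo, hi in bad):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            sample = str(rng.choice(samples))
            n = int(rng.integers(1, cs.noise_reads_max + 1))
            for j in range(n):
                s = pos + int(rng.integers(0, cs.read_len // 2))
                reads.append(ReadAlignment(
                    Interval(scaffold, s, s + cs.read_len, strand), sample))
            placed_noise.setdefault(scaffold, []).append(span)
            break
    reads.sort(key=lambda r: (r.interval.scaffold, r.interval.start,
                              r.interval.end, r.interval.strand, r.sample))
    return reads, truth


def ablate_motif(genome: Genome, consensus: str = "AWTAAA") -> Genome:
    """Genome copy with every occurrence of a motif (both strands) destroyed.

    Useful for building clean nulls: after ablation, implanted instances
    are the only matches.  Occurrences are broken by writing a ``C`` into
    the window (the PAS consensus and its reverse complement are C-free,
    so no new matches can arise); a few passes guard against overlaps.
    """
    from .signals import MotifModel, scan_motif
    motif = MotifModel.from_consensus(consensus)
    seqs = {}
    for name in genome:
        s = bytearray(genome[name], "ascii")
        for _ in range(5):
            text = bytes(s).decode("ascii")
            fwd = scan_motif(text, motif)
            rev = [len(s) - p - motif.length
                   for p in scan_motif(revcomp(text), motif)]
            hits = sorted(set(fwd + rev))
            if not hits:
                break
            for p in hits:
                s[p + motif.length // 2] = ord("C")
        seqs[name] = bytes(s).decode("ascii")
    return Genome(seqs)


# ---------------------------------------------------------------------------
# motif implantation
# ---------------------------------------------------------------------------

def implant_motifs(annotation: AnnotationSet, genome: Genome,
                   motif_config: Optional[MotifImplantConfig], seed: int
                   ) -> tuple[Genome, TruthTables]:
    """Write PAS and AT-rich motifs into 3' UTRs at known TTS offsets.

    For every transcript with a sufficiently long annotated 3' UTR, one
    PAS instance (AATAAA or ATTAAA) is written at a sampled offset in the
    PAS window and one AT-rich motif in the upstream window; offsets are
    transcript-orientation positions of the motif's first base relative to
    the last transcribed base (offset 0).  UTRs too short for the windows
    are skipped and logged.  Returns an edited genome copy and the truth
    table of implanted sites.
    """
    truth = TruthTables()
    if motif_config is None:
        return Genome({n: genome[n] for n in genome}), truth
    mc = motif_config
    rng = np.random.default_rng(seed)
    seqs = {n: bytearray(genome[n], "ascii") for n in genome}
    required = -mc.at_offset_range[0]

    for t in sorted(annotation.transcripts(), key=lambda t: t.id):
        if not t.utr3:
            continue
        utr_len = sum(u.length for u in t.utr3)
        if utr_len < required:
            logger.info("implant_motifs: %s 3' UTR too short (%d < %d), "
                        "skipped", t.id, utr_len, required)
            continue
        pas = str(rng.choice(mc.pas_variants))
        for motif, (olo, ohi) in ((pas, mc.pas_offset_range),
                                  (mc.at_rich_motif, mc.at_offset_range)):
            off = int(rng.integers(olo, ohi + 1))
            _implant_at_offset(seqs, t, motif, off, truth)
    return Genome({n: bytes(s).decode("ascii") for n, s in seqs.items()}), truth


def _implant_at_offset(seqs, t: Transcript, motif: str, off: int,
                       truth: TruthTables) -> None:
    anchor = t.end - 1 if t.strand == "+" else t.start
    if t.strand == "+":
        g0 = anchor + off
        seqs[t.scaffold][g0:g0 + len(motif)] = motif.encode()
        gs, ge = g0, g0 + len(motif)
    else:
        g0 = anchor - off  # first motif base, transcript orientation
        gs, ge = g0 - len(motif) + 1, g0 + 1
        seqs[t.scaffold][gs:ge] = revcomp(motif).encode()
    name = "PAS" if motif in ("AATAAA", "ATTAAA") else "ATrich"
    truth.motif_sites.append(TrueMotifSite(
        transcript_id=t.id, motif_name=name, offset=off,
        genomic_start=gs, genomic_end=ge, strand=t.strand))
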