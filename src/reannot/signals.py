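"""Transcription-terminal signal analysis: PAS and motif positional profiles.

Polyadenylation signals (PAS, consensus AWUAAA in mRNA, AWTAAA in DNA) and
other 3'-UTR motifs cluster just upstream of the transcription termination
site (TTS).  This module selects the "strict" transcript subsets the
analyses are anchored on (3' UTRs with tag-cluster support on long
scaffolds; TSSs whose promoters overlap no other gene), scans sequences
with IUPAC consensus strings or position-weight matrices, and builds

* per-20-bp-bin motif frequency profiles in a ±2 kb window around TTSs, and
* cumulative PAS-frequency curves up to 500 bp up/downstream of TSSs,
  scanned on the coding strand, whose contrast (faster accumulation
  upstream) reflects PAS depletion in the direction of transcription.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnnotationSet, Genome, Interval, Transcript, revcomp
from .extension import TagCluster

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SignalParams:
    min_scaffold_len: int = 50_000
    promoter_up: int = 100
    promoter_down: int = 50
    tts_window: int = 2_000
    bin_size: int = 20
    tss_window: int = 500
    pas_consensus: str = "AWTAAA"

    def __post_init__(self) -> None:
        if self.tts_window % self.bin_size:
            raise ValueError("bin_size must divide tts_window evenly")


# ---------------------------------------------------------------------------
# motif models and scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """Either an IUPAC consensus or a PWM with a log-odds threshold.

    The PWM holds per-position probabilities over ACGT (rows sum to 1);
    a window matches when its log-odds score against a uniform background
    reaches ``threshold_frac`` of the motif's maximum attainable score.
    """

    name: str = "motif"
    consensus: Optional[str] = None
    pwm: Optional[np.ndarray] = None  # shape (length, 4), rows sum to 1
    threshold_frac: float = 0.6
    _pssm: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC symbols {bad}")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("pwm must have shape (length, 4)")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-3):
                raise ValueError("pwm rows must sum to 1")
            self._pssm = np.log2((self.pwm + 1e-6) / 0.25)

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus else self.pwm.shape[0]

    @classmethod
    def from_consensus(cls, consensus: str, name: str = "consensus"
                       ) -> "MotifModel":
        return cls(name=name, consensus=consensus.upper().replace("U", "T"))


def read_meme_minimal(path) -> list[MotifModel]:
    """Motif models from a MEME minimal-format text file."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        counts = np.array(
            [[m.counts[b][i] for b in "ACGT"] for i in range(m.length)],
            dtype=float)
        pwm = counts / counts.sum(axis=1, keepdims=True)
        out.append(MotifModel(name=m.name or "motif", pwm=pwm))
    return out


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_motif(sequence: str, motif: MotifModel) -> list[int]:
    """All (overlapping) start positions matching the motif.

    IUPAC consensus: every window base must be compatible with the
    consensus symbol.  PWM: window log-odds must reach the threshold.
    ``N`` bases match nothing.
    """
    L = motif.length
    n = len(sequence)
    if n < L:
        return []
    codes = _encode(sequence)
    n_win = n - L + 1
    if motif.consensus is not None:
        ok = np.ones(n_win, dtype=bool)
        for j, sym in enumerate(motif.consensus.upper()):
            allowed = np.zeros(5, dtype=bool)
            for b in IUPAC[sym]:
                allowed[_BASE_INDEX[b]] = True
            ok &= allowed[codes[j:j + n_win]]
        return np.flatnonzero(ok).tolist()
    pssm = np.vstack([motif._pssm.T, np.full((1, L), -np.inf)]).T  # N row
    scores = np.zeros(n_win)
    for j in range(L):
        scores = scores + pssm[j, codes[j:j + n_win]]
    max_score = motif._pssm.max(axis=1).sum()
    return np.flatnonzero(scores >= motif.threshold_frac * max_score).tolist()


# ---------------------------------------------------------------------------
# strict anchor selection
# ---------------------------------------------------------------------------

def select_strict_utr3(annotation: AnnotationSet,
                       clusters: Sequence[TagCluster],
                       genome: Genome,
                       params: Optional[SignalParams] = None) -> set[str]:
    """Transcripts whose 3' UTR has tag-cluster support on a long scaffold.

    A transcript qualifies when it has an annotated 3' UTR, sits on a
    scaffold strictly longer than ``min_scaffold_len``, and its 3' UTR
    overlaps at least one same-strand cluster.
    """
    params = params or SignalParams()
    lengths = genome.lengths
    by_key: dict[tuple, list[TagCluster]] = {}
    for c in clusters:
        by_key.setdefault((c.interval.scaffold, c.interval.strand),
                          []).append(c)
    keep: set[str] = set()
    for t in annotation.transcripts():
        if not t.utr3:
            continue
        if lengths.get(t.scaffold, 0) <= params.min_scaffold_len:
            continue
        cands = by_key.get((t.scaffold, t.strand), [])
        if any(u.overlaps(c.interval) for u in t.utr3 for c in cands):
            keep.add(t.id)
    return keep


def select_strict_tss(annotation: AnnotationSet, genome: Genome,
                      params: Optional[SignalParams] = None) -> set[str]:
    """Transcripts on long scaffolds whose promoter overlaps no other gene.

    The promoter is ``promoter_up`` bp upstream and ``promoter_down`` bp
    downstream of the transcript 5' end, strand-aware, clamped at scaffold
    edges.
    """
    params = params or SignalParams()
    lengths = genome.lengths
    genes = list(annotation)
    spans_by_scaffold: dict[str, list[tuple[Interval, str]]] = {}
    for g in genes:
        spans_by_scaffold.setdefault(g.scaffold, []).append((g.span, g.id))
    keep: set[str] = set()
    for g in genes:
        if lengths.get(g.scaffold, 0) <= params.min_scaffold_len:
            continue
        for t in g.transcripts:
            p5 = t.five_prime_end
            if t.strand == "+":
                lo, hi = p5 - params.promoter_up, p5 + params.promoter_down
            else:
                lo, hi = p5 - params.promoter_down, p5 + params.promoter_up
            lo = max(0, lo)
            hi = min(lengths[g.scaffold], hi)
            clash = any(
                other_id != g.id and span.start < hi and lo < span.end
                for span, other_id in spans_by_scaffold[g.scaffold])
            if not clash:
                keep.add(t.id)
    return keep


# ---------------------------------------------------------------------------
# positional profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """A strand-aware genomic anchor base (offset 0 of a profile window)."""

    scaffold: str
    pos: int
    strand: str


def tts_anchors(annotation: AnnotationSet,
                ids: Optional[Iterable[str]] = None) -> list[Anchor]:
    """Anchors on the last transcribed base of (selected) transcripts."""
    wanted = set(ids) if ids is not None else None
    out = []
    for t in annotation.transcripts():
        if wanted is not None and t.id not in wanted:
            continue
        pos = t.end - 1 if t.strand == "+" else t.start
        out.append(Anchor(t.scaffold, pos, t.strand))
    return out


def tss_anchors(annotation: AnnotationSet,
                ids: Optional[Iterable[str]] = None) -> list[Anchor]:
    """Anchors on the first transcribed base of (selected) transcripts."""
    wanted = set(ids) if ids is not None else None
    out = []
    for t in annotation.transcripts():
        if wanted is not None and t.id not in wanted:
            continue
        pos = t.start if t.strand == "+" else t.end - 1
        out.append(Anchor(t.scaffold, pos, t.strand))
    return out


def _oriented_window(genome: Genome, anchor: Anchor, window: int
                     ) -> tuple[str, int]:
    """Sequence around an anchor in transcript orientation.

    Returns (seq, left_offset): ``seq[i]`` is the base at transcript-
    orientation offset ``left_offset + i`` from the anchor base (offset 0).
    Windows are trimmed at scaffold edges.
    """
    scaf = genome[anchor.scaffold]
    n = len(scaf)
    if anchor.strand == "+":
        lo = max(0, anchor.pos - window)
        hi = min(n, anchor.pos + window)
        return scaf[lo:hi], lo - anchor.pos
    lo = max(0, anchor.pos - window + 1)
    hi = min(n, anchor.pos + window + 1)
    return revcomp(scaf[lo:hi]), anchor.pos - (hi - 1)


@dataclass
class PositionalProfile:
    """Per-bin motif-hit frequencies in a window around anchors.

    ``centers`` are bin-center offsets in bp (negative = upstream of the
    anchor in transcript orientation); ``frequency[i]`` is hits per
    contributing sequence in that bin, with per-bin denominators so that
    edge-trimmed anchors only count where their window reaches.
    """

    centers: np.ndarray
    frequency: np.ndarray
    hit_counts: np.ndarray
    denominators: np.ndarray
    motif_name: str = "motif"

    @property
    def modal_bin_center(self) -> float:
        return float(self.centers[int(np.argmax(self.frequency))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.centers,
            "frequency": self.frequency,
            "hits": self.hit_counts,
            "n_sequences": self.denominators,
            "motif": self.motif_name,
        })


def positional_profile(anchors: Sequence[Anchor], genome: Genome,
                       motif: MotifModel,
                       params: Optional[SignalParams] = None,
                       window: Optional[int] = None) -> PositionalProfile:
    """Binned motif-hit frequency profile around a set of anchors.

    For each anchor, ±``window`` bp (default ``params.tts_window``) of
    sequence is taken in transcript orientation, scanned for the motif,
    and each hit is assigned to the 20-bp bin holding its first base
    (offset relative to the anchor).  Frequencies divide per-bin hit
    totals by the number of anchors whose window fully covers the bin.
    """
    params = params or SignalParams()
    W = window if window is not None else params.tts_window
    B = params.bin_size
    n_bins = 2 * W // B
    edges = np.arange(-W, W + B, B)
    hits = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    for anchor in anchors:
        seq, left = _oriented_window(genome, anchor, W)
        right = left + len(seq)  # offsets [left, right) available
        full = (edges[:-1] >= left) & (edges[1:] <= right)
        denom += full
        for p in scan_motif(seq, motif):
            off = left + p
            b = (off + W) // B
            if 0 <= b < n_bins and full[b]:
                hits[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, hits / np.maximum(denom, 1), 0.0)
    centers = edges[:-1] + B / 2
    return PositionalProfile(centers=centers, frequency=freq,
                             hit_counts=hits, denominators=denom,
                             motif_name=motif.name)


@dataclass
class CumulativeCurves:
    """Cumulative per-TSS PAS frequency by distance from the TSS."""

    offsets: np.ndarray        # 1..window bp
    upstream: np.ndarray
    downstream: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset_bp": self.offsets,
                             "upstream": self.upstream,
                             "downstream": self.downstream})


def cumulative_pas(tss_ids: Iterable[str], annotation: AnnotationSet,
                   genome: Genome,
                   params: Optional[SignalParams] = None) -> CumulativeCurves:
    """Cumulative PAS counts per TSS, up- vs downstream on the coding strand.

    For offsets 1..``tss_window``, the curves give the mean number of PAS
    consensus matches whose first base lies within that many bp upstream
    (respectively downstream, anchor base included) of each strict TSS.
    """
    params = params or SignalParams()
    W = params.tss_window
    motif = MotifModel.from_consensus(params.pas_consensus, name="PAS")
    anchors = tss_anchors(annotation, ids=tss_ids)
    up = np.zeros(W)
    down = np.zeros(W)
    n = len(anchors)
    for anchor in anchors:
        seq, left = _oriented_window(genome, anchor, W)
        for p in scan_motif(seq, motif):
            off = left + p
            if off < 0:
                up[-off - 1:] += 1   # within |off| bp upstream
            else:
                down[off:] += 1      # within off+1 bp downstream
    if n:
        up /= n
        down /= n
    return CumulativeCurves(offsets=np.arange(1, W + 1),
                            upstream=up, downstream=down)
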