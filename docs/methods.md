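# Methods

This note documents the models, rules and numerical choices behind
`reannot`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real data.

## Coordinate model

All internal coordinates are 0-based half-open on named scaffolds; GFF3
(1-based, fully closed) is converted only at the I/O boundary. A
transcript is an ordered chain of exons, strictly separated by ≥ 1 bp;
introns are defined as the inter-exon gaps, so exon lengths plus intron
lengths always equal the span length. UTRs are taken from the annotation
when present, otherwise derived as the exonic bases 5'/3' of the CDS on
the transcript strand. GFF3 writing uses a fixed ordering (scaffold,
start, feature rank), making writes byte-deterministic and the
read∘write∘read composition the identity on the model.

## ORFs and representative isoforms

`find_longest_orf` scans the sense strand of a spliced transcript
sequence for ATG→stop frames; the longest wins, ties broken by smallest
start. ORFs lacking an in-sequence stop are accepted only under an
explicit "open 3'" policy flag (default off) — coding-potential scoring is
out of scope, so an unterminated frame is not assumed to be coding. The
default minimum ORF length is 30 bp (10 codons); it is a conventional
noise floor, not a biological claim. A six-frame variant exists for raw
sequence but plays no role in representative selection, because
transcripts are already stranded. A gene's representative isoform is the
one with the longest ORF; ties fall back to the longest spliced transcript
and then the lexicographically smallest id, so selection is total and
deterministic.

## 3'-end extension

Reads are clustered single-linkage per (sample, scaffold, strand) with
"overlapping" read literally: ≥ 1 bp of overlap; abutting reads do not
merge. Filtering (≥ 10 reads, the `min_cluster_reads` default) happens
per sample *before* cross-sample merging, since tag counts are evidence
within a sample; merged clusters sum counts and union sample sets, and may
therefore exceed any single sample's count. Extension requires an
annotated 3' UTR and ≥ 10 bp overlap (`min_overlap_bp`) between the last
exon and a same-strand cluster, and only ever moves the 3' end outward;
when several clusters qualify, the farthest boundary wins (it is the
3'-most position with tag support). Extension is applied per transcript —
this subsumes the single-isoform case and leaves multi-isoform genes
well-defined. Clusters running past a scaffold edge are clamped with a
warning. These rules make the operation idempotent and monotone, which the
tests assert directly.

## Alternative-splicing classification

The seven classes are defined operationally on exon-chain differences
between an alternative isoform and the canonical (longest-ORF) isoform;
shared introns are ignored and each structural difference is consumed by
exactly one rule, under the precedence
IntRt > ExSk > AltAc/AltDo > AltTEx > IntSt/IntEnd:

* **IntRt** — a canonical intron entirely exonic in the alternative
  isoform through one exon that reaches into both flanking exons.
* **ExSk** — an alternative intron spanning exactly from one canonical
  intron's start to a later one's end, the canonical internal exon(s)
  between being fully intronic.
* **AltAc / AltDo** — a canonical and an alternative intron share the
  donor (AltAc) or acceptor (AltDo) but not the other site, *and* the
  exons flanking the differing site overlap each other. The overlap
  clause is deliberate: a genuinely novel terminal exon also shares one
  splice site with a canonical intron, and without the clause the
  donor/acceptor rules (which take precedence over AltTEx) would absorb
  every alternative-terminal-exon and read-through case. Donor and
  acceptor are resolved on the transcript strand (donor = boundary nearer
  the 5' end).
* **AltTEx** — the alternative first or last exon overlaps neither the
  corresponding canonical terminal exon, is reached through a novel
  (non-shared) junction, and the isoforms share at least one splice site
  elsewhere. The novel-junction clause separates true alternative
  terminal exons from intronic starts/ends, which are junction-free
  read-throughs.
* **IntSt / IntEnd** — the alternative transcript start/end lies strictly
  inside a canonical intron with no novel junction into the terminal
  exon.

Footprints are the intron (IntRt, IntSt, IntEnd), the skipped exon(s)
(ExSk), the interval between the competing splice sites (AltAc/AltDo), or
the alternative terminal exon (AltTEx); identical (class, footprint)
events from different isoforms merge, with supporter sets unioned.

Event support counts the transcripts exhibiting the **alternative** form.
"Supported by at least three transcripts" could also be read as counting
either form, or assembly-level alignments; the alternative-form reading is
the conservative one (it never inflates support with the canonical
majority) and is what `min_support = 3` filters on. The
%-of-AS-transcripts denominator is the union of supporters over all
classes; when a summary is built from externally supplied per-class
counts, that union is unknowable and the column is reported as undefined
rather than approximated. Percentages are rounded to one decimal; the
event-percentage column sums to 100 ± rounding of seven classes.

## Annotation comparison

Coverage between sets is measured over exonic bases (default), not spans:
the 80% threshold exists to tolerate missing UTRs, which is a property of
transcribed structure, and base-level coverage is what `overlapSelect`-
style tools compute. A span-based mode is provided as a switch. The
hierarchical Venn assignment walks the precedence order: every reference
gene lands in the region named by the lower-precedence sets covering it at
threshold, so reference-region counts sum exactly to the reference size;
a non-reference gene is counted only if no higher-precedence set covers
it. One-to-many correspondences (fragmented or merged models) are
reported in a separate correspondence table rather than double-counted in
regions. Intergenic distances use gene spans irrespective of strand, with
overlapping neighbours clamped to 0 and the median left undefined when no
scaffold holds two genes. Structure statistics tally exons and introns
over all transcripts, with per-gene averages over genes (so a single-
isoform annotation reproduces the intuitive per-gene numbers); gene
lengths are spans (introns included); genome coverage is the union of
spans over the genome length; ORF statistics use each gene's
representative isoform and require sequence.

## Terminal signals

"Scaffolds longer than 50 kb" is implemented as a strict inequality.
Promoters are −100..+50 bp around the transcript 5' end, strand-aware and
clamped at scaffold edges. PAS scanning is coding-strand only for both
TTS and TSS analyses — the upstream/downstream contrast at TSSs is only
meaningful in the gene's orientation — with a flag for double-strand
scanning. Positional profiles extract ±2,000 bp in transcript
orientation, assign each motif-hit start to the 20-bp bin holding its
offset, and divide per-bin hits by the number of anchors whose window
fully covers that bin: near scaffold edges a sequence simply stops
contributing to bins it cannot reach, which keeps frequencies unbiased
without discarding the anchor. Cumulative TSS curves count, per offset
k = 1..500, motif starts within k bp up- or downstream, normalised per
TSS; they are non-decreasing by construction. PWM scanning converts MEME
minimal-format probability matrices to log-odds against a uniform
background; a window matches at ≥ 60% of the motif's maximum score — a
tunable convention chosen because the upstream toolchain's threshold is
not published. `N` bases match nothing in either consensus or PWM mode.

## Synthetic data

The generators emulate the statistical shape of a compact animal genome:
log-normal intron lengths (mean ≈ 330 bp), 1 + Poisson exon counts
(mean ≈ 5.2), log-normal exon lengths (mean ≈ 225 bp), log-normal
intergenic gaps (median ≈ 590 bp), 5' UTRs ≈ 114 bp and 3' UTRs ≈ 188 bp
with a configurable presence probability, uniform random strands, and
i.i.d. uniform ACGT background — chosen so motif-null expectations are
closed-form (AWTAAA: 2·(1/4)⁶ per position). Three deliberate sequence
edits depart from the uniform background: each canonical CDS is written
as a clean ORF (ATG, stop-free codons, terminal stop), and an 11-mer
containing stop codons in all three frames is written at the transcript-5'
end of every intron and of every 3' UTR. These guarantee the canonical
isoform is its gene's unambiguous longest-ORF representative even after
isoforms with retained introns, shifted splice sites or read-throughs are
added; `spawn_isoforms` additionally verifies the property per drawn event
when given the genome, resampling the rare draws that would violate it.
Added isoforms carry at most one event each, so truth labels are
unambiguous; a configurable number of supporters replicate each event
(default 3, with an option for deliberately low-supported events at 2).
Tag pileups tile reads from 30 bp inside the last exon to a sampled
extension beyond the annotated end, so the retained cluster's far
boundary equals the true new end exactly; noise pileups are capped at 9
reads — one below the retention threshold — to sharpen filter tests.
`ablate_motif` destroys every occurrence of a motif on both strands
(writing a base foreign to the consensus), enabling implant-only nulls.

What passing these tests shows: the implementation applies its stated
rules exactly, recovers planted structure perfectly, and its estimators
match closed-form or brute-force oracles. What they do not show: behaviour
under real-data phenomena the generators omit — sequencing error,
internal priming, overlapping genes, non-uniform base composition,
incomplete or wrong input annotations, and assembly artefacts.

## Problem sizes and determinism

The test suite and the acceptance script run the synthetic pipeline at
200 genes across six ~150-kb scaffolds (≈ 0.9 Mb), with 500 genes for the
intergenic-median check where the median estimator needs the sample size;
these sizes give stable statistics while keeping a full run in seconds.
All randomness flows through `numpy.random.default_rng` seeded from a
single integer; identical seeds give byte-identical FASTA/GFF3/BED
outputs across runs and platforms.

## Known limitations

* Splice-site classification is structural only: no sequence scoring of
  donors/acceptors, no quantitative PSI estimates.
* Extension never creates new exons for clusters disjoint from the last
  exon; whether disjoint downstream clusters should seed novel terminal
  exons is left to annotation pipelines proper.
* The cross-sample cluster merge policy (union-merge after per-sample
  filtering) is one defensible reading of a procedure whose pooling
  details are underdetermined; merged counts are not comparable to
  per-sample counts.
* Motif discovery is out of scope; motif models are consumed (IUPAC or
  MEME minimal PWMs), not inferred, and no enrichment statistics are
  computed.
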