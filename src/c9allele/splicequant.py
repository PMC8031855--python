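"""Allele-aware RNA-seq quantification at the *C9orf72* exon-2 boundary.

Every read overlapping the first base of exon 2 (transcript orientation;
the exon's highest plus-strand coordinate, since the gene is on the minus
strand) is assigned exactly one label:

* ``authentic``   — spliced junction from a V1/V2/V3 first-exon donor;
* ``cryptic:Ck``  — spliced junction from one of the intron-1 cryptic donor
  sites C1–C4 (matched within a small window to absorb aligner jitter);
* ``unspliced``   — contiguous (junction-free) coverage across the
  intron-1/exon-2 boundary;
* ``outside``     — no overlap with the boundary;
* ``ambiguous``   — overlaps the boundary but fits no rule.

Boundary-class counts are per-base coverages at the boundary base, making
them commensurable with the mean per-base coverage over exons 2–5 (shared by
all variants), which stands in for the total transcript count at the 5' end
where library coverage is biased.  Transcript-class fractions follow by
subtraction: normal = (A − U − C)/A.  Reads overlapping heterozygous SNP
sites are assigned to their allele of origin via the haplotype map, which
supports the intron-read fold decomposition into an expression component
(gene body, introns 1–2 excluded) and a splicing component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genemodel import CrypticSiteRegistry, GeneModel, Interval
from .haplomap import HaplotypeMap

SENSE_STRAND = "-"  # C9orf72 transcripts run on the minus strand


@dataclass
class ReadRecord:
    """One aligned read: ordered genomic blocks plus observed SNP bases."""

    name: str
    chrom: str
    blocks: list[tuple[int, int]]  # 1-based inclusive, ascending, gaps = introns
    strand: str  # strand of the originating transcript: "-" sense, "+" antisense
    snp_obs: dict[int, str] = field(default_factory=dict)  # pos -> plus-strand base

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1:
                raise ValueError(f"read {self.name}: blocks overlap or unordered")
        for s, e in self.blocks:
            if s > e:
                raise ValueError(f"read {self.name}: inverted block {s}-{e}")

    def covers(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.blocks)

    def overlap_bases(self, interval: Interval) -> int:
        return sum(interval.overlap(s, e) for s, e in self.blocks)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class ReadClass:
    label: str  # authentic | cryptic:Ck | unspliced | outside | ambiguous
    variant: str | None = None  # V1/V2/V3 for authentic junctions
    cryptic_site: str | None = None

    @property
    def is_cryptic(self) -> bool:
        return self.label.startswith("cryptic")


@dataclass(frozen=True)
class AlleleAssignment:
    allele: str  # haplotype name or "unassigned"
    n_informative: int = 0
    conflict: bool = False
    mismatch: bool = False


@dataclass
class RetentionScore:
    intron: int
    score: float
    intron_density: float
    exon_density: float
    interval: Interval
    n_reads_counted: int


@dataclass
class TranscriptFractions:
    normal: float
    unspliced: float
    cryptic: float
    A: float
    U: float
    Cc: float

    def as_percent(self) -> tuple[float, float, float]:
        return (
            round(100 * self.normal, 1),
            round(100 * self.unspliced, 1),
            round(100 * self.cryptic, 1),
        )


@dataclass
class FoldDecomposition:
    total_fold: float
    expression_fold: float
    splicing_fold: float

    def rounded(self) -> tuple[float, float, float]:
        return (
            round(self.total_fold, 1),
            round(self.expression_fold, 1),
            round(self.splicing_fold, 1),
        )


# -- boundary classification -------------------------------------------------


def classify_exon2_boundary_read(
    read: ReadRecord,
    model: GeneModel,
    registry: CrypticSiteRegistry,
    min_anchor_bp: int = 1,
    donor_window_bp: int = 2,
) -> ReadClass:
    """Label one read by its behaviour at the exon-2 5' boundary.

    A read spans the boundary only if it covers the exon-2 first base with at
    least ``min_anchor_bp`` exonic bases *and* continues past it (an aligned
    base or junction at higher coordinates); a read whose alignment ends
    exactly at the boundary carries no splicing evidence and is ``outside``.
    """
    if read.chrom != model.chrom:
        return ReadClass(label="outside")
    b = model.exon2_boundary
    anchored = any(
        s <= b - min_anchor_bp + 1 and e >= b for s, e in read.blocks
    )
    if not anchored or read.span[1] <= b:
        return ReadClass(label="outside")

    # junction whose acceptor is the exon-2 start: the block ending exactly at
    # the boundary, followed (higher coordinates = transcript-upstream) by the
    # donor-side block
    for (s1, e1), (s2, e2) in zip(read.blocks, read.blocks[1:]):
        if e1 == b:
            donor = s2
            for variant, donor_pos in model.donors.items():
                if donor == donor_pos:
                    return ReadClass(label="authentic", variant=variant)
            site = registry.match(donor, window_bp=donor_window_bp)
            if site is not None:
                return ReadClass(
                    label=f"cryptic:{site.name}", cryptic_site=site.name
                )
            return ReadClass(label="ambiguous")

    # junction-free coverage across the intron-1/exon-2 boundary
    for s, e in read.blocks:
        if s <= b - min_anchor_bp + 1 and e >= b + min_anchor_bp:
            return ReadClass(label="unspliced")
    return ReadClass(label="ambiguous")


def boundary_class_counts(
    reads: Iterable[ReadRecord],
    model: GeneModel,
    registry: CrypticSiteRegistry,
    stranded: bool = True,
    **classify_kwargs,
) -> dict[str, int]:
    """Counts per boundary label; every boundary-overlapping read is counted
    under exactly one label."""
    counts: dict[str, int] = {}
    for read in reads:
        if stranded and read.strand != SENSE_STRAND:
            continue
        label = classify_exon2_boundary_read(
            read, model, registry, **classify_kwargs
        ).label
        if label != "outside":
            counts[label] = counts.get(label, 0) + 1
    return counts


# -- allelic origin ----------------------------------------------------------


def het_site_bases(
    hap_map: HaplotypeMap, pair: tuple[str, str]
) -> list[tuple[int, str, dict[str, frozenset[str]]]]:
    """(pos, rs_id, {haplotype: plus-strand allele set}) for every site
    informative between the two haplotypes, ordered by position."""
    out = []
    for rs_id in hap_map.informative_het_sites(pair):
        m = hap_map.marker(rs_id)
        out.append((m.pos, rs_id, {h: m.allele_set(h) for h in pair}))
    return out


def assign_allele(
    read: ReadRecord,
    het_sites: Sequence[tuple[int, str, Mapping[str, frozenset[str]]]],
) -> AlleleAssignment:
    """Allelic origin of a read from the informative SNP bases it carries.

    The read is assigned to the haplotype whose alleles match at *every*
    overlapped informative site; no overlap, a base outside both allele sets
    (sequencing error), or contradictory matches leave it unassigned.
    """
    matched: set[str] = set()
    n = 0
    mismatch = False
    for pos, _rs, bases_by_hap in het_sites:
        base = read.snp_obs.get(pos)
        if base is None or not read.covers(pos):
            continue
        n += 1
        hit = [h for h, alleles in bases_by_hap.items() if base in alleles]
        if not hit:
            mismatch = True
        else:
            matched.update(hit)
    if n == 0 or mismatch or len(matched) != 1:
        return AlleleAssignment(
            allele="unassigned",
            n_informative=n,
            conflict=len(matched) > 1,
            mismatch=mismatch,
        )
    return AlleleAssignment(allele=matched.pop(), n_informative=n)


# -- intron retention --------------------------------------------------------


def _per_base_density(
    reads: Iterable[ReadRecord], intervals: Sequence[Interval]
) -> tuple[float, int]:
    total_bases = 0
    n_reads = 0
    for read in reads:
        ov = sum(read.overlap_bases(iv) for iv in intervals)
        if ov:
            total_bases += ov
            n_reads += 1
    length = sum(len(iv) for iv in intervals)
    return total_bases / length, n_reads


def intron_retention_score(
    reads: Sequence[ReadRecord],
    model: GeneModel,
    intron_number: int,
    stranded: bool = True,
    apply_mask: bool = True,
) -> RetentionScore:
    """Per-base intron read density over per-base density across exons 2–5.

    For intron 1 the first ``model.antisense_mask_bp`` downstream of the HR
    are masked out (antisense transcripts co-localize there); with stranded
    data only sense-strand reads are counted, otherwise antisense
    contamination of intron 1 is possible and a warning is emitted.
    """
    if stranded:
        reads = [r for r in reads if r.strand == SENSE_STRAND]
    else:
        warnings.warn(
            "unstranded library: intron-1 signal may include antisense reads",
            stacklevel=2,
        )
    if intron_number == 1 and apply_mask:
        interval = model.intron1_masked
    else:
        interval = model.intron(intron_number)
    intron_density, n_reads = _per_base_density(reads, [interval])
    exon_density, _ = _per_base_density(reads, model.exon_span())
    if exon_density == 0:
        raise ValueError("zero read coverage over exons 2-5")
    return RetentionScore(
        intron=intron_number,
        score=intron_density / exon_density,
        intron_density=intron_density,
        exon_density=exon_density,
        interval=interval,
        n_reads_counted=n_reads,
    )


# -- transcript-class fractions ----------------------------------------------


def transcript_fractions(A: float, U: float, Cc: float) -> TranscriptFractions:
    """Class fractions from coverage-equivalents.

    ``A`` is the mean per-base coverage over exons 2–5 (all transcripts),
    ``U`` and ``Cc`` the unspliced and cryptic per-base coverages at the
    exon-2 boundary.  Normal transcripts are what remains after subtraction:
    (A − U − Cc)/A, clamped at zero with a warning if U + Cc exceeds A.
    """
    if A <= 0:
        raise ValueError("exon 2-5 coverage must be positive")
    if U < 0 or Cc < 0:
        raise ValueError("boundary coverages must be non-negative")
    normal = (A - U - Cc) / A
    if normal < 0:
        warnings.warn(
            "unspliced + cryptic coverage exceeds exon coverage; clamping "
            "normal fraction at 0",
            stacklevel=2,
        )
        normal = 0.0
    return TranscriptFractions(
        normal=normal, unspliced=U / A, cryptic=Cc / A, A=A, U=U, Cc=Cc
    )


def transcript_fractions_from_reads(
    reads: Sequence[ReadRecord],
    model: GeneModel,
    registry: CrypticSiteRegistry,
    stranded: bool = True,
    **classify_kwargs,
) -> TranscriptFractions:
    """Boundary classification + exon 2–5 coverage → class fractions."""
    if stranded:
        sense = [r for r in reads if r.strand == SENSE_STRAND]
    else:
        sense = list(reads)
    counts = boundary_class_counts(
        sense, model, registry, stranded=False, **classify_kwargs
    )
    U = counts.get("unspliced", 0)
    Cc = sum(n for label, n in counts.items() if label.startswith("cryptic"))
    A, _ = _per_base_density(sense, model.exon_span())
    return transcript_fractions(A, U, Cc)


# -- allele-resolved folds ---------------------------------------------------


def decompose_fold(
    intron_reads_allele_x: int,
    intron_reads_allele_y: int,
    body_reads_allele_x: int,
    body_reads_allele_y: int,
) -> FoldDecomposition:
    """Split the allelic intron-1 read fold into expression and splicing.

    total (intron-1 allelic ratio) = expression (gene-body allelic ratio,
    introns 1–2 excluded) × splicing (what remains); the identity holds
    exactly before rounding.
    """
    counts = (
        intron_reads_allele_x,
        intron_reads_allele_y,
        body_reads_allele_x,
        body_reads_allele_y,
    )
    if any(c <= 0 for c in counts):
        raise ValueError("all four read counts must be positive")
    total = intron_reads_allele_x / intron_reads_allele_y
    expression = body_reads_allele_x / body_reads_allele_y
    return FoldDecomposition(
        total_fold=total,
        expression_fold=expression,
        splicing_fold=total / expression,
    )


def allelic_read_counts(
    reads: Sequence[ReadRecord],
    model: GeneModel,
    het_sites: Sequence[tuple[int, str, Mapping[str, frozenset[str]]]],
    pair: tuple[str, str],
    region: str = "intron1",
    stranded: bool = True,
) -> dict[str, int]:
    """Identifiable (allele-assignable) read counts in a region.

    ``region``: "intron1" (masked) or "body" (all exons + introns 3–10,
    i.e. the gene excluding introns 1 and 2).
    """
    if region == "intron1":
        intervals = [model.intron1_masked]
    elif region == "body":
        intervals = [iv for iv in model.exons.values()] + [
            model.intron(i) for i in range(3, 11)
        ]
    else:
        raise ValueError(f"unknown region {region!r}")
    counts = {pair[0]: 0, pair[1]: 0}
    for read in reads:
        if stranded and read.strand != SENSE_STRAND:
            continue
        if not any(read.overlap_bases(iv) for iv in intervals):
            continue
        assignment = assign_allele(read, het_sites)
        if assignment.allele in counts:
            counts[assignment.allele] += 1
    return counts


def joint_retention_estimate(
    intron1_signal: float,
    intron2_signal: float,
    intron1_len: float = 1.0,
    intron2_len: float = 1.0,
) -> float:
    """Approximate fraction of intron-1-retaining transcripts that also
    retain intron 2: the ratio of length-normalized intron densities, capped
    at 1.  Assumes intron-2 retention occurs on intron-1-retaining
    transcripts (sequential retention); pass per-base densities directly or
    raw counts together with interval lengths.
    """
    if intron1_len <= 0 or intron2_len <= 0:
        raise ValueError("interval lengths must be positive")
    d1 = intron1_signal / intron1_len
    d2 = intron2_signal / intron2_len
    if d1 <= 0:
        raise ValueError("intron-1 density must be positive")
    if d2 < 0:
        raise ValueError("intron-2 density must be non-negative")
    return min(d2 / d1, 1.0)


# -- read I/O ----------------------------------------------------------------

_CHR9_LENGTH = 138_394_717  # GRCh38


def write_sam(
    reads: Sequence[ReadRecord], path: str | Path, chrom_length: int = _CHR9_LENGTH
) -> None:
    """Write reads as plain-text SAM (CIGAR M/N from blocks; SEQ carries the
    observed SNP bases on an 'A' filler)."""
    import pysam

    chroms = sorted({r.chrom for r in reads}) or ["chr9"]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_length} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(reads, key=lambda r: (r.chrom, r.blocks[0][0]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.name
            seg.reference_id = tid[read.chrom]
            seg.reference_start = read.blocks[0][0] - 1
            seg.flag = 16 if read.strand == "-" else 0
            seg.mapping_quality = 60
            cigar = []
            seq = []
            for i, (s, e) in enumerate(read.blocks):
                if i:
                    gap = s - read.blocks[i - 1][1] - 1
                    cigar.append((3, gap))  # N
                cigar.append((0, e - s + 1))  # M
                block_seq = ["A"] * (e - s + 1)
                for pos, base in read.snp_obs.items():
                    if s <= pos <= e and len(base) == 1:
                        block_seq[pos - s] = base
                seq.append("".join(block_seq))
            seg.cigartuples = cigar
            seg.query_sequence = "".join(seq)
            out.write(seg)


def reads_from_sam(
    path: str | Path, snp_positions: Iterable[int] | None = None
) -> list[ReadRecord]:
    """Read coordinate-sorted SAM/BAM into ReadRecords.

    ``snp_positions`` (1-based) selects the marker positions at which the
    aligned base is recorded for allelic assignment.
    """
    import pysam

    wanted = set(snp_positions or ())
    reads = []
    with pysam.AlignmentFile(str(path)) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            blocks = [(s + 1, e) for s, e in seg.get_blocks()]
            merged: list[tuple[int, int]] = []
            for s, e in blocks:  # pysam splits on I/D; rejoin contiguous blocks
                if merged and s == merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            snp_obs = {}
            if wanted:
                qseq = seg.query_sequence
                for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
                    if rpos + 1 in wanted:
                        snp_obs[rpos + 1] = qseq[qpos]
            reads.append(
                ReadRecord(
                    name=seg.query_name,
                    chrom=seg.reference_name,
                    blocks=merged,
                    strand="-" if seg.is_reverse else "+",
                    snp_obs=snp_obs,
                )
            )
    return reads


def reads_to_tsv(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Simplified tabular read format (name, chrom, blocks, strand, snp_obs)."""
    lines = ["name\tchrom\tblocks\tstrand\tsnp_obs"]
    for r in reads:
        blocks = ";".join(f"{s}-{e}" for s, e in r.blocks)
        obs = ",".join(f"{p}:{b}" for p, b in sorted(r.snp_obs.items()))
        lines.append(f"{r.name}\t{r.chrom}\t{blocks}\t{r.strand}\t{obs}")
    Path(path).write_text("\n".join(lines) + "\n")


def reads_from_tsv(path: str | Path) -> list[ReadRecord]:
    reads = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        name, chrom, blocks_s, strand, obs_s = (line.split("\t") + [""])[:5]
        blocks = [
            (int(p.split("-")[0]), int(p.split("-")[1]))
            for p in blocks_s.split(";")
            if p
        ]
        snp_obs = {}
        if obs_s:
            for item in obs_s.split(","):
                p, b = item.split(":")
                snp_obs[int(p)] = b
        reads.append(
            ReadRecord(
                name=name, chrom=chrom, blocks=blocks, strand=strand, snp_obs=snp_obs
            )
        )
    return reads
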