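"""Transcriptome data model, GFF3/FASTA input, and genomic<->mature coordinate maps.

All in-memory coordinates are 0-based half-open. GFF3 on disk is 1-based
inclusive and converted at the I/O boundary; BED and bedGraph are already
0-based half-open.

A mature (spliced) coordinate runs 5'->3' along the transcript, so position 0
is the transcript's 5' end regardless of genomic strand. For mRNAs the mature
axis is partitioned into three contiguous blocks: 5'UTR, CDS, 3'UTR.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

RNA_CLASSES = ("mRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other")

#: GFF3 feature types accepted as transcript records, mapped to RNA class.
FEATURE_TO_CLASS = {
    "mRNA": "mRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "ncRNA": "other",
    "transcript": "other",
}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """One transcript: strand, RNA class, exon chain and mature-axis segmentation.

    ``exons`` are ordered 5'->3' in transcript orientation (descending genomic
    start on the minus strand). ``utr5_len``/``cds_len``/``utr3_len`` segment
    the mature axis and are meaningful for mRNA only (zero otherwise).
    """

    id: str
    gene: str
    rna_class: str
    exons: tuple[GenomeInterval, ...]
    utr5_len: int = 0
    cds_len: int = 0
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise AnnotationError(f"{self.id}: unknown RNA class {self.rna_class!r}")
        if not self.exons:
            raise AnnotationError(f"{self.id}: transcript without exons")
        self.exons = tuple(self.exons)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationError(f"{self.id}: exons on mixed chromosomes/strands")
        # 5'->3' order and non-overlap along the genome
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if b.start < a.end:
                raise AnnotationError(f"{self.id}: overlapping exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if tuple(expected) != self.exons:
            raise AnnotationError(f"{self.id}: exons not ordered 5'->3'")
        if any(l < 0 for l in (self.utr5_len, self.cds_len, self.utr3_len)):
            raise AnnotationError(f"{self.id}: negative region length")
        if self.rna_class == "mRNA":
            if self.cds_len <= 0:
                raise AnnotationError(f"{self.id}: mRNA with cds_len <= 0")
            if self.utr5_len + self.cds_len + self.utr3_len != self.mature_length:
                raise AnnotationError(
                    f"{self.id}: region lengths do not sum to mature length"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all exons."""
        return min(e.start for e in self.exons), max(e.end for e in self.exons)

    @property
    def has_zero_length_region(self) -> bool:
        """True for an mRNA with an empty 5'UTR or 3'UTR.

        Such transcripts load fine but are excluded from metagene binning,
        where rescaling an empty region to a fixed bin count is undefined.
        """
        return self.rna_class == "mRNA" and (self.utr5_len == 0 or self.utr3_len == 0)

    def exon_offsets(self) -> list[int]:
        """Mature coordinate of each exon's first (5'-most) base."""
        offs, acc = [], 0
        for e in self.exons:
            offs.append(acc)
            acc += len(e)
        return offs

    def to_mature_coord(self, g: int) -> Optional[int]:
        """Map genomic position ``g`` to the spliced 5'->3' axis; None if intronic/outside."""
        for off, e in zip(self.exon_offsets(), self.exons):
            if e.contains(g):
                if self.strand == "+":
                    return off + (g - e.start)
                return off + (e.end - 1 - g)
        return None

    def to_genomic_coord(self, m: int) -> int:
        """Inverse of :meth:`to_mature_coord` (``m`` must be in range)."""
        if not 0 <= m < self.mature_length:
            raise AnnotationError(f"{self.id}: mature position {m} out of range")
        for off, e in zip(self.exon_offsets(), self.exons):
            if off <= m < off + len(e):
                d = m - off
                return e.start + d if self.strand == "+" else e.end - 1 - d
        raise AssertionError("unreachable")

    def region_at(self, m: int) -> str:
        """Region ('utr5' | 'cds' | 'utr3') of mature position ``m`` (mRNA only)."""
        if self.rna_class != "mRNA":
            raise AnnotationError(f"{self.id}: region_at on non-mRNA ({self.rna_class})")
        if not 0 <= m < self.mature_length:
            raise AnnotationError(
                f"{self.id}: mature position {m} outside [0, {self.mature_length})"
            )
        if m < self.utr5_len:
            return "utr5"
        if m < self.utr5_len + self.cds_len:
            return "cds"
        return "utr3"


@dataclass
class TranscriptomeAnnotation:
    """A keyed transcript collection plus chromosome lengths."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.transcripts.values():
            self._check_bounds(t)

    def _check_bounds(self, t: TranscriptModel) -> None:
        if t.chrom not in self.genome_lengths:
            raise AnnotationError(f"{t.id}: unknown chromosome {t.chrom}")
        if t.span[1] > self.genome_lengths[t.chrom]:
            raise AnnotationError(f"{t.id}: exon beyond end of {t.chrom}")

    def add(self, t: TranscriptModel) -> None:
        if t.id in self.transcripts:
            raise AnnotationError(f"duplicate transcript id {t.id}")
        self._check_bounds(t)
        self.transcripts[t.id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]

    def by_class(self, rna_class: str) -> list[TranscriptModel]:
        return [t for t in self if t.rna_class == rna_class]

    def to_table(self) -> pd.DataFrame:
        """Flat per-transcript table (one row per transcript)."""
        rows = [
            {
                "id": t.id,
                "gene": t.gene,
                "class": t.rna_class,
                "chrom": t.chrom,
                "strand": t.strand,
                "n_exons": len(t.exons),
                "mature_length": t.mature_length,
                "utr5_len": t.utr5_len,
                "cds_len": t.cds_len,
                "utr3_len": t.utr3_len,
            }
            for t in self
        ]
        return pd.DataFrame(rows)

    def write_table(self, path: str | os.PathLike) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _validate_gff3_lines(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"malformed GFF3 line {i}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"malformed GFF3 line {i}: {exc}") from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"malformed GFF3 line {i}: bad coordinates {start}..{end}"
                )


def _mature_extent(t_exons: list[GenomeInterval], strand: str,
                   sub: list[tuple[int, int]]) -> tuple[int, int]:
    """Mature [start, end) of a set of genomic sub-intervals (e.g. all CDS parts)."""
    # ``t_exons`` arrive already ordered 5'->3' in transcript orientation.
    probe = TranscriptModel(id="_probe", gene="", rna_class="other",
                            exons=tuple(t_exons))
    positions = []
    for s, e in sub:
        for g in (s, e - 1):
            m = probe.to_mature_coord(g)
            if m is None:
                raise AnnotationError("CDS/UTR feature outside exons")
            positions.append(m)
    return min(positions), max(positions) + 1


def load_annotation(gff3_path: str | os.PathLike,
                    fasta_path: str | os.PathLike) -> TranscriptomeAnnotation:
    """Read a GFF3 annotation and an indexed genome FASTA.

    Transcript features (mRNA, rRNA, tRNA, snRNA, snoRNA, ncRNA, transcript)
    are collected with their exon children. For mRNAs, UTR lengths come from
    five_prime_UTR/three_prime_UTR features when present and are otherwise
    derived from the CDS extent on the mature axis.
    """
    import gffutils
    import pyfaidx

    _validate_gff3_lines(gff3_path)
    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:",
            merge_strategy="error", keep_order=True,
        )
    except Exception as exc:  # sqlite duplicate-ID and parse errors
        raise AnnotationError(f"GFF3 load failed ({exc})") from exc

    fa = pyfaidx.Fasta(str(fasta_path))
    ann = TranscriptomeAnnotation(
        genome_lengths={name: len(fa[name]) for name in fa.keys()}
    )

    for ftype, rna_class in FEATURE_TO_CLASS.items():
        for feat in db.features_of_type(ftype):
            strand = feat.strand
            if strand not in ("+", "-"):
                raise AnnotationError(f"{feat.id}: missing strand")
            exon_feats = sorted(db.children(feat, featuretype="exon"),
                                key=lambda f: f.start)
            if exon_feats:
                exon_ivs = [GenomeInterval(feat.seqid, f.start - 1, f.end, strand)
                            for f in exon_feats]
            else:
                exon_ivs = [GenomeInterval(feat.seqid, feat.start - 1, feat.end, strand)]
            if strand == "-":
                exon_ivs = exon_ivs[::-1]

            utr5 = cds = utr3 = 0
            if rna_class == "mRNA":
                cds_feats = [(f.start - 1, f.end)
                             for f in db.children(feat, featuretype="CDS")]
                if not cds_feats:
                    raise AnnotationError(f"{feat.id}: mRNA without CDS features")
                mature_len = sum(len(e) for e in exon_ivs)
                u5 = [(f.start - 1, f.end)
                      for f in db.children(feat, featuretype="five_prime_UTR")]
                u3 = [(f.start - 1, f.end)
                      for f in db.children(feat, featuretype="three_prime_UTR")]
                if u5 or u3:
                    utr5 = sum(e - s for s, e in u5)
                    utr3 = sum(e - s for s, e in u3)
                    cds = mature_len - utr5 - utr3
                else:
                    cs, ce = _mature_extent(list(exon_ivs), strand, cds_feats)
                    utr5, cds, utr3 = cs, ce - cs, mature_len - ce

            gene = feat.attributes.get("gene", [feat.id])[0]
            ann.add(TranscriptModel(
                id=feat.id, gene=gene, rna_class=rna_class,
                exons=tuple(exon_ivs),
                utr5_len=utr5, cds_len=cds, utr3_len=utr3,
            ))

    if not ann.transcripts:
        raise AnnotationError("no transcript features found in GFF3")
    return ann


def to_mature_coord(t: TranscriptModel, g: int) -> Optional[int]:
    return t.to_mature_coord(g)


def region_at(t: TranscriptModel, m: int) -> str:
    return t.region_at(m)
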