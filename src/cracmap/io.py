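"""On-disk formats for the pipeline.

Read alignments travel as a flat :class:`pandas.DataFrame` ("read table") with
columns ``chrom, start, end, strand, sample, role, bio_rep, tech_rep, unique``
(0-based half-open intervals). On disk they are BED6 (name packs the sample
labels, score is 1 for uniquely mapped) or SAM via pysam.
"""

from __future__ import annotations

import os
import textwrap
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

READ_COLUMNS = [
    "chrom", "start", "end", "strand",
    "sample", "role", "bio_rep", "tech_rep", "unique",
]


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_protein_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(ann, path: str | os.PathLike) -> None:
    """Serialize a :class:`~cracmap.annotation.TranscriptomeAnnotation` as GFF3.

    mRNAs get gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR records;
    ncRNAs get a feature of their class type plus exons. Coordinates go out
    1-based inclusive.
    """
    class_to_feature = {"mRNA": "mRNA", "rRNA": "rRNA", "tRNA": "tRNA",
                        "snRNA": "snRNA", "snoRNA": "snoRNA", "other": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.genome_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.genome_lengths[chrom]}\n")
        for t in sorted(ann, key=lambda t: (t.chrom, t.span[0], t.id)):
            span_s, span_e = t.span
            ftype = class_to_feature[t.rna_class]

            def line(feat, s, e, attrs):
                fh.write("\t".join([
                    t.chrom, "cracmap", feat, str(s + 1), str(e), ".",
                    t.strand, ".", attrs,
                ]) + "\n")

            line("gene", span_s, span_e,
                 f"ID=gene:{t.id};gene={t.gene}")
            line(ftype, span_s, span_e,
                 f"ID={t.id};Parent=gene:{t.id};gene={t.gene}")
            for i, e in enumerate(t.exons, start=1):
                line("exon", e.start, e.end,
                     f"ID={t.id}.exon{i};Parent={t.id}")
            if t.rna_class == "mRNA":
                for region, ftype2 in (("utr5", "five_prime_UTR"),
                                       ("cds", "CDS"),
                                       ("utr3", "three_prime_UTR")):
                    for s, e in _region_genomic_blocks(t, region):
                        line(ftype2, s, e, f"ID={t.id}.{region};Parent={t.id}")


def _region_genomic_blocks(t, region: str) -> list[tuple[int, int]]:
    """Genomic [start, end) blocks of an mRNA region, exon by exon."""
    bounds = {"utr5": (0, t.utr5_len),
              "cds": (t.utr5_len, t.utr5_len + t.cds_len),
              "utr3": (t.utr5_len + t.cds_len, t.mature_length)}
    m0, m1 = bounds[region]
    blocks = []
    for off, e in zip(t.exon_offsets(), t.exons):
        lo, hi = max(m0, off), min(m1, off + len(e))
        if lo >= hi:
            continue
        if t.strand == "+":
            blocks.append((e.start + (lo - off), e.start + (hi - off)))
        else:
            blocks.append((e.end - (hi - off), e.end - (lo - off)))
    return sorted(blocks)


def write_reads_bed(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    name = (reads["sample"].astype(str) + "|" + reads["role"].astype(str)
            + "|" + reads["bio_rep"].astype(str) + "|" + reads["tech_rep"].astype(str))
    bed = pd.DataFrame({
        "chrom": reads["chrom"],
        "start": reads["start"],
        "end": reads["end"],
        "name": name,
        "score": reads["unique"].astype(int),
        "strand": reads["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | os.PathLike) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str})
    parts = bed["name"].str.split("|", expand=True)
    if parts.shape[1] != 4:
        raise ValueError(
            f"{path}: BED name field must be 'sample|role|bio_rep|tech_rep'"
        )
    return pd.DataFrame({
        "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
        "strand": bed["strand"],
        "sample": parts[0], "role": parts[1],
        "bio_rep": parts[2].astype(int), "tech_rep": parts[3].astype(int),
        "unique": bed["score"].astype(int) > 0,
    })[READ_COLUMNS]


def write_reads_sam(reads: pd.DataFrame, ann, path: str | os.PathLike) -> None:
    """Minimal single-end SAM; read group id packs the sample labels."""
    import pysam

    chroms = sorted(ann.genome_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(ann.genome_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}|{row.sample}|{row.role}|{row.bio_rep}|{row.tech_rep}"
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 42 if row.unique else 0
            length = int(row.end - row.start)
            a.cigarstring = f"{length}M"
            a.query_sequence = "N" * length
            out.write(a)


def read_reads_sam(path: str | os.PathLike, min_mapq: int = 1) -> pd.DataFrame:
    """Load a SAM/BAM; alignments with MAPQ >= ``min_mapq`` count as unique."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            parts = a.query_name.split("|")
            sample, role, bio, tech = (parts[1:5] if len(parts) >= 5
                                       else ("sample", "crac_tagged", "1", "1"))
            rows.append((a.reference_name, a.reference_start, a.reference_end,
                         "-" if a.is_reverse else "+", sample, role,
                         int(bio), int(tech), a.mapping_quality >= min_mapq))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read_alignments(path: str | os.PathLike) -> pd.DataFrame:
    """Dispatch on extension: .bed -> BED6, .sam/.bam -> SAM."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".bed":
        return read_reads_bed(path)
    if ext in (".sam", ".bam"):
        return read_reads_sam(path)
    raise ValueError(f"unsupported alignment format: {path}")


def write_bedgraph(runs: pd.DataFrame, path: str | os.PathLike,
                   track_name: str | None = None) -> None:
    """Write (chrom, start, end, value) runs as bedGraph."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        runs.to_csv(fh, sep="\t", header=False, index=False)


def write_count_table(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Tidy (transcript_id, sample, count) TSV from a wide counts frame."""
    tidy = (counts.rename_axis("transcript_id")
            .reset_index()
            .melt(id_vars="transcript_id", var_name="sample", value_name="count"))
    tidy.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    tidy = pd.read_csv(path, sep="\t")
    return tidy.pivot(index="transcript_id", columns="sample", values="count").fillna(0)
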