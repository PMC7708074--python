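"""Partition uniquely mapped reads into RNA classes, count reads per
transcript and per mRNA region, and normalize to RPM.

Assignment rule: a read belongs to the transcript (same strand) whose exons
contain the read's midpoint, ``floor((start + end - 1) / 2)``. When several
transcripts contain the midpoint the one with the longest total exonic
overlap with the read wins; remaining ties go to the lexicographically
smallest transcript id, so the result is independent of input read order.

RNA-class partitioning uses the same midpoint containment but resolves
multiple hits by a fixed class priority (abundant classes first), mimicking
the masking order of CRAC pipelines. Reads whose midpoint touches no
same-strand transcript are "intergenic".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import TranscriptomeAnnotation

CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "mRNA", "other")
SAMPLE_ROLES = ("crac_tagged", "crac_control", "rnaseq", "riboseq")


class AssignmentError(ValueError):
    pass


def read_midpoints(reads: pd.DataFrame) -> np.ndarray:
    s = reads["start"].to_numpy(dtype=np.int64)
    e = reads["end"].to_numpy(dtype=np.int64)
    return (s + e - 1) // 2


def exon_table(ann: TranscriptomeAnnotation) -> pd.DataFrame:
    """One row per exon with its transcript, class and mature offset."""
    rows = []
    for t in ann:
        for off, ex in zip(t.exon_offsets(), t.exons):
            rows.append((ex.chrom, ex.start, ex.end, ex.strand,
                         t.id, t.rna_class, off))
    df = pd.DataFrame(rows, columns=[
        "Chromosome", "Start", "End", "Strand", "tx", "rna_class", "offset",
    ])
    return df


def _candidate_pairs(reads: pd.DataFrame,
                     ann: TranscriptomeAnnotation) -> pd.DataFrame:
    """Join read intervals against exons (same strand).

    Returns one row per (read, exon) overlap with the exonic overlap length,
    whether the exon contains the read midpoint, and the mature coordinate of
    the midpoint within that exon's transcript.
    """
    import pyranges as pr

    unknown = set(reads["chrom"].unique()) - set(ann.genome_lengths)
    if unknown:
        raise AssignmentError(
            f"reads on unknown chromosome(s): {', '.join(sorted(unknown))}"
        )
    mids = read_midpoints(reads)
    query = pd.DataFrame({
        "Chromosome": reads["chrom"].to_numpy(),
        "Start": reads["start"].to_numpy(dtype=np.int64),
        "End": reads["end"].to_numpy(dtype=np.int64),
        "Strand": reads["strand"].to_numpy(),
        "ridx": np.arange(len(reads), dtype=np.int64),
        "mid": mids,
    })
    exons = exon_table(ann)
    if exons.empty or query.empty:
        return pd.DataFrame(columns=["ridx", "mid", "tx", "rna_class",
                                     "overlap", "contains", "mature_pos"])
    joined = pr.PyRanges(query).join(
        pr.PyRanges(exons), strandedness="same", suffix="_ex").df
    if joined.empty:
        return pd.DataFrame(columns=["ridx", "mid", "tx", "rna_class",
                                     "overlap", "contains", "mature_pos"])
    ov = (np.minimum(joined["End"], joined["End_ex"])
          - np.maximum(joined["Start"], joined["Start_ex"]))
    contains = (joined["Start_ex"] <= joined["mid"]) & (joined["mid"] < joined["End_ex"])
    plus = joined["Strand"].to_numpy() == "+"
    mature = np.where(
        plus,
        joined["offset"] + (joined["mid"] - joined["Start_ex"]),
        joined["offset"] + (joined["End_ex"] - 1 - joined["mid"]),
    )
    out = pd.DataFrame({
        "ridx": joined["ridx"].to_numpy(),
        "mid": joined["mid"].to_numpy(),
        "tx": joined["tx"].to_numpy(),
        "rna_class": joined["rna_class"].to_numpy(),
        "overlap": ov.to_numpy(),
        "contains": contains.to_numpy(),
        "mature_pos": mature,
    })
    return out


def assign_reads(reads: pd.DataFrame,
                 ann: TranscriptomeAnnotation) -> pd.DataFrame:
    """Per-read transcript assignment for uniquely mapped reads.

    Returns a frame with one row per assigned read: the read's sample labels
    plus ``tx``, ``rna_class`` and ``mature_pos`` (midpoint position on the
    winning transcript's mature axis). Unassigned reads are dropped.
    """
    reads = reads.reset_index(drop=True)
    uniq = reads[reads["unique"]].copy() if "unique" in reads else reads
    pairs = _candidate_pairs(uniq, ann)
    if pairs.empty:
        return pd.DataFrame(columns=list(uniq.columns)
                            + ["tx", "rna_class", "mature_pos"])
    # total exonic overlap per (read, transcript), summed over all exons
    pairs["tot_overlap"] = pairs.groupby(["ridx", "tx"])["overlap"].transform("sum")
    # a candidate must contain the midpoint; exons within a transcript do not
    # overlap, so exactly one row per candidate survives
    cand = pairs[pairs["contains"]]
    if cand.empty:
        return pd.DataFrame(columns=list(uniq.columns)
                            + ["tx", "rna_class", "mature_pos"])
    # winner: longest overlap, then smallest transcript id — order-free
    cand = cand.sort_values(["ridx", "tot_overlap", "tx"],
                            ascending=[True, False, True], kind="mergesort")
    winners = cand.drop_duplicates("ridx", keep="first")
    assigned = uniq.iloc[winners["ridx"].to_numpy()].copy()
    assigned["tx"] = winners["tx"].to_numpy()
    assigned["rna_class"] = winners["rna_class"].to_numpy()
    assigned["mature_pos"] = winners["mature_pos"].to_numpy()
    return assigned.reset_index(drop=True)


def classify_reads(reads: pd.DataFrame, ann: TranscriptomeAnnotation,
                   priority: tuple[str, ...] = CLASS_PRIORITY) -> pd.DataFrame:
    """Per-sample RNA-class share table (fractions sum to 1 per sample).

    Each unique read is assigned to exactly one class by midpoint overlap
    with ``priority`` deciding multi-class hits; reads overlapping nothing
    count as "intergenic".
    """
    reads = reads.reset_index(drop=True)
    uniq = reads[reads["unique"]].copy() if "unique" in reads else reads
    pairs = _candidate_pairs(uniq, ann)
    pairs = pairs[pairs["contains"]]
    rank = {c: i for i, c in enumerate(priority)}
    labels = pd.Series("intergenic", index=np.arange(len(uniq)))
    if not pairs.empty:
        pairs = pairs.assign(rank=pairs["rna_class"].map(rank))
        best = (pairs.sort_values(["ridx", "rank"], kind="mergesort")
                .drop_duplicates("ridx", keep="first"))
        labels.loc[best["ridx"].to_numpy()] = best["rna_class"].to_numpy()
    out = (pd.DataFrame({"sample": uniq["sample"].to_numpy(),
                         "rna_class": labels.to_numpy()})
           .groupby(["sample", "rna_class"]).size().rename("n_reads")
           .reset_index())
    totals = out.groupby("sample")["n_reads"].transform("sum")
    out["fraction"] = out["n_reads"] / totals
    return out


@dataclass
class CountMatrix:
    """Transcripts x samples raw counts with sample roles and library sizes.

    ``library_size`` is, by default, the number of transcriptome-assigned
    unique reads in the sample (for quantitative assays, the column total);
    RPM = count / library_size * 1e6.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample; columns: role, bio_rep, tech_rep, library_size
    rpm: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise AssignmentError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.samples["role"]) - set(SAMPLE_ROLES)
        if bad:
            raise AssignmentError(f"unknown sample roles: {sorted(bad)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.samples["library_size"]

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    def merged_with(self, other: "CountMatrix") -> "CountMatrix":
        """Union of transcripts, concatenation of samples."""
        overlap = set(self.counts.columns) & set(other.counts.columns)
        if overlap:
            raise AssignmentError(f"duplicate sample ids: {sorted(overlap)}")
        counts = pd.concat([self.counts, other.counts], axis=1).fillna(0).astype(int)
        samples = pd.concat([self.samples, other.samples])
        return CountMatrix(counts=counts, samples=samples)

    def write_tsv(self, counts_path: str | os.PathLike,
                  samples_path: Optional[str | os.PathLike] = None) -> None:
        out = self.counts.rename_axis("transcript_id")
        if self.rpm is not None:
            rpm = self.rpm.add_suffix(".rpm")
            out = pd.concat([out, rpm], axis=1)
        out.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")


def count_per_transcript(reads: pd.DataFrame, ann: TranscriptomeAnnotation,
                         assigned: Optional[pd.DataFrame] = None) -> CountMatrix:
    """Count uniquely mapped reads per transcript for every CRAC sample.

    ``assigned`` may carry a precomputed :func:`assign_reads` result to avoid
    repeating the interval join.
    """
    if assigned is None:
        assigned = assign_reads(reads, ann)
    tx_index = pd.Index(sorted(ann.transcripts), name="transcript_id")
    counts = (assigned.groupby(["tx", "sample"]).size().unstack(fill_value=0)
              .reindex(tx_index, fill_value=0))
    all_samples = reads[["sample", "role", "bio_rep", "tech_rep"]].drop_duplicates("sample")
    counts = counts.reindex(columns=all_samples["sample"].to_numpy(), fill_value=0)
    samples = all_samples.set_index("sample")
    samples["library_size"] = counts.sum(axis=0)
    return CountMatrix(counts=counts.astype(int), samples=samples)


def count_matrix_from_quant(quant: pd.DataFrame,
                            roles: Mapping[str, str]) -> CountMatrix:
    """Wrap RNA-seq / Ribo-seq count columns; library size = column sum."""
    samples = pd.DataFrame({
        "role": [roles[c] for c in quant.columns],
        "bio_rep": [i + 1 for i in range(len(quant.columns))],
        "tech_rep": 1,
        "library_size": quant.sum(axis=0).to_numpy(),
    }, index=pd.Index(quant.columns, name="sample"))
    return CountMatrix(counts=quant.astype(int), samples=samples)


def count_by_region(reads: pd.DataFrame, ann: TranscriptomeAnnotation,
                    assigned: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-transcript 5'UTR/CDS/3'UTR read counts (mRNA assignments only).

    Region counts sum to the transcript's mRNA read count for each sample.
    """
    if assigned is None:
        assigned = assign_reads(reads, ann)
    m = assigned[assigned["rna_class"] == "mRNA"].copy()
    if m.empty:
        return pd.DataFrame(columns=["tx", "sample", "utr5", "cds", "utr3"])
    u5 = m["tx"].map(lambda t: ann[t].utr5_len).to_numpy()
    cd = m["tx"].map(lambda t: ann[t].cds_len).to_numpy()
    pos = m["mature_pos"].to_numpy()
    m["region"] = np.select([pos < u5, pos < u5 + cd],
                            ["utr5", "cds"], default="utr3")
    out = (m.groupby(["tx", "sample", "region"]).size()
           .unstack("region", fill_value=0)
           .reindex(columns=["utr5", "cds", "utr3"], fill_value=0)
           .reset_index())
    out.columns.name = None
    return out


def rpm_normalize(cm: CountMatrix,
                  library_sizes: Optional[pd.Series] = None) -> CountMatrix:
    """Attach RPM values; raw counts are preserved.

    ``library_sizes`` may override the stored (transcriptome-assigned)
    denominators, e.g. with all-genome-mapped totals.
    """
    libs = cm.library_sizes if library_sizes is None else library_sizes
    libs = libs.reindex(cm.counts.columns)
    if (libs <= 0).any() or libs.isna().any():
        bad = list(libs.index[(libs <= 0) | libs.isna()])
        raise AssignmentError(f"zero/missing library size for: {bad}")
    rpm = cm.counts.div(libs, axis=1) * 1e6
    return replace(cm, rpm=rpm)
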