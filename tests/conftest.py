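"""Shared fixtures: toy transcripts built by hand and a small seeded
simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cracmap import assign
from cracmap.annotation import (GenomeInterval, TranscriptModel,
                                TranscriptomeAnnotation)
from cracmap.synthetic import (SimulationConfig, simulate_crac_reads,
                               simulate_quant_tables, simulate_transcriptome)


def make_transcript(tid="tx1", chrom="chr1", strand="+",
                    exons=None, rna_class="mRNA",
                    utr5=100, cds=900, utr3=300, gene=None):
    if exons is None:
        length = utr5 + cds + utr3 if rna_class == "mRNA" else 1300
        exons = ((100, 100 + length),)
    ivs = [GenomeInterval(chrom, s, e, strand) for s, e in exons]
    if strand == "-":
        ivs = sorted(ivs, key=lambda e: e.start, reverse=True)
    else:
        ivs = sorted(ivs, key=lambda e: e.start)
    kw = {}
    if rna_class == "mRNA":
        kw = dict(utr5_len=utr5, cds_len=cds, utr3_len=utr3)
    return TranscriptModel(id=tid, gene=gene or tid.upper(),
                           rna_class=rna_class, exons=tuple(ivs), **kw)


def make_annotation(*transcripts, genome_lengths=None):
    if genome_lengths is None:
        genome_lengths = {}
        for t in transcripts:
            genome_lengths[t.chrom] = max(genome_lengths.get(t.chrom, 0),
                                          t.span[1] + 100)
    ann = TranscriptomeAnnotation(genome_lengths=dict(genome_lengths))
    for t in transcripts:
        ann.add(t)
    return ann


def make_reads(rows, sample="s1", role="crac_tagged", bio=1, tech=1):
    """rows: iterable of (chrom, start, end, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["sample"] = sample
    df["role"] = role
    df["bio_rep"] = bio
    df["tech_rep"] = tech
    df["unique"] = True
    return df


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_mrna=80,
        n_ncrna={"rRNA": 2, "tRNA": 10, "snRNA": 2, "snoRNA": 5, "other": 3},
        reads_per_sample=40_000,
        n_true_targets=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    genome, ann, truth = simulate_transcriptome(small_cfg)
    reads = simulate_crac_reads(ann, truth, small_cfg)
    assigned = assign.assign_reads(reads, ann)
    cm = assign.count_per_transcript(reads, ann, assigned=assigned)
    quant = simulate_quant_tables(truth, small_cfg)
    roles = {c: ("rnaseq" if c.startswith("rnaseq") else "riboseq")
             for c in quant.columns}
    cm = cm.merged_with(assign.count_matrix_from_quant(quant, roles))
    cm = assign.rpm_normalize(cm)
    return {"cfg": small_cfg, "genome": genome, "ann": ann, "truth": truth,
            "reads": reads, "assigned": assigned, "cm": cm, "quant": quant}
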