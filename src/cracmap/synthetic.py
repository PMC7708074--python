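"""Seeded generator of a toy genome, annotation, CRAC read alignments and
RNA-seq/Ribo-seq count tables, with ground truth for recovery tests.

The generator emulates the statistical structure a CRAC experiment on an
abundant 3'UTR-binding protein produces:

* log-normal transcript abundance;
* an mRNA-dominated class composition for the tagged sample (by default the
  protein shows no class-level preference beyond abundance: non-coding RNA
  abundances are rescaled so that abundance shares match the configured read
  shares, which keeps CRAC and RNA-seq libraries compositionally comparable);
* strong 3'UTR-biased crosslink placement within bound mRNAs
  (default region weights 0.05/0.20/0.75 for 5'UTR/CDS/3'UTR);
* a subset of "true target" mRNAs with multiplicatively enriched binding,
  drawn from the upper half of the mRNA abundance distribution;
* two biological x two technical tagged replicates, where technical
  replicates share the biological per-transcript noise factor;
* a partially uniform untagged-control background.

Replicate noise calibration: per-transcript biological noise is a log-normal
factor with ``replicate_noise_sd`` (natural-log sd). The default 0.49 is set
analytically so that the rank correlation between tagged biological
replicates lands near 0.82: with abundance sdlog 1.0 and binding-propensity
sdlog 0.5 the cross-transcript signal variance is s^2 = 1.25 (nat log), a
Spearman of 0.82 corresponds to a Pearson of ~0.835 on the log scale for
bivariate normal data, and solving s^2/(s^2 + sd_b^2 + sd_t^2) = 0.835 with
technical sd 0.10 gives sd_b ~ 0.49.

All transcripts are single-exon; spliced-coordinate handling is exercised by
the annotation layer's own tests, and single-exon placement keeps the
read-midpoint assignment rule exact.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import (AnnotationError, GenomeInterval, TranscriptModel,
                         TranscriptomeAnnotation)
from .io import READ_COLUMNS

_ROLE_STREAM = {"tagged": 11, "control": 12}
_ASSAY_STREAM = {"rnaseq": 21, "riboseq": 22}
_BIO_NOISE_STREAM = 101
_TECH_NOISE_STREAM = 102


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_n_ncrna() -> dict[str, int]:
    return {"rRNA": 6, "tRNA": 60, "snRNA": 6, "snoRNA": 40, "other": 20}


def _default_ncrna_lengths() -> dict[str, tuple[int, int]]:
    return {"rRNA": (120, 3400), "tRNA": (70, 95), "snRNA": (100, 1200),
            "snoRNA": (80, 200), "other": (200, 2000)}


def _default_class_shares() -> dict[str, float]:
    return {"mRNA": 0.60, "rRNA": 0.25, "tRNA": 0.05,
            "snoRNA": 0.04, "snRNA": 0.02, "other": 0.04}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_mrna: int = 2000
    n_ncrna: dict[str, int] = field(default_factory=_default_n_ncrna)
    utr5_range: tuple[int, int] = (30, 250)
    cds_range: tuple[int, int] = (300, 2400)
    utr3_range: tuple[int, int] = (60, 400)
    ncrna_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=_default_ncrna_lengths)
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.0
    propensity_sdlog: float = 0.5
    class_read_shares: dict[str, float] = field(default_factory=_default_class_shares)
    region_weights: tuple[float, float, float] = (0.05, 0.20, 0.75)
    n_true_targets: int = 160
    target_enrichment: tuple[float, float] = (2.5, 4.0)
    replicate_noise_sd: float = 0.49
    technical_noise_sd: float = 0.10
    control_background: float = 0.30
    reads_per_sample: int = 1_000_000
    read_length: int = 30
    n_bio_replicates: int = 2
    n_tech_replicates: int = 2
    rnaseq_replicates: int = 2
    riboseq_replicates: int = 2
    te_sdlog: float = 0.35
    n_chromosomes: int = 4
    intergenic_spacing: int = 200
    edge_margin: int = 100
    max_chrom_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        share_sum = sum(self.class_read_shares.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise ConfigError(f"class_read_shares sum to {share_sum}, not 1")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ConfigError("region_weights must sum to 1")
        if any(w < 0 for w in self.region_weights):
            raise ConfigError("region_weights must be non-negative")
        if self.reads_per_sample <= 0:
            raise ConfigError("reads_per_sample must be > 0")
        lo, hi = self.target_enrichment
        if not (1.0 < lo <= hi):
            raise ConfigError("target enrichment factors must be > 1")
        if not 0.0 <= self.control_background <= 1.0:
            raise ConfigError("control_background must be in [0, 1]")
        if self.read_length <= 0:
            raise ConfigError("read_length must be > 0")
        if self.edge_margin < self.read_length:
            raise ConfigError("edge_margin must cover at least one read length")

    def to_yaml(self, path: str | os.PathLike) -> None:
        import yaml

        d = dataclasses.asdict(self)
        for k in ("utr5_range", "cds_range", "utr3_range",
                  "target_enrichment", "region_weights"):
            d[k] = list(d[k])
        d["ncrna_length_ranges"] = {k: list(v)
                                    for k, v in d["ncrna_length_ranges"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("utr5_range", "cds_range", "utr3_range",
                  "target_enrichment", "region_weights"):
            if k in d:
                d[k] = tuple(d[k])
        if "ncrna_length_ranges" in d:
            d["ncrna_length_ranges"] = {k: tuple(v)
                                        for k, v in d["ncrna_length_ranges"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-transcript generative parameters, written alongside outputs."""

    abundance: pd.Series          # relative abundance, sums to 1
    propensity: pd.Series         # binding propensity (1.0 for non-mRNA)
    target_enrichment: pd.Series  # indexed by true-target ids only
    te_factor: pd.Series          # ribosome-profiling translation efficiency
    region_weights: tuple[float, float, float]

    @property
    def target_ids(self) -> list[str]:
        return list(self.target_enrichment.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "abundance": self.abundance,
            "propensity": self.propensity,
            "te_factor": self.te_factor,
        })
        df["is_target"] = df.index.isin(self.target_enrichment.index)
        df["enrichment"] = self.target_enrichment.reindex(df.index).fillna(1.0)
        return df.rename_axis("transcript_id")

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_transcriptome(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], TranscriptomeAnnotation, GroundTruth]:
    """Build a toy genome, its annotation and the generative ground truth.

    Deterministic for a fixed ``cfg.seed``. Transcripts are packed left to
    right on ``n_chromosomes`` chromosomes with fixed intergenic spacing;
    chromosomes are sized to fit unless ``max_chrom_length`` caps them.
    """
    rng = np.random.default_rng(cfg.seed)

    ids: list[str] = []
    classes: list[str] = []
    genes: list[str] = []
    lengths: list[int] = []
    regions: list[tuple[int, int, int]] = []

    for i in range(cfg.n_mrna):
        u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1)) // 3 * 3
        u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        ids.append(f"mRNA_{i + 1:05d}")
        genes.append(f"GENE{i + 1:05d}")
        classes.append("mRNA")
        lengths.append(u5 + cds + u3)
        regions.append((u5, cds, u3))
    for cls, n in cfg.n_ncrna.items():
        lo, hi = cfg.ncrna_length_ranges[cls]
        for i in range(n):
            ids.append(f"{cls}_{i + 1:03d}")
            genes.append(f"{cls.upper()}{i + 1:03d}")
            classes.append(cls)
            lengths.append(int(rng.integers(lo, hi + 1)))
            regions.append((0, 0, 0))

    n_all = len(ids)
    if n_all == 0:
        raise ConfigError("no transcripts configured")
    strands = np.where(rng.random(n_all) < 0.5, "+", "-")

    # sequential packing, round-robin over chromosomes
    cursors = [cfg.edge_margin] * cfg.n_chromosomes
    ann = TranscriptomeAnnotation(genome_lengths={})
    placements = []
    for i in range(n_all):
        c = i % cfg.n_chromosomes
        start = cursors[c]
        end = start + lengths[i]
        cursors[c] = end + cfg.intergenic_spacing
        if cfg.max_chrom_length is not None and end + cfg.edge_margin > cfg.max_chrom_length:
            raise ConfigError(
                f"chromosome budget exceeded packing {ids[i]} "
                f"(need {end + cfg.edge_margin} > {cfg.max_chrom_length})"
            )
        placements.append((f"chr{c + 1}", start, end))

    genome: dict[str, str] = {}
    for c in range(cfg.n_chromosomes):
        genome[f"chr{c + 1}"] = _random_sequence(rng, cursors[c] + cfg.edge_margin)
    ann.genome_lengths = {k: len(v) for k, v in genome.items()}

    for i in range(n_all):
        chrom, s, e = placements[i]
        u5, cds, u3 = regions[i]
        ann.add(TranscriptModel(
            id=ids[i], gene=genes[i], rna_class=classes[i],
            exons=(GenomeInterval(chrom, s, e, str(strands[i])),),
            utr5_len=u5, cds_len=cds, utr3_len=u3,
        ))

    # abundance: log-normal, then per-class rescaling so that abundance
    # shares match class_read_shares for the classes actually present
    raw = rng.lognormal(cfg.abundance_meanlog, cfg.abundance_sdlog, n_all)
    abundance = pd.Series(raw, index=ids)
    cls_series = pd.Series(classes, index=ids)
    present = [c for c in cfg.class_read_shares if (cls_series == c).any()]
    for c in present:
        mask = cls_series == c
        abundance[mask] *= cfg.class_read_shares[c] / abundance[mask].sum()
    abundance /= abundance.sum()

    propensity = pd.Series(1.0, index=ids)
    m_mask = cls_series == "mRNA"
    propensity[m_mask] = rng.lognormal(0.0, cfg.propensity_sdlog, int(m_mask.sum()))

    te_factor = pd.Series(rng.lognormal(0.0, cfg.te_sdlog, n_all), index=ids)

    # true targets: abundant mRNAs (upper half of the mRNA abundance range)
    if cfg.n_true_targets > 0:
        m_ab = abundance[m_mask]
        candidates = m_ab[m_ab >= m_ab.median()].index.to_numpy()
        if len(candidates) < cfg.n_true_targets:
            raise ConfigError(
                f"cannot draw {cfg.n_true_targets} targets from "
                f"{len(candidates)} abundant mRNAs"
            )
        chosen = rng.choice(candidates, size=cfg.n_true_targets, replace=False)
        chosen = sorted(str(x) for x in chosen)
        factors = rng.uniform(*cfg.target_enrichment, size=len(chosen))
        enrichment = pd.Series(factors, index=chosen)
    else:
        enrichment = pd.Series(dtype=float)

    truth = GroundTruth(abundance=abundance, propensity=propensity,
                        target_enrichment=enrichment, te_factor=te_factor,
                        region_weights=cfg.region_weights)
    return genome, ann, truth


def _annotation_arrays(ann: TranscriptomeAnnotation) -> pd.DataFrame:
    rows = []
    for t in ann:
        s, e = t.span
        rows.append((t.id, t.rna_class, t.chrom, s, e, t.strand,
                     t.utr5_len, t.cds_len, t.utr3_len, t.mature_length,
                     len(t.exons)))
    return pd.DataFrame(rows, columns=[
        "id", "rna_class", "chrom", "start", "end", "strand",
        "utr5_len", "cds_len", "utr3_len", "mature_length", "n_exons",
    ]).set_index("id")


def _replicate_noise(cfg: SimulationConfig, index: pd.Index,
                     bio_rep: int, tech_rep: int) -> np.ndarray:
    bio_rng = np.random.default_rng([cfg.seed, _BIO_NOISE_STREAM, bio_rep])
    tech_rng = np.random.default_rng(
        [cfg.seed, _TECH_NOISE_STREAM, bio_rep, tech_rep])
    bio = bio_rng.lognormal(0.0, cfg.replicate_noise_sd, len(index))
    tech = tech_rng.lognormal(0.0, cfg.technical_noise_sd, len(index))
    return bio * tech


def simulate_crac_sample(
    ann: TranscriptomeAnnotation,
    truth: GroundTruth,
    cfg: SimulationConfig,
    role: str,
    bio_rep: int = 1,
    tech_rep: int = 1,
) -> pd.DataFrame:
    """Generate one CRAC library as a read table.

    Tagged libraries place each read by: class ~ class_read_shares;
    transcript ~ abundance x propensity (x enrichment for true targets)
    x replicate noise; region ~ region_weights (mRNA) and position uniform
    within the region. The control ignores propensity/enrichment/noise and
    scatters a ``control_background`` fraction uniformly over the genome.
    """
    if role not in ("tagged", "control"):
        raise ConfigError(f"unknown sample role {role!r}")
    rng = np.random.default_rng(
        [cfg.seed, _ROLE_STREAM[role], bio_rep, tech_rep])
    tx = _annotation_arrays(ann)
    if (tx["n_exons"] > 1).any():
        raise ConfigError("the read simulator requires single-exon transcripts")
    n_reads = cfg.reads_per_sample

    if role == "tagged":
        weights = (truth.abundance * truth.propensity).copy()
        enr = truth.target_enrichment.reindex(weights.index).fillna(1.0)
        weights *= enr
        weights *= _replicate_noise(cfg, weights.index, bio_rep, tech_rep)
        n_background = 0
        sample = f"crac_b{bio_rep}t{tech_rep}"
        sample_role = "crac_tagged"
    else:
        weights = truth.abundance.copy()
        n_background = int(rng.binomial(n_reads, cfg.control_background))
        sample = f"control_b{bio_rep}t{tech_rep}"
        sample_role = "crac_control"

    n_transcript_reads = n_reads - n_background
    tx = tx.loc[weights.index]
    cls = tx["rna_class"]

    # class, then transcript within class
    shares = {c: s for c, s in cfg.class_read_shares.items() if (cls == c).any()}
    share_vec = np.array(list(shares.values()), dtype=float)
    share_vec /= share_vec.sum()
    n_per_class = rng.multinomial(n_transcript_reads, share_vec)

    counts = np.zeros(len(tx), dtype=np.int64)
    for (c, _), n_c in zip(shares.items(), n_per_class):
        mask = (cls == c).to_numpy()
        w = weights.to_numpy()[mask]
        counts[mask] = rng.multinomial(int(n_c), w / w.sum())

    rep = np.repeat(np.arange(len(tx)), counts)
    u5 = tx["utr5_len"].to_numpy()[rep]
    cd = tx["cds_len"].to_numpy()[rep]
    u3 = tx["utr3_len"].to_numpy()[rep]
    mat_len = tx["mature_length"].to_numpy()[rep]
    is_mrna = (cls == "mRNA").to_numpy()[rep]

    # mature midpoint: region ~ region_weights for mRNA, uniform otherwise
    w5, wc, w3 = cfg.region_weights
    u = rng.random(len(rep))
    region = np.searchsorted(np.cumsum([w5, wc]), u)  # 0/1/2
    r_start = np.select([region == 0, region == 1], [0, u5], default=u5 + cd)
    r_len = np.select([region == 0, region == 1], [u5, cd], default=u3)
    pos_in = np.floor(rng.random(len(rep)) * r_len).astype(np.int64)
    m = np.where(is_mrna, r_start + pos_in,
                 np.floor(rng.random(len(rep)) * mat_len).astype(np.int64))

    strand = tx["strand"].to_numpy()[rep]
    g_start = tx["start"].to_numpy()[rep]
    g_end = tx["end"].to_numpy()[rep]
    g_mid = np.where(strand == "+", g_start + m, g_end - 1 - m)
    starts = g_mid - (cfg.read_length - 1) // 2
    chrom = tx["chrom"].to_numpy()[rep]

    frames = [pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + cfg.read_length,
        "strand": strand,
    })]

    if n_background:
        chroms = sorted(ann.genome_lengths)
        lens = np.array([ann.genome_lengths[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_background, p=lens / lens.sum())
        bstart = np.floor(
            rng.random(n_background) * (lens[ci] - cfg.read_length)
        ).astype(np.int64)
        frames.append(pd.DataFrame({
            "chrom": np.array(chroms)[ci], "start": bstart,
            "end": bstart + cfg.read_length,
            "strand": np.where(rng.random(n_background) < 0.5, "+", "-"),
        }))

    reads = pd.concat(frames, ignore_index=True)
    reads["sample"] = sample
    reads["role"] = sample_role
    reads["bio_rep"] = bio_rep
    reads["tech_rep"] = tech_rep
    reads["unique"] = True
    return reads[READ_COLUMNS]


def simulate_crac_reads(ann: TranscriptomeAnnotation, truth: GroundTruth,
                        cfg: SimulationConfig,
                        include_control: bool = True) -> pd.DataFrame:
    """All tagged replicates (n_bio x n_tech) plus one control, concatenated."""
    frames = [
        simulate_crac_sample(ann, truth, cfg, "tagged", b, t)
        for b in range(1, cfg.n_bio_replicates + 1)
        for t in range(1, cfg.n_tech_replicates + 1)
    ]
    if include_control:
        frames.append(simulate_crac_sample(ann, truth, cfg, "control", 1, 1))
    return pd.concat(frames, ignore_index=True)


def simulate_quant_counts(truth: GroundTruth, cfg: SimulationConfig,
                          assay: str, replicate_id: int = 1) -> pd.Series:
    """One RNA-seq or Ribo-seq library as a transcript count vector.

    Counts are multinomial over all transcripts with probabilities
    proportional to abundance (times the per-transcript translation
    efficiency factor for Ribo-seq); replicates differ only by the
    multinomial draw.
    """
    if assay not in _ASSAY_STREAM:
        raise ConfigError(f"unknown assay {assay!r}")
    rng = np.random.default_rng([cfg.seed, _ASSAY_STREAM[assay], replicate_id])
    p = truth.abundance.copy()
    if assay == "riboseq":
        p = p * truth.te_factor
    p = p / p.sum()
    counts = rng.multinomial(cfg.reads_per_sample, p.to_numpy())
    return pd.Series(counts, index=p.index, name=f"{assay}_{replicate_id}")


def simulate_quant_tables(truth: GroundTruth,
                          cfg: SimulationConfig) -> pd.DataFrame:
    """All RNA-seq and Ribo-seq replicates, transcripts x samples."""
    cols = [simulate_quant_counts(truth, cfg, "rnaseq", r)
            for r in range(1, cfg.rnaseq_replicates + 1)]
    cols += [simulate_quant_counts(truth, cfg, "riboseq", r)
             for r in range(1, cfg.riboseq_replicates + 1)]
    return pd.concat(cols, axis=1)
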