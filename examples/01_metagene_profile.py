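"""Simulate a small CRAC experiment and profile where the protein binds.

Builds a toy transcriptome, generates tagged CRAC libraries with a strong
3'UTR crosslink bias, and computes the RNA-class composition, the 120-bin
metagene profile and per-transcript region fractions.
"""

from cracmap import assign, metagene
from cracmap.pipeline import run_experiment
from cracmap.synthetic import SimulationConfig

cfg = SimulationConfig(
    n_mrna=300,
    n_ncrna={"rRNA": 2, "tRNA": 20, "snRNA": 2, "snoRNA": 8, "other": 4},
    reads_per_sample=200_000,
    n_true_targets=24,
    seed=42,
)
exp = run_experiment(cfg)

shares = assign.classify_reads(
    exp.reads[exp.reads["sample"] == "crac_b1t1"], exp.ann)
print("RNA-class composition of one tagged library:")
for row in shares.itertuples(index=False):
    print(f"  {row.rna_class:<11} {row.fraction:6.1%}")

profiles, skipped = metagene.profiles_from_assignment(exp.tagged_assigned, exp.ann)
agg, n = metagene.aggregate_metagene(profiles, exp.cm, min_rpm=100)
print(f"\nAggregate metagene over n={n} mRNAs with >100 RPM "
      f"(each transcript's reads normalized to 1):")
print(f"  mass in 5'UTR bins (0-9):     {agg[:10].sum():.3f}")
print(f"  mass in CDS bins (10-109):    {agg[10:110].sum():.3f}")
print(f"  mass in 3'UTR bins (110-119): {agg[110:].sum():.3f}")

rc = assign.count_by_region(exp.reads, exp.ann, assigned=exp.tagged_assigned)
pooled = rc.groupby("tx")[["utr5", "cds", "utr3"]].sum().reset_index()
fr = metagene.region_fraction(pooled)
box = metagene.boxplot_summary(fr["f3"])
print(f"\nPer-transcript 3'UTR fraction: median {box.median:.3f} "
      f"(IQR {box.q1:.3f}-{box.q3:.3f}, {len(box.outliers)} outliers)")
print("A median near 0.75 means about three quarters of this protein's "
      "binding falls in 3'UTRs, matching the configured crosslink weights.")
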