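"""Call high-confidence protein targets against an RNA-seq background.

Spikes a set of truly enriched mRNAs into the simulation, applies the three
filters (>128 RPM, >1.5-fold CRAC/RNA-seq ratio, p < 0.01) and measures how
well the spiked set is recovered.
"""

from cracmap import targets
from cracmap.pipeline import run_experiment, spike_recovery
from cracmap.synthetic import SimulationConfig

cfg = SimulationConfig(
    n_mrna=500,
    n_ncrna={"rRNA": 2, "tRNA": 20, "snRNA": 2, "snoRNA": 8, "other": 4},
    reads_per_sample=400_000,
    n_true_targets=40,
    target_enrichment=(2.5, 4.0),
    propensity_sdlog=0.0,   # spiked enrichment is the only binding signal
    seed=7,
)
exp = run_experiment(cfg, include_control=False, include_riboseq=False)

calls = targets.call_targets(exp.cm, ann=exp.ann)  # moderated test, defaults
hc = calls[calls["high_confidence"]]
print(f"{len(hc)} of {cfg.n_mrna} mRNAs pass all three filters "
      f"(RPM > 128, ratio > 1.5, p < 0.01)\n")
print("Top calls (smallest p first):")
cols = ["transcript_id", "crac_rpm", "rnaseq_rpm", "ratio", "p_value"]
print(hc[cols].head(8).to_string(index=False,
                                 float_format=lambda v: f"{v:.4g}"))

rec = spike_recovery(exp, calls)
print(f"\nAgainst the {rec['n_true']} spiked targets: "
      f"precision {rec['precision']:.2f}, recall {rec['recall']:.2f}.")
print("Precision near 1 means essentially every call is a genuinely "
      "enriched transcript; recall is limited by replicate noise relative "
      "to the spiked effect sizes.")

# a raw-coverage track for the strongest call, as a genome browser would show
best = hc["transcript_id"].iloc[0]
runs = targets.export_track(exp.reads, "crac_b1t1", best, ann=exp.ann)
print(f"\nCoverage track for {best} in replicate b1t1: "
      f"{len(runs)} bedGraph runs, maximum depth {runs['depth'].max()}")
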