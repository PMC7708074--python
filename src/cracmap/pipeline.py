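"""One-call composition of the simulation and analysis stages.

Convenience layer for scripted analyses and tests: simulate an experiment,
assign reads, and assemble the joint CRAC + RNA-seq/Ribo-seq count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import assign, synthetic
from .annotation import TranscriptomeAnnotation
from .assign import CountMatrix
from .synthetic import GroundTruth, SimulationConfig


@dataclass
class Experiment:
    """Everything one simulated CRAC study produces."""

    cfg: SimulationConfig
    ann: TranscriptomeAnnotation
    truth: GroundTruth
    reads: pd.DataFrame
    assigned: pd.DataFrame
    cm: CountMatrix

    @property
    def tagged_assigned(self) -> pd.DataFrame:
        return self.assigned[self.assigned["role"] == "crac_tagged"]


def run_experiment(cfg: SimulationConfig,
                   include_control: bool = True,
                   include_riboseq: bool = True) -> Experiment:
    """Simulate, assign and count one full experiment.

    The count matrix holds all tagged CRAC replicates (plus the untagged
    control if requested) with transcriptome-assigned library sizes, and the
    RNA-seq (and optionally Ribo-seq) multinomial count tables, RPM-normalized.
    """
    _, ann, truth = synthetic.simulate_transcriptome(cfg)
    reads = synthetic.simulate_crac_reads(ann, truth, cfg,
                                          include_control=include_control)
    assigned = assign.assign_reads(reads, ann)
    cm = assign.count_per_transcript(reads, ann, assigned=assigned)
    cols = [synthetic.simulate_quant_counts(truth, cfg, "rnaseq", r)
            for r in range(1, cfg.rnaseq_replicates + 1)]
    if include_riboseq:
        cols += [synthetic.simulate_quant_counts(truth, cfg, "riboseq", r)
                 for r in range(1, cfg.riboseq_replicates + 1)]
    quant = pd.concat(cols, axis=1)
    roles = {c: ("rnaseq" if c.startswith("rnaseq") else "riboseq")
             for c in quant.columns}
    cm = cm.merged_with(assign.count_matrix_from_quant(quant, roles))
    cm = assign.rpm_normalize(cm)
    return Experiment(cfg=cfg, ann=ann, truth=truth, reads=reads,
                      assigned=assigned, cm=cm)


def spike_recovery(experiment: Experiment, calls: pd.DataFrame) -> dict:
    """Precision/recall of high-confidence calls against the spiked targets."""
    called = set(calls.loc[calls["high_confidence"], "transcript_id"])
    true = set(experiment.truth.target_ids)
    tp = len(called & true)
    return {
        "n_called": len(called),
        "n_true": len(true),
        "tp": tp,
        "precision": tp / len(called) if called else float("nan"),
        "recall": tp / len(true) if true else float("nan"),
    }
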