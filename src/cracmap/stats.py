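"""Replicate and cross-assay correlation, and sample-level PCA.

Values are log2(RPM + pseudocount) over the transcripts detected (nonzero
raw count) in at least one sample; the log transform stabilizes the heavy
right tail of RPM-scale data and the pseudocount keeps zeros finite. PCA is
run on centered features without unit-variance scaling, since every feature
is already on the common log-RPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assign import CountMatrix


class StatsError(ValueError):
    pass


@dataclass
class SampleMatrix:
    """Log-transformed RPM values, transcripts x samples."""

    values: pd.DataFrame
    pseudocount: float = 1.0

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix, pseudocount: float = 1.0,
                          transcript_filter: str = "nonzero_any") -> "SampleMatrix":
        if cm.rpm is None:
            raise StatsError("CountMatrix has no RPM values; run rpm_normalize")
        rpm = cm.rpm
        if transcript_filter == "nonzero_any":
            rpm = rpm[(cm.counts > 0).any(axis=1)]
        elif transcript_filter != "all":
            raise StatsError(f"unknown transcript_filter {transcript_filter!r}")
        return cls(values=np.log2(rpm + pseudocount), pseudocount=pseudocount)


def correlate(sm: SampleMatrix, a: str, b: str, method: str = "spearman") -> float:
    """Correlation coefficient between two samples over all transcripts.

    Pearson acts on the transformed values; Spearman is Pearson on mid-ranks
    (ties get average ranks).
    """
    x = sm.values[a].to_numpy()
    y = sm.values[b].to_numpy()
    if len(x) < 3:
        raise StatsError("need at least 3 transcripts")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance: correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise StatsError(f"unknown method {method!r}")


def correlation_matrix(sm: SampleMatrix, method: str = "spearman") -> pd.DataFrame:
    cols = list(sm.values.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = correlate(sm, a, b, method)
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class PcaResult:
    """Sample coordinates in PC space and % variance explained."""

    coordinates: pd.DataFrame       # samples x components
    variance_explained: np.ndarray  # percent per component, non-increasing

    def distance(self, a: str, b: str, n_components: int = 2) -> float:
        d = (self.coordinates.loc[a].to_numpy()[:n_components]
             - self.coordinates.loc[b].to_numpy()[:n_components])
        return float(np.sqrt((d ** 2).sum()))


def pca_samples(sm: SampleMatrix) -> PcaResult:
    """PCA with samples as observations and transcripts as features.

    Components come from the SVD of the feature-centered matrix; each
    component's sign is fixed so that its largest-magnitude transcript
    loading is positive, making the output deterministic.
    """
    X = sm.values.to_numpy().T  # samples x transcripts
    if X.shape[0] < 2:
        raise StatsError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U * S
    total = (S ** 2).sum()
    var_expl = (S ** 2) / total * 100.0 if total > 0 else np.zeros_like(S)
    names = [f"PC{k + 1}" for k in range(len(S))]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=sm.values.columns, columns=names),
        variance_explained=var_expl,
    )


def plot_pca(res: PcaResult, roles: pd.Series, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for role in roles.unique():
        idx = roles.index[roles == role]
        sub = res.coordinates.loc[idx]
        ax.scatter(sub["PC1"], sub["PC2"], label=role, s=40)
    ax.set_xlabel(f"PC1 ({res.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({res.variance_explained[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
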