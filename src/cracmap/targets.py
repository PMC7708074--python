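"""High-confidence target calling and single-locus coverage tracks.

A transcript is a high-confidence target when all three filters pass
(strict inequalities): mean CRAC RPM above ``rpm_threshold`` (default 128),
CRAC/RNA-seq enrichment ratio above ``ratio_threshold`` (default 1.5), and
enrichment p-value below ``p_threshold`` (default 0.01).

Two enrichment tests are provided:

* ``welch`` — a one-sided Welch t-test on log2(RPM + 0.5) treating every
  CRAC library (including technical replicates) as an independent sample.
* ``moderated`` (default) — technical replicates are first averaged within
  each biological replicate, since they share the biological noise factor
  and treating them as independent understates the standard error. The
  per-transcript group variances (which have very few degrees of freedom)
  are then shrunk toward a mean-expression-dependent trend with an
  empirical-Bayes scaled-inverse-chi-square prior fitted across
  transcripts, and a one-sided Welch-type t-statistic is referred to a
  t distribution with moderated Welch-Satterthwaite degrees of freedom.
  This is the standard small-replicate remedy in sequencing analysis and
  keeps the test calibrated under the null while restoring power.

Raw p-values drive the filter; a Benjamini-Hochberg column is emitted for
information only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .annotation import TranscriptomeAnnotation
from .assign import CountMatrix, rpm_normalize

TINY_P = float(np.nextafter(0, 1))


class TargetError(ValueError):
    pass


@dataclass(frozen=True)
class CallingThresholds:
    rpm_threshold: float = 128.0
    ratio_threshold: float = 1.5
    p_threshold: float = 0.01

    def __post_init__(self) -> None:
        if min(self.rpm_threshold, self.ratio_threshold, self.p_threshold) <= 0:
            raise TargetError("thresholds must be positive")


def enrichment_pvalue(crac_rpms: Sequence[float],
                      rnaseq_rpms: Sequence[float],
                      pseudocount: float = 0.5) -> float:
    """One-sided Welch t-test p-value for CRAC > RNA-seq on log2(rpm + pc).

    Degenerate inputs (both groups with zero variance) return 1 when the
    means are equal or the CRAC mean is lower, and the smallest positive
    float when the CRAC mean is higher.
    """
    a = np.log2(np.asarray(crac_rpms, dtype=float) + pseudocount)
    b = np.log2(np.asarray(rnaseq_rpms, dtype=float) + pseudocount)
    if len(a) < 2 or len(b) < 2:
        raise TargetError("each group needs at least 2 replicate values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        return 1.0 if diff <= 0 else TINY_P
    se = np.sqrt(va / len(a) + vb / len(b))
    t = diff / se
    df = se ** 4 / ((va / len(a)) ** 2 / (len(a) - 1)
                    + (vb / len(b)) ** 2 / (len(b) - 1))
    return float(sps.t.sf(t, df))


def _welch_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise one-sided Welch p-values (A > B) with degenerate handling."""
    res = sps.ttest_ind(A, B, axis=1, equal_var=False, alternative="greater")
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        diff = A.mean(axis=1) - B.mean(axis=1)
        p[bad] = np.where(diff[bad] > 0, TINY_P, 1.0)
    return p


def _fit_variance_prior(s2: np.ndarray, df: int,
                        mean_expr: np.ndarray,
                        window: int = 101) -> tuple[np.ndarray, float]:
    """Trend + prior df for empirical-Bayes variance shrinkage.

    The trend v0 is a running median of the per-transcript variances along
    mean expression (rescaled to be unbiased for the mean of a scaled
    chi-square); the prior degrees of freedom d0 are fitted by matching the
    observed spread of log(s2/v0) to what sampling noise alone (trigamma)
    would produce — the classic moment estimator for a scaled-F model.
    Returns (v0 per transcript, d0; d0=inf when s2 shows no excess spread).
    """
    n = len(s2)
    order = np.argsort(mean_expr, kind="mergesort")
    s2_sorted = pd.Series(s2[order])
    w = max(5, min(window, n if n % 2 else n - 1))
    med = s2_sorted.rolling(w, center=True, min_periods=1).median().to_numpy()
    # median of s2 ~ v * chi2_df/df underestimates the mean level v
    chi2_median_factor = sps.chi2.median(df) / df
    v0 = np.empty(n)
    v0[order] = med / chi2_median_factor
    v0 = np.maximum(v0, 1e-12)

    ok = s2 > 0
    if ok.sum() < 10:
        return v0, np.inf
    z = np.log(s2[ok] / v0[ok])
    excess = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 1e-6:
        return v0, np.inf
    from scipy.optimize import brentq

    # trigamma is monotone decreasing; invert on a wide bracket
    f = lambda d0: special.polygamma(1, d0 / 2.0) - excess
    if f(1e-3) < 0:
        return v0, 1e-3
    d0 = brentq(f, 1e-3, 1e7)
    return v0, float(d0)


def moderated_enrichment_pvalues(
    crac_log: pd.DataFrame,
    rna_log: pd.DataFrame,
    crac_bio_rep: Sequence[int],
) -> pd.Series:
    """Vectorized moderated one-sided test (CRAC > RNA-seq) per transcript."""
    bio = np.asarray(list(crac_bio_rep))
    groups = sorted(set(bio))
    if len(groups) < 2:
        raise TargetError("need at least 2 biological CRAC replicates")
    # collapse technical replicates onto biological means
    bio_means = np.stack(
        [crac_log.to_numpy()[:, bio == g].mean(axis=1) for g in groups], axis=1)
    B = rna_log.to_numpy()
    if B.shape[1] < 2:
        raise TargetError("need at least 2 RNA-seq replicates")

    n1, n2 = bio_means.shape[1], B.shape[1]
    df1, df2 = n1 - 1, n2 - 1
    x1, x2 = bio_means.mean(axis=1), B.mean(axis=1)
    s1 = bio_means.var(axis=1, ddof=1)
    s2 = B.var(axis=1, ddof=1)

    mean_expr = (x1 + x2) / 2
    v01, d01 = _fit_variance_prior(s1, df1, mean_expr)
    v02, d02 = _fit_variance_prior(s2, df2, mean_expr)

    def posterior(s2_obs, v0, d0, df):
        if np.isinf(d0):
            return v0.copy(), 1e7
        return (d0 * v0 + df * s2_obs) / (d0 + df), d0

    s1_post, d01_eff = posterior(s1, v01, d01, df1)
    s2_post, d02_eff = posterior(s2, v02, d02, df2)

    v1, v2 = s1_post / n1, s2_post / n2
    se = np.sqrt(v1 + v2)
    t = (x1 - x2) / se
    df_mod = (v1 + v2) ** 2 / (v1 ** 2 / (d01_eff + df1)
                               + v2 ** 2 / (d02_eff + df2))
    p = sps.t.sf(t, df_mod)
    return pd.Series(p, index=crac_log.index)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return sps.false_discovery_control(np.clip(p, 0, 1), method="bh")


def call_targets(cm: CountMatrix,
                 thresholds: CallingThresholds = CallingThresholds(),
                 ann: Optional[TranscriptomeAnnotation] = None,
                 method: str = "moderated",
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Score every mRNA against the three filters; rows sorted by p then id.

    ``ann`` restricts scoring to mRNAs; without it all transcripts are
    scored. An RNA-seq mean of zero makes the ratio infinite, in which case
    the ratio filter defers to the RPM filter.
    """
    if cm.rpm is None:
        cm = rpm_normalize(cm)
    crac = cm.samples_with_role("crac_tagged")
    rna = cm.samples_with_role("rnaseq")
    if len(crac) < 2 or len(rna) < 2:
        raise TargetError(
            f"need >=2 crac_tagged and >=2 rnaseq samples, have "
            f"{len(crac)} and {len(rna)}"
        )
    rpm = cm.rpm
    if ann is not None:
        mrna_ids = [t.id for t in ann if t.rna_class == "mRNA"]
        rpm = rpm.loc[rpm.index.intersection(mrna_ids)]

    crac_rpm = rpm[crac]
    rna_rpm = rpm[rna]
    mean_crac = crac_rpm.mean(axis=1)
    mean_rna = rna_rpm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_rna > 0, mean_crac / mean_rna, np.inf)
        ratio = np.where((mean_rna == 0) & (mean_crac == 0), np.nan, ratio)

    crac_log = np.log2(crac_rpm + pseudocount)
    rna_log = np.log2(rna_rpm + pseudocount)
    if method == "welch":
        p = _welch_pvalues(crac_log.to_numpy(), rna_log.to_numpy())
    elif method == "moderated":
        bio = cm.samples.loc[crac, "bio_rep"].to_numpy()
        p = moderated_enrichment_pvalues(crac_log, rna_log, bio).to_numpy()
    else:
        raise TargetError(f"unknown test method {method!r}")

    pass_rpm = mean_crac.to_numpy() > thresholds.rpm_threshold
    pass_ratio = np.where(np.isinf(ratio), pass_rpm,
                          ratio > thresholds.ratio_threshold)
    pass_p = p < thresholds.p_threshold

    out = pd.DataFrame({
        "transcript_id": rpm.index,
        "crac_rpm": mean_crac.to_numpy(),
        "rnaseq_rpm": mean_rna.to_numpy(),
        "ratio": ratio,
        "p_value": p,
        "q_value": benjamini_hochberg(p),
        "pass_rpm": pass_rpm,
        "pass_ratio": pass_ratio.astype(bool),
        "pass_p": pass_p,
    })
    out["high_confidence"] = out[["pass_rpm", "pass_ratio", "pass_p"]].all(axis=1)
    return (out.sort_values(["p_value", "transcript_id"], kind="mergesort")
            .reset_index(drop=True))


def export_track(reads: pd.DataFrame, sample: str, locus: str,
                 ann: Optional[TranscriptomeAnnotation] = None) -> pd.DataFrame:
    """Raw per-base coverage of uniquely mapped reads as bedGraph runs.

    ``locus`` is a chromosome name, or a transcript id when ``ann`` is
    given (then only same-strand reads over the transcript's genomic span
    contribute). Each read adds 1 over its whole interval; only nonzero
    runs are returned as (chrom, start, end, depth).
    """
    sel = reads[(reads["sample"] == sample) & reads["unique"]]
    if ann is not None and locus in ann.transcripts:
        t = ann[locus]
        chrom, (lo, hi) = t.chrom, t.span
        sel = sel[(sel["chrom"] == chrom) & (sel["strand"] == t.strand)]
    else:
        if ann is not None and locus not in ann.genome_lengths:
            raise TargetError(f"unknown chromosome or transcript: {locus}")
        chrom = locus
        sel = sel[sel["chrom"] == chrom]
        if sel.empty:
            return pd.DataFrame(columns=["chrom", "start", "end", "depth"])
        lo = int(sel["start"].min())
        hi = int(sel["end"].max())
    sel = sel[(sel["end"] > lo) & (sel["start"] < hi)]
    if sel.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "depth"])
    span = hi - lo
    delta = np.zeros(span + 1, dtype=np.int64)
    starts = np.clip(sel["start"].to_numpy() - lo, 0, span)
    ends = np.clip(sel["end"].to_numpy() - lo, 0, span)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    cov = np.cumsum(delta[:-1])
    change = np.flatnonzero(np.diff(cov)) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [span]])
    depth = cov[run_starts]
    keep = depth > 0
    return pd.DataFrame({
        "chrom": chrom,
        "start": run_starts[keep] + lo,
        "end": run_ends[keep] + lo,
        "depth": depth[keep],
    })
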