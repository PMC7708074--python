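"""120-bin metagene profiling with per-transcript normalization.

Each mRNA's mature axis is rescaled region by region into a fixed number of
bins (10 for the 5'UTR, 100 for the CDS, 10 for the 3'UTR by default) so
that transcripts of different lengths and UTR/CDS proportions become
comparable. All reads mapping to one transcript are normalized to a
unit-sum histogram before averaging, which removes abundance weighting and
yields an unbiased positional binding profile across transcripts.

Transcripts with an empty 5'UTR or 3'UTR are excluded (rescaling an empty
region is undefined) and reported in a skip list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, TranscriptomeAnnotation
from .assign import CountMatrix


class MetageneError(ValueError):
    pass


@dataclass(frozen=True)
class BinScheme:
    """Bins per region; defaults give the 120-bin layout (10/100/10)."""

    n_utr5: int = 10
    n_cds: int = 100
    n_utr3: int = 10

    def __post_init__(self) -> None:
        if min(self.n_utr5, self.n_cds, self.n_utr3) < 1:
            raise MetageneError("every region needs at least one bin")

    @property
    def total(self) -> int:
        return self.n_utr5 + self.n_cds + self.n_utr3


def bin_index(t: TranscriptModel, m: int, scheme: BinScheme = BinScheme()) -> int:
    """Global bin of mature position ``m``.

    Within a region of length L, local bin = min(floor(d * n / L), n - 1)
    where d is the offset into the region; the region blocks are then laid
    out 5'UTR, CDS, 3'UTR.
    """
    if t.has_zero_length_region:
        raise MetageneError(f"{t.id}: zero-length UTR, excluded from binning")
    region = t.region_at(m)  # validates range and mRNA class
    if region == "utr5":
        d, L, n, off = m, t.utr5_len, scheme.n_utr5, 0
    elif region == "cds":
        d, L, n, off = m - t.utr5_len, t.cds_len, scheme.n_cds, scheme.n_utr5
    else:
        d = m - t.utr5_len - t.cds_len
        L, n, off = t.utr3_len, scheme.n_utr3, scheme.n_utr5 + scheme.n_cds
    return off + min(d * n // L, n - 1)


def transcript_profile(t: TranscriptModel, mature_positions: Sequence[int],
                       scheme: BinScheme = BinScheme()) -> np.ndarray:
    """Unit-sum histogram of read midpoints over the bin layout."""
    positions = np.asarray(mature_positions, dtype=np.int64)
    if positions.size == 0:
        raise MetageneError(f"{t.id}: no reads; caller must filter")
    bins = np.array([bin_index(t, int(m), scheme) for m in positions])
    hist = np.bincount(bins, minlength=scheme.total).astype(float)
    return hist / hist.sum()


def profiles_from_assignment(
    assigned: pd.DataFrame,
    ann: TranscriptomeAnnotation,
    scheme: BinScheme = BinScheme(),
    samples: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-transcript unit-sum profiles from an :func:`~cracmap.assign.assign_reads` frame.

    Pools reads across ``samples`` (default: all samples present). Returns
    (profiles matrix indexed by transcript id, skipped transcript ids) where
    skips are mRNAs with reads but an empty UTR.
    """
    df = assigned[assigned["rna_class"] == "mRNA"]
    if samples is not None:
        df = df[df["sample"].isin(set(samples))]
    skipped: list[str] = []
    rows, index = [], []
    for tid, grp in df.groupby("tx", sort=True):
        t = ann[tid]
        if t.has_zero_length_region:
            skipped.append(tid)
            continue
        # vectorized binning over the three regions
        m = grp["mature_pos"].to_numpy(dtype=np.int64)
        u5, cd, u3 = t.utr5_len, t.cds_len, t.utr3_len
        in5 = m < u5
        in3 = m >= u5 + cd
        incds = ~(in5 | in3)
        b = np.empty(len(m), dtype=np.int64)
        b[in5] = np.minimum(m[in5] * scheme.n_utr5 // u5, scheme.n_utr5 - 1)
        b[incds] = scheme.n_utr5 + np.minimum(
            (m[incds] - u5) * scheme.n_cds // cd, scheme.n_cds - 1)
        b[in3] = scheme.n_utr5 + scheme.n_cds + np.minimum(
            (m[in3] - u5 - cd) * scheme.n_utr3 // u3, scheme.n_utr3 - 1)
        hist = np.bincount(b, minlength=scheme.total).astype(float)
        rows.append(hist / hist.sum())
        index.append(tid)
    profiles = pd.DataFrame(np.array(rows) if rows else
                            np.empty((0, scheme.total)),
                            index=pd.Index(index, name="transcript_id"))
    return profiles, skipped


def aggregate_metagene(
    profiles: pd.DataFrame,
    cm: CountMatrix,
    min_rpm: float = 100.0,
    samples: Optional[Iterable[str]] = None,
    filter_mode: str = "rpm",
) -> tuple[np.ndarray, int]:
    """Mean of per-transcript unit-sum profiles over abundance-filtered mRNAs.

    The filter keeps transcripts whose pooled value across ``samples``
    (default: all tagged CRAC samples) exceeds ``min_rpm`` — interpreted as
    RPM of pooled counts (``filter_mode='rpm'``) or as a raw pooled read
    count (``filter_mode='reads'``). Returns (aggregate profile, number of
    contributing transcripts).
    """
    if samples is None:
        samples = cm.samples_with_role("crac_tagged") or list(cm.counts.columns)
    samples = list(samples)
    pooled = cm.counts[samples].sum(axis=1)
    if filter_mode == "rpm":
        lib = cm.library_sizes[samples].sum()
        if lib <= 0:
            raise MetageneError("empty pooled library")
        value = pooled / lib * 1e6
    elif filter_mode == "reads":
        value = pooled
    else:
        raise MetageneError(f"unknown filter_mode {filter_mode!r}")
    keep = profiles.index.intersection(value.index[value > min_rpm])
    if len(keep) == 0:
        raise MetageneError(f"no transcript passes the {filter_mode} filter")
    return profiles.loc[keep].to_numpy().mean(axis=0), len(keep)


def region_fraction(region_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-row (f5, fcds, f3) from utr5/cds/utr3 counts; rows must be nonzero."""
    total = region_counts[["utr5", "cds", "utr3"]].sum(axis=1)
    if (total <= 0).any():
        bad = region_counts.loc[total <= 0, "tx"].tolist() \
            if "tx" in region_counts else list(total.index[total <= 0])
        raise MetageneError(f"zero region-count total for: {bad[:5]}")
    out = region_counts.copy()
    for col, frac in (("utr5", "f5"), ("cds", "fcds"), ("utr3", "f3")):
        out[frac] = out[col] / total
    return out


def region_fraction_summary(fractions: pd.DataFrame) -> pd.DataFrame:
    """Median and mean of per-transcript region fractions (median is the
    headline figure)."""
    rows = []
    for frac in ("f5", "fcds", "f3"):
        rows.append({"region": frac, "median": fractions[frac].median(),
                     "mean": fractions[frac].mean()})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey box parameters: quartiles by linear interpolation, whiskers at
    the most extreme data points within 1.5 IQR of the quartiles."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MetageneError("boxplot of empty data")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    wlo, whi = inside.min(), inside.max()
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxplotSummary(median=float(med), q1=float(q1), q3=float(q3),
                          whisker_low=float(wlo), whisker_high=float(whi),
                          outliers=outliers)


def heatmap_matrix(profiles: pd.DataFrame,
                   ordering: str = "by_3utr_fraction",
                   scheme: BinScheme = BinScheme()) -> pd.DataFrame:
    """Per-transcript profile matrix with a deterministic row order.

    ``by_3utr_fraction`` sorts rows by the profile mass in the 3'UTR bins,
    descending (ties by id); ``by_id`` sorts lexicographically.
    """
    if profiles.empty:
        raise MetageneError("no profiles to order")
    if ordering == "by_id":
        return profiles.sort_index()
    if ordering != "by_3utr_fraction":
        raise MetageneError(f"unknown ordering {ordering!r}")
    f3 = profiles.iloc[:, scheme.n_utr5 + scheme.n_cds:].sum(axis=1)
    order = (f3.rename("f3").rename_axis("transcript_id").reset_index()
             .sort_values(["f3", "transcript_id"], ascending=[False, True],
                          kind="mergesort"))
    return profiles.loc[order["transcript_id"].to_numpy()]


def write_aggregate_tsv(profile: np.ndarray, path) -> None:
    pd.DataFrame({"bin": np.arange(len(profile)), "density": profile}) \
        .to_csv(path, sep="\t", index=False)


def plot_metagene(profile: np.ndarray, path, scheme: BinScheme = BinScheme(),
                  title: str = "metagene") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(np.arange(len(profile)), profile, lw=1.2)
    for x in (scheme.n_utr5, scheme.n_utr5 + scheme.n_cds):
        ax.axvline(x - 0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("bin (5'UTR | CDS | 3'UTR)")
    ax.set_ylabel("mean normalized density")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "per-transcript profiles") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", interpolation="nearest",
                   cmap="viridis")
    ax.set_xlabel("bin")
    ax.set_ylabel("transcript")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
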