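"""Copy-number estimation from binned fragment depth.

Fragment midpoints are counted in fixed-size genomic bins (100 kb by
default); per-haplotype integer copy numbers are recovered by k-means
clustering of bin counts, with the modal cluster anchored at the
baseline copy (1 for a haplotype profile, 2 for bulk). Bulk dosage
change between two samples is summarized as a normalized depth ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_BIN_SIZE = 100_000


@dataclass
class CNVProfile:
    """Per-bin depth and integer copy number for one sample/haplotype."""

    bin_size: int
    haplotype: str  # bulk | paternal | maternal
    df: pd.DataFrame  # chrom, start, count, depth, copy

    def region_bins(self, chrom: str, start: int | None = None, end: int | None = None):
        m = self.df.chrom == chrom
        if start is not None:
            m &= self.df.start >= start
        if end is not None:
            m &= self.df.start < end
        return self.df[m]


def bin_fragment_frequencies(
    fragments: pd.DataFrame,
    bin_size: int,
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Count fragment midpoints per bin; bins tile each chromosome
    half-open, a midpoint exactly on a boundary falls in the next bin."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frames = []
    for chrom, length in chrom_sizes.items():
        n_bins = int(np.ceil(length / bin_size))
        counts = np.zeros(n_bins, dtype=int)
        if not fragments.empty:
            sub = fragments[fragments.chrom == chrom]
            if len(sub):
                mid = ((sub.start.to_numpy() + sub.end.to_numpy()) // 2).astype(int)
                idx = mid // bin_size
                np.add.at(counts, idx[idx < n_bins], 1)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": np.arange(n_bins) * bin_size, "count": counts}
            )
        )
    return pd.concat(frames, ignore_index=True)


def kmeans_copy_number(
    bin_counts: pd.DataFrame,
    k_range=(1, 2, 3, 4),
    seed: int = 0,
    baseline_copy: int = 1,
    haplotype: str = "paternal",
    mask: np.ndarray | None = None,
) -> CNVProfile:
    """Cluster bin counts into copy-number states.

    k is selected over ``k_range`` by silhouette score (k=1 only when all
    counts are identical); the modal cluster (most bins) is assigned the
    baseline copy and other clusters the rounded ratio of their mean to
    the modal mean times the baseline. Masked bins get copy -1 (no call).
    """
    df = bin_counts.copy()
    counts = df["count"].to_numpy(dtype=float)
    if mask is None:
        mask = np.zeros(len(counts), dtype=bool)
    active = ~mask
    vals = counts[active]
    if (vals > 0).sum() < 2 and len(vals) >= 2 and not np.all(vals == vals[0]):
        raise ValueError("need at least 2 non-zero bins to cluster")
    copies = np.full(len(counts), -1, dtype=int)
    if len(vals) == 0:
        pass
    elif np.all(vals == vals[0]):
        copies[active] = baseline_copy if vals[0] > 0 else 0
    else:
        x = vals.reshape(-1, 1)
        best = None
        n_distinct = len(np.unique(vals))
        for k in k_range:
            if k < 2 or k >= len(vals) or k > n_distinct:
                continue
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(x, km.labels_)
            if best is None or score > best[0]:
                best = (score, km)
        if best is None:
            copies[active] = baseline_copy
        else:
            km = best[1]
            labels = km.labels_
            means = km.cluster_centers_.ravel()
            modal = np.bincount(labels).argmax()
            modal_mean = means[modal]
            cluster_copy = {
                c: max(int(round(baseline_copy * means[c] / modal_mean)), 0) if modal_mean > 0 else 0
                for c in range(len(means))
            }
            cluster_copy[modal] = baseline_copy
            copies[active] = np.array([cluster_copy[c] for c in labels])
    med = np.median(vals[vals > 0]) if len(vals) and (vals > 0).any() else 1.0
    df["depth"] = counts / med if med > 0 else counts
    df["copy"] = copies
    return CNVProfile(bin_size=_infer_bin_size(df), haplotype=haplotype, df=df)


def _infer_bin_size(df: pd.DataFrame) -> int:
    starts = np.sort(df.start.unique())
    if len(starts) > 1:
        return int(np.min(np.diff(starts)[np.diff(starts) > 0]))
    return DEFAULT_BIN_SIZE


def _normalized_depth(bin_counts: pd.DataFrame, exclude_regions=None) -> np.ndarray:
    counts = bin_counts["count"].to_numpy(dtype=float)
    baseline = np.ones(len(counts), dtype=bool)
    if exclude_regions:
        for chrom, start, end in exclude_regions:
            m = (bin_counts.chrom == chrom) & (bin_counts.start >= start) & (bin_counts.start < end)
            baseline &= ~m.to_numpy()
    base_counts = counts[baseline]
    base_counts = base_counts[base_counts > 0]
    if len(base_counts) == 0:
        raise ValueError("no non-zero baseline bins for normalization")
    return counts / np.median(base_counts)


def cnv_change_ratio(
    case_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    region: tuple[str, int, int],
    exclude_regions=None,
) -> float:
    """Mean case/control normalized depth over a region.

    Each sample is first normalized by its genome-wide median bin depth
    (optionally excluding declared CNV regions from the baseline); a
    whole-chromosome trisomy against a diploid control yields 1.5.
    """
    if not case_counts[["chrom", "start"]].equals(control_counts[["chrom", "start"]]):
        raise ValueError("case and control profiles must share the same bin grid")
    chrom, start, end = region
    sel = (
        (case_counts.chrom == chrom) & (case_counts.start >= start) & (case_counts.start < end)
    ).to_numpy()
    if not sel.any():
        raise ValueError(f"region {region} covers no bins")
    case_norm = _normalized_depth(case_counts, exclude_regions)
    control_norm = _normalized_depth(control_counts, exclude_regions)
    control_mean = control_norm[sel].mean()
    if control_mean <= 0:
        raise ValueError("control has zero coverage in region")
    return float(case_norm[sel].mean() / control_mean)


def cnv_similarity(
    paternal: CNVProfile,
    maternal: CNVProfile,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window haplotype copy-number similarity min(Cp,Cm)/max(Cp,Cm).

    Windows where both haplotype mean copies are 0 score 1 (identical);
    no-call bins (copy -1) are ignored within a window.
    """
    if not paternal.df[["chrom", "start"]].equals(maternal.df[["chrom", "start"]]):
        raise ValueError("profiles must share the same bin grid")
    df = paternal.df[["chrom", "start"]].copy()
    df["cp"] = paternal.df["copy"].to_numpy()
    df["cm"] = maternal.df["copy"].to_numpy()
    df["window_start"] = (df.start // window) * window
    rows = []
    for (chrom, wstart), grp in df.groupby(["chrom", "window_start"], sort=True):
        cp = grp.cp[grp.cp >= 0]
        cm = grp.cm[grp.cm >= 0]
        mp = cp.mean() if len(cp) else np.nan
        mm = cm.mean() if len(cm) else np.nan
        if np.isnan(mp) or np.isnan(mm):
            sim = np.nan
        elif mp == 0 and mm == 0:
            sim = 1.0
        else:
            sim = min(mp, mm) / max(mp, mm)
        rows.append((chrom, int(wstart), int(wstart) + window, mp, mm, sim))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "paternal_copy", "maternal_copy", "similarity"]
    )
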