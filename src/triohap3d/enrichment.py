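"""Enrichment of altered 3D features in 1D-variant genomic regions.

Fixed windows (100 kb by default) are classified by their 1D variation
status — abnormal CNV (a significant CNV event in the case but not the
control), high SNP density (case SNPs at least twice the control AND
more than 100 excess SNPs per window), both, consistent (no CNV event
and fewer than 10 SNPs), or other — and a chi-square test with odds
ratio and Woolf 95% CI asks whether windows of a class are enriched for
altered structural features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("abnormal_cnv", "high_snp", "both", "consistent", "other")


def _window_overlap_flags(windows: pd.DataFrame, regions) -> np.ndarray:
    """True per window iff any region overlaps it by >= 1 bp."""
    flags = np.zeros(len(windows), dtype=bool)
    for chrom, start, end in regions:
        m = (windows.chrom == chrom) & (windows.start < end) & (windows.end > start)
        flags |= m.to_numpy()
    return flags


def _window_snp_counts(windows: pd.DataFrame, snp_positions: dict) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=int)
    for chrom, grp in windows.groupby("chrom", sort=False):
        pos = np.sort(np.asarray(snp_positions.get(chrom, []), dtype=int))
        lo = np.searchsorted(pos, grp.start.to_numpy())
        hi = np.searchsorted(pos, grp.end.to_numpy())
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def classify_regions(
    cnv_case,
    cnv_control,
    snp_case: dict,
    snp_control: dict,
    chrom_sizes: dict[str, int],
    window: int = 100_000,
    high_snp_ratio: float = 2.0,
    high_snp_excess: int = 100,
    low_snp_max: int = 10,
) -> pd.DataFrame:
    """Partition the genome into 1D-variation classes.

    ``cnv_case``/``cnv_control`` are iterables of significant CNV events
    (chrom, start, end); ``snp_case``/``snp_control`` map chromosome to
    SNP position arrays. Every window gets exactly one class.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, window)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + window, length))))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    case_cnv = _window_overlap_flags(windows, cnv_case)
    ctrl_cnv = _window_overlap_flags(windows, cnv_control)
    n_case = _window_snp_counts(windows, snp_case)
    n_ctrl = _window_snp_counts(windows, snp_control)

    abnormal = case_cnv & ~ctrl_cnv
    high = (n_case >= high_snp_ratio * n_ctrl) & (n_case - n_ctrl > high_snp_excess)
    consistent = ~case_cnv & (n_case < low_snp_max)

    cls = np.full(len(windows), "other", dtype=object)
    cls[consistent] = "consistent"
    cls[high] = "high_snp"
    cls[abnormal] = "abnormal_cnv"
    cls[abnormal & high] = "both"
    windows["class"] = cls
    windows["snp_case"] = n_case
    windows["snp_control"] = n_ctrl
    return windows


@dataclass
class EnrichmentResult:
    """2x2 association of altered features with a region class."""

    target_class: str
    table: np.ndarray  # [[altered_in, altered_out], [other_in, other_out]]
    chi2: float
    pvalue: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def odds_ratio_ci(table: np.ndarray, haldane: bool = True):
    """Odds ratio ad/bc with Woolf 95% CI; Haldane +0.5 when a cell is 0."""
    t = np.asarray(table, dtype=float)
    if haldane and (t == 0).any():
        t = t + 0.5
    a, b, c, d = t.ravel()
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.96 * se))
    hi = float(np.exp(np.log(orr) + 1.96 * se))
    return float(orr), lo, hi


def feature_enrichment(
    altered_feature_regions,
    classification: pd.DataFrame,
    target_class: str,
    correction: bool = False,
) -> EnrichmentResult:
    """Chi-square enrichment of altered-feature windows in one class.

    Rows of the 2x2 table are windows containing / not containing an
    altered structural feature; columns are in / out of the target class.
    Chi-square is computed without Yates correction by default.
    """
    if classification.empty:
        raise ValueError("empty classification")
    if target_class not in CLASSES:
        raise ValueError(f"unknown class {target_class!r}")
    has_feature = _window_overlap_flags(classification, altered_feature_regions)
    in_class = (classification["class"] == target_class).to_numpy()
    a = int((has_feature & in_class).sum())
    b = int((has_feature & ~in_class).sum())
    c = int((~has_feature & in_class).sum())
    d = int((~has_feature & ~in_class).sum())
    table = np.array([[a, b], [c, d]])
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    orr, lo, hi = odds_ratio_ci(table)
    return EnrichmentResult(target_class, table, float(chi2), float(p), orr, lo, hi)
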