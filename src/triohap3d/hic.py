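"""Contact matrices and 3D-structure comparison.

Builds bulk and haplotype-resolved contact matrices from contact pairs,
and compares two samples' chromatin architecture at three scales:

* **matrix similarity** — Pearson correlation of upper-triangle entries;
* **A/B compartments** — sign of the first eigenvector of the
  observed/expected correlation matrix, with the change ratio
  |PC1_case - PC1_control| / max(|PC1_case|, |PC1_control|); a region is
  altered when the ratio exceeds 0.5 or the compartment label switches;
* **TADs and loops** — stand-in callers (insulation-score minima; donut
  Poisson enrichment) feeding conservation classifiers: TAD pairs are
  conserved when the overlap exceeds 90% of the larger TAD, loop pairs
  when both anchors move by at most 5 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    haplotype: str = "bulk"
    cis_pairs: int = 0
    trans_pairs: int = 0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> float:
        iu = np.triu_indices(self.n_bins)
        return float(self.matrix[iu].sum())


def build_contact_matrix(
    pairs: pd.DataFrame,
    bin_size: int,
    chrom: str,
    chrom_length: int,
    haplotype_filter: str | None = None,
    haplotype_column: str = "label",
) -> ContactMatrix:
    """Bin cis contact pairs of one chromosome into a symmetric matrix.

    ``haplotype_filter`` keeps only pairs whose event-level haplotype
    label (from :func:`triohap3d.phasing.assign_contacts`, or the hidden
    truth column) matches. Trans pairs touching the chromosome are
    counted in the report but not binned.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = int(np.ceil(chrom_length / bin_size))
    mat = np.zeros((n_bins, n_bins))
    sub = pairs
    if haplotype_filter is not None and len(pairs):
        sub = pairs[pairs[haplotype_column] == haplotype_filter]
    cis = trans = 0
    if len(sub):
        on_a = sub.chromA == chrom
        on_b = sub.chromB == chrom
        cis_mask = on_a & on_b
        trans = int(((on_a | on_b) & ~cis_mask).sum())
        cs = sub[cis_mask]
        cis = len(cs)
        if cis:
            bi = (cs.posA.to_numpy() // bin_size).astype(int)
            bj = (cs.posB.to_numpy() // bin_size).astype(int)
            np.add.at(mat, (bi, bj), 1)
            np.add.at(mat, (bj, bi), 1)
            diag = bi == bj
            if diag.any():  # added twice above
                np.add.at(mat, (bi[diag], bj[diag]), -1)
    return ContactMatrix(
        chrom=chrom,
        bin_size=bin_size,
        matrix=mat,
        haplotype=haplotype_filter or "bulk",
        cis_pairs=cis,
        trans_pairs=trans,
    )


def downsample_contacts(pairs: pd.DataFrame, n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of exactly n pairs without replacement."""
    if n > len(pairs):
        raise ValueError(f"cannot downsample {len(pairs)} pairs to {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return pairs.iloc[np.sort(idx)].reset_index(drop=True)


def matrix_similarity(a: ContactMatrix, b: ContactMatrix) -> float:
    """Pearson correlation over upper-triangle entries (incl. diagonal).

    NaN-masked entries are excluded pairwise; returns NaN when either
    vector is constant.
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(a.n_bins)
    x, y = a.matrix[iu], b.matrix[iu]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def region_similarity(a: ContactMatrix, b: ContactMatrix, start: int, end: int) -> float:
    """Matrix similarity restricted to bins overlapping [start, end) bp."""
    lo = start // a.bin_size
    hi = int(np.ceil(end / a.bin_size))
    lo, hi = max(lo, 0), min(hi, a.n_bins)
    if hi - lo < 2:
        return float("nan")
    sub_a = ContactMatrix(a.chrom, a.bin_size, a.matrix[lo:hi, lo:hi])
    sub_b = ContactMatrix(b.chrom, b.bin_size, b.matrix[lo:hi, lo:hi])
    return matrix_similarity(sub_a, sub_b)


# ---------------------------------------------------------------------------
# A/B compartments


@dataclass
class CompartmentTrack:
    """Per-bin first-eigenvector values and A/B labels (A iff PC1 > 0)."""

    chrom: str
    bin_size: int
    pc1: np.ndarray  # NaN where uninformative
    labels: np.ndarray  # 'A' | 'B' | 'NA'


def _observed_over_expected(mat: np.ndarray, informative: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    oe = np.zeros_like(mat, dtype=float)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = informative[i] & informative[j]
        if not ok.any():
            continue
        expected = mat[i[ok], j[ok]].mean()
        if expected > 0:
            oe[i[ok], j[ok]] = mat[i[ok], j[ok]] / expected
            oe[j[ok], i[ok]] = oe[i[ok], j[ok]]
    return oe


def compute_compartments(matrix: ContactMatrix, orientation_track: np.ndarray) -> CompartmentTrack:
    """A/B compartment assignment from a cis contact matrix.

    Distance-normalizes the matrix (observed/expected per diagonal),
    takes the Pearson correlation matrix, and extracts its first
    eigenvector. The eigenvector's arbitrary sign is fixed so that its
    correlation with ``orientation_track`` (e.g. gene density) is
    positive; bins with zero coverage get NaN/'NA'.
    """
    mat = matrix.matrix
    n = matrix.n_bins
    orientation_track = np.asarray(orientation_track, dtype=float)
    if len(orientation_track) != n:
        raise ValueError("orientation_track length must equal bin count")
    coverage = mat.sum(axis=1)
    informative = coverage > 0
    if informative.sum() < 10:
        raise ValueError("need >= 10 informative bins")
    oe = _observed_over_expected(mat, informative)
    sub = oe[np.ix_(informative, informative)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    pc1_sub = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    pc1 = np.full(n, np.nan)
    pc1[informative] = pc1_sub
    ref = orientation_track[informative]
    if np.std(ref) > 0 and np.std(pc1_sub) > 0:
        if np.corrcoef(pc1_sub, ref)[0, 1] < 0:
            pc1 = -pc1
    labels = np.where(np.isnan(pc1) | (pc1 == 0), "NA", np.where(pc1 > 0, "A", "B"))
    return CompartmentTrack(matrix.chrom, matrix.bin_size, pc1, labels)


@dataclass
class ChangeRatioTrack:
    """Per-bin compartment change ratio and conserved/altered call."""

    chrom: str
    bin_size: int
    df: pd.DataFrame  # start, ratio, call


def compartment_change_ratio(case: CompartmentTrack, control: CompartmentTrack) -> ChangeRatioTrack:
    """Change ratio = |PC1_case - PC1_control| / max(|PC1_case|, |PC1_control|).

    Ratio 0 when both PC1 are 0. A bin is altered when the ratio exceeds
    0.5 or when the A/B labels differ; bins lacking a PC1 value on either
    side get call 'NA'.
    """
    if case.bin_size != control.bin_size or len(case.pc1) != len(control.pc1):
        raise ValueError("tracks must share the same bin grid")
    n = len(case.pc1)
    ratios = np.full(n, np.nan)
    calls = np.full(n, "NA", dtype=object)
    for i in range(n):
        a, b = case.pc1[i], control.pc1[i]
        if np.isnan(a) or np.isnan(b):
            continue
        denom = max(abs(a), abs(b))
        ratio = 0.0 if denom == 0 else abs(a - b) / denom
        ratios[i] = ratio
        altered = ratio > 0.5 or case.labels[i] != control.labels[i]
        calls[i] = "altered" if altered else "conserved"
    df = pd.DataFrame(
        {"start": np.arange(n) * case.bin_size, "ratio": ratios, "call": calls}
    )
    return ChangeRatioTrack(case.chrom, case.bin_size, df)


# ---------------------------------------------------------------------------
# TADs


def insulation_score(matrix: ContactMatrix, window: int) -> np.ndarray:
    """Mean contact count in a window x window square crossing the
    diagonal at each bin; NaN at chromosome edges."""
    mat = matrix.matrix
    n = matrix.n_bins
    if window >= n:
        raise ValueError("insulation window must be smaller than the matrix")
    score = np.full(n, np.nan)
    for i in range(window, n - window):
        score[i] = mat[i - window : i, i + 1 : i + 1 + window].mean()
    return score


def call_tads(matrix: ContactMatrix, insulation_window: int = 3) -> pd.DataFrame:
    """TADs as intervals between insulation-score boundaries.

    Boundaries are local minima of the insulation score lying below
    (mean - 1 sd) of the valid scores; TADs are the inter-boundary
    intervals, reported in bp.
    """
    score = insulation_score(matrix, insulation_window)
    valid = ~np.isnan(score)
    mean, sd = np.nanmean(score), np.nanstd(score)
    thresh = mean - sd
    n = matrix.n_bins
    boundaries = []
    for i in range(1, n - 1):
        if not valid[i]:
            continue
        left = score[i - 1] if valid[i - 1] else np.inf
        right = score[i + 1] if valid[i + 1] else np.inf
        if score[i] < left and score[i] <= right and score[i] < thresh:
            boundaries.append(i)
    edges = [0] + boundaries + [n]
    bs = matrix.bin_size
    rows = [
        (matrix.chrom, edges[k] * bs, edges[k + 1] * bs)
        for k in range(len(edges) - 1)
        if edges[k + 1] > edges[k]
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def classify_tads(tads_case: pd.DataFrame, tads_control: pd.DataFrame) -> pd.DataFrame:
    """Conservation call per case TAD.

    A case TAD is conserved iff some control TAD on the same chromosome
    overlaps it by more than 90% of the length of the larger of the two.
    """
    calls = []
    for t in tads_case.itertuples():
        best_frac = 0.0
        ctl = tads_control[tads_control.chrom == t.chrom]
        for c in ctl.itertuples():
            ov = min(t.end, c.end) - max(t.start, c.start)
            if ov <= 0:
                continue
            larger = max(t.end - t.start, c.end - c.start)
            best_frac = max(best_frac, ov / larger)
        calls.append("conserved" if best_frac > 0.9 else "altered")
    out = tads_case.copy()
    out["call"] = calls
    return out


# ---------------------------------------------------------------------------
# loops


def call_loops(
    matrix: ContactMatrix,
    neighborhood: int = 2,
    min_distance: int = 3,
    alpha: float = 0.05,
    min_count: float = 3.0,
) -> pd.DataFrame:
    """Point-wise contact enrichment (loop) calls.

    Candidates are off-diagonal pixels (|i-j| >= min_distance) with at
    least ``min_count`` contacts whose count exceeds the mean of their
    surrounding donut (square ring of half-width ``neighborhood``
    excluding the central 3x3); p-values are Poisson upper tails with
    the donut mean as expectation, retained at Benjamini-Hochberg
    FDR < alpha. The ``min_count`` floor suppresses single-contact
    pixels on an empty background whose Poisson tail would otherwise be
    spuriously extreme.
    """
    mat = matrix.matrix
    n = matrix.n_bins
    cand = []
    for i in range(n):
        for j in range(i + min_distance, n):
            c = mat[i, j]
            if c < min_count:
                continue
            lo_i, hi_i = max(i - neighborhood, 0), min(i + neighborhood + 1, n)
            lo_j, hi_j = max(j - neighborhood, 0), min(j + neighborhood + 1, n)
            block = mat[lo_i:hi_i, lo_j:hi_j]
            ring_mask = np.ones(block.shape, dtype=bool)
            ci, cj = i - lo_i, j - lo_j
            ring_mask[max(ci - 1, 0) : ci + 2, max(cj - 1, 0) : cj + 2] = False
            ring = block[ring_mask]
            if ring.size == 0:
                continue
            expected = ring.mean()
            if c <= expected:
                continue
            p = stats.poisson.sf(c - 1, max(expected, 1e-12))
            cand.append((matrix.chrom, i, j, float(c), float(expected), float(p)))
    df = pd.DataFrame(cand, columns=["chrom", "bin_i", "bin_j", "count", "expected", "pvalue"])
    if df.empty:
        df["qvalue"] = pd.Series(dtype=float)
        return df
    df["qvalue"] = multipletests(df.pvalue, method="fdr_bh")[1]
    return df[df.qvalue < alpha].reset_index(drop=True)


def classify_loops(
    loops_case: pd.DataFrame, loops_control: pd.DataFrame, window: int = 5
) -> pd.DataFrame:
    """Conservation call per case loop: conserved iff some control loop
    on the same chromosome has both anchors within ``window`` bins."""
    calls = []
    for l in loops_case.itertuples():
        ctl = loops_control[loops_control.chrom == l.chrom]
        conserved = any(
            abs(l.bin_i - c.bin_i) <= window and abs(l.bin_j - c.bin_j) <= window
            for c in ctl.itertuples()
        )
        calls.append("conserved" if conserved else "altered")
    out = loops_case.copy()
    out["call"] = calls
    return out


# ---------------------------------------------------------------------------


def haplotype_interaction_summary(
    paternal: ContactMatrix,
    maternal: ContactMatrix,
    region: tuple[int, int] | None = None,
) -> dict:
    """Contact counts per parental matrix over a region (both ends in
    the region), their maternal/paternal ratio, and cis fractions."""
    if paternal.matrix.shape != maternal.matrix.shape:
        raise ValueError("matrices must share a bin grid")
    n = paternal.n_bins
    if region is None:
        lo, hi = 0, n
    else:
        lo = region[0] // paternal.bin_size
        hi = int(np.ceil(region[1] / paternal.bin_size))
        lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        raise ValueError("empty region")
    iu = np.triu_indices(hi - lo)

    def _count(m):
        return float(m.matrix[lo:hi, lo:hi][iu].sum())

    pat, mat = _count(paternal), _count(maternal)
    out = {
        "paternal_contacts": pat,
        "maternal_contacts": mat,
        "maternal_paternal_ratio": mat / pat if pat > 0 else float("nan"),
    }
    for label, m in (("paternal", paternal), ("maternal", maternal)):
        tot = m.cis_pairs + m.trans_pairs
        out[f"{label}_cis_fraction"] = m.cis_pairs / tot if tot else float("nan")
    return out
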