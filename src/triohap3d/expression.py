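"""Expression normalization, fold changes, and allele-specific counts.

Normalization follows the median-of-ratios scheme: per-sample size
factors are the median across genes of the ratio of the count to the
gene's geometric mean across samples. Haplotype-resolved expression
counts phased RNA fragments (paternal vs maternal) per gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def normalize_counts(count_table: pd.DataFrame):
    """Median-of-ratios normalization.

    ``count_table`` is genes x samples. Returns ``(size_factors,
    normalized_table)``. Size factors use only genes with non-zero counts
    in every sample.
    """
    counts = count_table.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has non-zero counts in all samples")
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    log_sf = np.median(log_counts - log_geomean, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1 -> renormalization is a no-op
    size_factors = np.exp(log_sf)
    sf = pd.Series(size_factors, index=count_table.columns, name="size_factor")
    normalized = count_table / sf
    return sf, normalized


def fold_change(
    normalized: pd.DataFrame,
    case: str,
    control: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene (case + pseudocount) / (control + pseudocount)."""
    return (normalized[case] + pseudocount) / (normalized[control] + pseudocount)


def _exon_trees(gene_model: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in gene_model.itertuples():
        if r.end <= r.start:
            continue
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene_id)
    return trees


def haplotype_expression(
    paternal_fragments: pd.DataFrame,
    maternal_fragments: pd.DataFrame,
    gene_model: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene paternal/maternal fragment counts from phased RNA reads.

    A fragment counts for a gene when its midpoint falls in one of the
    gene's exons; a midpoint inside exons of several genes counts for
    each and flags those genes ambiguous. Counts are normalized by the
    total informative coverage of each haplotype; the reported ratio is
    maternal/paternal of the normalized values (NaN when paternal is 0).
    """
    if gene_model.empty:
        raise ValueError("gene model is empty")
    trees = _exon_trees(gene_model)
    genes = list(dict.fromkeys(gene_model.gene_id))
    counts = {g: {"paternal": 0, "maternal": 0} for g in genes}
    ambiguous = {g: False for g in genes}
    for hap, frags in (("paternal", paternal_fragments), ("maternal", maternal_fragments)):
        if frags.empty:
            continue
        mids = (frags.start.to_numpy() + frags.end.to_numpy()) // 2
        for chrom, mid in zip(frags.chrom.to_numpy(), mids):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = {iv.data for iv in tree.at(int(mid))}
            if len(hits) > 1:
                for g in hits:
                    ambiguous[g] = True
            for g in hits:
                counts[g][hap] += 1
    tot_p = max(sum(c["paternal"] for c in counts.values()), 0)
    tot_m = max(sum(c["maternal"] for c in counts.values()), 0)
    rows = []
    for g in genes:
        cp, cm = counts[g]["paternal"], counts[g]["maternal"]
        np_ = cp / tot_p if tot_p else np.nan
        nm = cm / tot_m if tot_m else np.nan
        if tot_p == 0 or tot_m == 0 or cp == 0:
            ratio = np.nan
        else:
            ratio = nm / np_
        rows.append((g, cp, cm, np_, nm, ratio, ambiguous[g]))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "paternal_count", "maternal_count",
            "paternal_norm", "maternal_norm", "maternal_paternal_ratio", "ambiguous",
        ],
    )
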