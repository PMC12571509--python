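"""Parental-origin SNP classification and haplotype assignment of reads.

Trio SNPs are classified as shared (both parents and child),
parent-specific (exactly one parent; transmitted if also in the child),
or excluded (child-only). Fragments carrying the alternate allele at one
or more transmitted parent-specific sites are assigned to that parent's
haplotype; evidence for both parents is a conflict and the fragment is
discarded rather than arbitrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PATERNAL, MATERNAL

CATEGORIES = ("paternal_specific", "maternal_specific", "shared", "excluded")
LABELS = (PATERNAL, MATERNAL, "unassigned", "conflict")

_TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "category", "transmitted"]


@dataclass
class PhasedSNPTable:
    """Classified trio SNPs plus a fast lookup of informative sites.

    ``df`` holds one row per (chrom, pos, alt) with its category;
    ``lookup`` maps (chrom, pos) -> (alt, parent) for transmitted
    parent-specific sites only — the sites that can tag a child read.
    """

    df: pd.DataFrame

    def __post_init__(self):
        informative = self.df[
            self.df.category.isin(["paternal_specific", "maternal_specific"])
            & self.df.transmitted
        ]
        self.lookup = {
            (r.chrom, int(r.pos)): (r.alt, PATERNAL if r.category == "paternal_specific" else MATERNAL)
            for r in informative.itertuples()
        }

    def counts(self) -> dict[str, int]:
        return self.df.category.value_counts().to_dict()


def _site_key(sites) -> set[tuple]:
    """Normalize a variant input to a set of (chrom, pos, ref, alt)."""
    if isinstance(sites, pd.DataFrame):
        return {(r.chrom, int(r.pos), r.ref, r.alt) for r in sites.itertuples()}
    return {(c, int(p), r, a) for c, p, r, a in sites}


def classify_snps(father_variants, mother_variants, child_variants) -> PhasedSNPTable:
    """Classify trio SNP sites by parental origin.

    Sites are keyed by (chrom, pos, alt); multiallelic records must be
    split beforehand. Sites where different samples carry different
    alternate alleles at the same position are excluded with a warning.
    """
    father = _site_key(father_variants)
    mother = _site_key(mother_variants)
    child = _site_key(child_variants)

    by_pos: dict[tuple, set] = {}
    for s in father | mother | child:
        by_pos.setdefault((s[0], s[1]), set()).add(s[3])
    conflicted = {k for k, alts in by_pos.items() if len(alts) > 1}
    if conflicted:
        warnings.warn(f"{len(conflicted)} positions with conflicting alt alleles excluded")

    rows = []
    for site in sorted(father | mother | child):
        chrom, pos, ref, alt = site
        in_f, in_m, in_c = site in father, site in mother, site in child
        transmitted = in_c
        if (chrom, pos) in conflicted:
            category = "excluded"
        elif in_f and in_m:
            category = "shared" if in_c else "excluded"
        elif in_f:
            category = "paternal_specific"
        elif in_m:
            category = "maternal_specific"
        else:  # child only
            category = "excluded"
        rows.append((chrom, pos, ref, alt, category, transmitted))
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return PhasedSNPTable(df)


def assign_alleles(evidence, lookup) -> str:
    """Label from observed (chrom, pos, base) evidence.

    evidence: iterable of (chrom, pos, base). A site votes for a parent
    iff it is a transmitted parent-specific site and the observed base is
    the alternate allele.
    """
    has_pat = has_mat = False
    for chrom, pos, base in evidence:
        hit = lookup.get((chrom, int(pos)))
        if hit is None:
            continue
        alt, parent = hit
        if base == alt:
            if parent == PATERNAL:
                has_pat = True
            else:
                has_mat = True
    if has_pat and has_mat:
        return "conflict"
    if has_pat:
        return PATERNAL
    if has_mat:
        return MATERNAL
    return "unassigned"


def assign_fragment(fragment, table: PhasedSNPTable) -> str:
    """Haplotype label for a single fragment.

    ``fragment`` is any mapping/namespace with ``chrom`` and ``alleles``
    (tuple of (pos, base)), e.g. a row of a fragment table.
    """
    chrom = fragment["chrom"] if isinstance(fragment, dict) else fragment.chrom
    alleles = fragment["alleles"] if isinstance(fragment, dict) else fragment.alleles
    return assign_alleles(((chrom, p, b) for p, b in alleles), table.lookup)


def split_library(fragments: pd.DataFrame, table: PhasedSNPTable):
    """Assign every fragment; return (paternal, maternal, report).

    Conflict and unassigned fragments appear in neither output; the
    report counts all four labels.
    """
    if fragments.empty:
        report = {lab: 0 for lab in LABELS}
        empty = fragments.copy()
        return empty, empty.copy(), report
    lookup = table.lookup
    labels = np.array(
        [
            assign_alleles(((c, p, b) for p, b in al), lookup)
            for c, al in zip(fragments["chrom"], fragments["alleles"])
        ]
    )
    fragments = fragments.assign(label=labels)
    report = {lab: int((labels == lab).sum()) for lab in LABELS}
    pat = fragments[labels == PATERNAL].drop(columns="label").reset_index(drop=True)
    mat = fragments[labels == MATERNAL].drop(columns="label").reset_index(drop=True)
    return pat, mat, report


def assign_contacts(pairs: pd.DataFrame, table: PhasedSNPTable) -> pd.DataFrame:
    """Add a ``label`` column to a contact-pair table.

    Evidence from both ends is pooled; ends disagreeing on the parent
    make the event a conflict.
    """
    if pairs.empty:
        return pairs.assign(label=pd.Series(dtype=object))
    lookup = table.lookup
    labels = []
    for row in pairs.itertuples():
        ev = [(row.chromA, p, b) for p, b in row.allelesA]
        ev += [(row.chromB, p, b) for p, b in row.allelesB]
        labels.append(assign_alleles(ev, lookup))
    return pairs.assign(label=labels)


@dataclass
class SNPDensityScore:
    """Per-bin paternal/maternal SNP count difference over a region."""

    chrom: str
    start: int
    end: int
    bin_size: int
    bins: pd.DataFrame  # bin_start, paternal, maternal, difference
    total: int


def snp_density_difference(
    paternal_positions,
    maternal_positions,
    region: tuple[str, int, int],
    bin_size: int,
) -> SNPDensityScore:
    """Sum over bins of |paternal SNP count - maternal SNP count|.

    Quantifies how unevenly phasing-informative SNPs are distributed
    between the two parental haplotypes across a region.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chrom, start, end = region
    if end <= start or start < 0:
        raise ValueError(f"invalid region {region}")
    edges = np.arange(start, end + bin_size, bin_size)
    if edges[-1] < end:
        edges = np.append(edges, end)
    pat = np.asarray(sorted(p for p in paternal_positions if start <= p < end))
    mat = np.asarray(sorted(p for p in maternal_positions if start <= p < end))
    pat_counts, _ = np.histogram(pat, bins=edges)
    mat_counts, _ = np.histogram(mat, bins=edges)
    diff = np.abs(pat_counts - mat_counts)
    bins = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "paternal": pat_counts,
            "maternal": mat_counts,
            "difference": diff,
        }
    )
    return SNPDensityScore(chrom, start, end, bin_size, bins, int(diff.sum()))
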