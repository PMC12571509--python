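"""Synthetic trio-trisomy data generator.

Emulates a father/mother/child trio in which the child carries an extra
copy of one chromosome (trisomy) inherited from one parent. Ground truth
— which haplotype every fragment and contact came from, the per-haplotype
chromatin structure, and the generative expression parameters — is
recorded so that every downstream stage can be scored against it.

Coordinates are 0-based half-open throughout; VCF export is 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PATERNAL = "paternal"
MATERNAL = "maternal"
HAPLOTYPES = (PATERNAL, MATERNAL)

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class GenomeSpec:
    """Design of the simulated trio genome.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs.
    snp_rate
        Expected heterozygous-SNP density per bp per parent (the
        parent-specific, transmitted sites that make phasing possible).
    trisomy_chrom
        Chromosome present in three copies in the child.
    trisomy_origin
        Parent contributing the extra copy (``"paternal"``/``"maternal"``).
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr21", 5_000_000))
    snp_rate: float = 1e-3
    trisomy_chrom: str = "chr21"
    trisomy_origin: str = MATERNAL
    seed: int = 0
    shared_snp_rate: float | None = None  # default: snp_rate / 2
    nontransmitted_fraction: float = 0.1
    structure_bin_size: int = 50_000
    divergence_window: int = 1_000_000
    divergence_prob: float = 0.3

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has non-positive length")
        if not (0 <= self.snp_rate <= 0.01):
            raise ConfigurationError("snp_rate must be in [0, 0.01]")
        if self.trisomy_origin not in HAPLOTYPES:
            raise ConfigurationError("trisomy_origin must be 'paternal' or 'maternal'")
        if self.trisomy_chrom not in dict(self.chromosomes):
            raise ConfigurationError(f"trisomy_chrom {self.trisomy_chrom!r} not in chromosomes")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class HaplotypeStructure:
    """True 3D structure of one haplotype: per-chromosome compartment
    labels (+1 = A, -1 = B) per structure bin, TAD intervals and loop
    anchors in bin units."""

    bin_size: int
    compartments: dict[str, np.ndarray]
    tads: dict[str, list[tuple[int, int]]]
    loops: dict[str, list[tuple[int, int]]]


@dataclass
class TrioTruth:
    """Complete ground truth of a simulated trio."""

    spec: GenomeSpec
    snps: pd.DataFrame  # chrom, pos, ref, alt, category, transmitted
    copy_counts: dict[str, dict[str, int]]  # chrom -> {paternal: n, maternal: n}
    structures: dict[str, HaplotypeStructure]
    divergent_windows: dict[str, list[tuple[int, int]]]  # bp intervals
    genes: pd.DataFrame | None = None
    expr_params: pd.DataFrame | None = None

    def snp_positions(self, chrom: str) -> pd.DataFrame:
        return self.snps[self.snps.chrom == chrom].sort_values("pos")

    def total_copies(self, chrom: str) -> int:
        cc = self.copy_counts[chrom]
        return cc[PATERNAL] + cc[MATERNAL]


def _draw_positions(rng, length, rate, taken):
    n = rng.poisson(length * rate)
    pos = set()
    while len(pos) < n:
        cand = rng.integers(0, length, size=n - len(pos))
        pos.update(int(p) for p in cand if p not in taken and p not in pos)
    taken.update(pos)
    return sorted(pos)


def _alleles(rng, n):
    ref_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + shift) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def simulate_trio_genomes(spec: GenomeSpec) -> TrioTruth:
    """Generate trio SNPs, child copy counts, and per-haplotype structure.

    Each parent-specific SNP is heterozygous in that parent; transmitted
    sites carry the alternate allele on the child's corresponding
    haplotype, so they unambiguously tag reads. Shared SNPs occur in both
    parents and the child and are uninformative for assignment.
    """
    rng = np.random.default_rng(spec.seed)
    shared_rate = spec.shared_snp_rate if spec.shared_snp_rate is not None else spec.snp_rate / 2

    rows = []
    for chrom, length in spec.chromosomes:
        taken: set[int] = set()
        for category, rate in (
            ("paternal_specific", spec.snp_rate),
            ("maternal_specific", spec.snp_rate),
            ("shared", shared_rate),
        ):
            positions = _draw_positions(rng, length, rate, taken)
            if not positions:
                continue
            refs, alts = _alleles(rng, len(positions))
            if category == "shared":
                transmitted = np.ones(len(positions), dtype=bool)
            else:
                transmitted = rng.random(len(positions)) >= spec.nontransmitted_fraction
            for p, r, a, t in zip(positions, refs, alts, transmitted):
                rows.append((chrom, p, r, a, category, bool(t)))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "category", "transmitted"])
    if snps.empty:
        snps = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "category", "transmitted"])
    else:
        snps = snps.sort_values(["chrom", "pos"]).reset_index(drop=True)

    copy_counts = {}
    for chrom, _ in spec.chromosomes:
        cc = {PATERNAL: 1, MATERNAL: 1}
        if chrom == spec.trisomy_chrom:
            cc[spec.trisomy_origin] = 2
        copy_counts[chrom] = cc

    pat_structure = _random_structure(spec, rng)
    mat_structure, divergent = _diverge_structure(spec, pat_structure, rng)

    return TrioTruth(
        spec=spec,
        snps=snps,
        copy_counts=copy_counts,
        structures={PATERNAL: pat_structure, MATERNAL: mat_structure},
        divergent_windows=divergent,
    )


def _random_structure(spec: GenomeSpec, rng) -> HaplotypeStructure:
    comps, tads, loops = {}, {}, {}
    bs = spec.structure_bin_size
    for chrom, length in spec.chromosomes:
        n_bins = max(1, math.ceil(length / bs))
        # alternating A/B blocks of 8-15 bins
        labels = np.empty(n_bins, dtype=int)
        label = int(rng.choice([1, -1]))
        i = 0
        while i < n_bins:
            block = int(rng.integers(8, 16))
            labels[i : i + block] = label
            label = -label
            i += block
        comps[chrom] = labels
        # consecutive TADs of 6-12 bins
        tad_list = []
        i = 0
        while i < n_bins:
            size = int(rng.integers(6, 13))
            tad_list.append((i, min(i + size, n_bins)))
            i += size
        tads[chrom] = tad_list
        # one loop per larger TAD, anchors well inside
        loop_list = []
        for start, end in tad_list:
            if end - start >= 8 and rng.random() < 0.5:
                loop_list.append((start + 1, end - 2))
        loops[chrom] = loop_list
    return HaplotypeStructure(bin_size=bs, compartments=comps, tads=tads, loops=loops)


def _diverge_structure(spec, base: HaplotypeStructure, rng):
    """Copy the paternal structure and perturb it inside randomly chosen
    megabase windows: flip compartment labels, dissolve TAD boundaries,
    relocate loops. The perturbed windows are recorded as ground truth
    for haplotype-similarity checks."""
    bs = base.bin_size
    comps, tads, loops, divergent = {}, {}, {}, {}
    for chrom, length in spec.chromosomes:
        labels = base.compartments[chrom].copy()
        n_bins = len(labels)
        windows = []
        for w_start in range(0, length, spec.divergence_window):
            if rng.random() < spec.divergence_prob:
                windows.append((w_start, min(w_start + spec.divergence_window, length)))
        divergent[chrom] = windows
        win_bins: set[int] = set()
        for w_start, w_end in windows:
            win_bins.update(range(w_start // bs, math.ceil(w_end / bs)))
        for b in win_bins:
            if b < n_bins:
                labels[b] = -labels[b]
        comps[chrom] = labels

        # drop TAD boundaries falling strictly inside divergent windows
        boundaries = sorted({b for s, e in base.tads[chrom] for b in (s, e)})
        kept = [b for b in boundaries if b in (0, n_bins) or b not in win_bins]
        if 0 not in kept:
            kept.insert(0, 0)
        if n_bins not in kept:
            kept.append(n_bins)
        tads[chrom] = [(kept[i], kept[i + 1]) for i in range(len(kept) - 1)]

        # relocate loops whose anchors fall in divergent windows
        new_loops = []
        for i, j in base.loops[chrom]:
            if i in win_bins or j in win_bins:
                shift = int(rng.integers(6, 12))
                jj = min(j + shift, n_bins - 1)
                if jj - i >= 3:
                    new_loops.append((i, jj))
            else:
                new_loops.append((i, j))
        loops[chrom] = new_loops
    return HaplotypeStructure(bin_size=bs, compartments=comps, tads=tads, loops=loops), divergent


# ---------------------------------------------------------------------------
# fragments


def _observed_alleles(truth: TrioTruth, chrom, starts, ends, haplotype, rng, error_rate):
    """Per fragment, the (pos, base) tuples observed at SNP sites covered
    by [start, end). The base reflects the source haplotype: alternate
    allele at that parent's transmitted specific sites and at shared
    sites, reference otherwise; flipped with probability error_rate."""
    sub = truth.snp_positions(chrom)
    out = [()] * len(starts)
    if sub.empty:
        return out
    pos = sub.pos.to_numpy()
    ref = sub.ref.to_numpy()
    alt = sub.alt.to_numpy()
    cat = sub.category.to_numpy()
    trans = sub.transmitted.to_numpy()
    own = f"{haplotype}_specific"
    carries_alt = ((cat == own) & trans) | (cat == "shared")
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    covered = np.nonzero(hi > lo)[0]
    for f in covered:
        alleles = []
        for k in range(lo[f], hi[f]):
            base = alt[k] if carries_alt[k] else ref[k]
            if error_rate > 0 and rng.random() < error_rate:
                base = ref[k] if base == alt[k] else alt[k]
            alleles.append((int(pos[k]), str(base)))
        out[f] = tuple(alleles)
    return out


_FRAG_COLUMNS = ["chrom", "start", "end", "frag_id", "true_hap", "alleles"]


def simulate_fragments(
    truth: TrioTruth,
    coverage: float = 10.0,
    frag_len: int = 150,
    library: str = "wgs",
    seed: int = 0,
    error_rate: float = 0.0,
    n_fragments: int | None = None,
) -> pd.DataFrame:
    """Sample sequencing fragments from the child genome.

    WGS fragments are Poisson per haplotype copy with a genome-average
    depth of ``coverage`` on diploid chromosomes (a trisomic chromosome
    is therefore 1.5x deeper). RNA fragments are a multinomial of size
    ``n_fragments`` over (gene, haplotype) cells weighted by baseline
    expression times haplotype copy number.
    """
    if library not in ("wgs", "rna"):
        raise ConfigurationError("library must be 'wgs' or 'rna'")
    if library == "wgs" and coverage <= 0:
        raise ConfigurationError("coverage must be positive")
    rng = np.random.default_rng(seed)
    parts = []
    fid = 0
    if library == "wgs":
        for chrom, length in truth.spec.chromosomes:
            if frag_len > length:
                raise ConfigurationError(f"frag_len {frag_len} exceeds {chrom} length {length}")
            for hap in HAPLOTYPES:
                copies = truth.copy_counts[chrom][hap]
                lam = length * coverage * copies / (2 * frag_len)
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                starts = rng.integers(0, length - frag_len + 1, size=n)
                ends = starts + frag_len
                alleles = _observed_alleles(truth, chrom, starts, ends, hap, rng, error_rate)
                parts.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "start": starts,
                            "end": ends,
                            "frag_id": np.arange(fid, fid + n),
                            "true_hap": hap,
                            "alleles": alleles,
                        }
                    )
                )
                fid += n
    else:
        if truth.genes is None:
            raise ConfigurationError("RNA library requires genes: run simulate_expression first")
        if n_fragments is None:
            n_fragments = int(coverage)
        genes = truth.genes
        params = truth.expr_params.set_index("gene_id")
        cells = []
        weights = []
        for g in genes.itertuples():
            e = float(params.loc[g.gene_id, "e_control"])
            for hap in HAPLOTYPES:
                copies = truth.copy_counts[g.chrom][hap]
                cells.append((g.chrom, g.start, g.end, hap))
                weights.append(e * copies / 2.0)
        weights = np.asarray(weights, dtype=float)
        if n_fragments > 0 and weights.sum() > 0:
            counts = rng.multinomial(n_fragments, weights / weights.sum())
        else:
            counts = np.zeros(len(weights), dtype=int)
        for (chrom, gs, ge, hap), n in zip(cells, counts):
            if n == 0:
                continue
            span = max(ge - gs - frag_len, 1)
            starts = gs + rng.integers(0, span, size=n)
            ends = np.minimum(starts + frag_len, ge)
            alleles = _observed_alleles(truth, chrom, starts, ends, hap, rng, error_rate)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "frag_id": np.arange(fid, fid + n),
                        "true_hap": hap,
                        "alleles": alleles,
                    }
                )
            )
            fid += n
    if not parts:
        return pd.DataFrame(columns=_FRAG_COLUMNS)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Hi-C contacts


@dataclass(frozen=True)
class StructureStrengths:
    """Contact-probability multipliers for the three structure layers."""

    compartment: float = 3.0
    tad: float = 5.0
    loop: float = 50.0

    def __post_init__(self):
        if min(self.compartment, self.tad, self.loop) < 1:
            raise ConfigurationError("structure strengths must be >= 1")


def contact_probability_grid(truth: TrioTruth, chrom: str, haplotype: str,
                             strengths: StructureStrengths) -> np.ndarray:
    """Symmetric bin-pair contact probability grid for one chromosome and
    haplotype: power-law distance decay boosted within compartment blocks
    of equal label, within TADs, and at loop anchors."""
    st = truth.structures[haplotype]
    labels = st.compartments[chrom]
    n = len(labels)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    grid = 1.0 / (1.0 + dist)
    same_comp = labels[:, None] == labels[None, :]
    grid[same_comp] *= strengths.compartment
    tad_id = np.full(n, -1)
    for t, (s, e) in enumerate(st.tads[chrom]):
        tad_id[s:e] = t
    same_tad = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    grid[same_tad] *= strengths.tad
    for i, j in st.loops[chrom]:
        grid[i, j] *= strengths.loop
        grid[j, i] *= strengths.loop
    return grid


def simulate_contacts(
    truth: TrioTruth,
    n_contacts: int = 500_000,
    cis_fraction: float = 0.9993,
    strengths: StructureStrengths | None = None,
    seed: int = 0,
    read_len: int = 150,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Sample chromatin contact pairs with hidden haplotype of origin.

    Cis pairs are multinomial over the per-haplotype probability grids
    (haplotypes weighted by chromosome length x copy number); trans pairs
    join two distinct chromosomes uniformly. Each end records observed
    alleles at SNPs within ``read_len`` bp, as for fragments.
    """
    if n_contacts < 0:
        raise ConfigurationError("n_contacts must be >= 0")
    if not 0 <= cis_fraction <= 1:
        raise ConfigurationError("cis_fraction must be in [0, 1]")
    strengths = strengths or StructureStrengths()
    rng = np.random.default_rng(seed)
    cols = ["chromA", "posA", "chromB", "posB", "true_hap", "allelesA", "allelesB"]
    if n_contacts == 0:
        return pd.DataFrame(columns=cols)
    n_cis = int(rng.binomial(n_contacts, cis_fraction))
    n_trans = n_contacts - n_cis
    bs = truth.spec.structure_bin_size
    sizes = truth.spec.chrom_sizes

    cells = []
    weights = []
    for chrom, length in truth.spec.chromosomes:
        for hap in HAPLOTYPES:
            cells.append((chrom, hap))
            weights.append(length * truth.copy_counts[chrom][hap])
    weights = np.asarray(weights, dtype=float)
    alloc = rng.multinomial(n_cis, weights / weights.sum()) if n_cis else np.zeros(len(cells), int)

    parts = []
    for (chrom, hap), n in zip(cells, alloc):
        if n == 0:
            continue
        grid = contact_probability_grid(truth, chrom, hap, strengths)
        nb = grid.shape[0]
        iu, ju = np.triu_indices(nb)
        probs = grid[iu, ju].astype(float)
        probs /= probs.sum()
        counts = rng.multinomial(n, probs)
        sel = np.nonzero(counts)[0]
        bi = np.repeat(iu[sel], counts[sel])
        bj = np.repeat(ju[sel], counts[sel])
        length = sizes[chrom]
        posA = np.minimum(bi * bs + rng.integers(0, bs, size=len(bi)), length - 1)
        posB = np.minimum(bj * bs + rng.integers(0, bs, size=len(bj)), length - 1)
        allelesA = _observed_alleles(truth, chrom, posA, posA + read_len, hap, rng, error_rate)
        allelesB = _observed_alleles(truth, chrom, posB, posB + read_len, hap, rng, error_rate)
        parts.append(
            pd.DataFrame(
                {
                    "chromA": chrom, "posA": posA,
                    "chromB": chrom, "posB": posB,
                    "true_hap": hap, "allelesA": allelesA, "allelesB": allelesB,
                }
            )
        )

    if n_trans > 0 and len(truth.spec.chromosomes) >= 2:
        names = [c for c, _ in truth.spec.chromosomes]
        lens = np.array([sizes[c] for c in names], dtype=float)
        p = lens / lens.sum()
        recs = {k: [] for k in cols}
        for _ in range(n_trans):
            a, b = rng.choice(len(names), size=2, replace=False, p=p)
            hap = HAPLOTYPES[int(rng.integers(0, 2))]
            pa = int(rng.integers(0, sizes[names[a]]))
            pb = int(rng.integers(0, sizes[names[b]]))
            recs["chromA"].append(names[a]); recs["posA"].append(pa)
            recs["chromB"].append(names[b]); recs["posB"].append(pb)
            recs["true_hap"].append(hap)
            recs["allelesA"].append(
                _observed_alleles(truth, names[a], np.array([pa]), np.array([pa + read_len]), hap, rng, error_rate)[0]
            )
            recs["allelesB"].append(
                _observed_alleles(truth, names[b], np.array([pb]), np.array([pb + read_len]), hap, rng, error_rate)[0]
            )
        parts.append(pd.DataFrame(recs))
    if not parts:
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: TrioTruth,
    n_genes: int = 300,
    noise_sd: float = 0.2,
    seed: int = 0,
    gene_length: int = 10_000,
    eqtl_prob: float = 0.3,
):
    """Place genes and generate control/trisomy expression under the
    multiplicative dosage model

        E_trisomy = E_control * (VC_t * prod VF_t) / (VC_c * prod VF_c)
                    * V_similarity * exp(N(0, noise_sd)).

    VC is copy number relative to diploid (1.5 on the trisomy chromosome),
    VF are per-eQTL fold changes, and V_similarity is < 1 only for genes
    overlapping a structurally divergent window. Returns
    ``(control_table, trisomy_table, eqtl_table)`` and records all
    parameters in ``truth``.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    total_len = sum(l for _, l in truth.spec.chromosomes)
    gene_rows = []
    gid = 0
    for chrom, length in truth.spec.chromosomes:
        k = int(round(n_genes * length / total_len))
        if gid + k > n_genes or chrom == truth.spec.chromosomes[-1][0]:
            k = n_genes - gid
        if k <= 0:
            continue
        slot = length // max(k, 1)
        for s in range(k):
            lo = s * slot
            start = lo + int(rng.integers(0, max(slot - gene_length, 1)))
            gene_rows.append((f"g{gid:05d}", chrom, start, min(start + gene_length, length)))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])

    divergent = truth.divergent_windows
    params = []
    eqtl_rows = []
    for g in genes.itertuples():
        e_control = float(rng.lognormal(mean=3.0, sigma=1.0))
        vc_case = truth.total_copies(g.chrom) / 2.0
        vc_control = 1.0
        vf_case, vf_control = 1.0, 1.0
        for sample, holder in (("case", "vf_case"), ("control", "vf_control")):
            if rng.random() < eqtl_prob:
                n_eqtl = int(rng.integers(1, 3))
                for k in range(n_eqtl):
                    vf = float(rng.lognormal(0.0, 0.25))
                    eqtl_rows.append((g.gene_id, f"{g.gene_id}_v{sample}{k}", vf, sample))
                    if sample == "case":
                        vf_case *= vf
                    else:
                        vf_control *= vf
        in_divergent = any(
            g.start < w_end and g.end > w_start for w_start, w_end in divergent.get(g.chrom, [])
        )
        v_sim = float(rng.uniform(0.5, 0.9)) if in_divergent else 1.0
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        e_case = e_control * (vc_case * vf_case) / (vc_control * vf_control) * v_sim * noise
        params.append(
            (g.gene_id, e_control, e_case, vc_case, vc_control, vf_case, vf_control, v_sim, noise_sd)
        )
    expr_params = pd.DataFrame(
        params,
        columns=[
            "gene_id", "e_control", "e_case", "vc_case", "vc_control",
            "vf_case_prod", "vf_control_prod", "v_similarity", "noise_sd",
        ],
    )
    truth.genes = genes
    truth.expr_params = expr_params
    control = expr_params[["gene_id", "e_control"]].rename(columns={"e_control": "count"})
    trisomy = expr_params[["gene_id", "e_case"]].rename(columns={"e_case": "count"})
    eqtl = pd.DataFrame(eqtl_rows, columns=["gene_id", "variant_id", "fold_change", "sample"])
    return control, trisomy, eqtl
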