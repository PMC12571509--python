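# Methods

This note documents the model implemented by `triohap3d`, the synthetic
trio generator used to validate it, the main numerical choices, and the
design decisions that were left open by the problem statement.

## 1. Trio phasing

Genotypes of father, mother, and child are compared per SNP site:

- **shared** — alternate allele present in both parents and the child.
  Shared sites are uninformative for haplotype assignment.
- **parent-specific** — alternate allele in exactly one parent. The site is
  flagged **transmitted** when it is also present in the child; only
  transmitted parent-specific sites are used for assignment.
- **excluded** — sites seen only in the child (de novo or genotyping
  error), and sites seen in both parents but not the child. Conflicting
  alternate alleles at one position exclude all records at that position
  and emit a warning.

A sequencing fragment (or RNA read) is assigned to the **paternal** or
**maternal** haplotype when it carries the alternate allele at one or more
transmitted sites specific to that parent. Evidence for both parents is a
**conflict** and the fragment is discarded from haplotype-resolved
analyses; no evidence leaves the fragment **unassigned** (it still
contributes to bulk analyses). Hi-C contacts pool the allele evidence of
both read ends before applying the same rule. Coordinates are 0-based
half-open everywhere in memory; 1-based coordinates appear only in VCF
files on disk.

The per-window SNP-density difference score is the absolute difference of
paternal- and maternal-specific transmitted SNP counts per window. Using
the absolute difference (rather than a signed or normalized quantity) was a
design choice: it makes "high density difference" symmetric in the parents.

## 2. Copy number

Fragment midpoints are histogrammed in fixed-size bins (default 100 kb).
Two estimators operate on the binned counts:

- **Per-haplotype integer copies.** Bin counts are clustered with k-means,
  selecting k over 1–4 by silhouette score (k = 1 only when all counts are
  equal; k is also capped by the number of distinct values). The modal
  cluster is anchored at the baseline copy (1 for a haplotype, 2 for bulk)
  and other clusters get the rounded ratio of their mean to the modal mean.
  This is a deliberately simple stand-in for a dedicated read-depth CNV
  caller; it is adequate because the simulated depth differences are large
  (integer copy steps at ≥10× coverage).
- **Bulk dosage change ratio.** Each sample's bin counts are normalized by
  the sample's genome-wide median over non-zero bins (optionally excluding
  declared CNV regions from that baseline); the change ratio of a region is
  the ratio of case to control mean normalized depth. The genome must
  contain enough diploid territory that the median sits on diploid bins —
  this is why validation genomes pair the trisomic chromosome with a
  larger diploid chromosome.

Haplotype copy-number similarity per 1-Mb window is
`min(C_p, C_m) / max(C_p, C_m)` of the window-mean copies, defined as 1
when both are zero. The min/max form is a bounded, symmetric similarity in
[0, 1]; it is our choice of summary, not a canonical statistic.

## 3. 3D genome structure

Contact matrices are dense symmetric per-chromosome matrices at a fixed
bin size (default 50 kb), optionally restricted to contacts assigned to one
haplotype. Matrix similarity is the Pearson correlation over the upper
triangle (NaN bins pairwise-excluded).

**Compartments.** The matrix is observed/expected-normalized per diagonal,
converted to a correlation matrix, and the leading eigenvector scaled by
the square root of its eigenvalue is the PC1 track. Its global sign is
chosen to correlate positively with an orientation track (gene density in
the pipeline). Bins with PC1 > 0 are A, < 0 are B; zero-coverage bins are
NA. At least 10 informative bins are required. The case/control change
ratio per bin is

    ratio = |PC1_case − PC1_control| / max(|PC1_case|, |PC1_control|)

with a bin called altered when ratio > 0.5 **or** the A/B label switches.
We read the denominator as the max of absolute values (so the ratio is
scale-free and in [0, 2]); a ratio of exactly 0.5 is conserved (strict
inequality).

**TADs.** The insulation score of a bin is the mean contact count in a
square window (default 3 bins) straddling the bin. Boundaries are local
insulation minima deeper than one standard deviation below the mean; TADs
are the intervals between consecutive boundaries. A case TAD is
**conserved** when *some* control TAD overlaps it by more than 90% of the
length of the larger of the two TADs, otherwise altered. This insulation
caller is a transparent stand-in for production TAD callers; the
conservation rule, not the caller, is the validated contract.

**Loops.** A pixel is a loop candidate when its count exceeds a
donut-shaped local background (ring of half-width 2 bins excluding the
center 3×3), at least 3 bins off the diagonal, with a minimum count of 3
(suppresses single-contact pixels on empty background). Significance is a
Poisson upper-tail test against the donut expectation with
Benjamini–Hochberg correction at α = 0.05. A case loop is conserved when a
control loop lies within 5 bins in both anchors.

## 4. Expression

Normalization is median-of-ratios: per-sample size factors are the median
over all-positive genes of count / geometric-mean, re-centered so the size
factors have geometric mean 1 (making normalization idempotent). Fold
change uses a pseudocount of 1 by default. Haplotype-resolved expression
counts phased RNA fragment midpoints per gene exon, normalizes by each
haplotype's total informative coverage, and reports the maternal/paternal
ratio.

## 5. Prediction

The expected case expression of a gene is

    E_case = E_control × (VC_case × ∏ VF_case) / (VC_control × ∏ VF_control) × V_similarity

with VC the copy-number value (copy / 2; 1.5 for a gene on the trisomic
chromosome, 1 without CNV), VF the fold changes of regulatory variants
acting on the gene in that sample, and V_similarity ∈ (0, 1] a
haplotype-structure similarity discount (floored at 0.01). A prediction is
correct when |log2(predicted / observed)| ≤ log2(1.5); accuracy is the
fraction of correct genes.

## 6. Region classification and enrichment

100-kb windows are classified with precedence
both > abnormal_cnv > high_snp > consistent > other:

- **abnormal_cnv** — case copy differs from control copy in the window;
- **high_snp** — SNP-density difference at least 2× the control and
  exceeding it by ≥ 100, with control below it;
- **both** — both conditions;
- **consistent** — normal CNV and low (≤ 10) density difference in both;
- **other** — anything else.

Enrichment of structural alterations in a class is a 2×2 chi-square test
(no Yates correction) with the odds ratio and Woolf's log-normal 95%
confidence interval; Haldane's +0.5 correction is applied when any cell is
zero.

## 7. Synthetic trio generator

The generator emulates, at reduced scale, the data of a trio study with a
maternal-origin trisomy-21 case:

- **Genome.** Default two chromosomes (10-Mb "chr1", 5-Mb "chr21"); the
  trisomic chromosome carries two copies of the origin parent's haplotype.
  SNPs are placed per parent at a configurable rate (default 10⁻³/bp
  specific, half that shared), with a fraction (default 0.1)
  non-transmitted.
- **WGS/RNA fragments.** Per-haplotype Poisson fragment counts proportional
  to copy number (bulk coverage is stated for the diploid state, so a
  trisomic chromosome is covered at 1.5×). Fragments record the true
  haplotype and the observed alleles at covered SNP sites (optionally with
  a base-error rate). RNA fragments are drawn per gene proportional to
  control expression × copy dosage.
- **Hi-C contacts.** Cis contacts are drawn from per-(chromosome,
  haplotype) probability grids: distance decay 1/(1 + d) modulated by
  compartment checkerboard (3×), TAD blocks (5×), and loop pixels (50×);
  the cis fraction defaults to 0.9993. Maternal structure diverges from
  paternal in random 1-Mb windows (probability 0.3 per window): flipped
  compartment labels, dissolved TAD boundaries, relocated loops.
- **Expression.** Control expression is log-normal; case expression is
  generated *exactly* under the prediction equation (trisomy dosage,
  per-gene regulatory fold changes with probability 0.3, V_similarity drawn
  from U(0.5, 0.9) for genes in divergent windows) times log-normal noise
  exp(N(0, σ)). This closes the loop: with σ = 0 the predictor must recover
  every gene.

**What the generator does not emulate:** mappability and GC bias, read
pairs and fragment-size distributions, genotyping error in the parents,
structural variants other than whole-chromosome trisomy, distance-dependent
Hi-C noise structure, RNA isoforms, and biological inter-individual
variability. Published headline percentages from real trios (e.g. specific
prediction accuracies or genome-wide cis fractions) are therefore not
reproduction targets; the validated claims are the structural and
statistical properties above.

## 8. Key parameters

| Parameter | Default | Rationale |
|---|---|---|
| CNV bin size | 100 kb | matches the dosage analyses; ≥10× coverage gives ~1000 fragments/bin |
| k-means k range | 1–4 | copy states 0–3 expected in a trisomy study |
| Structure bin size | 50 kb | resolves 300–600-kb TADs in multi-Mb toy chromosomes |
| Compartment change threshold | 0.5 | altered iff ratio > 0.5 (strict) or label switch |
| TAD conservation overlap | > 0.9 × larger TAD | strong reciprocal-style overlap |
| Loop conservation window | 5 bins per anchor | tolerant to caller jitter |
| Loop FDR / min distance / min count | 0.05 / 3 bins / 3 | BH-corrected donut-Poisson; excludes diagonal; suppresses empty-background artifacts |
| Prediction tolerance | 1.5-fold | correctness = within 1.5× of observed |
| High-SNP window rule | ratio ≥ 2 and excess ≥ 100; low ≤ 10 | separates planted density differences from Poisson noise at default SNP rates |
| Cis fraction | 0.9993 | high-quality in-situ Hi-C regime |
| Similarity floor | 0.01 | keeps Eq. predictions finite and positive |

Problem sizes used in tests and the acceptance script (multi-Mb
chromosomes, 10× coverage, 5×10⁵ contacts) are the package's own choice:
large enough that every statistic is in its asymptotic regime, small enough
to run the whole validation suite in well under a minute.

## 9. Open design decisions

- The change-ratio denominator (max of absolute PC1 values) and strict
  inequality at 0.5 are our reading; both are pinned by hand-value tests.
- SNP-density difference is an absolute count difference, not a rate.
- The min/max haplotype CNV similarity and the insulation/donut callers are
  transparent stand-ins for heavier production tools; results depending on
  caller internals are out of scope.
- The raw maternal/paternal informative-contact ratio on the trisomic
  chromosome is biased by the chance asymmetry of informative SNP density
  between haplotypes; tests normalize it against a diploid control sharing
  the same SNPs.
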