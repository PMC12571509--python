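"""End-to-end haplotype-resolved analysis on a synthetic trio.

Runs every stage in dependency order on generated data: trio SNP
classification, fragment/contact haplotype splitting, bulk and
per-haplotype CNV, contact matrices with compartments/TADs/loops and
their conservation calls, haplotype expression, region enrichment, and
expression prediction. All randomness flows from the single config seed;
outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv, enrichment, expression, hic, io, phasing, prediction, simulate
from .config import PipelineConfig

log = logging.getLogger("triohap3d")


def _trio_variant_sets(truth: simulate.TrioTruth):
    """Father/mother/child site sets implied by the truth SNP table."""
    father, mother, child = set(), set(), set()
    for r in truth.snps.itertuples():
        site = (r.chrom, int(r.pos), r.ref, r.alt)
        if r.category == "shared":
            father.add(site)
            mother.add(site)
            child.add(site)
        elif r.category == "paternal_specific":
            father.add(site)
            if r.transmitted:
                child.add(site)
        elif r.category == "maternal_specific":
            mother.add(site)
            if r.transmitted:
                child.add(site)
    return father, mother, child


def diploid_control(truth: simulate.TrioTruth) -> simulate.TrioTruth:
    """A control individual sharing the trio's genome design but diploid
    everywhere (copy 1/1 on every chromosome)."""
    ctl = copy.copy(truth)
    ctl.copy_counts = {c: {simulate.PATERNAL: 1, simulate.MATERNAL: 1} for c in truth.copy_counts}
    return ctl


def _gene_density_track(genes: pd.DataFrame, chrom: str, n_bins: int, bin_size: int) -> np.ndarray:
    track = np.zeros(n_bins)
    for g in genes[genes.chrom == chrom].itertuples():
        track[g.start // bin_size : int(np.ceil(g.end / bin_size))] += 1
    return track


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; write per-stage tables plus summary.json; return
    the summary dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in
             ("genome", "expr", "wgs_case", "wgs_control", "rna", "hic_case", "hic_control")}

    spec = simulate.GenomeSpec(
        chromosomes=tuple((c, int(l)) for c, l in config.chromosomes),
        snp_rate=config.snp_rate,
        trisomy_chrom=config.trisomy_chrom,
        trisomy_origin=config.trisomy_origin,
        seed=seeds["genome"],
    )
    truth = simulate.simulate_trio_genomes(spec)
    control_truth = diploid_control(truth)
    sizes = spec.chrom_sizes
    summary: dict = {"config_seed": config.seed, "chromosomes": config.chromosomes}

    # --- synthetic data -----------------------------------------------------
    control_expr, trisomy_expr, eqtl = simulate.simulate_expression(
        truth, n_genes=config.n_genes, noise_sd=config.expression_noise_sd, seed=seeds["expr"]
    )
    control_truth.genes = truth.genes
    control_truth.expr_params = truth.expr_params
    wgs_case = simulate.simulate_fragments(
        truth, coverage=config.wgs_coverage, frag_len=config.frag_len, seed=seeds["wgs_case"]
    )
    wgs_control = simulate.simulate_fragments(
        control_truth, coverage=config.wgs_coverage, frag_len=config.frag_len,
        seed=seeds["wgs_control"],
    )
    rna = simulate.simulate_fragments(
        truth, library="rna", frag_len=config.frag_len, seed=seeds["rna"],
        n_fragments=config.rna_fragments,
    )
    contacts_case = simulate.simulate_contacts(
        truth, n_contacts=config.n_contacts, cis_fraction=config.cis_fraction,
        seed=seeds["hic_case"],
    )
    contacts_control = simulate.simulate_contacts(
        control_truth, n_contacts=config.n_contacts, cis_fraction=config.cis_fraction,
        seed=seeds["hic_control"],
    )

    # --- phasing ------------------------------------------------------------
    father, mother, child = _trio_variant_sets(truth)
    table = phasing.classify_snps(father, mother, child)
    table.df.to_csv(outdir / "phased_snps.tsv", sep="\t", index=False)
    summary["snp_categories"] = table.counts()

    pat_wgs, mat_wgs, wgs_report = phasing.split_library(wgs_case, table)
    summary["wgs_assignment"] = wgs_report
    pat_rna, mat_rna, rna_report = phasing.split_library(rna, table)
    summary["rna_assignment"] = rna_report
    tagged_case = phasing.assign_contacts(contacts_case, table)

    # --- CNV ----------------------------------------------------------------
    case_bins = cnv.bin_fragment_frequencies(wgs_case, config.cnv_bin_size, sizes)
    control_bins = cnv.bin_fragment_frequencies(wgs_control, config.cnv_bin_size, sizes)
    tri_len = sizes[config.trisomy_chrom]
    ratio = cnv.cnv_change_ratio(case_bins, control_bins, (config.trisomy_chrom, 0, tri_len))
    summary["cnv_change_ratio_trisomy_chrom"] = ratio

    pat_bins = cnv.bin_fragment_frequencies(pat_wgs, config.cnv_bin_size, sizes)
    mat_bins = cnv.bin_fragment_frequencies(mat_wgs, config.cnv_bin_size, sizes)
    mask = (pat_bins["count"].to_numpy() == 0) & (mat_bins["count"].to_numpy() == 0)
    pat_profile = cnv.kmeans_copy_number(pat_bins, seed=config.seed, haplotype="paternal", mask=mask)
    mat_profile = cnv.kmeans_copy_number(mat_bins, seed=config.seed, haplotype="maternal", mask=mask)
    for prof, name in ((pat_profile, "paternal"), (mat_profile, "maternal")):
        io.write_bed(prof.df.assign(end=prof.df.start + config.cnv_bin_size),
                     outdir / f"cnv_{name}.bed", extra_cols=["copy"])
    tri_mat = mat_profile.region_bins(config.trisomy_chrom)
    tri_pat = pat_profile.region_bins(config.trisomy_chrom)
    summary["haplotype_copy_trisomy_chrom"] = {
        "maternal_mode": int(tri_mat[tri_mat["copy"] >= 0]["copy"].mode().iloc[0]),
        "paternal_mode": int(tri_pat[tri_pat["copy"] >= 0]["copy"].mode().iloc[0]),
    }
    cnv_sim = cnv.cnv_similarity(pat_profile, mat_profile, window=10 * config.cnv_bin_size)
    cnv_sim.to_csv(outdir / "cnv_similarity.tsv", sep="\t", index=False)

    # --- Hi-C ---------------------------------------------------------------
    bs = config.compartment_bin_size
    structure = {}
    for chrom in sizes:
        m_case = hic.build_contact_matrix(contacts_case, bs, chrom, sizes[chrom])
        m_control = hic.build_contact_matrix(contacts_control, bs, chrom, sizes[chrom])
        io.write_matrix(m_case, outdir / f"matrix_case_{chrom}.tsv")
        sim = hic.matrix_similarity(m_case, m_control)
        track = _gene_density_track(truth.genes, chrom, m_case.n_bins, bs)
        comp_case = hic.compute_compartments(m_case, track)
        comp_control = hic.compute_compartments(m_control, track)
        change = hic.compartment_change_ratio(comp_case, comp_control)
        io.write_bedgraph(chrom, bs, comp_case.pc1, outdir / f"pc1_case_{chrom}.bedgraph")
        tads_case = hic.call_tads(m_case)
        tads_control = hic.call_tads(m_control)
        tad_calls = hic.classify_tads(tads_case, tads_control)
        loops_case = hic.call_loops(m_case)
        loops_control = hic.call_loops(m_control)
        loop_calls = hic.classify_loops(loops_case, loops_control, window=config.loop_window)
        structure[chrom] = {
            "matrix_similarity": sim,
            "compartment_altered_bins": int((change.df.call == "altered").sum()),
            "compartment_bins": int((change.df.call != "NA").sum()),
            "tads": int(len(tad_calls)),
            "tads_conserved": int((tad_calls.call == "conserved").sum()),
            "loops": int(len(loop_calls)),
            "loops_conserved": int((loop_calls.call == "conserved").sum()),
        }
        tad_calls.to_csv(outdir / f"tads_{chrom}.tsv", sep="\t", index=False)
        loop_calls.to_csv(outdir / f"loops_{chrom}.tsv", sep="\t", index=False)
    summary["structure"] = structure

    # haplotype-resolved matrices on the trisomy chromosome
    chrom = config.trisomy_chrom
    pat_m = hic.build_contact_matrix(tagged_case, bs, chrom, sizes[chrom], haplotype_filter="paternal")
    mat_m = hic.build_contact_matrix(tagged_case, bs, chrom, sizes[chrom], haplotype_filter="maternal")
    summary["haplotype_hic_trisomy_chrom"] = hic.haplotype_interaction_summary(pat_m, mat_m)
    cis = int((contacts_case.chromA == contacts_case.chromB).sum())
    summary["cis_fraction"] = cis / len(contacts_case) if len(contacts_case) else float("nan")

    # --- expression ---------------------------------------------------------
    counts = pd.DataFrame(
        {
            "control": control_expr.set_index("gene_id")["count"],
            "case": trisomy_expr.set_index("gene_id")["count"],
        }
    )
    sf, norm = expression.normalize_counts(counts)
    fc = expression.fold_change(norm, "case", "control")
    norm.to_csv(outdir / "expression_normalized.tsv", sep="\t")
    hap_expr = expression.haplotype_expression(pat_rna, mat_rna, truth.genes)
    hap_expr.to_csv(outdir / "haplotype_expression.tsv", sep="\t", index=False)
    tri_genes = truth.genes.chrom == config.trisomy_chrom
    summary["median_fc_trisomy_genes"] = float(fc[truth.genes[tri_genes].gene_id].median())

    # --- enrichment ---------------------------------------------------------
    cnv_events = [(config.trisomy_chrom, 0, tri_len)]
    snp_case = {
        c: truth.snps[(truth.snps.chrom == c) & truth.snps.transmitted].pos.to_numpy()
        for c in sizes
    }
    snp_control = {c: snp_case[c][::2] for c in sizes}  # control carries half the density
    classification = enrichment.classify_regions(
        cnv_events, [], snp_case, snp_control, sizes,
        window=config.snp_density_window,
        high_snp_excess=config.high_snp_excess, low_snp_max=config.low_snp_max,
    )
    classification.to_csv(outdir / "region_classes.tsv", sep="\t", index=False)
    altered = [
        (config.trisomy_chrom, int(r.start), int(r.start + bs))
        for r in pd.read_csv(outdir / f"tads_{config.trisomy_chrom}.tsv", sep="\t").itertuples()
        if r.call == "altered"
    ]
    enr = {}
    for cls in ("abnormal_cnv", "consistent"):
        if (classification["class"] == cls).any() and altered:
            res = enrichment.feature_enrichment(altered, classification, cls)
            enr[cls] = {"odds_ratio": res.odds_ratio, "pvalue": res.pvalue}
    summary["enrichment"] = enr

    # --- prediction ---------------------------------------------------------
    cnv_calls = pd.DataFrame(
        [(config.trisomy_chrom, 0, tri_len, 3)], columns=["chrom", "start", "end", "copy"]
    )
    sim_series = truth.expr_params.set_index("gene_id")["v_similarity"]
    result = prediction.predict_table(
        control_expr.set_index("gene_id")["count"],
        trisomy_expr.set_index("gene_id")["count"],
        truth.genes,
        cnv_case=cnv_calls,
        eqtl=eqtl,
        similarity=sim_series,
        tolerance_fold=config.accuracy_tolerance_fold,
    )
    result.df.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    result_nosim = prediction.predict_table(
        control_expr.set_index("gene_id")["count"],
        trisomy_expr.set_index("gene_id")["count"],
        truth.genes,
        cnv_case=cnv_calls,
        eqtl=eqtl,
        similarity=None,
        tolerance_fold=config.accuracy_tolerance_fold,
    )
    summary["prediction_accuracy"] = result.accuracy
    summary["prediction_accuracy_without_similarity"] = result_nosim.accuracy

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary
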