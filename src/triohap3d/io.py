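"""Readers and writers for the interchange formats.

VCF is 1-based (converted to the package's 0-based internal positions on
read); BED/pairs/fragments are 0-based half-open. Contact matrices
persist as sorted triplet text (bin_i bin_j count, upper triangle) with
a JSON sidecar header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .hic import ContactMatrix


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(sites: pd.DataFrame, path, sample: str, chrom_sizes: dict[str, int] | None = None):
    """Write heterozygous sites (chrom, pos 0-based, ref, alt) as a
    minimal single-sample VCF with GT 0/1."""
    contigs = ""
    if chrom_sizes:
        contigs = "".join(
            f"##contig=<ID={c},length={l}>\n" for c, l in chrom_sizes.items()
        )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for r in sites.sort_values(["chrom", "pos"]).itertuples():
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t0/1\n")


def read_vcf(path) -> set[tuple[str, int, str, str]]:
    """Sites where the sample carries an alternate allele, as
    (chrom, pos 0-based, ref, alt); multiallelic records are split."""
    out = set()
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                carried = True
                if samples:
                    carried = any(
                        alt_idx in (rec.samples[s]["GT"] or ()) for s in samples
                    )
                if carried:
                    out.add((rec.chrom, rec.pos - 1, rec.ref, alt))
    return out


# ---------------------------------------------------------------------------
# fragments / pairs


def _encode_alleles(alleles) -> str:
    return "|".join(f"{p}:{b}" for p, b in alleles) if alleles else "."


def _decode_alleles(text: str):
    if text == "." or not text:
        return ()
    return tuple((int(p), b) for p, b in (item.split(":") for item in text.split("|")))


def write_fragments(fragments: pd.DataFrame, path):
    df = fragments.copy()
    df["alleles"] = [_encode_alleles(a) for a in df["alleles"]]
    cols = ["chrom", "start", "end", "frag_id", "alleles"]
    if "true_hap" in df.columns:
        cols.append("true_hap")
    df[cols].to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = _read_tsv(path, {"chrom", "start", "end", "frag_id", "alleles"})
    df["alleles"] = [_decode_alleles(str(a)) for a in df["alleles"]]
    return df


def write_pairs(pairs: pd.DataFrame, path):
    df = pairs.copy()
    for col in ("allelesA", "allelesB"):
        if col in df.columns:
            df[col] = [_encode_alleles(a) for a in df[col]]
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = _read_tsv(path, {"chromA", "posA", "chromB", "posB"})
    for col in ("allelesA", "allelesB"):
        if col in df.columns:
            df[col] = [_decode_alleles(str(a)) for a in df[col]]
    return df


def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: {e}") from e
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    # integer sanity on coordinate columns, reporting the first bad line
    for col in required & {"start", "end", "posA", "posB", "pos"}:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
    return df


# ---------------------------------------------------------------------------
# BED / BEDPE / counts / bedgraph


def write_bed(df: pd.DataFrame, path, extra_cols=()):
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, extra_cols=()) -> pd.DataFrame:
    cols = ["chrom", "start", "end", *extra_cols]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=cols)
    if df.shape[1] < len(cols):
        raise ParseError(f"{path}: expected >= {len(cols)} columns")
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df


def write_bedpe(loops: pd.DataFrame, path, bin_size: int):
    """Loop calls (chrom, bin_i, bin_j, ...) as BEDPE anchor intervals."""
    rows = []
    for l in loops.itertuples():
        rows.append(
            (
                l.chrom, l.bin_i * bin_size, (l.bin_i + 1) * bin_size,
                l.chrom, l.bin_j * bin_size, (l.bin_j + 1) * bin_size,
                getattr(l, "pvalue", "."),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path, bin_size: int) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[1] < 6:
        raise ParseError(f"{path}: BEDPE needs >= 6 columns")
    return pd.DataFrame(
        {
            "chrom": raw[0],
            "bin_i": raw[1] // bin_size,
            "bin_j": raw[4] // bin_size,
        }
    )


def write_counts(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=True)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bedgraph(chrom: str, bin_size: int, values: np.ndarray, path):
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# contact matrix triplets


def write_matrix(matrix: ContactMatrix, path):
    """Sorted upper-triangle triplet text plus a .json sidecar header."""
    path = Path(path)
    iu, ju = np.triu_indices(matrix.n_bins)
    vals = matrix.matrix[iu, ju]
    nz = vals != 0
    trip = pd.DataFrame({"bin1": iu[nz], "bin2": ju[nz], "count": vals[nz]})
    trip.sort_values(["bin1", "bin2"]).to_csv(path, sep="\t", index=False)
    header = {
        "chrom": matrix.chrom,
        "bin_size": matrix.bin_size,
        "n_bins": matrix.n_bins,
        "haplotype": matrix.haplotype,
        "cis_pairs": matrix.cis_pairs,
        "trans_pairs": matrix.trans_pairs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def read_matrix(path) -> ContactMatrix:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    trip = pd.read_csv(path, sep="\t")
    n = header["n_bins"]
    mat = np.zeros((n, n))
    bi = trip.bin1.to_numpy(dtype=int)
    bj = trip.bin2.to_numpy(dtype=int)
    mat[bi, bj] = trip["count"].to_numpy()
    mat[bj, bi] = trip["count"].to_numpy()
    return ContactMatrix(
        chrom=header["chrom"],
        bin_size=header["bin_size"],
        matrix=mat,
        haplotype=header.get("haplotype", "bulk"),
        cis_pairs=header.get("cis_pairs", 0),
        trans_pairs=header.get("trans_pairs", 0),
    )
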