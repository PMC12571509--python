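"""Trisomy gene expression prediction from 1D and 3D features.

The predicted trisomy expression of a gene is

    E_case = E_control * (VC_case * prod_i VF_case_i)
                       / (VC_control * prod_j VF_control_j) * V_similarity

where VC is the gene's copy number relative to diploid (1 when no
significant CNV event overlaps the gene, 1.5 for a trisomic gene), VF
are eQTL fold changes attributed to each sample's genotype, and
V_similarity is the case/control Hi-C matrix similarity over the gene
body. A prediction is counted correct when it is within a fold-change
tolerance of the observed value on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def copy_number_value(gene: tuple[str, int, int], cnv_calls: pd.DataFrame) -> float:
    """VC for a gene: copy/2 of the best-overlapping significant CNV
    call, or 1 when no call overlaps the gene."""
    chrom, start, end = gene
    if cnv_calls is None or cnv_calls.empty:
        return 1.0
    sub = cnv_calls[(cnv_calls.chrom == chrom) & (cnv_calls.start < end) & (cnv_calls.end > start)]
    if sub.empty:
        return 1.0
    ov = np.minimum(sub.end, end) - np.maximum(sub.start, start)
    best = sub.iloc[int(np.argmax(ov))]
    return float(best["copy"]) / 2.0


def predict_expression(
    e_control: float,
    vc_case: float,
    vf_case: list[float] | tuple = (),
    vc_control: float = 1.0,
    vf_control: list[float] | tuple = (),
    v_similarity: float = 1.0,
) -> float:
    """Multiplicative dosage/eQTL/similarity prediction (see module doc)."""
    if e_control < 0:
        raise ValueError("e_control must be >= 0")
    if vc_control <= 0:
        raise ValueError("vc_control must be positive")
    if not 0 < v_similarity <= 1:
        raise ValueError("v_similarity must be in (0, 1]")
    return (
        e_control
        * (vc_case * math.prod(vf_case))
        / (vc_control * math.prod(vf_control))
        * v_similarity
    )


@dataclass
class PredictionResult:
    """Per-gene predictions with observed values and correctness flags."""

    df: pd.DataFrame  # gene_id, e_control, e_predicted, e_observed, correct
    tolerance_fold: float

    @property
    def accuracy(self) -> float:
        return float(self.df.correct.mean())


def predict_table(
    control_expression: pd.Series,
    observed_expression: pd.Series,
    genes: pd.DataFrame,
    cnv_case: pd.DataFrame | None = None,
    cnv_control: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    similarity: pd.Series | None = None,
    similarity_floor: float = 0.01,
    tolerance_fold: float = 1.5,
) -> PredictionResult:
    """Run the prediction for every gene in ``genes``.

    ``eqtl`` has columns (gene_id, variant_id, fold_change, sample) with
    sample in {case, control}; ``similarity`` maps gene_id to gene-body
    Hi-C similarity (values <= 0 are floored at ``similarity_floor`` to
    keep predictions positive; missing genes default to 1).
    """
    vf_case: dict[str, list] = {}
    vf_control: dict[str, list] = {}
    if eqtl is not None and len(eqtl):
        for r in eqtl.itertuples():
            (vf_case if r.sample == "case" else vf_control).setdefault(r.gene_id, []).append(
                float(r.fold_change)
            )
    rows = []
    for g in genes.itertuples():
        e_c = float(control_expression.get(g.gene_id, np.nan))
        e_obs = float(observed_expression.get(g.gene_id, np.nan))
        if np.isnan(e_c) or np.isnan(e_obs):
            continue
        vc_t = copy_number_value((g.chrom, g.start, g.end), cnv_case)
        vc_c = copy_number_value((g.chrom, g.start, g.end), cnv_control)
        v_sim = 1.0
        if similarity is not None and g.gene_id in similarity.index:
            v = similarity[g.gene_id]
            if np.isfinite(v):
                v_sim = max(float(v), similarity_floor)
        pred = predict_expression(
            e_c, vc_t, vf_case.get(g.gene_id, ()), max(vc_c, similarity_floor),
            vf_control.get(g.gene_id, ()), min(v_sim, 1.0),
        )
        rows.append((g.gene_id, e_c, pred, e_obs, _is_correct(pred, e_obs, tolerance_fold)))
    df = pd.DataFrame(
        rows, columns=["gene_id", "e_control", "e_predicted", "e_observed", "correct"]
    )
    return PredictionResult(df, tolerance_fold)


def _is_correct(pred: float, obs: float, tolerance_fold: float) -> bool:
    if pred == 0 and obs == 0:
        return True
    if pred <= 0 or obs <= 0:
        return False
    return abs(math.log2(pred / obs)) <= math.log2(tolerance_fold)


def prediction_accuracy(results, tolerance_fold: float = 1.5) -> float:
    """Fraction of genes predicted within ``tolerance_fold`` of observed.

    ``results`` is a PredictionResult or a DataFrame with e_predicted /
    e_observed columns (re-scored at the given tolerance).
    """
    df = results.df if isinstance(results, PredictionResult) else results
    if df.empty:
        raise ValueError("no predictions to score")
    correct = [
        _is_correct(p, o, tolerance_fold) for p, o in zip(df.e_predicted, df.e_observed)
    ]
    return float(np.mean(correct))
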