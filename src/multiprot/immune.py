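"""Signature-based cell-type scoring (single-sample GSEA engine).

Each cell type is represented by a marker gene set; a sample's score is a
rank-based single-sample enrichment score (weighted ECDF difference between
in-set and out-of-set genes). Aggregates follow the microenvironment-score
convention: immune score = mean of immune-category cell scores, stroma
score = mean of stroma-category scores, microenvironment = immune + stroma.
The Th1/Th2 ratio is a per-sample prognostic / immunotherapy-response
indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, SignatureSet, ValidationError


def ssgsea_score(
    expression: pd.Series,
    gene_set,
    alpha: float = 0.25,
    min_overlap: int = 10,
) -> float:
    """Single-sample enrichment score of ``gene_set`` in one sample.

    Genes are ranked by descending expression; the score integrates the
    difference between the weighted in-set ECDF (weights |value|^alpha) and
    the unweighted out-of-set ECDF, divided by the number of out-of-set
    genes. The normalizing constant only sets the scale — every downstream
    use (ranks, ratios, clustering) is scale-free.
    """
    expr = expression.dropna()
    genes = set(gene_set.genes) if hasattr(gene_set, "genes") else set(gene_set)
    in_set = expr.index.isin(genes)
    n = expr.size
    m = int(in_set.sum())
    if m < min_overlap:
        raise ValidationError(
            f"gene set overlap {m} below min_overlap={min_overlap}"
        )
    if m == n:
        raise ValidationError("gene set covers every quantified gene")
    order = np.argsort(-expr.to_numpy(), kind="mergesort")
    in_sorted = in_set[order]
    vals_sorted = np.abs(expr.to_numpy()[order]) ** alpha
    w_in = np.where(in_sorted, vals_sorted, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        # all in-set values are zero; fall back to unweighted membership
        w_in = in_sorted.astype(float)
        denom_in = w_in.sum()
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(~in_sorted) / (n - m)
    return float(np.sum(cdf_in - cdf_out) / (n - m))


def cell_scores(
    expression: AbundanceMatrix | pd.DataFrame,
    signatures: SignatureSet,
    alpha: float = 0.25,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Sample × cell-type score table with immune / stroma / microenvironment
    aggregates. Signatures whose overlap with the quantified features falls
    below ``min_overlap`` are skipped (recorded in ``.attrs['skipped']``).
    """
    data = expression.data if isinstance(expression, AbundanceMatrix) else expression
    immune_sets = signatures.by_category("immune")
    if not immune_sets:
        raise ValidationError("no immune-category signatures; aggregates undefined")
    scores: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    usable = []
    for gs in signatures:
        overlap = len(gs.genes & set(data.index))
        if overlap < min_overlap:
            skipped.append(gs.name)
        else:
            usable.append(gs)
    for sample in data.columns:
        expr = data[sample]
        scores[sample] = {
            gs.name: ssgsea_score(expr, gs, alpha=alpha, min_overlap=min_overlap)
            for gs in usable
        }
    table = pd.DataFrame(scores).T  # samples x cell types
    immune_cols = [gs.name for gs in usable if gs.category == "immune"]
    stroma_cols = [gs.name for gs in usable if gs.category == "stroma"]
    if not immune_cols:
        raise ValidationError("no immune-category signatures passed the overlap floor")
    table["immune_score"] = table[immune_cols].mean(axis=1)
    table["stroma_score"] = (
        table[stroma_cols].mean(axis=1) if stroma_cols else 0.0
    )
    table["microenvironment_score"] = table["immune_score"] + table["stroma_score"]
    table.attrs["skipped"] = skipped
    table.attrs["cell_types"] = [gs.name for gs in usable]
    return table


def th1_th2_ratio(
    scores: pd.DataFrame,
    th1_col: str = "Th1",
    th2_col: str = "Th2",
    eps: float = 0.0,
) -> pd.Series:
    """Per-sample (Th1 + eps) / (Th2 + eps) score ratio.

    With scores positive by construction eps stays 0; samples whose Th2
    score (+ eps) is not positive get NaN and are listed in
    ``.attrs['undefined']``.
    """
    for col in (th1_col, th2_col):
        if col not in scores.columns:
            raise ValidationError(f"column {col!r} absent from score table")
    denom = scores[th2_col] + eps
    ratio = (scores[th1_col] + eps) / denom.where(denom > 0)
    ratio.name = "th1_th2_ratio"
    ratio.attrs["undefined"] = list(ratio.index[denom <= 0])
    return ratio
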