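"""Cell-cycle module scoring and phase assignment.

A module score compares the mean expression of a gene set against a
matched control set: genes are binned by average expression across samples
and controls are drawn from the same bin, so the score is centred at zero
for sets that behave like the background. Samples are assigned G1 / S /
G2M from their S and G2/M module scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, ValidationError


def module_score(
    expression: AbundanceMatrix | pd.DataFrame,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-sample module score: mean(set genes) - mean(control genes).

    Genes are cut into ``n_bins`` equal-frequency bins of average log2
    expression; for each set gene, ``n_ctrl`` control genes are drawn (with
    replacement) from the non-set genes of its bin. Empty bins fall back to
    the nearest bin that has non-set genes, with a warning.
    """
    data = expression.data if isinstance(expression, AbundanceMatrix) else expression
    genes = set(gene_set.genes) if hasattr(gene_set, "genes") else set(gene_set)
    present = sorted(genes & set(data.index))
    if len(present) < 2:
        raise ValidationError("gene set must overlap >= 2 quantified features")
    avg = data.mean(axis=1, skipna=True)
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    rng = np.random.default_rng(seed)
    non_set = avg.index[~avg.index.isin(present)]
    bin_members = {
        b: [g for g in avg.index[bins == b] if g not in genes] for b in range(n_bins)
    }
    control_genes: list[str] = []
    for g in present:
        b = int(bins[g])
        members = bin_members.get(b, [])
        if not members:
            warnings.warn(f"bin {b} has no non-set genes; using nearest bin")
            for offset in range(1, n_bins):
                for cand in (b - offset, b + offset):
                    if bin_members.get(cand):
                        members = bin_members[cand]
                        break
                if members:
                    break
            if not members:
                members = list(non_set)
        control_genes.extend(rng.choice(members, size=n_ctrl, replace=True))
    set_mean = data.loc[present].mean(axis=0, skipna=True)
    ctrl_mean = data.loc[control_genes].mean(axis=0, skipna=True)
    score = set_mean - ctrl_mean
    score.name = "module_score"
    return score


def assign_phase(s_score: float, g2m_score: float) -> str:
    """S if s > g2m and s > 0; G2M if g2m >= s and g2m > 0; else G1."""
    if s_score > g2m_score and s_score > 0:
        return "S"
    if g2m_score >= s_score and g2m_score > 0:
        return "G2M"
    return "G1"


def phase_assignments(
    expression: AbundanceMatrix | pd.DataFrame,
    s_genes,
    g2m_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score both modules and label every sample with its phase."""
    s = module_score(expression, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m = module_score(
        expression, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1
    )
    out = pd.DataFrame({"s_score": s, "g2m_score": g2m})
    out["phase"] = [
        assign_phase(a, b) for a, b in zip(out["s_score"], out["g2m_score"])
    ]
    return out
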