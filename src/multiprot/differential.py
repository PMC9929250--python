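"""Differential screens: paired tumor-vs-NAT and unpaired group contrasts.

Rank tests throughout (Wilcoxon signed-rank for paired tumor/NAT contrasts,
Mann-Whitney rank-sum for unpaired contrasts), Benjamini-Hochberg adjustment,
linear-scale fold changes, DEP calling at FC > 2 and adjusted p < 0.05, and
the six-group partition of features by their tumor/NAT ratios in the two
histologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import AbundanceMatrix, SampleInfo, ValidationError

FC_METHODS = ("mean_ratio", "median_ratio", "paired_median_of_ratios")


def paired_wilcoxon(tumor, nat) -> float:
    """Two-sided Wilcoxon signed-rank p for paired vectors.

    Zero differences are dropped (Wilcoxon's convention). The exact null is
    used for n <= 25 when the absolute differences are tie-free; otherwise
    the normal approximation with continuity and tie correction. All
    differences zero yields p = 1.
    """
    tumor = np.asarray(tumor, dtype=float)
    nat = np.asarray(nat, dtype=float)
    if tumor.shape != nat.shape:
        raise ValidationError("paired vectors must have equal length")
    diffs = tumor - nat
    diffs = diffs[~np.isnan(diffs)]
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    if nonzero.size < 3:
        # signed-rank cannot reject at conventional levels; exact p anyway
        method = "exact"
    else:
        ties = np.unique(np.abs(nonzero)).size < nonzero.size
        method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.pvalue)


def ranksum(group_a, group_b) -> float:
    """Two-sided Mann-Whitney rank-sum p; exact when min(n) <= 10 and tie-free."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("ranksum requires both groups non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_change(tumor, nat, method: str = "paired_median_of_ratios") -> float:
    """Linear-scale tumor/NAT ratio.

    ``mean_ratio``: mean(tumor)/mean(nat); ``median_ratio``:
    median(tumor)/median(nat); ``paired_median_of_ratios``: median of the
    per-pair ratios (requires equal lengths). Values must be positive
    (imputation precedes fold-change computation).
    """
    if method not in FC_METHODS:
        raise ValidationError(f"unknown fold-change method {method!r}")
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(nat, dtype=float)
    t = t[~np.isnan(t)] if method != "paired_median_of_ratios" else t
    n = n[~np.isnan(n)] if method != "paired_median_of_ratios" else n
    if method == "paired_median_of_ratios":
        if t.shape != n.shape:
            raise ValidationError("paired fold change needs equal-length vectors")
        keep = ~(np.isnan(t) | np.isnan(n))
        t, n = t[keep], n[keep]
    if np.any(t <= 0) or np.any(n <= 0):
        raise ValidationError("fold change requires positive values")
    if method == "mean_ratio":
        return float(np.mean(t) / np.mean(n))
    if method == "median_ratio":
        return float(np.median(t) / np.median(n))
    return float(np.median(t / n))


@dataclass
class ScreenResult:
    """Feature-level differential table plus the thresholds applied."""

    table: pd.DataFrame  # index: feature_id; p_value, bh_adjusted_p, fold_change, direction
    fc_threshold: float
    alpha: float

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "down"])


def screen_deps(
    results: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> ScreenResult:
    """Call DEPs: up = FC > threshold and adjusted p < alpha (strict); down
    symmetric at FC < 1/threshold. ``results`` needs columns ``p_value``,
    ``bh_adjusted_p``, ``fold_change``.
    """
    if fc_threshold <= 1:
        raise ValidationError("fold-change threshold must exceed 1")
    table = results.copy()
    sig = table["bh_adjusted_p"] < alpha
    up = sig & (table["fold_change"] > fc_threshold)
    down = sig & (table["fold_change"] < 1.0 / fc_threshold)
    table["direction"] = "ns"
    table.loc[up, "direction"] = "up"
    table.loc[down, "direction"] = "down"
    return ScreenResult(table=table, fc_threshold=fc_threshold, alpha=alpha)


def paired_screen(
    matrix: AbundanceMatrix,
    samples: SampleInfo,
    histology: str | None = None,
    fc_method: str = "paired_median_of_ratios",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Tumor-vs-NAT screen over complete pairs (optionally one histology).

    Expects a log2-scale matrix; fold changes are computed on the linear
    scale (2**x). Features with fewer than 3 complete pairs are dropped.
    """
    if matrix.scale != "log2":
        raise ValidationError("paired_screen expects a log2-scale matrix")
    pairs = samples.complete_pairs()
    if histology is not None:
        pairs = pairs[pairs["histology"] == histology]
    t_cols = [c for c in pairs["tumor"] if c in matrix.data.columns]
    n_cols = [c for c in pairs["NAT"] if c in matrix.data.columns]
    tmat = matrix.data[t_cols].to_numpy()
    nmat = matrix.data[n_cols].to_numpy()
    rows = []
    for i, feat in enumerate(matrix.feature_ids):
        t, n = tmat[i], nmat[i]
        keep = ~(np.isnan(t) | np.isnan(n))
        if keep.sum() < 3:
            continue
        p = paired_wilcoxon(t[keep], n[keep])
        fc = fold_change(2.0 ** t[keep], 2.0 ** n[keep], method=fc_method)
        rows.append((feat, p, fc, int(keep.sum())))
    table = pd.DataFrame(
        rows, columns=["feature_id", "p_value", "fold_change", "n_pairs"]
    ).set_index("feature_id")
    table["bh_adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    return screen_deps(table, fc_threshold=fc_threshold, alpha=alpha)


def group_screen(
    matrix: AbundanceMatrix,
    samples_a: list[str],
    samples_b: list[str],
    fc_method: str = "median_ratio",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Unpaired two-group screen (e.g. DGC vs IGC, subtype vs rest)."""
    if matrix.scale != "log2":
        raise ValidationError("group_screen expects a log2-scale matrix")
    amat = matrix.data[list(samples_a)].to_numpy()
    bmat = matrix.data[list(samples_b)].to_numpy()
    rows = []
    for i, feat in enumerate(matrix.feature_ids):
        a = amat[i][~np.isnan(amat[i])]
        b = bmat[i][~np.isnan(bmat[i])]
        if a.size == 0 or b.size == 0:
            continue
        p = ranksum(a, b)
        fc = fold_change(2.0 ** a, 2.0 ** b, method=fc_method)
        rows.append((feat, p, fc, a.size, b.size))
    table = pd.DataFrame(
        rows, columns=["feature_id", "p_value", "fold_change", "n_a", "n_b"]
    ).set_index("feature_id")
    table["bh_adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
    return screen_deps(table, fc_threshold=fc_threshold, alpha=alpha)


@dataclass
class SixGroupPartition:
    assignments: pd.Series  # feature_id -> group 1..6
    excluded: list[str]

    @property
    def counts(self) -> pd.Series:
        return self.assignments.value_counts().reindex(range(1, 7), fill_value=0)


def partition_six_groups(
    dgc_ratio: pd.Series,
    igc_ratio: pd.Series,
    ratio_filter: float = 2.0,
    dominance: float = 2.0,
) -> SixGroupPartition:
    """Partition features by their tumor/NAT ratios in the two histologies.

    Only features whose DGC and IGC ratios differ by >= ``ratio_filter``-fold
    (in either direction) are assigned. Groups: 1/2 up in both histologies
    (DGC- vs IGC-dominant by a ``dominance``-fold ratio-of-ratios), 4/5 down
    in both (DGC- vs IGC-dominant), 3 up in DGC and down in IGC, 6 the
    converse. Features lacking either ratio are excluded with a flag.
    """
    common = dgc_ratio.index.intersection(igc_ratio.index)
    excluded = sorted(set(dgc_ratio.index).symmetric_difference(igc_ratio.index))
    out = {}
    for feat in common:
        d, g = dgc_ratio[feat], igc_ratio[feat]
        if np.isnan(d) or np.isnan(g):
            excluded.append(feat)
            continue
        rr = d / g
        if max(rr, 1.0 / rr) < ratio_filter:
            continue  # fails the 2-fold DGC-vs-IGC filter
        d_up, g_up = d > 1.0, g > 1.0
        if d_up and g_up:
            out[feat] = 1 if rr >= dominance else 2
        elif (not d_up) and (not g_up):
            out[feat] = 4 if (1.0 / rr) >= dominance else 5
        elif d_up and not g_up:
            out[feat] = 3
        else:
            out[feat] = 6
    return SixGroupPartition(
        assignments=pd.Series(out, dtype=int), excluded=excluded
    )
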