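"""TF DNA-binding activity analysis.

TFRE enrichment compares each protein's mean normalized abundance in the
TF-activity (DNA pull-down) layer against the whole proteome; proteins with
a ratio above 4 are called TFRE-enriched (annotated TFs are always
reported). Master-TF nomination requires three criteria: (a) activity up in
tumors vs paired NATs, (b) activity up in one subtype vs the rest, and (c)
hypergeometric enrichment of the TF's target genes among the relevant DEP
set. The kinase-TF network retains positive, significant Spearman
correlations between kinase activities and TF phospho-sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceMatrix, SampleInfo, TFTargetNetwork, ValidationError
from .differential import fold_change, paired_wilcoxon, ranksum


def tfre_enrichment(
    tf_layer: pd.DataFrame | AbundanceMatrix,
    proteome: pd.DataFrame | AbundanceMatrix,
    annotated_tfs: set[str] | None = None,
    ratio_threshold: float = 4.0,
) -> pd.DataFrame:
    """Per-protein TF-layer / proteome mean-abundance ratio with the > 4-fold
    enrichment call (strict). Both inputs must be normalized to comparable
    relative scales (FOT / quantile). Proteins absent from the proteome are
    flagged, not silently dropped.
    """
    tf_data = tf_layer.data if isinstance(tf_layer, AbundanceMatrix) else tf_layer
    prot_data = proteome.data if isinstance(proteome, AbundanceMatrix) else proteome
    annotated_tfs = annotated_tfs or set()
    tf_mean = tf_data.mean(axis=1, skipna=True)
    prot_mean = prot_data.mean(axis=1, skipna=True)
    rows = []
    for protein, numer in tf_mean.items():
        if protein not in prot_mean.index or not prot_mean[protein] > 0:
            rows.append((protein, np.nan, False, True))
            continue
        ratio = numer / prot_mean[protein]
        enriched = bool(ratio > ratio_threshold) or protein in annotated_tfs
        rows.append((protein, ratio, enriched, False))
    out = pd.DataFrame(
        rows, columns=["protein", "ratio", "enriched", "flagged"]
    ).set_index("protein")
    out["annotated_tf"] = [p in annotated_tfs for p in out.index]
    return out


def hypergeom_enrichment(target_genes: set, dep_set: set, universe: set) -> float:
    """Upper-tail hypergeometric p: P(overlap >= observed) for the TF's
    targets among the DEP set, within the quantified-protein universe.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not target_genes:
        raise ValidationError("empty target set")
    targets = set(target_genes) & set(universe)
    deps = set(dep_set) & set(universe)
    k = len(targets & deps)
    M, n, N = len(universe), len(deps), len(targets)
    return float(stats.hypergeom.sf(k - 1, M, n, N))


@dataclass
class MasterTFResult:
    table: pd.DataFrame  # one row per (tf, subtype) with criteria and p-values

    @property
    def nominated(self) -> set[tuple[str, object]]:
        nom = self.table[self.table["nominated"]]
        return set(zip(nom["tf"], nom["subtype"]))

    @property
    def nominated_tfs(self) -> set[str]:
        return set(self.table.loc[self.table["nominated"], "tf"])


def nominate_master_tfs(
    tf_layer: AbundanceMatrix,
    samples: SampleInfo,
    subtype_labels: pd.Series,
    network: TFTargetNetwork,
    dep_sets: dict,
    universe: set[str],
    alpha: float = 0.05,
    fc_tumor: float = 1.5,
    fc_subtype: float = 1.5,
) -> MasterTFResult:
    """Nominate master TFs per subtype by the three-criteria rule.

    ``subtype_labels`` maps patient_id -> subtype for the patients under
    study; ``dep_sets`` maps subtype -> set of altered target-gene symbols
    (e.g. proteins upregulated in that subtype vs the rest); ``universe`` is
    the quantified-protein universe for the hypergeometric test. TF activity
    values are expected on the log2 scale; fold changes are computed on the
    linear scale.
    """
    if tf_layer.scale != "log2":
        raise ValidationError("nominate_master_tfs expects log2 TF activities")
    pairs = samples.complete_pairs()
    pairs = pairs[pairs.index.isin(subtype_labels.index)]
    t_cols = list(pairs["tumor"])
    n_cols = list(pairs["NAT"])
    data = tf_layer.data
    rows = []
    subtypes = sorted(pd.unique(subtype_labels.loc[pairs.index]))
    for tf in tf_layer.feature_ids:
        t_vals = data.loc[tf, t_cols].to_numpy()
        n_vals = data.loc[tf, n_cols].to_numpy()
        keep = ~(np.isnan(t_vals) | np.isnan(n_vals))
        crit_a_p, crit_a_fc, crit_a = np.nan, np.nan, False
        if keep.sum() >= 3:
            crit_a_p = paired_wilcoxon(t_vals[keep], n_vals[keep])
            crit_a_fc = fold_change(
                2.0 ** t_vals[keep], 2.0 ** n_vals[keep], "paired_median_of_ratios"
            )
            crit_a = crit_a_p < alpha and crit_a_fc > fc_tumor
        for subtype in subtypes:
            in_pat = subtype_labels.index[subtype_labels == subtype]
            out_pat = subtype_labels.index[subtype_labels != subtype]
            in_cols = [pairs.loc[p, "tumor"] for p in in_pat if p in pairs.index]
            out_cols = [pairs.loc[p, "tumor"] for p in out_pat if p in pairs.index]
            a = data.loc[tf, in_cols].dropna().to_numpy()
            b = data.loc[tf, out_cols].dropna().to_numpy()
            crit_b_p, crit_b_fc, crit_b = np.nan, np.nan, False
            if a.size >= 2 and b.size >= 2:
                crit_b_p = ranksum(a, b)
                crit_b_fc = fold_change(2.0 ** a, 2.0 ** b, "median_ratio")
                crit_b = crit_b_p < alpha and crit_b_fc > fc_subtype
            targets = network.targets(tf)
            if targets:
                crit_c_p = hypergeom_enrichment(
                    set(targets), set(dep_sets.get(subtype, set())), universe
                )
                crit_c = crit_c_p < alpha
                flagged = False
            else:
                crit_c_p, crit_c, flagged = np.nan, False, True
            rows.append(
                dict(
                    tf=tf, subtype=subtype,
                    criterion_a_p=crit_a_p, criterion_a_fc=crit_a_fc,
                    criterion_b_p=crit_b_p, criterion_b_fc=crit_b_fc,
                    criterion_c_p=crit_c_p,
                    criterion_a=crit_a, criterion_b=crit_b, criterion_c=crit_c,
                    no_targets=flagged,
                    nominated=bool(crit_a and crit_b and crit_c),
                )
            )
    return MasterTFResult(table=pd.DataFrame(rows))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p: exact permutation null for n <= 9,
    t-approximation otherwise. Constant vectors are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError("spearman_test needs >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant vector; rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        xc = rx - rx.mean()
        denom = np.sqrt(np.sum(xc**2) * np.sum((ry - ry.mean()) ** 2))
        perms = np.array(list(itertools.permutations(ry)))
        r_null = (perms - ry.mean()) @ xc / denom
        p = float(np.mean(np.abs(r_null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def kinase_tf_network(
    kinase_activity: pd.DataFrame,
    tf_sites: pd.DataFrame,
    alpha: float = 0.05,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Retained kinase → TF-phospho-site edges (rho > 0 and p < alpha).

    Both inputs are value × sample frames sharing sample columns. Pairs with
    fewer than ``min_samples`` shared observations or a constant vector are
    skipped and listed in ``.attrs['skipped']``.
    """
    shared = kinase_activity.columns.intersection(tf_sites.columns)
    rows, skipped = [], []
    for kinase in kinase_activity.index:
        kv = kinase_activity.loc[kinase, shared]
        for site in tf_sites.index:
            sv = tf_sites.loc[site, shared]
            keep = kv.notna() & sv.notna()
            if keep.sum() < min_samples:
                skipped.append((kinase, site, "insufficient_samples"))
                continue
            try:
                rho, p = spearman_test(kv[keep], sv[keep])
            except ValidationError:
                skipped.append((kinase, site, "constant_vector"))
                continue
            if rho > 0 and p < alpha:
                rows.append((kinase, site, rho, p))
    out = pd.DataFrame(rows, columns=["kinase", "tf_phospho_site", "spearman_rho", "p_value"])
    out.attrs["skipped"] = skipped
    return out
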