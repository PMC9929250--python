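"""Consensus-clustering subtype discovery and concordance evaluation.

Monti-style consensus clustering: repeatedly subsample items, cluster each
subsample (agglomerative, Euclidean distance), and record for every item
pair the fraction of co-sampled repetitions in which the pair co-clusters.
The consensus CDF and its delta-area across k guide the choice of cluster
number; final labels come from hierarchically clustering 1 - consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

from .datamodel import ValidationError


@dataclass
class ConsensusResult:
    sample_ids: list[str]
    consensus: dict[int, np.ndarray]       # k -> samples x samples consensus matrix
    labels: dict[int, pd.Series]           # k -> sample_id -> 1..k
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, CDF values)
    areas: dict[int, float]                # k -> area under consensus CDF
    delta_area: dict[int, float]           # k -> relative area increase
    pac: dict[int, float]                  # k -> proportion of ambiguous clustering
    seed: int
    params: dict = field(default_factory=dict)

    def consensus_frame(self, k: int) -> pd.DataFrame:
        return pd.DataFrame(self.consensus[k], index=self.sample_ids, columns=self.sample_ids)


def consensus_cluster(
    data: pd.DataFrame,
    k_range=range(2, 7),
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    linkage_method: str = "average",
) -> ConsensusResult:
    """Consensus clustering of the columns of ``data`` (features × samples).

    Feature selection is the caller's responsibility (e.g. tumor-upregulated
    proteins on the log2 scale). Defaults follow the common protocol: 1000
    subsampling repetitions at fraction 0.8, k from 2 to 6, Euclidean
    distance with average-linkage agglomerative clustering.
    """
    ks = sorted(k_range)
    n = data.shape[1]
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValidationError(f"k range must lie within [2, {n - 1}]")
    if not 0 < subsample_fraction <= 1:
        raise ValidationError("subsample fraction must be in (0, 1]")
    sample_ids = list(data.columns)
    X = data.to_numpy().T  # samples x features
    X = np.nan_to_num(X, nan=np.nanmean(X))
    full_dist = squareform(pdist(X, metric="euclidean"), checks=False)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        sub = squareform(full_dist[np.ix_(idx, idx)], checks=False)
        Z = linkage(sub, method=linkage_method)
        for k in ks:
            lab = fcluster(Z, t=min(k, m), criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
    never = co_sampled == 0
    np.fill_diagonal(never, False)
    consensus, labels, cdf, areas, pac = {}, {}, {}, {}, {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in ks:
            C = np.where(co_sampled > 0, co_clustered[k] / np.maximum(co_sampled, 1), 0.0)
            C = (C + C.T) / 2.0
            np.fill_diagonal(C, 1.0)
            consensus[k] = C
            Zc = linkage(squareform(1.0 - C, checks=False), method=linkage_method)
            lab = fcluster(Zc, t=k, criterion="maxclust")
            labels[k] = pd.Series(lab, index=sample_ids)
            grid, cdf_vals, area = _consensus_cdf(C)
            cdf[k] = (grid, cdf_vals)
            areas[k] = area
            tri = C[np.triu_indices(n, 1)]
            pac[k] = float(np.mean((tri > 0.1) & (tri < 0.9)))
    delta = {}
    prev = None
    for k in ks:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    result = ConsensusResult(
        sample_ids=sample_ids, consensus=consensus, labels=labels, cdf=cdf,
        areas=areas, delta_area=delta, pac=pac, seed=seed,
        params=dict(
            reps=reps, subsample_fraction=subsample_fraction,
            distance="euclidean", linkage=linkage_method, k_range=ks,
            never_co_sampled=int(never.sum() // 2),
        ),
    )
    return result


def _consensus_cdf(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n = C.shape[0]
    tri = np.sort(C[np.triu_indices(n, 1)])
    grid = np.linspace(0.0, 1.0, 101)
    cdf_vals = np.searchsorted(tri, grid, side="right") / tri.size
    area = float(np.trapezoid(cdf_vals, grid))
    return grid, cdf_vals, area


@dataclass
class KSelection:
    chosen_k: int
    delta_area: dict[int, float]
    pac: dict[int, float]
    ambiguous: bool
    min_cluster_fraction: float = float("nan")
    survival_logrank_p: dict[int, float] = field(default_factory=dict)


def select_k(
    result: ConsensusResult,
    survival: pd.DataFrame | None = None,
    pac_ambiguity_threshold: float = 0.3,
    min_cluster_fraction: float = 0.1,
) -> KSelection:
    """Choose k as the argmax of the delta-area curve (k >= 2).

    If ``survival`` (a patient-indexed frame with ``time`` and ``event``
    columns; matrix samples must be patient ids) is supplied, an advisory
    log-rank p per k is reported alongside — it never overrides delta-area.
    The selection is flagged ambiguous when the consensus matrix at the
    chosen k has a high proportion of intermediate entries (PAC), or when
    the chosen partition is degenerate — some cluster holds less than
    ``min_cluster_fraction`` of the samples, the signature of structureless
    data where hierarchical cuts peel off stable outlier singletons.
    """
    ks = sorted(result.delta_area)
    chosen = max(ks, key=lambda k: result.delta_area[k])
    logrank_ps = {}
    if survival is not None:
        from .clinical import logrank_test

        for k in ks:
            lab = result.labels[k]
            common = [s for s in lab.index if s in survival.index]
            if len(common) >= 2 and lab[common].nunique() >= 2:
                sub = survival.loc[common]
                if sub["event"].sum() > 0:
                    res = logrank_test(
                        sub["time"].to_numpy(),
                        sub["event"].to_numpy(),
                        lab[common].to_numpy(),
                    )
                    logrank_ps[k] = res["p"]
    sizes = result.labels[chosen].value_counts()
    min_frac = float(sizes.min() / sizes.sum())
    ambiguous = (
        result.pac[chosen] > pac_ambiguity_threshold
        or min_frac < min_cluster_fraction
    )
    return KSelection(
        chosen_k=chosen,
        delta_area=dict(result.delta_area),
        pac=dict(result.pac),
        ambiguous=ambiguous,
        min_cluster_fraction=min_frac,
        survival_logrank_p=logrank_ps,
    )


def signature_proteins(
    data: pd.DataFrame,
    labels: pd.Series,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    top_n: int | None = None,
) -> dict:
    """Per-subtype signature features: one-vs-rest rank-sum p and linear
    fold change on log2 data; signature = FC > threshold and p < alpha.
    With ``top_n``, the top features by ascending p (fold change breaking
    ties) are returned instead.
    """
    from .differential import fold_change, ranksum

    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValidationError("signature_proteins needs >= 2 subtypes")
    out = {}
    for subtype in subtypes:
        in_cols = list(labels.index[labels == subtype])
        out_cols = list(labels.index[labels != subtype])
        rows = []
        for feat in data.index:
            a = data.loc[feat, in_cols].dropna().to_numpy()
            b = data.loc[feat, out_cols].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            p = ranksum(a, b)
            fc = fold_change(2.0 ** a, 2.0 ** b, "median_ratio")
            rows.append((feat, p, fc))
        table = pd.DataFrame(rows, columns=["feature_id", "p_value", "fold_change"])
        table = table.set_index("feature_id")
        sig = table[(table["fold_change"] > fc_threshold) & (table["p_value"] < alpha)]
        sig = sig.sort_values(["p_value", "fold_change"], ascending=[True, False])
        if top_n is not None:
            sig = sig.head(top_n)
        out[subtype] = sig
    return out


def subset_percentage(count: int, total: int, decimals: int = 0) -> float:
    """Percentage of a cluster falling in its modal partner cluster, rounded
    half away from zero to ``decimals`` places (65.217 -> 65; 88.057 -> 88.1).
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    pct = 100.0 * count / total
    factor = 10.0 ** decimals
    return float(np.floor(pct * factor + 0.5) / factor)


def concordance_test(labels_a: pd.Series, labels_b: pd.Series) -> dict:
    """Chi-square concordance between two labelings of shared patients.

    Returns the Pearson chi-square (no continuity correction), its p-value,
    the contingency table, and per-cluster modal subset percentages
    (integer-rounded, half away from zero).
    """
    common = labels_a.index.intersection(labels_b.index)
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("degenerate contingency table")
    chi2, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    subset = {}
    for cluster in table.index:
        row = table.loc[cluster]
        modal = row.idxmax()
        subset[cluster] = {
            "modal_cluster": modal,
            "count": int(row[modal]),
            "total": int(row.sum()),
            "percentage": subset_percentage(int(row[modal]), int(row.sum())),
        }
    return {
        "chi2": float(chi2),
        "p": float(p),
        "contingency": table,
        "subset_percentages": subset,
    }
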