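"""Normalization and sample-level quality control.

The proteome layer is normalized per sample to FOT (fraction of total ×
1e6): each protein's intensity divided by the sample's total over observed
proteins. Phospho and TF-activity layers are quantile normalized. Missing
values are imputed with the layer-wide minimum observed value (the
convention used when low abundance drives missingness), and analysis is
performed on log2 values. Sample QC flags samples whose median abundance is
an upper outlier of the cohort's median distribution and always removes
tumor/NAT pairs as a unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import AbundanceMatrix, SampleInfo, ValidationError

FOT_SCALE = 1e6


def fot_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each column by its sum over observed entries, times 1e6."""
    if matrix.scale != "raw":
        raise ValidationError("fot_normalize expects a raw-scale matrix")
    sums = matrix.data.sum(axis=0, skipna=True)
    n_obs = matrix.data.notna().sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty) > 0:
        raise ValidationError(f"all-missing sample column(s): {list(empty.index)}")
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValidationError(f"non-positive column sum for sample(s): {bad}")
    out = matrix.data.div(sums, axis=1) * FOT_SCALE
    return matrix.with_data(out, scale="raw")


def _reference_distribution(data: pd.DataFrame) -> np.ndarray:
    """Cross-column mean of order statistics, aligned to the row count.

    Columns with fewer observed values (missing entries) contribute their
    empirical quantile function evaluated on the common grid.
    """
    n = data.shape[0]
    grid = np.linspace(0.0, 1.0, n)
    acc = np.zeros(n)
    for col in data.columns:
        obs = np.sort(data[col].dropna().to_numpy())
        m = obs.size
        if m == n:
            acc += obs
        else:
            # linear interpolation of the column's quantile function
            acc += np.interp(grid, np.linspace(0.0, 1.0, m), obs)
    return acc / data.shape[1]


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Force every column onto the cross-column mean of order statistics.

    Ties within a column receive the mean of the reference values they span;
    missing entries are excluded from ranking and remain missing.
    """
    data = matrix.data
    if data.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returning identity")
        return matrix.with_data(data.copy())
    ref_full = _reference_distribution(data)
    n = data.shape[0]
    out = data.copy()
    for col in data.columns:
        obs = data[col].dropna()
        m = obs.size
        if m == 0:
            raise ValidationError(f"all-missing sample column: {col}")
        if m == n:
            ref = ref_full
        else:
            ref = np.interp(
                np.linspace(0.0, 1.0, m), np.linspace(0.0, 1.0, n), ref_full
            )
        order = np.argsort(obs.to_numpy(), kind="mergesort")
        assigned = np.empty(m)
        assigned[order] = ref
        # average the reference values spanned by each tied group
        ranks = rankdata(obs.to_numpy(), method="average")
        normalized = pd.Series(assigned).groupby(ranks).transform("mean").to_numpy()
        out.loc[obs.index, col] = normalized
    return matrix.with_data(out)


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; requires strictly positive observed values."""
    if matrix.scale != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    vals = matrix.data.to_numpy()
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValidationError(
            "log2_transform requires positive values; impute before transforming"
        )
    return matrix.with_data(np.log2(matrix.data), scale="log2")


def log2_inverse(matrix: AbundanceMatrix) -> AbundanceMatrix:
    if matrix.scale != "log2":
        raise ValidationError("log2_inverse expects a log2-scale matrix")
    return matrix.with_data(2.0 ** matrix.data, scale="raw")


def impute_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every missing entry with the layer's global minimum observed value."""
    vals = matrix.data.to_numpy()
    if np.all(np.isnan(vals)):
        raise ValidationError("cannot impute a fully missing matrix")
    global_min = np.nanmin(vals)
    out = matrix.data.fillna(global_min)
    return matrix.with_data(out)


@dataclass
class QCReport:
    """Per-sample QC outcome with pair-symmetric exclusions."""

    medians: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)  # sample_id -> reason
    retained: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"median": self.medians})
        df["excluded"] = [s in self.excluded for s in df.index]
        df["reason"] = [self.excluded.get(s, "") for s in df.index]
        return df


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan-style dip: max deviation of the ECDF from the closest
    monotone-then-antitone (unimodal) CDF, approximated by scanning candidate
    modes with greatest-convex-minorant / least-concave-majorant fits.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        return 0.0
    ecdf = np.arange(1, n + 1) / n
    best = np.inf
    # candidate mode at each order statistic; convex fit left, concave right
    for m in range(n):
        left = _hull_deviation(x[: m + 1], ecdf[: m + 1], convex=True)
        right = _hull_deviation(x[m:], ecdf[m:], convex=False)
        best = min(best, max(left, right))
    return 0.5 * best


def _hull_deviation(x: np.ndarray, y: np.ndarray, convex: bool) -> float:
    if x.size < 3:
        return 0.0
    sign = 1.0 if convex else -1.0
    hull = [0]
    for i in range(1, x.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (x[i1] - x[i0]) * (y[i] - y[i0]) - (y[i1] - y[i0]) * (x[i] - x[i0])
            if sign * cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    fitted = np.interp(x, x[hull], y[hull])
    return float(np.max(np.abs(y - fitted)))


def qc_filter_samples(
    matrix: AbundanceMatrix,
    samples: SampleInfo,
    iqr_factor: float = 1.5,
    dip_threshold: float | None = None,
) -> QCReport:
    """Flag samples whose median observed log2 abundance exceeds
    Q3 + ``iqr_factor``·IQR of the cohort's median distribution, optionally
    screen for bimodal distributions (``dip_threshold``), and propagate any
    exclusion to the tumor/NAT partner.
    """
    if matrix.shape[1] < 4:
        raise ValidationError("qc_filter_samples needs >= 4 samples for quartiles")
    data = matrix.data
    if matrix.scale == "raw":
        logged = np.log2(data.where(data > 0))
    else:
        logged = data
    medians = logged.median(axis=0, skipna=True)
    q1, q3 = np.quantile(medians.to_numpy(), [0.25, 0.75])  # linear interpolation
    upper = q3 + iqr_factor * (q3 - q1)
    excluded: dict[str, str] = {}
    for s, med in medians.items():
        if med > upper:
            excluded[s] = "median_outlier"
    if dip_threshold is not None:
        for s in matrix.sample_ids:
            if s in excluded:
                continue
            obs = logged[s].dropna().to_numpy()
            if obs.size >= 4 and dip_statistic(obs) > dip_threshold:
                excluded[s] = "bimodal"
    # pair symmetry: a sample is retained iff its partner is retained
    pairs = samples.pairs()
    for _, row in pairs.iterrows():
        t, n = row.get("tumor"), row.get("NAT")
        for a, b in ((t, n), (n, t)):
            if isinstance(a, str) and a in excluded and isinstance(b, str):
                excluded.setdefault(b, "partner_failed")
    retained = []
    for _, row in pairs.iterrows():
        t, n = row.get("tumor"), row.get("NAT")
        if (
            isinstance(t, str)
            and isinstance(n, str)
            and t in medians.index
            and n in medians.index
            and t not in excluded
            and n not in excluded
        ):
            retained.extend([t, n])
    return QCReport(medians=medians, excluded=excluded, retained=retained)


def prepare_layer(
    matrix: AbundanceMatrix,
    impute_before_log: bool = True,
) -> AbundanceMatrix:
    """Standard per-layer pipeline to analysis-ready log2 values.

    Proteome: FOT → impute → log2. Phospho / TF activity: quantile
    normalize → impute → log2. Whether imputation precedes the log
    transform is configurable; with minimum-value imputation the two orders
    give identical values, so the flag only matters for exotic imputers.
    """
    if matrix.layer == "proteome":
        norm = fot_normalize(matrix)
    else:
        norm = quantile_normalize(matrix)
    if impute_before_log:
        return log2_transform(impute_min(norm))
    return impute_min(log2_transform(norm))
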