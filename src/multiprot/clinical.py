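"""Survival estimation and testing, optimal dichotomization, and mutation
cis/trans-effect screening.

Kaplan-Meier product-limit curves with Greenwood variance, the log-rank
test, Cox proportional-hazards ratios (Efron ties) with Wald 95% CIs, a
maximally-selected log-rank cutpoint search for dichotomizing continuous
markers, and per-(gene, protein) Fisher exact tests classifying mutation
effects as cis (same gene symbol) or trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .datamodel import MutationTable, ValidationError
from .differential import bh_adjust


@dataclass
class SurvivalFit:
    curves: dict          # group -> DataFrame(time, survival, ci_lower, ci_upper, n_at_risk)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    cox: pd.DataFrame | None = None


def km_estimate(times, events, groups=None) -> SurvivalFit:
    """Product-limit survival estimates per group with Greenwood 95% bands."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("km_estimate requires at least one subject")
    _check_surv(times, events)
    if groups is None:
        groups = np.zeros(times.size, dtype=int)
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        ev = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
                "n_at_risk": ev["at_risk"].to_numpy(),
            }
        )
    return SurvivalFit(curves=curves)


def logrank_test(times, events, groups) -> dict:
    """Standard observed-minus-expected log-rank chi-square, df = groups - 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    _check_surv(times, events)
    if events.sum() == 0:
        raise ValidationError("log-rank test undefined with no events")
    if pd.unique(groups).size < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value)}


def cox_hr(
    times, events, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Cox partial-likelihood fit (Efron ties): HR = exp(beta) with Wald 95%
    CI per covariate. Constant covariates and under-determined fits are
    rejected; non-convergence surfaces as an error with diagnostics.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_surv(times, events)
    cov = covariates.reset_index(drop=True).astype(float)
    nunique = cov.nunique()
    if (nunique <= 1).any():
        bad = list(nunique.index[nunique <= 1])
        raise ValidationError(f"constant covariate(s): {bad}")
    if events.sum() < cov.shape[1] + 1:
        raise ValidationError("too few events for the number of covariates")
    df = cov.copy()
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_ci_lower": summary["exp(coef) lower 95%"],
            "hr_ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out


def _check_surv(times, events):
    if np.any(times < 0):
        raise ValidationError("survival times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")


def _logrank_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores: event indicator minus the Nelson-Aalen
    cumulative hazard at the subject's observed time."""
    n = times.size
    cumhaz_at = {}
    cumhaz = 0.0
    for t in np.unique(times):
        d = ((times == t) & (events == 1)).sum()
        r = (times >= t).sum()
        cumhaz += d / r
        cumhaz_at[t] = cumhaz
    return events - np.array([cumhaz_at[t] for t in times])


def _maxstat_z(scores: np.ndarray, below: np.ndarray) -> float:
    """Standardized linear rank statistic for one candidate split, using the
    permutation mean/variance of the score sum (the maximally-selected
    rank-statistic construction)."""
    n = scores.size
    n1 = int(below.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    abar = scores.mean()
    v = n1 * n2 / (n * (n - 1)) * ((scores - abar) ** 2).sum()
    if v <= 0:
        return 0.0
    return (scores[below].sum() - n1 * abar) / np.sqrt(v)


def optimal_cutpoint(
    marker, times, events,
    quantile_range: tuple[float, float] = (0.10, 0.90),
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Scans candidate cutpoints between the marker's 10th and 90th
    percentiles; each below/above split is scored by the standardized
    log-rank score sum (per-subject log-rank scores with their permutation
    mean and variance — the maximally-selected rank-statistic construction),
    and the argmax cutpoint is returned (ties broken toward the median).
    The maximally selected statistic is reported uncorrected; an optional
    permutation reference (``n_permutations`` > 0) estimates how often a
    marker unrelated to survival reaches the observed maximum.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _check_surv(times, events)
    if marker.size < 10:
        raise ValidationError("optimal_cutpoint needs >= 10 subjects")
    if np.unique(marker).size == 1:
        raise ValidationError("all marker values equal; no cutpoint exists")
    lo, hi = np.quantile(marker, quantile_range)
    candidates = np.unique(marker[(marker >= lo) & (marker <= hi)])
    candidates = candidates[:-1] if candidates.size > 1 else candidates
    if candidates.size == 0:
        raise ValidationError("no candidate cutpoints inside the quantile range")
    scores = _logrank_scores(times, events)
    stats_abs = {}
    for c in candidates:
        below = marker <= c
        if below.all() or not below.any():
            continue
        stats_abs[c] = abs(_maxstat_z(scores, below))
    if not stats_abs:
        raise ValidationError("no admissible cutpoint produced two groups")
    max_stat = max(stats_abs.values())
    med = np.median(marker)
    best = min(
        (c for c, s in stats_abs.items() if s == max_stat),
        key=lambda c: abs(c - med),
    )
    out = {"cutpoint": float(best), "max_statistic": float(max_stat)}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(marker)
            null_max = 0.0
            for c in candidates:
                below = perm <= c
                if below.all() or not below.any():
                    continue
                null_max = max(null_max, abs(_maxstat_z(scores, below)))
            if null_max >= max_stat:
                exceed += 1
        out["permutation_p"] = (exceed + 1) / (n_permutations + 1)
    return out


def cis_trans_fisher(
    mutations: MutationTable,
    protein_status: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher exact screen of mutation effects on protein status.

    ``protein_status`` is a patients × proteins boolean frame (True = the
    protein is "up" in that patient under the caller's dichotomization).
    For every (mutated gene, protein) pair a two-sided Fisher exact test is
    run on the mutated/WT × up/not-up 2×2 table; p-values are BH-adjusted
    within each mutated gene; pairs where the gene symbol equals the
    protein are classed cis, all others trans. A zero margin yields p = 1
    with a degenerate flag.
    """
    genes = genes if genes is not None else mutations.genes
    patients = [p for p in mutations.patients if p in protein_status.index]
    status = protein_status.loc[patients].astype(bool)
    rows = []
    for gene in genes:
        mut = mutations.table.loc[patients, gene].to_numpy()
        pvals, metas = [], []
        for protein in status.columns:
            up = status[protein].to_numpy()
            a = int((mut & up).sum())
            b = int((mut & ~up).sum())
            c = int((~mut & up).sum())
            d = int((~mut & ~up).sum())
            degenerate = min(a + b, c + d) == 0 or min(a + c, b + d) == 0
            if degenerate:
                p = 1.0
                odds = np.nan
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            direction = "up" if (a + b > 0 and c + d > 0 and (a / (a + b)) > (c / (c + d))) else "down"
            pvals.append(p)
            metas.append((protein, p, odds, direction, degenerate))
        adj = bh_adjust(np.asarray(pvals))
        for (protein, p, odds, direction, degenerate), q in zip(metas, adj):
            rows.append(
                dict(
                    mutated_gene=gene,
                    protein=protein,
                    effect_class="cis" if protein == gene else "trans",
                    p=p,
                    bh_adjusted_p=q,
                    odds_ratio=odds,
                    direction=direction,
                    degenerate=degenerate,
                )
            )
    return pd.DataFrame(rows)
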