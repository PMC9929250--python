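"""Kinase-substrate enrichment analysis (KSEA).

A kinase's activity change is scored from the log2 tumor/NAT fold changes of
its quantified substrate phospho-sites: z = (s_bar - p_bar) * sqrt(m) / delta,
where s_bar is the mean substrate log2FC, m the number of quantified
substrates, and p_bar / delta the mean and standard deviation of all
quantified site log2FCs (the background). Significance comes from a
permutation null that redraws substrate sets of size m from all sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import KinaseSubstrateMap, ValidationError
from .differential import bh_adjust


def ksea_zscores(
    site_log2fc: pd.Series,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Score every kinase with >= ``min_substrates`` quantified substrates.

    Returns a DataFrame indexed by kinase with columns z_score, m,
    mean_substrate_log2fc, background_mean, background_sd. Kinases below the
    substrate floor are omitted (listed in ``.attrs['omitted']``).
    """
    fc = site_log2fc.dropna()
    if fc.size < 2:
        raise ValidationError("KSEA needs >= 2 quantified sites")
    p_bar = float(fc.mean())
    delta = float(fc.std(ddof=1))
    if delta == 0:
        raise ValidationError("background SD is zero; z-scores undefined")
    quantified = set(fc.index)
    rows, omitted = [], []
    for kinase in ks_map.kinases:
        subs = sorted(ks_map.substrates(kinase) & quantified)
        m = len(subs)
        if m < min_substrates:
            omitted.append(kinase)
            continue
        s_bar = float(fc[subs].mean())
        z = (s_bar - p_bar) * np.sqrt(m) / delta
        rows.append((kinase, z, m, s_bar))
    out = pd.DataFrame(
        rows, columns=["kinase", "z_score", "m", "mean_substrate_log2fc"]
    ).set_index("kinase")
    out["background_mean"] = p_bar
    out["background_sd"] = delta
    out.attrs["omitted"] = omitted
    return out


def ksea_permutation_p(
    site_log2fc: pd.Series,
    substrates,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided permutation p for one kinase's |z| with add-one correction.

    Null substrate sets of the same size are drawn without replacement from
    all quantified sites; p = (b + 1) / (n_perm + 1) where b counts null
    |z| >= observed |z|.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    fc = site_log2fc.dropna()
    subs = sorted(set(substrates) & set(fc.index))
    m = len(subs)
    if m == 0 or m > fc.size:
        raise ValidationError("substrate set empty or larger than the site universe")
    vals = fc.to_numpy()
    p_bar = vals.mean()
    delta = vals.std(ddof=1)
    if delta == 0:
        raise ValidationError("background SD is zero")
    z_obs = (fc[subs].mean() - p_bar) * np.sqrt(m) / delta
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        draw = rng.choice(vals, size=m, replace=False)
        z_null = (draw.mean() - p_bar) * np.sqrt(m) / delta
        if abs(z_null) >= abs(z_obs) - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def ksea(
    site_log2fc: pd.Series,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """z-scores plus permutation p and BH-adjusted p for every scored kinase."""
    table = ksea_zscores(site_log2fc, ks_map, min_substrates=min_substrates)
    rng = np.random.default_rng(seed)
    pvals = [
        ksea_permutation_p(site_log2fc, ks_map.substrates(k), n_perm=n_perm, seed=rng)
        for k in table.index
    ]
    table = table.copy()
    table["permutation_p"] = pvals
    table["bh_adjusted_p"] = bh_adjust(table["permutation_p"].to_numpy())
    return table


def kinase_activity_matrix(
    site_log2fc_matrix: pd.DataFrame,
    ks_map: KinaseSubstrateMap,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Per-patient kinase activity z-scores (kinases × patients).

    Each column of ``site_log2fc_matrix`` (sites × patients, e.g. per-patient
    tumor/NAT log2 ratios) is scored independently; a kinase must clear the
    substrate floor in a column to receive a value there (NaN otherwise).
    """
    cols = {}
    for patient in site_log2fc_matrix.columns:
        try:
            scores = ksea_zscores(
                site_log2fc_matrix[patient], ks_map, min_substrates=min_substrates
            )
            cols[patient] = scores["z_score"]
        except ValidationError:
            cols[patient] = pd.Series(dtype=float)
    return pd.DataFrame(cols)
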