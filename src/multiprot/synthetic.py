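"""Synthetic paired tumor/NAT cohort generator with a ground-truth ledger.

Emulates the statistical structure every downstream stage assumes: paired
log-normal intensities with abundance-dependent (logistic) missingness,
planted tumor-vs-NAT effects, proteomic subtypes carried by signature
proteins, TF-activity subtypes driven by master TFs whose activity shifts
propagate to their target-gene proteins, kinase-activity shifts propagated
to substrate phospho-sites, mutation cis/trans effects, planted cell-type
profiles feeding marker signatures, and exponential survival with
subtype-dependent hazards under uniform censoring.

Randomness flows through two ``numpy.random.Generator`` streams in a fixed
draw order — a structure stream (feature identities, planted sets, the
regulatory network, the kinase map) and a noise stream (patients, noise,
labels, mutations, survival) — so a seed pair fully determines the cohort
on any platform, and cohorts sharing a structure seed share their planted
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    ClinicalRecord,
    GeneSet,
    KinaseSubstrateMap,
    MutationTable,
    SampleInfo,
    SignatureSet,
    TFTargetNetwork,
    ValidationError,
)
from . import io as mio

CELL_TYPES = {
    "Th1": "immune",
    "Th2": "immune",
    "macrophage": "immune",
    "NK": "immune",
    "fibroblast": "stroma",
    "epithelial": "other",
}


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration; defaults define the reference study
    conditions used throughout the test-suite."""

    n_patients: tuple = (("DGC", 40), ("IGC", 50))
    n_proteins: int = 2000
    n_phospho: int = 3000
    n_tf: int = 150
    baseline_mean_range: tuple = (16.0, 24.0)
    feature_sd: float = 0.5
    sample_offset_sd: float = 0.15
    # tumor-vs-NAT differential program (per histology)
    de_fraction: float = 0.10
    de_effect: float = 2.0
    de_up_fraction: float = 0.6
    # proteomic subtypes
    n_subtypes: tuple = (("DGC", 3), ("IGC", 3))
    signature_per_subtype: int = 60
    subtype_boost: float = 1.5
    # TF-activity layer and subtypes
    tf_noise_sd: float = 0.4
    n_tf_subtypes: int = 2
    tf_signature_per_subtype: int = 15
    tf_tumor_effect: float = 1.5
    tf_subtype_boost: float = 2.0
    targets_per_tf: int = 15
    master_target_shift: float = 1.5
    # kinases
    n_kinases: int = 30
    substrates_per_kinase: int = 15
    n_active_kinases: int = 5
    kinase_shift: float = 1.2
    n_negative_kinases: int = 2  # of the active ones, shifted down
    phospho_de_fraction: float = 0.05
    phospho_de_effect: float = 2.0
    # mutations
    panel_size: int = 20
    n_effect_genes: int = 2
    background_mutation_rate: float = 0.10
    effect_mutation_rate: float = 0.25
    cis_effect: float = -2.0
    trans_effect: float = 1.5
    trans_targets_per_gene: int = 10
    # microenvironment
    markers_per_cell_type: int = 25
    cell_effect_scale: float = 2.0
    # survival (months)
    baseline_hazard: float = 0.02
    hazard_multipliers: tuple = (1.0, 2.0, 3.5)
    censor_max: float = 60.0
    # missingness: P(missing | x) = 1 / (1 + exp((x - midpoint) / slope))
    missing_midpoint: float = 14.5
    missing_slope: float = 1.0
    # differential/signature programs are planted on the lower-abundance half
    # of the proteome (below this baseline log2 mean), so the stable
    # high-abundance background dominates column totals and FOT ratios are
    # not distorted by the planted program
    planted_max_abundance: float = 20.0

    def __post_init__(self):
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if not 0 <= self.phospho_de_fraction <= 1:
            raise ValidationError("phospho_de_fraction must lie in [0, 1]")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValidationError("hazard multipliers must be positive")
        for hist, k in self.n_subtypes:
            n = dict(self.n_patients).get(hist, 0)
            if k > n:
                raise ValidationError(f"{hist}: K={k} exceeds n_patients={n}")

    def null(self) -> "CohortParams":
        """All planted effects set to zero (null-calibration conditions)."""
        return replace(
            self,
            de_effect=0.0,
            subtype_boost=0.0,
            tf_tumor_effect=0.0,
            tf_subtype_boost=0.0,
            master_target_shift=0.0,
            kinase_shift=0.0,
            phospho_de_effect=0.0,
            cis_effect=0.0,
            trans_effect=0.0,
            cell_effect_scale=0.0,
            hazard_multipliers=tuple(1.0 for _ in self.hazard_multipliers),
        )


@dataclass
class GroundTruth:
    de_features: dict                      # hist -> {feature: log2 effect}
    subtype_labels: dict                   # hist -> Series patient -> 1..K
    subtype_signature_features: dict       # (hist, k) -> {feature: boost}
    tf_subtype_labels: dict                # hist -> Series patient -> 1..K
    tf_signature: dict                     # (hist, k) -> {tf: boost}
    master_tfs: dict                       # (hist, k) -> {"tf", "activity_shift", "targets", "target_shift"}
    active_kinases: dict                   # kinase -> substrate shift (log2)
    phospho_de: dict                       # site -> log2 effect
    mutated_gene_effects: dict             # gene -> {"cis_effect", "trans_targets", "trans_effect"}
    survival_hazard_multipliers: dict      # subtype index (1..K) -> multiplier
    cell_fraction_profiles: pd.DataFrame   # patients x cell types


@dataclass
class SyntheticCohort:
    layers: dict                           # layer name -> AbundanceMatrix (raw)
    samples: SampleInfo
    clinical: list
    mutations: MutationTable
    kinase_map: KinaseSubstrateMap
    network: TFTargetNetwork
    signatures: SignatureSet
    truth: GroundTruth
    seed: int
    params: CohortParams

    @property
    def proteome(self) -> AbundanceMatrix:
        return self.layers["proteome"]

    @property
    def phospho(self) -> AbundanceMatrix:
        return self.layers["phospho"]

    @property
    def tf_activity(self) -> AbundanceMatrix:
        return self.layers["tf_activity"]


def _balanced_labels(rng, patients, k) -> pd.Series:
    base = np.tile(np.arange(1, k + 1), int(np.ceil(len(patients) / k)))[: len(patients)]
    return pd.Series(rng.permutation(base), index=patients)


def generate_cohort(
    params: CohortParams | None = None,
    seed: int = 0,
    structure_seed: int | None = None,
) -> SyntheticCohort:
    """Generate one cohort. ``seed`` drives patients, noise, labels,
    mutations and survival; ``structure_seed`` (default: ``seed``) drives the
    planted structure — feature identities, planted sets, master TFs, the
    regulatory network and the kinase map — so two cohorts generated with
    the same ``structure_seed`` and different ``seed`` share their planted
    contrasts and serve as training/validation pairs."""
    params = params or CohortParams()
    if structure_seed is None:
        structure_seed = seed
    rng_s = np.random.default_rng([int(structure_seed), 11])   # structure stream
    rng = np.random.default_rng([int(seed), 23])               # noise stream
    hists = [h for h, _ in params.n_patients]
    n_pat = dict(params.n_patients)
    n_sub = dict(params.n_subtypes)

    # ---- identifiers -----------------------------------------------------
    tf_names = [f"TF{i:03d}" for i in range(1, params.n_tf + 1)]
    other = [f"PROT{i:04d}" for i in range(1, params.n_proteins - params.n_tf + 1)]
    proteins = tf_names + other
    patients = [f"{h}{i:03d}" for h in hists for i in range(1, n_pat[h] + 1)]
    hist_of = {p: p[:3] for p in patients}
    sample_rows = []
    for p in patients:
        sample_rows.append((f"{p}_T", p, "tumor", hist_of[p]))
        sample_rows.append((f"{p}_N", p, "NAT", hist_of[p]))
    samples = SampleInfo(
        pd.DataFrame(sample_rows, columns=["sample_id", "patient_id", "tissue", "histology"])
    )
    sample_ids = samples.sample_ids

    residues = rng_s.choice(["S", "T", "Y"], size=params.n_phospho, p=[0.8, 0.15, 0.05])
    site_prot = rng_s.choice(other, size=params.n_phospho)  # sites on non-TF proteins
    positions = rng_s.integers(1, 1200, size=params.n_phospho)
    sites = []
    seen = set()
    for pr, rs, pos in zip(site_prot, residues, positions):
        sid = f"{pr}_{rs}{pos}"
        while sid in seen:
            pos += 1
            sid = f"{pr}_{rs}{pos}"
        seen.add(sid)
        sites.append(sid)

    # ---- baseline abundances (drawn first: planted sets depend on them) ---
    mu = rng_s.uniform(*params.baseline_mean_range, size=params.n_proteins)
    mu_site = rng_s.uniform(*params.baseline_mean_range, size=params.n_phospho)
    mu_of = dict(zip(proteins, mu))

    # ---- planted feature sets (disjoint slices of shuffled pools) --------
    low = [p for p in other if mu_of[p] <= params.planted_max_abundance]
    high = [p for p in other if mu_of[p] > params.planted_max_abundance]
    pool = list(rng_s.permutation(low)) + list(rng_s.permutation(high))

    def take(n):
        nonlocal pool
        if n > len(pool):
            raise ValidationError("feature pool exhausted; reduce planted set sizes")
        out, pool = pool[:n], pool[n:]
        return out

    n_de = int(round(params.de_fraction * params.n_proteins))
    n_de_up = int(round(params.de_up_fraction * n_de))
    de_features: dict[str, dict[str, float]] = {}
    sig_features: dict[tuple, dict[str, float]] = {}
    for h in hists:
        de = {}
        for f in take(n_de_up):
            de[f] = params.de_effect
        for f in take(n_de - n_de_up):
            de[f] = -params.de_effect
        for k in range(1, n_sub[h] + 1):
            sig = take(params.signature_per_subtype)
            sig_features[(h, k)] = {f: params.subtype_boost for f in sig}
            for f in sig:  # signature proteins are also tumor-upregulated
                de[f] = params.de_effect
        de_features[h] = de
    cis_genes = take(params.n_effect_genes)
    trans_targets = {
        g: set(take(params.trans_targets_per_gene)) for g in cis_genes
    }
    master_target_pool = {
        (h, k): take(params.targets_per_tf)
        for h in hists
        for k in range(1, params.n_tf_subtypes + 1)
    }
    cell_markers = {
        ct: take(params.markers_per_cell_type) for ct in CELL_TYPES
    }

    # ---- subtype labels ---------------------------------------------------
    subtype_labels = {
        h: _balanced_labels(rng, [p for p in patients if hist_of[p] == h], n_sub[h])
        for h in hists
    }
    tf_subtype_labels = {
        h: _balanced_labels(
            rng, [p for p in patients if hist_of[p] == h], params.n_tf_subtypes
        )
        for h in hists
    }

    # ---- TF signatures, masters, regulatory network ----------------------
    tf_pool = list(rng_s.permutation(tf_names))
    tf_signature: dict[tuple, dict[str, float]] = {}
    master_tfs: dict[tuple, dict] = {}
    used_tfs = []
    for h in hists:
        for k in range(1, params.n_tf_subtypes + 1):
            chunk = tf_pool[: params.tf_signature_per_subtype]
            tf_pool = tf_pool[params.tf_signature_per_subtype:]
            tf_signature[(h, k)] = {tf: params.tf_subtype_boost for tf in chunk}
            master = chunk[0]
            master_tfs[(h, k)] = dict(
                tf=master,
                activity_shift=params.tf_tumor_effect + params.tf_subtype_boost,
                targets=set(master_target_pool[(h, k)]),
                target_shift=params.master_target_shift,
            )
            used_tfs.extend(chunk)
    network_map: dict[str, set[str]] = {}
    master_target_genes = {g for tg in master_target_pool.values() for g in tg}
    decoy_pool = [p for p in other if p not in master_target_genes]
    for tf in tf_names:
        master_key = next(
            (key for key, m in master_tfs.items() if m["tf"] == tf), None
        )
        if master_key is not None:
            network_map[tf] = set(master_target_pool[master_key])
        else:
            network_map[tf] = set(rng_s.choice(decoy_pool, size=params.targets_per_tf, replace=False))
    network = TFTargetNetwork(network_map)

    # ---- kinase map -------------------------------------------------------
    site_pool = list(rng_s.permutation(sites))
    ks_mapping = {}
    kinase_names = [f"KIN{i:02d}" for i in range(1, params.n_kinases + 1)]
    for kn in kinase_names:
        ks_mapping[kn] = set(site_pool[: params.substrates_per_kinase])
        site_pool = site_pool[params.substrates_per_kinase:]
    kinase_map = KinaseSubstrateMap(ks_mapping)
    active_kinases = {}
    for i, kn in enumerate(kinase_names[: params.n_active_kinases]):
        sign = -1.0 if i < params.n_negative_kinases else 1.0
        active_kinases[kn] = sign * params.kinase_shift
    n_pde = int(round(params.phospho_de_fraction * params.n_phospho))
    phospho_de = {
        s: (params.phospho_de_effect if i % 2 == 0 else -params.phospho_de_effect)
        for i, s in enumerate(site_pool[:n_pde])  # sites not mapped to kinases
    }

    # ---- mutations --------------------------------------------------------
    panel_extra = [p for p in decoy_pool if p not in cis_genes][: params.panel_size - params.n_effect_genes]
    panel = cis_genes + panel_extra
    mut = pd.DataFrame(False, index=patients, columns=panel)
    for gene in panel:
        rate = params.effect_mutation_rate if gene in cis_genes else params.background_mutation_rate
        n_carriers = max(3, int(round(rate * len(patients)))) if gene in cis_genes else int(round(rate * len(patients)))
        carriers = rng.choice(patients, size=n_carriers, replace=False)
        mut.loc[carriers, gene] = True
    mutations = MutationTable(mut, panel=panel)
    mutated_gene_effects = {
        g: dict(
            cis_effect=params.cis_effect,
            trans_targets=trans_targets[g],
            trans_effect=params.trans_effect,
        )
        for g in cis_genes
    }

    # ---- cell-type profiles ----------------------------------------------
    cell_types = list(CELL_TYPES)
    weights = rng.dirichlet(np.ones(len(cell_types)), size=len(patients))
    cell_profiles = pd.DataFrame(weights, index=patients, columns=cell_types)

    # ---- log2 abundance construction --------------------------------------
    offsets = pd.Series(
        rng.normal(0.0, params.sample_offset_sd, size=len(sample_ids)), index=sample_ids
    )

    prot = pd.DataFrame(
        mu[:, None] + offsets.to_numpy()[None, :]
        + rng.normal(0.0, params.feature_sd, size=(params.n_proteins, len(sample_ids))),
        index=proteins, columns=sample_ids,
    )
    phos = pd.DataFrame(
        mu_site[:, None] + offsets.to_numpy()[None, :]
        + rng.normal(0.0, params.feature_sd, size=(params.n_phospho, len(sample_ids))),
        index=sites, columns=sample_ids,
    )

    tumor_cols = {p: f"{p}_T" for p in patients}
    for h in hists:
        h_pats = [p for p in patients if hist_of[p] == h]
        h_tumors = [tumor_cols[p] for p in h_pats]
        for f, eff in de_features[h].items():
            prot.loc[f, h_tumors] += eff
        for k in range(1, n_sub[h] + 1):
            k_tumors = [tumor_cols[p] for p in h_pats if subtype_labels[h][p] == k]
            for f, boost in sig_features[(h, k)].items():
                prot.loc[f, k_tumors] += boost
        for k in range(1, params.n_tf_subtypes + 1):
            m = master_tfs[(h, k)]
            k_tumors = [tumor_cols[p] for p in h_pats if tf_subtype_labels[h][p] == k]
            for g in m["targets"]:
                prot.loc[g, k_tumors] += m["target_shift"]
    all_tumors = [tumor_cols[p] for p in patients]
    for gene in cis_genes:
        carriers = [p for p in patients if mut.loc[p, gene]]
        c_tumors = [tumor_cols[p] for p in carriers]
        prot.loc[gene, c_tumors] += params.cis_effect
        for tgt in trans_targets[gene]:
            prot.loc[tgt, c_tumors] += params.trans_effect
    for ct in cell_types:
        w = cell_profiles[ct]
        for p in patients:
            prot.loc[cell_markers[ct], tumor_cols[p]] += params.cell_effect_scale * w[p]

    for kn, shift in active_kinases.items():
        phos.loc[sorted(kinase_map.substrates(kn)), all_tumors] += shift
    for s, eff in phospho_de.items():
        phos.loc[s, all_tumors] += eff

    # TF activity: the TF's protein row plus extra noise plus activity effects
    tf_act = prot.loc[tf_names].copy()
    tf_act += rng.normal(0.0, params.tf_noise_sd, size=tf_act.shape)
    for h in hists:
        h_pats = [p for p in patients if hist_of[p] == h]
        h_tumors = [tumor_cols[p] for p in h_pats]
        for k in range(1, params.n_tf_subtypes + 1):
            k_tumors = [tumor_cols[p] for p in h_pats if tf_subtype_labels[h][p] == k]
            for tf, boost in tf_signature[(h, k)].items():
                tf_act.loc[tf, h_tumors] += params.tf_tumor_effect
                tf_act.loc[tf, k_tumors] += boost

    # ---- abundance-dependent missingness, then raw scale ------------------
    layers = {}
    for name, frame in (("proteome", prot), ("phospho", phos), ("tf_activity", tf_act)):
        vals = frame.to_numpy()
        p_missing = 1.0 / (1.0 + np.exp((vals - params.missing_midpoint) / params.missing_slope))
        missing = rng.random(vals.shape) < p_missing
        raw = np.power(2.0, vals)
        raw[missing] = np.nan
        layers[name] = AbundanceMatrix(
            pd.DataFrame(raw, index=frame.index, columns=frame.columns),
            scale="raw", layer=name,
        )

    # ---- survival ----------------------------------------------------------
    clinical = []
    mults = dict(enumerate(params.hazard_multipliers, start=1))
    for p in patients:
        h = hist_of[p]
        k = int(subtype_labels[h][p])
        lam = params.baseline_hazard * mults.get(k, 1.0)
        dfs_t = rng.exponential(1.0 / lam)
        dfs_c = rng.uniform(0, params.censor_max)
        os_t = dfs_t + rng.exponential(1.0 / (2.0 * lam))
        os_c = rng.uniform(0, params.censor_max * 1.2)
        clinical.append(
            ClinicalRecord(
                patient_id=p,
                dfs_time=round(min(dfs_t, dfs_c), 2),
                dfs_event=int(dfs_t <= dfs_c),
                os_time=round(min(os_t, os_c), 2),
                os_event=int(os_t <= os_c),
                chemotherapy=bool(rng.random() < 0.8),
                stage=str(rng.choice(["I", "II", "III", "IV"], p=[0.15, 0.3, 0.35, 0.2])),
                age=float(np.round(rng.uniform(35, 80), 1)),
                gender=str(rng.choice(["M", "F"], p=[0.65, 0.35])),
            )
        )

    signatures = SignatureSet(
        GeneSet(name=ct, genes=frozenset(cell_markers[ct]), category=cat)
        for ct, cat in CELL_TYPES.items()
    )
    truth = GroundTruth(
        de_features=de_features,
        subtype_labels=subtype_labels,
        subtype_signature_features=sig_features,
        tf_subtype_labels=tf_subtype_labels,
        tf_signature=tf_signature,
        master_tfs=master_tfs,
        active_kinases=active_kinases,
        phospho_de=phospho_de,
        mutated_gene_effects=mutated_gene_effects,
        survival_hazard_multipliers=mults,
        cell_fraction_profiles=cell_profiles,
    )
    return SyntheticCohort(
        layers=layers,
        samples=samples,
        clinical=clinical,
        mutations=mutations,
        kinase_map=kinase_map,
        network=network,
        signatures=signatures,
        truth=truth,
        seed=seed,
        params=params,
    )


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """One machine-readable row per planted effect."""
    rows = []
    t = cohort.truth
    for h, feats in t.de_features.items():
        for f, eff in feats.items():
            if eff != 0:
                rows.append(("de_feature", h, f, eff))
    for (h, k), feats in t.subtype_signature_features.items():
        for f, eff in feats.items():
            if eff != 0:
                rows.append(("subtype_signature", f"{h}/subtype{k}", f, eff))
    for kn, eff in t.active_kinases.items():
        if eff != 0:
            rows.append(("active_kinase", "all", kn, eff))
    for (h, k), m in t.master_tfs.items():
        if m["activity_shift"] != 0:
            rows.append(("master_tf", f"{h}/tf_subtype{k}", m["tf"], m["activity_shift"]))
    for g, eff in t.mutated_gene_effects.items():
        if eff["cis_effect"] != 0:
            rows.append(("mutation_cis", "all", g, eff["cis_effect"]))
        if eff["trans_effect"] != 0:
            for tgt in sorted(eff["trans_targets"]):
                rows.append(("mutation_trans", g, tgt, eff["trans_effect"]))
    for s, eff in t.phospho_de.items():
        if eff != 0:
            rows.append(("phospho_de", "all", s, eff))
    return pd.DataFrame(rows, columns=["effect_type", "stratum", "target", "magnitude"])


def write_bundle(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the full TSV/GMT bundle readable by the io module."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer, matrix in cohort.layers.items():
        mio.write_abundance_matrix(matrix, directory / mio.BUNDLE_FILES[layer])
    mio.write_sample_info(cohort.samples, directory / mio.BUNDLE_FILES["samples"])
    mio.write_clinical(cohort.clinical, directory / mio.BUNDLE_FILES["clinical"])
    mio.write_mutation_table(cohort.mutations, directory / mio.BUNDLE_FILES["mutations"])
    mio.write_network(cohort.network, directory / mio.BUNDLE_FILES["network"])
    mio.write_kinase_substrate_map(
        cohort.kinase_map, directory / mio.BUNDLE_FILES["kinase_map"]
    )
    mio.write_gmt(cohort.signatures, directory / mio.BUNDLE_FILES["signatures"])
    truth_report(cohort).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
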