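"""Readers and writers for the tabular dataset bundle.

All tables are UTF-8 TSV with a header row. Missing abundance values are
written as empty cells; the string ``NA`` is also accepted on read (both
occur in proteomics supplementary tables). Gene sets use the GMT format.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    ClinicalRecord,
    FormatError,
    GeneSet,
    KinaseSubstrateMap,
    MutationTable,
    ReconciliationError,
    SampleInfo,
    SignatureSet,
    TFTargetNetwork,
    ValidationError,
)

_NA_VALUES = ["", "NA"]

CLINICAL_COLUMNS = [
    "patient_id",
    "dfs_time",
    "dfs_event",
    "os_time",
    "os_event",
    "chemotherapy",
    "stage",
    "age",
    "gender",
]


def read_abundance_matrix(path: str | Path, layer: str, scale: str) -> AbundanceMatrix:
    """Read a features × samples TSV (first column = feature ids)."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
        )
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse abundance matrix {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"abundance matrix {path} has no sample columns")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature rows in {path}: {dup}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value in {path}: {exc}") from exc
    return AbundanceMatrix(df, scale=scale, layer=layer)


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_sample_info(path: str | Path) -> SampleInfo:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleInfo(df)


def write_sample_info(samples: SampleInfo, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                dfs_time=float(row["dfs_time"]),
                dfs_event=int(row["dfs_event"]),
                os_time=float(row["os_time"]),
                os_event=int(row["os_event"]),
                chemotherapy=_parse_bool(row["chemotherapy"]),
                stage=str(row["stage"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
            )
        )
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [vars(r).copy() for r in records]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path, panel: Iterable[str] | None = None) -> MutationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MutationTable(df.astype(int).astype(bool), panel=panel)


def write_mutation_table(mutations: MutationTable, path: str | Path) -> None:
    df = mutations.table.astype(int)
    df.index.name = df.index.name or "patient_id"
    df.to_csv(path, sep="\t")


def read_network(path: str | Path) -> TFTargetNetwork:
    """Read a TF → target edge list (two tab-separated columns with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"network file {path} needs two columns (TF, target)")
    tf_col, tg_col = df.columns[:2]
    mapping: dict[str, set[str]] = {}
    for tf, tg in zip(df[tf_col], df[tg_col]):
        mapping.setdefault(tf, set()).add(tg)
    return TFTargetNetwork(mapping)


def write_network(network: TFTargetNetwork, path: str | Path) -> None:
    rows = [(tf, tg) for tf in network.tfs for tg in sorted(network.targets(tf))]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_kinase_substrate_map(path: str | Path) -> KinaseSubstrateMap:
    """Read a kinase → phospho-site edge list (two tab-separated columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"kinase map {path} needs two columns (kinase, site)")
    k_col, s_col = df.columns[:2]
    mapping: dict[str, set[str]] = {}
    for k, s in zip(df[k_col], df[s_col]):
        mapping.setdefault(k, set()).add(s)
    return KinaseSubstrateMap(mapping)


def write_kinase_substrate_map(ksmap: KinaseSubstrateMap, path: str | Path) -> None:
    rows = [(k, s) for k in ksmap.kinases for s in sorted(ksmap.substrates(k))]
    pd.DataFrame(rows, columns=["kinase", "site"]).to_csv(path, sep="\t", index=False)


_CATEGORY_PREFIX = "category="


def read_gmt(path: str | Path) -> SignatureSet:
    """Read GMT: one set per line — name, description, then member genes.

    A description of the form ``category=immune`` assigns the set's category;
    anything else maps to ``other``. Duplicate genes within a line are stored
    once.
    """
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            category = "other"
            if desc.startswith(_CATEGORY_PREFIX):
                category = desc[len(_CATEGORY_PREFIX):]
            sets.append(GeneSet(name=name, genes=genes, category=category))
    return SignatureSet(sets)


def write_gmt(signatures: SignatureSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in signatures:
            desc = f"{_CATEGORY_PREFIX}{gs.category}"
            fh.write("\t".join([gs.name, desc, *sorted(gs.genes)]) + "\n")


BUNDLE_FILES = {
    "proteome": "proteome.tsv",
    "phospho": "phospho.tsv",
    "tf_activity": "tf_activity.tsv",
    "samples": "samples.tsv",
    "clinical": "clinical.tsv",
    "mutations": "mutations.tsv",
    "network": "tf_network.tsv",
    "kinase_map": "kinase_substrates.tsv",
    "signatures": "signatures.gmt",
}


def validate_bundle(directory: str | Path) -> dict[str, str]:
    """Validate a dataset bundle directory; return {component: status}.

    Reads every component file, applies type-level validation, and checks
    that all matrix sample ids resolve to the sample table. Raises on the
    first hard error; returns a per-component status map on success.
    """
    directory = Path(directory)
    status: dict[str, str] = {}
    samples = read_sample_info(directory / BUNDLE_FILES["samples"])
    status["samples"] = f"ok ({len(samples)} samples)"
    for layer in ("proteome", "phospho", "tf_activity"):
        p = directory / BUNDLE_FILES[layer]
        if not p.exists():
            status[layer] = "absent"
            continue
        mat = read_abundance_matrix(p, layer=layer, scale="raw")
        mat.reconcile(samples)
        status[layer] = f"ok ({mat.shape[0]} features x {mat.shape[1]} samples)"
    clin_path = directory / BUNDLE_FILES["clinical"]
    if clin_path.exists():
        records = read_clinical(clin_path)
        unknown = {r.patient_id for r in records} - set(samples.table["patient_id"])
        if unknown:
            raise ReconciliationError(
                f"clinical patient id(s) absent from sample table: {sorted(unknown)}"
            )
        status["clinical"] = f"ok ({len(records)} patients)"
    for key in ("mutations", "network", "kinase_map", "signatures"):
        p = directory / BUNDLE_FILES[key]
        if not p.exists():
            status[key] = "absent"
            continue
        if key == "mutations":
            read_mutation_table(p)
        elif key == "network":
            read_network(p)
        elif key == "kinase_map":
            read_kinase_substrate_map(p)
        else:
            read_gmt(p)
        status[key] = "ok"
    return status
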