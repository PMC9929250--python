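"""Shared domain types for multilevel proteomic analysis.

Three abundance layers (proteome, phospho-proteome, TF DNA-binding activity)
share one sample annotation table describing patient pairing (tumor vs normal
adjacent tissue, NAT) and Lauren histology. All gene/protein identifiers are
opaque, case-sensitive symbols; no identifier mapping is performed anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LAYERS = ("proteome", "phospho", "tf_activity")
SCALES = ("raw", "log2")
TISSUES = ("tumor", "NAT")
HISTOLOGIES = ("DGC", "IGC", "MGC")
STAGES = ("I", "II", "III", "IV")


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


class ReconciliationError(ValueError):
    """Cross-table references (e.g. sample ids) do not resolve."""


_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>\d+)$")


@dataclass(frozen=True)
class PhosphoSiteID:
    """A phosphorylation site: protein symbol + residue + 1-based position.

    Identity (equality, hashing) is the rendered site id; the localization
    score is carried metadata.
    """

    protein: str
    residue: str
    position: int
    localization_score: float = field(default=float("nan"), compare=False)

    def __post_init__(self):
        if self.residue not in ("S", "T", "Y"):
            raise ValidationError(f"residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, text: str, localization_score: float = float("nan")) -> "PhosphoSiteID":
        m = _SITE_RE.match(text)
        if m is None:
            raise FormatError(f"cannot parse phospho-site id {text!r}")
        return cls(
            protein=m.group("protein"),
            residue=m.group("residue"),
            position=int(m.group("position")),
            localization_score=localization_score,
        )


class SampleInfo:
    """Sample annotation: sample_id, patient_id, tissue (tumor/NAT), histology.

    Wraps a DataFrame indexed by sample_id. Each patient has at most one
    tumor and one NAT sample and a single histology.
    """

    COLUMNS = ("sample_id", "patient_id", "tissue", "histology")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        bad_tissue = set(table["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValidationError(f"unknown tissue value(s): {sorted(bad_tissue)}")
        bad_hist = set(table["histology"]) - set(HISTOLOGIES)
        if bad_hist:
            raise ValidationError(f"unknown histology value(s): {sorted(bad_hist)}")
        counts = table.groupby(["patient_id", "tissue"]).size()
        if (counts > 1).any():
            raise ValidationError("a patient has more than one sample per tissue")
        nhist = table.groupby("patient_id")["histology"].nunique()
        if (nhist > 1).any():
            raise ValidationError("histology must be constant within a patient")
        self.table = table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table["patient_id"].unique())

    def histology_of(self, patient_id: str) -> str:
        rows = self.table[self.table["patient_id"] == patient_id]
        return rows["histology"].iloc[0]

    def pairs(self) -> pd.DataFrame:
        """Return one row per patient with tumor/NAT sample ids (NaN if absent)."""
        wide = self.table.pivot_table(
            index="patient_id", columns="tissue", values="sample_id", aggfunc="first"
        )
        for t in TISSUES:
            if t not in wide.columns:
                wide[t] = np.nan
        hist = self.table.groupby("patient_id")["histology"].first()
        out = wide[list(TISSUES)].join(hist)
        return out

    def complete_pairs(self) -> pd.DataFrame:
        p = self.pairs()
        return p.dropna(subset=["tumor", "NAT"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleInfo":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleInfo(self.table.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


class AbundanceMatrix:
    """A features × samples abundance matrix for one omic layer.

    ``data`` is a DataFrame (rows = features, columns = samples) with NaN
    marking missing (undetected) entries. ``scale`` is ``raw`` (nonnegative
    intensities) or ``log2``.
    """

    def __init__(self, data: pd.DataFrame, scale: str, layer: str):
        if scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {scale!r}")
        if layer not in LAYERS:
            raise ValidationError(f"layer must be one of {LAYERS}, got {layer!r}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature id(s): {dup}")
        if data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in matrix header")
        values = data.to_numpy(dtype=float, copy=False)
        if scale == "raw" and np.nanmin(values, initial=np.inf) < 0:
            raise ValidationError("raw-scale abundances must be nonnegative")
        self.data = data.astype(float)
        self.scale = scale
        self.layer = layer

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean mask, True where the entry is missing."""
        return self.data.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(data, scale or self.scale, self.layer)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        return self.with_data(self.data.loc[:, list(sample_ids)])

    def reconcile(self, samples: SampleInfo) -> None:
        unknown = set(self.sample_ids) - set(samples.sample_ids)
        if unknown:
            raise ReconciliationError(
                f"matrix sample id(s) absent from sample table: {sorted(unknown)}"
            )


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotation with DFS/OS endpoints (months)."""

    patient_id: str
    dfs_time: float
    dfs_event: int
    os_time: float
    os_event: int
    chemotherapy: bool
    stage: str
    age: float
    gender: str

    def __post_init__(self):
        for name in ("dfs_time", "os_time"):
            t = getattr(self, name)
            if not np.isnan(t) and t < 0:
                raise ValidationError(f"{name} must be >= 0, got {t}")
        for name in ("dfs_event", "os_event"):
            e = getattr(self, name)
            if e not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1, got {e}")
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    return pd.DataFrame(rows).set_index("patient_id", drop=False)


class TFTargetNetwork:
    """Directed TF → target-gene mapping (CellNet-style regulatory network)."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self.mapping: dict[str, frozenset[str]] = {
            tf: frozenset(targets) for tf, targets in mapping.items()
        }

    def targets(self, tf: str) -> frozenset[str]:
        return self.mapping.get(tf, frozenset())

    @property
    def tfs(self) -> list[str]:
        return list(self.mapping)

    def __contains__(self, tf: str) -> bool:
        return tf in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


class KinaseSubstrateMap:
    """Kinase → set of phospho-site ids (rendered 'PROT_S123' strings)."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self.mapping: dict[str, frozenset[str]] = {}
        for kinase, sites in mapping.items():
            sites = frozenset(str(s) for s in sites)
            if not sites:
                raise ValidationError(f"kinase {kinase!r} has an empty substrate set")
            self.mapping[kinase] = sites

    def substrates(self, kinase: str) -> frozenset[str]:
        return self.mapping[kinase]

    @property
    def kinases(self) -> list[str]:
        return list(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)


class MutationTable:
    """Patients × genes boolean table of non-silent variant calls."""

    def __init__(self, table: pd.DataFrame, panel: Iterable[str] | None = None):
        table = table.astype(bool)
        if panel is not None:
            extra = set(table.columns) - set(panel)
            if extra:
                raise ValidationError(f"genes outside declared panel: {sorted(extra)}")
        self.table = table
        self.panel = list(panel) if panel is not None else list(table.columns)

    @property
    def patients(self) -> list[str]:
        return list(self.table.index)

    @property
    def genes(self) -> list[str]:
        return list(self.table.columns)

    def carriers(self, gene: str) -> list[str]:
        col = self.table[gene]
        return list(col.index[col])


SIGNATURE_CATEGORIES = ("immune", "stroma", "pathway", "other")


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]
    category: str = "other"

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValidationError(f"gene set {self.name!r} must have >= 2 genes")
        if self.category not in SIGNATURE_CATEGORIES:
            raise ValidationError(
                f"category must be one of {SIGNATURE_CATEGORIES}, got {self.category!r}"
            )


class SignatureSet:
    """Named gene sets with a coarse category (immune / stroma / pathway / other)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self.sets:
                raise ValidationError(f"duplicate gene-set name {gs.name!r}")
            self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def by_category(self, category: str) -> list[GeneSet]:
        return [gs for gs in self.sets.values() if gs.category == category]
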