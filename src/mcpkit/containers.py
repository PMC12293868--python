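"""Core in-memory containers shared by all pipeline stages.

Matrices are genes/probes × samples pandas DataFrames wrapped in light
dataclasses that enforce the invariants every stage relies on: unique IDs,
finite non-negative abundances, beta values in [0, 1], detection p-values
aligned with expression values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BetaMatrix",
    "MirnaMatrix",
    "AnnotationTable",
    "SAMPLE_TABLE_COLUMNS",
    "PHASES",
    "validate_sample_table",
]

#: Columns every sample table carries. ``cycle``/``week``/``observed_fraction``
#: may be NA (healthy donors have no treatment cycle; most visits carry no
#: flow-cytometry observation).
SAMPLE_TABLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "group",
    "cycle",
    "week",
    "batch",
    "observed_fraction",
    "phase",
]

PHASES = {"pretreatment", "on_treatment", "remission", "relapse", "donor"}


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Linear-scale abundances (genes × samples) with optional detection p-values."""

    values: pd.DataFrame
    detection_pvals: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.detection_pvals is not None:
            if self.detection_pvals.shape != self.values.shape:
                raise ValueError("detection_pvals shape differs from values")
            d = self.detection_pvals.to_numpy(dtype=float)
            if ((d < 0) | (d > 1)).any() or not np.all(np.isfinite(d)):
                raise ValueError("detection p-values must lie in [0, 1]")
            self.detection_pvals = self.detection_pvals.set_axis(
                self.values.index
            ).set_axis(self.values.columns, axis=1)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "ExpressionMatrix":
        det = None
        if self.detection_pvals is not None:
            det = self.detection_pvals.loc[:, samples]
        return ExpressionMatrix(self.values.loc[:, samples], det)


@dataclass
class BetaMatrix:
    """Methylation beta values in [0, 1] (probes × samples)."""

    beta: pd.DataFrame
    probe_to_gene: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe")
        _check_unique(self.beta.columns, "sample")
        arr = self.beta.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any() or (arr > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


@dataclass
class MirnaMatrix:
    """miRNA abundances (miRNAs × samples) plus the miRNA → family mapping."""

    values: pd.DataFrame
    family_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "miRNA")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("miRNA values must be finite and non-negative")

    def family_members(self) -> dict:
        fams: dict = {}
        for mirna in self.values.index:
            fam = self.family_map.get(mirna, mirna)
            fams.setdefault(fam, []).append(mirna)
        return fams


@dataclass
class AnnotationTable:
    """term → gene-set membership (GO terms, motifs, or miRNA families)."""

    sets: dict
    universe: set

    def __post_init__(self) -> None:
        self.sets = {t: set(g) for t, g in self.sets.items()}
        self.universe = set(self.universe)
        for term, genes in self.sets.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __getitem__(self, term: str) -> set:
        return self.sets[term]

    def __contains__(self, term: str) -> bool:
        return term in self.sets


def validate_sample_table(table: pd.DataFrame) -> list:
    """Return a list of invariant violations (empty list = valid).

    Checks uniqueness of sample IDs, known phases/groups, observed fractions
    restricted to patient samples and to [0, 1].
    """
    problems = []
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        return [f"missing columns: {missing}"]
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        problems.append(f"duplicate sample IDs: {dups}")
    bad_phase = set(table["phase"].dropna()) - PHASES
    if bad_phase:
        problems.append(f"unknown phases: {sorted(bad_phase)}")
    bad_group = set(table["group"].dropna()) - {"patient", "healthy"}
    if bad_group:
        problems.append(f"unknown groups: {sorted(bad_group)}")
    obs = table["observed_fraction"]
    has_obs = obs.notna()
    if (has_obs & (table["group"] != "patient")).any():
        rows = table.loc[has_obs & (table["group"] != "patient"), "sample_id"]
        problems.append(
            "observed_fraction on non-patient samples: " + ", ".join(rows.tolist())
        )
    vals = obs.dropna().astype(float)
    if ((vals < 0) | (vals > 1)).any():
        problems.append("observed_fraction outside [0, 1]")
    return problems
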