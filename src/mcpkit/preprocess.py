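"""Normalization, probe filtering, qPCR conversion, and cell-count arithmetic.

These steps precede all modelling: bead-array intensities are quantile-
normalized across samples, probes detected nowhere or essentially constant
are dropped, qPCR cycle thresholds convert to relative abundance against the
endogenous control, and manual/flow cell counts convert to malignant-cell
fractions with the clinical burden classes layered on top.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "CellCounts",
    "QpcrRecord",
    "quantile_normalize",
    "filter_noninformative_probes",
    "ct_to_abundance",
    "malignant_fraction_from_counts",
    "classify_tumor_burden",
]


@dataclass
class CellCounts:
    """Differential counts from microscopy (monocytes, lymphocytes) and flow
    cytometry (T = CD3+, B, NK, malignant = CD4+CD7−CD26−)."""

    monocytes: float
    lymphocytes: float
    t_cells: float
    b_cells: float
    nk_cells: float
    malignant: float

    def __post_init__(self) -> None:
        for name in ("monocytes", "lymphocytes", "t_cells", "b_cells",
                     "nk_cells", "malignant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        if self.malignant > self.t_cells:
            raise ValueError("malignant cells cannot exceed CD3+ T cells")


@dataclass
class QpcrRecord:
    """Triplicate qPCR measurement with the endogenous control.

    Replicates spreading more than ``max_spread`` cycles flag the record for
    repetition rather than silently averaging.
    """

    ct_target: float
    ct_gapdh: float
    replicate_cts: tuple = ()
    max_spread: float = 0.5

    @property
    def needs_repeat(self) -> bool:
        if len(self.replicate_cts) < 2:
            return False
        return (max(self.replicate_cts) - min(self.replicate_cts)) > self.max_spread


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the identical value multiset.

    Each column's order statistics are replaced by the across-column mean of
    the order statistics; ties within a column receive the mean of the
    quantile values their rank range spans, so the transform is idempotent.
    """
    if isinstance(matrix, ExpressionMatrix):
        matrix = matrix.values
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported")
    order_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        lo = stats.rankdata(col, method="min").astype(int) - 1
        hi = stats.rankdata(col, method="max").astype(int)  # exclusive
        cum = np.concatenate([[0.0], np.cumsum(order_means)])
        out[:, j] = (cum[hi] - cum[lo]) / (hi - lo)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_noninformative_probes(
    matrix: ExpressionMatrix,
    detection_threshold: float = 0.05,
    min_ratio: float = 1.2,
    ratio_floor: float = 1e-6,
) -> tuple:
    """Drop probes detected in no sample or with max/min ratio below 1.2.

    Returns ``(kept ExpressionMatrix, removal DataFrame)`` where the removal
    table records per dropped probe which criterion fired.  Zero or negative
    values make the ratio undefined; they are floored at ``ratio_floor``
    (flagged in the removal reasons when the floor was applied).
    """
    if matrix.detection_pvals is None:
        raise ValueError("detection p-values are required for probe filtering")
    vals = matrix.values.to_numpy(dtype=float)
    det = matrix.detection_pvals.to_numpy(dtype=float)
    undetected = (det > detection_threshold).all(axis=1)
    floored = (vals <= 0).any(axis=1)
    safe = np.maximum(vals, ratio_floor)
    ratio = safe.max(axis=1) / safe.min(axis=1)
    low_ratio = ratio < min_ratio
    removed_mask = undetected | low_ratio
    reasons = []
    for i, probe in enumerate(matrix.values.index):
        if not removed_mask[i]:
            continue
        why = []
        if undetected[i]:
            why.append(f"detection p > {detection_threshold} in all samples")
        if low_ratio[i]:
            why.append(f"max/min ratio {ratio[i]:.4g} < {min_ratio}")
        if floored[i]:
            why.append("ratio computed with floored values")
        reasons.append((probe, "; ".join(why)))
    removed = pd.DataFrame(reasons, columns=["probe", "reason"]).set_index("probe")
    keep = ~removed_mask
    kept = ExpressionMatrix(
        matrix.values.loc[keep], matrix.detection_pvals.loc[keep]
    )
    return kept, removed


def ct_to_abundance(ct_target: float, ct_gapdh: float) -> float:
    """Relative abundance 2^(Ct_control − Ct_target) against the GAPDH control."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_gapdh)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_gapdh - ct_target))


def malignant_fraction_from_counts(counts: CellCounts) -> dict:
    """Malignant fraction of lymphocytes and of PBMCs from cell counts.

    fraction_of_lymphocytes = malignant / (T + B + NK); fraction_of_pbmc
    scales that by the lymphocyte share of PBMCs, lymphocytes / (lymphocytes
    + monocytes).  The combining arithmetic is this package's declared
    definition (the counting protocol names the ingredients only).
    """
    lymph_gated = counts.t_cells + counts.b_cells + counts.nk_cells
    if lymph_gated <= 0:
        raise ZeroDivisionError("no gated lymphocytes: fraction undefined")
    frac_lymph = counts.malignant / lymph_gated
    pbmc = counts.lymphocytes + counts.monocytes
    if counts.malignant == 0:
        frac_pbmc = 0.0
    elif pbmc <= 0:
        raise ZeroDivisionError("no PBMC counts: fraction undefined")
    else:
        frac_pbmc = frac_lymph * counts.lymphocytes / pbmc
    if not (0.0 <= frac_lymph <= 1.0 and 0.0 <= frac_pbmc <= 1.0):
        raise ValueError("counts imply a fraction outside [0, 1]")
    return {
        "fraction_of_lymphocytes": float(frac_lymph),
        "fraction_of_pbmc": float(frac_pbmc),
    }


def classify_tumor_burden(fraction_of_lymphocytes_percent: float) -> str:
    """Clinical burden class from the CD4+CD26− percentage of lymphocytes.

    <20% → LTB, 20–50% → MTB, >50% → HTB.  The class definitions use strict
    '>' for the upper classes, so the boundary values 20 and 50 fall in the
    lower class.
    """
    v = float(fraction_of_lymphocytes_percent)
    if not 0.0 <= v <= 100.0:
        raise ValueError("percentage must lie in [0, 100]")
    if v <= 20.0:
        return "LTB"
    if v <= 50.0:
        return "MTB"
    return "HTB"
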