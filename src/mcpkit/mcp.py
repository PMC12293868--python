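"""Malignancy-gene selection and the malignant cell predictor (MCP).

Selection regresses each gene's abundance on the malignant-cell fraction
(with batch covariates), keeps positively-associated genes at BH FDR < 5%,
then drops genes whose late-cycle expression falls significantly below the
healthy-donor level (one-sided p ≤ 0.5 — the printed, deliberately lenient
floor criterion).  The predictor fits a per-gene calibration line
x_g = a_g + b_g·f on the training series and inverts it by precision-weighted
least squares, so a new sample's malignant percentage is

    f̂ = Σ_g w_g·b_g·(x_g − a_g) / Σ_g w_g·b_g²,  w_g = b_g²/s_g²,

clipped to [0, 100].  The estimator is invariant to rescaling all expression
by a constant and ignores genes with zero calibration slope.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .regulation import bh_adjust

log = logging.getLogger("mcpkit")

__all__ = [
    "GeneAssociation",
    "McpModel",
    "select_malignancy_genes",
    "strong_subset",
    "fit_mcp",
    "predict_burden",
    "standardize_external",
    "evaluate_predictions",
]


@dataclass
class McpModel:
    """Per-gene calibration parameters mapping expression to malignant fraction."""

    genes: list
    intercept: np.ndarray  # a_g: abundance at fraction 0
    slope: np.ndarray  # b_g: abundance per unit fraction
    resid_var: np.ndarray  # s_g^2
    weight: np.ndarray  # w_g = b_g^2 / s_g^2 (capped when s_g^2 = 0)
    training_samples: list = field(default_factory=list)
    burden_source: str = "trajectory"
    healthy_ref_mean: Optional[np.ndarray] = None
    healthy_ref_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.weight < 0).any():
            raise ValueError("weights must be non-negative")
        if not (self.slope > 0).any():
            raise ValueError("model needs at least one positive slope")

    def to_dict(self) -> dict:
        d = {
            "genes": list(self.genes),
            "intercept": self.intercept.tolist(),
            "slope": self.slope.tolist(),
            "resid_var": self.resid_var.tolist(),
            "weight": self.weight.tolist(),
            "training_samples": list(self.training_samples),
            "burden_source": self.burden_source,
        }
        if self.healthy_ref_mean is not None:
            d["healthy_ref_mean"] = self.healthy_ref_mean.tolist()
            d["healthy_ref_sd"] = self.healthy_ref_sd.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "McpModel":
        return cls(
            genes=list(d["genes"]),
            intercept=np.asarray(d["intercept"], dtype=float),
            slope=np.asarray(d["slope"], dtype=float),
            resid_var=np.asarray(d["resid_var"], dtype=float),
            weight=np.asarray(d["weight"], dtype=float),
            training_samples=list(d.get("training_samples", [])),
            burden_source=d.get("burden_source", "trajectory"),
            healthy_ref_mean=(
                np.asarray(d["healthy_ref_mean"], dtype=float)
                if "healthy_ref_mean" in d else None
            ),
            healthy_ref_sd=(
                np.asarray(d["healthy_ref_sd"], dtype=float)
                if "healthy_ref_sd" in d else None
            ),
        )


#: GeneAssociation is a DataFrame with these columns, indexed by gene_id.
ASSOCIATION_COLUMNS = [
    "slope",
    "slope_p",
    "q_value",
    "direction",
    "healthy_floor_p",
    "fold_change",
    "selected",
]
GeneAssociation = pd.DataFrame  # alias documenting the tabular contract


def _design_matrix(fracs: np.ndarray, batch_labels) -> tuple:
    cols = [np.ones_like(fracs), fracs]
    names = ["intercept", "fraction"]
    levels = []
    if batch_labels is not None:
        levels = sorted(pd.unique(pd.Series(batch_labels)))
        for lev in levels[1:]:  # first level is the reference
            cols.append((np.asarray(batch_labels) == lev).astype(float))
            names.append(f"batch[{lev}]")
    X = np.column_stack(cols)
    return X, names, levels


def select_malignancy_genes(
    expr,
    trajectory: pd.Series,
    batches: Optional[pd.Series] = None,
    healthy_expr: Optional[pd.DataFrame] = None,
    late_cycle_samples: Optional[Sequence] = None,
    q_threshold: float = 0.05,
    healthy_floor_p: float = 0.5,
) -> pd.DataFrame:
    """Per-gene association with the malignant-cell fraction.

    ``trajectory`` maps patient sample → fraction; ``healthy_expr`` holds the
    healthy-donor columns and ``late_cycle_samples`` the late-treatment patient
    samples used in the healthy-floor filter.  Returns the GeneAssociation
    table for every gene with the ``selected`` flag set where direction is
    positive, BH q < ``q_threshold`` and the one-sided late-below-healthy test
    gives p > ``healthy_floor_p``.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    patient_samples = [s for s in trajectory.index if s in values.columns]
    if len(patient_samples) < len(trajectory):
        missing = set(trajectory.index) - set(patient_samples)
        raise ValueError(f"trajectory samples missing from expression: {missing}")
    fracs = trajectory.loc[patient_samples].to_numpy(dtype=float)
    Y = values.loc[:, patient_samples].to_numpy(dtype=float)

    batch_labels = (
        batches.loc[patient_samples].to_numpy() if batches is not None else None
    )
    X, names, levels = _design_matrix(fracs, batch_labels)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough samples for the regression design")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        collinear = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(
            f"singular regression design; collinear columns: {collinear}"
        )

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # (p, genes)
    resid = Y.T - X @ beta
    dof = n - p
    s2 = (resid**2).sum(axis=0) / dof
    se_slope = np.sqrt(np.maximum(s2 * XtX_inv[1, 1], 1e-300))
    slope = beta[1]
    tstat = slope / se_slope
    slope_p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    q = bh_adjust(slope_p)

    # model-predicted fold change across the observed burden range
    f_min, f_max = float(fracs.min()), float(fracs.max())
    a = beta[0]
    pred_lo = a + slope * f_min
    pred_hi = a + slope * f_max
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(pred_lo > 0, pred_hi / pred_lo, np.inf)
    fold = np.where(np.isfinite(fold), np.maximum(fold, 0.0), np.inf)

    floor_p = np.ones(values.shape[0])
    if healthy_expr is not None and late_cycle_samples is not None:
        late = [s for s in late_cycle_samples if s in values.columns]
        if len(late) < 2 or healthy_expr.shape[1] < 2:
            raise ValueError("need >= 2 late-cycle and >= 2 healthy samples")
        H = healthy_expr.reindex(values.index).to_numpy(dtype=float)
        L = values.loc[:, late].to_numpy(dtype=float)
        floor_p = _healthy_floor_pvalues(
            np.log2(np.maximum(L, 1e-12)),
            np.log2(np.maximum(H, 1e-12)),
            late_batches=(batches.loc[late].to_numpy()
                          if batches is not None else None),
            healthy_batches=(
                batches.reindex(healthy_expr.columns).to_numpy()
                if batches is not None
                and healthy_expr.columns.isin(batches.index).all()
                else None
            ),
        )

    selected = (slope > 0) & (q < q_threshold) & (floor_p > healthy_floor_p)
    return pd.DataFrame(
        {
            "slope": slope,
            "slope_p": slope_p,
            "q_value": q,
            "direction": np.sign(slope).astype(int),
            "healthy_floor_p": floor_p,
            "fold_change": fold,
            "selected": selected,
        },
        index=values.index,
    )


def _healthy_floor_pvalues(L, H, late_batches=None, healthy_batches=None):
    """One-sided p-values that late-cycle expression is BELOW healthy.

    Computed on log2 values.  With batch labels for both groups, a per-gene
    OLS with group + additive batch covariates supplies the one-sided t on
    the group contrast (batch effects are log-additive); otherwise a Welch
    test is used.  Small p = strong evidence the gene dropped below healthy.
    """
    if late_batches is not None and healthy_batches is not None:
        groups = np.concatenate([np.ones(L.shape[1]), np.zeros(H.shape[1])])
        labels = np.concatenate([late_batches, healthy_batches])
        X, _, _ = _design_matrix(groups, labels)
        if np.linalg.matrix_rank(X) == X.shape[1] and X.shape[0] > X.shape[1]:
            Y = np.hstack([L, H]).T
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ Y
            resid = Y - X @ beta
            dof = X.shape[0] - X.shape[1]
            s2 = (resid**2).sum(axis=0) / dof
            se = np.sqrt(np.maximum(s2 * XtX_inv[1, 1], 1e-300))
            t = beta[1] / se
            return stats.t.cdf(t, dof)  # alternative: late < healthy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(L, H, axis=1, equal_var=False,
                              alternative="less")
    return np.nan_to_num(res.pvalue, nan=1.0)


def strong_subset(associations: pd.DataFrame, min_fold: float = 2.0) -> list:
    """Selected genes whose model-predicted fold across the burden range is
    at least ``min_fold`` (the conservative, strongly-changing subset)."""
    mask = associations["selected"] & (associations["fold_change"] >= min_fold)
    return associations.index[mask].tolist()


def fit_mcp(
    expr,
    trajectory: pd.Series,
    genes: Optional[Sequence] = None,
    healthy_expr: Optional[pd.DataFrame] = None,
    min_burden_range: float = 0.3,
    weight_cap: float = 1e12,
) -> McpModel:
    """Fit per-gene calibration lines x_g = a_g + b_g·f on training samples.

    Requires ≥ 5 training samples spanning a burden range ≥ ``min_burden_range``
    (an essentially flat series cannot identify the calibration).  Weights are
    b_g²/s_g², capped for genes with zero residual variance.  ``healthy_expr``
    (healthy-donor columns) is stored as the normalization reference for
    cross-platform standardization.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if genes is not None:
        values = values.loc[list(genes)]
    samples = [s for s in trajectory.index if s in values.columns]
    if len(samples) < 5:
        raise ValueError("need at least 5 training samples")
    fracs = trajectory.loc[samples].to_numpy(dtype=float)
    if fracs.max() - fracs.min() < min_burden_range:
        raise ValueError(
            f"training burden range {fracs.max() - fracs.min():.3f} below "
            f"{min_burden_range}: calibration unidentifiable"
        )
    Y = values.loc[:, samples].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(fracs), fracs])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T
    resid = Y.T - X @ beta
    dof = max(len(samples) - 2, 1)
    s2 = (resid**2).sum(axis=0) / dof
    a, b = beta[0], beta[1]
    # snap numerically-zero slopes so flat genes carry exactly zero weight
    scale = np.maximum(np.abs(a), 1.0)
    b = np.where(np.abs(b) < 1e-9 * scale, 0.0, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(s2 > 0, b**2 / s2, np.where(b != 0, weight_cap, 0.0))
    w = np.minimum(np.nan_to_num(w, nan=0.0), weight_cap)
    w = np.where(b == 0, 0.0, w)

    ref_mean = ref_sd = None
    if healthy_expr is not None:
        H = healthy_expr.reindex(values.index).to_numpy(dtype=float)
        ref_mean = H.mean(axis=1)
        ref_sd = H.std(axis=1, ddof=1) if H.shape[1] > 1 else np.zeros(len(a))
    return McpModel(
        genes=values.index.tolist(),
        intercept=a,
        slope=b,
        resid_var=s2,
        weight=w,
        training_samples=list(samples),
        healthy_ref_mean=ref_mean,
        healthy_ref_sd=ref_sd,
    )


def predict_burden(model: McpModel, sample_expr, min_gene_overlap: float = 0.5):
    """Predicted malignant-cell percentage for each sample (clipped [0, 100]).

    ``sample_expr`` is a DataFrame (genes × samples) or a Series for one
    sample.  Genes absent from the input are dropped with a warning; below
    ``min_gene_overlap`` coverage the prediction is refused.
    """
    single = isinstance(sample_expr, pd.Series)
    df = sample_expr.to_frame() if single else sample_expr
    if isinstance(df, ExpressionMatrix):
        df = df.values
    present = [g for g in model.genes if g in df.index]
    overlap = len(present) / len(model.genes)
    if overlap < min_gene_overlap:
        raise ValueError(
            f"only {overlap:.0%} of model genes present (need >= "
            f"{min_gene_overlap:.0%})"
        )
    if overlap < 1.0:
        log.warning("dropping %d model genes absent from input",
                    len(model.genes) - len(present))
    idx = [model.genes.index(g) for g in present]
    a = model.intercept[idx]
    b = model.slope[idx]
    w = model.weight[idx]
    denom = float(np.sum(w * b**2))
    if denom <= 0:
        raise ValueError("all calibration weights are zero")
    X = df.loc[present].to_numpy(dtype=float)
    f_hat = (w * b) @ (X - a[:, None]) / denom
    percents = np.clip(f_hat * 100.0, 0.0, 100.0)
    out = pd.Series(percents, index=df.columns, name="predicted_percent")
    return float(out.iloc[0]) if single else out


def standardize_external(
    external_expr,
    external_healthy_ref: Sequence,
    model: McpModel,
    min_gene_overlap: float = 0.5,
) -> pd.DataFrame:
    """Map an external cohort onto the training platform's scale.

    Per gene, a location/scale transform sends the external healthy-reference
    distribution onto the training healthy reference stored in the model;
    genes absent externally are dropped.  Requires ≥ 2 external reference
    samples and ≥ ``min_gene_overlap`` gene coverage.
    """
    df = external_expr.values if isinstance(external_expr, ExpressionMatrix) \
        else external_expr
    ref_cols = [s for s in external_healthy_ref if s in df.columns]
    if len(ref_cols) < 2:
        raise ValueError("need >= 2 external healthy-like reference samples")
    if model.healthy_ref_mean is None:
        raise ValueError("model carries no training healthy reference")
    present = [g for g in model.genes if g in df.index]
    if len(present) / len(model.genes) < min_gene_overlap:
        raise ValueError("insufficient gene overlap with the model")
    idx = [model.genes.index(g) for g in present]
    train_mean = model.healthy_ref_mean[idx]
    train_sd = model.healthy_ref_sd[idx]
    sub = df.loc[present]
    ext_mean = sub[ref_cols].mean(axis=1).to_numpy()
    ext_sd = sub[ref_cols].std(axis=1, ddof=1).to_numpy()
    scale = np.where((ext_sd > 0) & (train_sd > 0), train_sd / ext_sd, 1.0)
    adjusted = (sub.to_numpy() - ext_mean[:, None]) * scale[:, None] \
        + train_mean[:, None]
    return pd.DataFrame(adjusted, index=present, columns=sub.columns)


def evaluate_predictions(predicted, observed) -> dict:
    """Pearson r and mean absolute error (percentage points) of predictions."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need >= 3 paired values")
    mae = float(np.mean(np.abs(pred - obs)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        return {"pearson_r": float("nan"), "mae": mae,
                "note": "correlation undefined: zero variance"}
    r, p = stats.pearsonr(pred, obs)
    return {"pearson_r": float(r), "pearson_p": float(p), "mae": mae}
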