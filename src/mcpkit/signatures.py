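"""Threshold-cascade signatures: surface-marker candidates, relapse
re-expression, the residual-disease gene set, and the activator/repressor
("yin-yang") anti-correlation statistic.

Every cascade returns a per-gene audit table recording which criterion each
gene passed or failed, so membership can be reconstructed from the audit
trail alone.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .regulation import bh_adjust

__all__ = [
    "MarkerCriteria",
    "filter_surface_markers",
    "relapse_reexpression",
    "residual_disease_signature",
    "yin_yang_correlation",
]


@dataclass
class MarkerCriteria:
    """Thresholds of the four-way surface-marker cascade.

    A candidate must be annotated to one of ``required_terms`` (plasma
    membrane or receptor activity) and pass all four differential-expression
    criteria: ≥2-fold change in the index patient across treatment,
    significant pre-treatment elevation over healthy donors in the other
    patients, a ≥1.2-fold significant difference between purified CD26− and
    CD26+ cells, and a significant difference between purified patient CD4
    cells and healthy CD4 cells.  "At least" folds are inclusive; p
    thresholds strict.
    """

    min_fold_index: float = 2.0
    max_p_pretreat_vs_healthy: float = 0.05
    min_fold_cd26: float = 1.2
    max_p_cd26: float = 0.05
    max_p_purified_vs_healthy: float = 0.05
    required_terms: tuple = ("GO:0005886", "GO:0004872")

    def __post_init__(self) -> None:
        if self.min_fold_index <= 1 or self.min_fold_cd26 <= 1:
            raise ValueError("fold thresholds must exceed 1")
        for p in (self.max_p_pretreat_vs_healthy, self.max_p_cd26,
                  self.max_p_purified_vs_healthy):
            if not 0 < p < 1:
                raise ValueError("p thresholds must lie in (0, 1)")


#: dataset_stack keys expected by filter_surface_markers; each maps to a
#: DataFrame indexed by gene with 'fold' and (except the index-patient entry)
#: 'p_value' columns.
STACK_KEYS = (
    "index_fold",            # fold change across the index patient's treatment
    "pretreat_vs_healthy",   # other patients' pre-treatment vs healthy donors
    "cd26neg_vs_cd26pos",    # purified CD26− vs CD26+ cells
    "purified_vs_healthy",   # purified patient CD4 vs healthy CD4
)


def filter_surface_markers(
    candidate_genes: Sequence,
    annotations,
    dataset_stack: Mapping,
    criteria: Optional[MarkerCriteria] = None,
) -> pd.DataFrame:
    """Apply the annotation requirement and four expression criteria.

    Returns an audit table indexed by candidate gene with per-criterion pass
    flags, the underlying folds/p-values, an ``evaluable`` flag (False when a
    comparison is missing for the gene — such genes never pass silently) and
    the final ``selected`` flag.
    """
    criteria = criteria or MarkerCriteria()
    missing = [k for k in STACK_KEYS if k not in dataset_stack]
    if missing:
        raise ValueError(f"dataset_stack lacks comparisons: {missing}")
    ann_sets = annotations.sets if hasattr(annotations, "sets") else annotations
    term_members = set()
    for term in criteria.required_terms:
        term_members |= set(ann_sets.get(term, set()))

    rows = []
    for gene in candidate_genes:
        rec = {"term_pass": gene in term_members, "evaluable": True}
        stack = {k: dataset_stack[k] for k in STACK_KEYS}
        try:
            idx_fold = float(stack["index_fold"].loc[gene, "fold"])
            rec["index_fold"] = idx_fold
            rec["c1_pass"] = idx_fold >= criteria.min_fold_index

            pre = stack["pretreat_vs_healthy"].loc[gene]
            rec["pretreat_fold"] = float(pre["fold"])
            rec["pretreat_p"] = float(pre["p_value"])
            rec["c2_pass"] = (pre["fold"] > 1.0) and (
                pre["p_value"] < criteria.max_p_pretreat_vs_healthy
            )

            cd26 = stack["cd26neg_vs_cd26pos"].loc[gene]
            rec["cd26_fold"] = float(cd26["fold"])
            rec["cd26_p"] = float(cd26["p_value"])
            rec["c3_pass"] = (cd26["fold"] >= criteria.min_fold_cd26) and (
                cd26["p_value"] < criteria.max_p_cd26
            )

            pur = stack["purified_vs_healthy"].loc[gene]
            rec["purified_p"] = float(pur["p_value"])
            rec["c4_pass"] = pur["p_value"] < criteria.max_p_purified_vs_healthy
        except KeyError:
            rec["evaluable"] = False
            for c in ("c1_pass", "c2_pass", "c3_pass", "c4_pass"):
                rec.setdefault(c, False)
        rec["selected"] = (
            rec["evaluable"] and rec["term_pass"]
            and rec["c1_pass"] and rec["c2_pass"]
            and rec["c3_pass"] and rec["c4_pass"]
        )
        rows.append(pd.Series(rec, name=gene))
    return pd.DataFrame(rows)


def relapse_reexpression(
    expr,
    relapse_sample: str,
    reference_samples: Sequence,
    low_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-gene relapse fold over the reference-phase mean.

    ``low_relapse`` flags genes with fold < ``low_threshold`` (a fold exactly
    at the threshold is NOT low — the printed rule is '<1.5-fold').  A zero
    reference mean leaves the fold undefined (NaN) with ``undefined`` set.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if relapse_sample not in values.columns:
        raise ValueError(f"relapse sample {relapse_sample!r} absent")
    refs = [s for s in reference_samples if s in values.columns]
    if not refs:
        raise ValueError("need at least one reference-phase sample")
    ref_mean = values[refs].mean(axis=1)
    relapse = values[relapse_sample]
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(ref_mean > 0, relapse / ref_mean, np.nan)
    out = pd.DataFrame(
        {
            "relapse_fold": fold,
            "undefined": ref_mean <= 0,
        },
        index=values.index,
    )
    out["low_relapse"] = (out["relapse_fold"] < low_threshold) & ~out["undefined"]
    return out


def residual_disease_signature(
    expr,
    remission_samples: Sequence,
    healthy_samples: Sequence,
    relapse_sample: Optional[str],
    mcp_genes: Sequence,
    min_remission_fold: float = 1.2,
    max_remission_fdr: float = 0.05,
    min_relapse_increase: float = 1.2,
    max_relapse_fdr: float = 0.05,
    strong_relapse_fold: float = 1.5,
) -> pd.DataFrame:
    """Two-stage residual-disease cascade over the predictor's genes.

    Stage 1 keeps genes still elevated during clinical remission: one-sided
    Welch test remission > healthy, BH across candidates, requiring fold ≥
    ``min_remission_fold`` and q < ``max_remission_fdr``.  Stage 2 requires a
    further relapse increase over the remission distribution: a standardized
    one-sample test of the single relapse value against the remission
    mean/SD (prediction-interval scaling), BH across stage-1 survivors,
    increase ≥ ``min_relapse_increase`` at q < ``max_relapse_fdr``.
    ``strong_relapse`` marks increases above ``strong_relapse_fold``.

    Without a relapse sample, stage 2 is skipped and the ``stage2_skipped``
    attribute on the returned frame is set.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    rem = [s for s in remission_samples if s in values.columns]
    hea = [s for s in healthy_samples if s in values.columns]
    if len(rem) < 2 or len(hea) < 2:
        raise ValueError("need >= 2 remission and >= 2 healthy samples")
    genes = [g for g in mcp_genes if g in values.index]
    sub = values.loc[genes]
    R = np.log2(np.maximum(sub[rem].to_numpy(dtype=float), 1e-12))
    H = np.log2(np.maximum(sub[hea].to_numpy(dtype=float), 1e-12))
    res = stats.ttest_ind(R, H, axis=1, equal_var=False, alternative="greater")
    p1 = np.nan_to_num(res.pvalue, nan=1.0)
    q1 = bh_adjust(p1)
    fold1 = sub[rem].mean(axis=1) / np.maximum(sub[hea].mean(axis=1), 1e-12)
    stage1 = (fold1.to_numpy() >= min_remission_fold) & (q1 < max_remission_fdr)

    out = pd.DataFrame(
        {
            "remission_fold_vs_healthy": fold1,
            "remission_q": q1,
            "stage1_pass": stage1,
        },
        index=pd.Index(genes),
    )
    out["relapse_increase"] = np.nan
    out["relapse_q"] = np.nan
    out["stage2_pass"] = False
    out["strong_relapse"] = False

    skipped = relapse_sample is None or relapse_sample not in values.columns
    if not skipped and stage1.any():
        surv = out.index[stage1]
        rem_vals = sub.loc[surv, rem].to_numpy(dtype=float)
        rem_log = np.log2(np.maximum(rem_vals, 1e-12))
        mu = rem_log.mean(axis=1)
        sd = rem_log.std(axis=1, ddof=1)
        n = rem_log.shape[1]
        x = np.log2(np.maximum(
            sub.loc[surv, relapse_sample].to_numpy(dtype=float), 1e-12))
        t = (x - mu) / np.maximum(sd * math.sqrt(1.0 + 1.0 / n), 1e-12)
        p2 = stats.t.sf(t, df=n - 1)
        q2 = bh_adjust(p2)
        increase = sub.loc[surv, relapse_sample] / np.maximum(
            sub.loc[surv, rem].mean(axis=1), 1e-12
        )
        out.loc[surv, "relapse_increase"] = increase
        out.loc[surv, "relapse_q"] = q2
        out.loc[surv, "stage2_pass"] = (
            (increase.to_numpy() >= min_relapse_increase)
            & (q2 < max_relapse_fdr)
        )
        out.loc[surv, "strong_relapse"] = (
            out.loc[surv, "stage2_pass"]
            & (out.loc[surv, "relapse_increase"] > strong_relapse_fold)
        )
    out["member"] = out["stage1_pass"] & (
        out["stage2_pass"] if not skipped else True
    )
    out.attrs["stage2_skipped"] = bool(skipped)
    return out


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n ≤ 8)."""
    n = len(rx)
    total = 0
    extreme = 0
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float((cx**2).sum() * (cy**2).sum()))
    if denom == 0:
        return float("nan")
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float((cx * cy[list(perm)]).sum()) / denom
        total += 1
        if abs(r) >= target:
            extreme += 1
    return extreme / total


def yin_yang_correlation(
    activator_values,
    repressor_values,
    pseudo_count: float = 1.0,
    exact_max_n: int = 8,
) -> dict:
    """Rank anti-correlation of the activator/repressor pair across samples.

    Returns Spearman rho (mid-rank ties), its p-value (exact permutation
    enumeration for n ≤ ``exact_max_n``, asymptotic otherwise) and the
    per-sample log2 activator/repressor ratio with a pseudo-count.  Constant
    vectors leave the correlation undefined (NaN, noted).
    """
    a = pd.Series(activator_values).astype(float)
    r = pd.Series(repressor_values).astype(float)
    if len(a) != len(r) or len(a) < 5:
        raise ValueError("need >= 5 paired samples")
    log_ratio = np.log2((a + pseudo_count) / (r + pseudo_count))
    if a.nunique() == 1 or r.nunique() == 1:
        return {
            "rho": float("nan"),
            "p_value": float("nan"),
            "log_ratio": log_ratio,
            "note": "correlation undefined: constant input",
        }
    rho = float(stats.spearmanr(a, r).statistic)
    if len(a) <= exact_max_n:
        rx = stats.rankdata(a)
        ry = stats.rankdata(r)
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(a, r).pvalue)
    return {"rho": rho, "p_value": p, "log_ratio": log_ratio}
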