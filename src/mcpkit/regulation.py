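"""Multiplicity procedures and regulatory-layer analyses.

Hypergeometric overlaps report the expected count (A×B)/C, fold enrichment
and exact upper-tail p; motif enrichment uses Bonferroni correction, the
gene-wise screens (miRNA families, methylation probes) use Benjamini–Hochberg.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "bh_adjust",
    "bonferroni_adjust",
    "hypergeom_overlap",
    "fisher_exact_2x2",
    "motif_enrichment",
    "select_treatment_mirnas",
    "mirna_target_coverage",
    "detect_methylation_changes",
    "regulatory_overlap_matrix",
]


@dataclass
class OverlapResult:
    """Two-set overlap drawn from a common universe."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    observed: int
    expected: float
    fold: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "A": self.set_a_size,
            "B": self.set_b_size,
            "C": self.universe_size,
            "observed": self.observed,
            "expected": self.expected,
            "fold": self.fold,
            "p_value": self.p_value,
        }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values) -> np.ndarray:
    """min(1, m·p) per test."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def hypergeom_overlap(A: int, B: int, C: int, k: int) -> OverlapResult:
    """Overlap of a size-A and a size-B set from a size-C universe.

    expected = A·B/C, fold = k/expected, p = exact upper tail P(X ≥ k) of the
    hypergeometric distribution.
    """
    for name, val in (("A", A), ("B", B), ("C", C), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    A, B, C, k = int(A), int(B), int(C), int(k)
    if A > C:
        raise ValueError(f"precondition violated: A ({A}) > C ({C})")
    if B > C:
        raise ValueError(f"precondition violated: B ({B}) > C ({C})")
    if k > min(A, B):
        raise ValueError(f"precondition violated: k ({k}) > min(A, B)")
    if k < max(0, A + B - C):
        raise ValueError(
            f"precondition violated: k ({k}) < max(0, A + B − C)"
        )
    expected = A * B / C if C > 0 else 0.0
    fold = k / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(k - 1, C, A, B)) if C > 0 else 1.0
    return OverlapResult(A, B, C, k, expected, fold, min(p, 1.0))


def fisher_exact_2x2(table) -> tuple:
    """Two-sided Fisher exact p (minimum-likelihood rule) and odds ratio.

    Empty margins make the odds ratio undefined (returned as NaN) with p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or (t < 0).any() or (t != np.round(t)).any():
            raise ValueError("table must be 2x2 with non-negative integers")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, float("nan")
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.pvalue), float(res.statistic)


def motif_enrichment(
    gene_set: set,
    motif_annotation: Mapping,
    universe: set,
    min_fold: float = 1.2,
    p_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Per-motif enrichment of binding-site annotations in a gene set.

    fold = (k/|set|)/(K/|universe|); significance is the hypergeometric upper
    tail with Bonferroni correction across motifs.  Returns every motif with
    columns in_set, in_universe, fold, p_value, p_adjusted, significant
    (fold ≥ ``min_fold`` and adjusted p < ``p_threshold``), sorted by
    adjusted p then descending fold.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    sets = motif_annotation.sets if hasattr(motif_annotation, "sets") \
        else dict(motif_annotation)
    rows = []
    for term in sorted(sets):
        members = set(sets[term]) & universe
        K = len(members)
        k = len(members & gene_set)
        if K == 0 or len(gene_set) == 0 or k == 0:
            fold = 0.0
            p = 1.0
        else:
            fold = (k / len(gene_set)) / (K / len(universe))
            p = float(stats.hypergeom.sf(k - 1, len(universe), K, len(gene_set)))
        rows.append((term, k, K, fold, p))
    df = pd.DataFrame(
        rows, columns=["term", "in_set", "in_universe", "fold", "p_value"]
    ).set_index("term")
    df["p_adjusted"] = bonferroni_adjust(df["p_value"].to_numpy())
    df["significant"] = (df["fold"] >= min_fold) & (df["p_adjusted"] < p_threshold)
    return df.sort_values(["p_adjusted", "fold"], ascending=[True, False])


def _collapse_families(values: pd.DataFrame, family_map: Mapping, how: str):
    fams: dict = {}
    for mirna in values.index:
        fams.setdefault(family_map.get(mirna, mirna), []).append(mirna)
    agg = {"max": np.max, "mean": np.mean}[how]
    collapsed = pd.DataFrame(
        {fam: values.loc[members].apply(agg, axis=0)
         for fam, members in fams.items()}
    ).T
    return collapsed


def select_treatment_mirnas(
    mirna_values: pd.DataFrame,
    early_samples: Sequence,
    late_samples: Sequence,
    family_map: Optional[Mapping] = None,
    min_fold: float = 2.0,
    max_fdr: float = 0.001,
    collapse: str = "max",
) -> pd.DataFrame:
    """miRNA families significantly induced by treatment.

    Member rows are collapsed per family (max by default — conservative for
    increase detection), a one-sided Welch test of late > early is BH-adjusted
    across families, and a family is selected when its late/early fold is at
    least ``min_fold`` at q < ``max_fdr``.  Without a family mapping each
    miRNA is its own family (warning emitted).
    """
    if hasattr(mirna_values, "values") and hasattr(mirna_values, "family_map"):
        if family_map is None:
            family_map = mirna_values.family_map
        mirna_values = mirna_values.values
    early = [s for s in early_samples if s in mirna_values.columns]
    late = [s for s in late_samples if s in mirna_values.columns]
    if len(early) < 2 or len(late) < 2:
        raise ValueError("need >= 2 samples in both the early and late groups")
    if family_map is None:
        warnings.warn("no family mapping: falling back to per-miRNA analysis")
        family_map = {}
    collapsed = _collapse_families(mirna_values, family_map, collapse)
    E = np.log2(np.maximum(collapsed[early].to_numpy(dtype=float), 1e-12))
    L = np.log2(np.maximum(collapsed[late].to_numpy(dtype=float), 1e-12))
    res = stats.ttest_ind(L, E, axis=1, equal_var=False, alternative="greater")
    p = np.nan_to_num(res.pvalue, nan=1.0)
    fold = collapsed[late].mean(axis=1) / np.maximum(
        collapsed[early].mean(axis=1), 1e-12
    )
    q = bh_adjust(p)
    out = pd.DataFrame(
        {"fold": fold, "p_value": p, "q_value": q},
        index=collapsed.index,
    )
    out["selected"] = (out["fold"] >= min_fold) & (out["q_value"] < max_fdr)
    return out.sort_values("q_value")


def mirna_target_coverage(
    selected_families: Sequence,
    target_table: Mapping,
    gene_set: set,
    universe: set,
) -> dict:
    """Per-family target enrichment plus the multi-family coverage histogram.

    Returns ``{"per_family": {family: OverlapResult}, "coverage": counts of
    genes targeted by ≥1/≥3/≥5 families, "histogram": exact coverage counts}``.
    Families without targets contribute zero coverage (not an error).
    """
    gene_set = set(gene_set)
    universe = set(universe)
    per_family = {}
    counts: dict = {g: 0 for g in gene_set}
    for fam in selected_families:
        targets = set(target_table.get(fam, set())) & universe
        hits = targets & gene_set
        per_family[fam] = hypergeom_overlap(
            len(gene_set), len(targets), len(universe), len(hits)
        )
        for g in hits:
            counts[g] += 1
    histogram: dict = {}
    for g, c in counts.items():
        histogram[c] = histogram.get(c, 0) + 1
    cov = {
        "ge1": sum(1 for c in counts.values() if c >= 1),
        "ge3": sum(1 for c in counts.values() if c >= 3),
        "ge5": sum(1 for c in counts.values() if c >= 5),
    }
    return {"per_family": per_family, "coverage": cov, "histogram": histogram}


def detect_methylation_changes(
    beta: pd.DataFrame,
    trajectory: pd.Series,
    probe_to_gene: Optional[Mapping] = None,
    min_delta: float = 0.20,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Probes whose methylation tracks the malignant-cell fraction.

    Per probe: Spearman rho against the burden trajectory (BH across probes)
    and delta_beta = mean(low-burden tercile) − mean(high-burden tercile),
    terciles defined on the trajectory with ties broken by sample order.
    significant ⇔ |delta_beta| ≥ ``min_delta`` and q < ``max_fdr``; direction
    is hypomethylated-in-malignant when rho < 0 (beta rises as burden falls).
    Constant probes are excluded (rho undefined) and listed with a notice.
    """
    if hasattr(beta, "beta"):
        if probe_to_gene is None:
            probe_to_gene = beta.probe_to_gene
        beta = beta.beta
    samples = [s for s in trajectory.index if s in beta.columns]
    if len(samples) < 6:
        raise ValueError("need >= 6 samples for tercile contrasts")
    fr = trajectory.loc[samples].to_numpy(dtype=float)
    B = beta.loc[:, samples].to_numpy(dtype=float)

    order = np.argsort(fr, kind="stable")
    third = len(samples) // 3
    low_idx = order[:third] if third else order[:1]
    high_idx = order[-third:] if third else order[-1:]
    delta = B[:, low_idx].mean(axis=1) - B[:, high_idx].mean(axis=1)

    constant = np.all(B == B[:, [0]], axis=1)
    rho = np.full(B.shape[0], np.nan)
    pvals = np.full(B.shape[0], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(B.shape[0]):
            if constant[i]:
                continue
            res = stats.spearmanr(B[i], fr)
            rho[i], pvals[i] = res.statistic, res.pvalue
    ok = ~constant
    q = np.full(B.shape[0], np.nan)
    if ok.any():
        q[ok] = bh_adjust(pvals[ok])
    out = pd.DataFrame(
        {
            "gene_id": [probe_to_gene.get(p, "") if probe_to_gene else ""
                        for p in beta.index],
            "delta_beta": delta,
            "rho": rho,
            "p_value": pvals,
            "q_value": q,
            "excluded_constant": constant,
        },
        index=beta.index,
    )
    out["direction"] = np.where(
        out["rho"] < 0, "hypomethylated_in_malignant", "hypermethylated_in_malignant"
    )
    out.loc[constant, "direction"] = "constant"
    out["significant"] = (
        ~constant & (np.abs(out["delta_beta"]) >= min_delta)
        & (out["q_value"] < max_fdr)
    )
    return out


def regulatory_overlap_matrix(
    motif_targets: set,
    mirna_targets_union: set,
    demethylated_genes: set,
    universe: set,
) -> dict:
    """Pairwise and triple overlap among the three regulatory layers."""
    sets = {
        "motif": set(motif_targets) & set(universe),
        "mirna": set(mirna_targets_union) & set(universe),
        "methylation": set(demethylated_genes) & set(universe),
    }
    for name, s in (("motif", motif_targets), ("mirna", mirna_targets_union),
                    ("methylation", demethylated_genes)):
        if not set(s) <= set(universe):
            raise ValueError(f"{name} set extends beyond the universe")
    C = len(set(universe))
    pairs = {}
    names = list(sets)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = names[i], names[j]
            k = len(sets[a] & sets[b])
            pairs[f"{a}|{b}"] = hypergeom_overlap(len(sets[a]), len(sets[b]), C, k)
    triple = sets["motif"] & sets["mirna"] & sets["methylation"]
    return {
        "pairwise": pairs,
        "triple_members": sorted(triple),
        "triple_size": len(triple),
    }
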