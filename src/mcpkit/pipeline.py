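"""End-to-end orchestration: chain burden fitting, gene selection, predictor
training and the regulatory-layer analyses over one cohort bundle.

These helpers define the default sample groupings (healthy train/valid split,
remission window, early/late treatment phases for the miRNA contrast) and are
what the CLI subcommands and the worked examples call.
"""
from __future__ import annotations

from typing import Optional

import pandas as pd

from . import burden as burden_mod
from . import mcp as mcp_mod
from . import regulation as reg_mod
from . import signatures as sig_mod
from .synthetic import CohortBundle, PLANTED_MOTIF

__all__ = [
    "sample_groups",
    "run_core_analysis",
    "run_regulatory_analysis",
]


def sample_groups(samples: pd.DataFrame, late_cycle_start: int = 9) -> dict:
    """Standard sample groupings used throughout the pipeline.

    late_cycle: treatment cycles ≥ ``late_cycle_start`` (the window of the
    healthy-floor filter); remission: samples whose phase is 'remission';
    early: pre-treatment plus the first two cycles (the high-burden end of
    the miRNA contrast).
    """
    pat = samples[samples["group"] == "patient"]
    visits = pat[pat["phase"] != "relapse"]
    healthy = samples[samples["group"] == "healthy"]
    train = healthy[healthy["sample_id"].str.endswith("_train")]
    valid = healthy[healthy["sample_id"].str.endswith("_valid")]
    if train.empty:  # no naming convention: first 4 donors train
        train = healthy.iloc[: min(4, len(healthy))]
        valid = healthy.iloc[min(4, len(healthy)):]
    relapse = pat[pat["phase"] == "relapse"]["sample_id"].tolist()
    return {
        "patient_visits": visits["sample_id"].tolist(),
        "relapse": relapse[0] if relapse else None,
        "healthy_train": train["sample_id"].tolist(),
        "healthy_valid": valid["sample_id"].tolist(),
        "late_cycle": visits.loc[
            visits["cycle"].astype(float) >= late_cycle_start, "sample_id"
        ].tolist(),
        "remission": visits.loc[
            visits["phase"] == "remission", "sample_id"
        ].tolist(),
        "early": visits.loc[
            visits["cycle"].astype(float) <= 2, "sample_id"
        ].tolist(),
    }


def run_core_analysis(
    bundle: CohortBundle,
    q_threshold: float = 0.05,
    strong_min_fold: float = 2.0,
) -> dict:
    """Burden fit → gene selection → predictor training on one bundle."""
    groups = sample_groups(bundle.samples)
    model, traj = burden_mod.trajectory_from_sample_table(bundle.samples)
    visit_traj = traj.loc[groups["patient_visits"], "fraction"]

    expr = bundle.expression
    healthy_train = expr.values[groups["healthy_train"]]
    batches = bundle.samples.set_index("sample_id")["batch"]
    assoc = mcp_mod.select_malignancy_genes(
        expr,
        visit_traj,
        batches=batches,
        healthy_expr=healthy_train,
        late_cycle_samples=groups["late_cycle"],
        q_threshold=q_threshold,
    )
    selected = assoc.index[assoc["selected"]].tolist()
    strong = mcp_mod.strong_subset(assoc, min_fold=strong_min_fold)
    mcp_model = mcp_mod.fit_mcp(
        expr, visit_traj, genes=selected, healthy_expr=healthy_train
    )
    predictions = mcp_mod.predict_burden(mcp_model, expr.values)
    return {
        "groups": groups,
        "burden_model": model,
        "trajectory": traj,
        "associations": assoc,
        "selected_genes": selected,
        "strong_genes": strong,
        "mcp_model": mcp_model,
        "predictions": predictions,
    }


def run_regulatory_analysis(
    bundle: CohortBundle,
    core: Optional[dict] = None,
    gene_set: Optional[list] = None,
) -> dict:
    """Motif / miRNA / methylation layers plus the three-way overlap."""
    core = core or run_core_analysis(bundle)
    groups = core["groups"]
    traj = core["trajectory"]
    gene_set = gene_set if gene_set is not None else core["strong_genes"]
    universe = set(bundle.annotations.universe)
    gene_set = [g for g in gene_set if g in universe]

    motif = reg_mod.motif_enrichment(
        set(gene_set), bundle.annotations, universe
    )
    # high- vs low-burden visit contrast for treatment-induced miRNA families
    high = traj.loc[groups["patient_visits"], "fraction"]
    early = [s for s in groups["patient_visits"] if high[s] >= 0.5]
    late = [s for s in groups["patient_visits"] if high[s] <= 0.1]
    mirnas = reg_mod.select_treatment_mirnas(
        bundle.mirna.values, early, late, family_map=bundle.mirna.family_map
    )
    selected_fams = mirnas.index[mirnas["selected"]].tolist()
    coverage = reg_mod.mirna_target_coverage(
        [f for f in selected_fams if f in bundle.targets],
        bundle.targets,
        set(gene_set),
        universe,
    )
    visit_traj = traj.loc[groups["patient_visits"], "fraction"]
    meth = reg_mod.detect_methylation_changes(
        bundle.beta.beta, visit_traj, probe_to_gene=bundle.beta.probe_to_gene
    )
    demeth_genes = set(
        meth.loc[
            meth["significant"]
            & (meth["direction"] == "hypomethylated_in_malignant"),
            "gene_id",
        ]
    )
    mirna_union = set()
    for fam, targets in bundle.targets.items():
        if fam in selected_fams:
            mirna_union |= set(targets)
    overlap = reg_mod.regulatory_overlap_matrix(
        set(bundle.annotations[PLANTED_MOTIF]) & set(gene_set)
        if PLANTED_MOTIF in bundle.annotations else set(),
        mirna_union & set(gene_set),
        demeth_genes & set(gene_set),
        set(gene_set) if gene_set else universe,
    )

    act, rep = bundle.truth.tf_pair
    vals = bundle.expression.values
    visit_ids = groups["patient_visits"] + (
        [groups["relapse"]] if groups["relapse"] else []
    )
    yy = sig_mod.yin_yang_correlation(
        vals.loc[act, visit_ids], vals.loc[rep, visit_ids]
    )
    return {
        "motif": motif,
        "mirnas": mirnas,
        "selected_families": selected_fams,
        "coverage": coverage,
        "methylation": meth,
        "overlap": overlap,
        "yin_yang": yy,
    }
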