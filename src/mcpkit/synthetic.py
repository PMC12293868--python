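"""Synthetic cohort generator.

Emulates a bulk-PBMC expression study of an HDAC-inhibitor-treated leukemic
CTCL patient: every sample is a two-component mixture of malignant and normal
cells whose malignant fraction follows a treatment-response trajectory.  On
top of the mRNA mixture the generator plants the regulatory layers the
analysis modules are designed to detect — an anti-correlated PAR bZIP
activator/repressor pair, hypomethylated promoter probes, treatment-induced
miRNA families with target tables, and a transcription-factor binding-motif
annotation — and returns full truth tables so every downstream stage can be
scored against ground truth without any external data.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical (config, seed) pairs reproduce every
matrix bit for bit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    AnnotationTable,
    BetaMatrix,
    ExpressionMatrix,
    MirnaMatrix,
)

__all__ = [
    "ARCHETYPES",
    "CohortConfig",
    "TruthTables",
    "CohortBundle",
    "generate_burden_trajectory",
    "generate_expression",
    "generate_methylation",
    "generate_mirna",
    "generate_cohort",
    "generate_validation_cohort",
]

ARCHETYPES = (
    "complete_responder",
    "non_responder",
    "partial_responder_rebound",
    "stable",
)

#: surface term names used in generated GO annotations
GO_PLASMA_MEMBRANE = "GO:0005886"
GO_RECEPTOR_ACTIVITY = "GO:0004872"
#: name of the planted shared binding motif of the activator/repressor pair
PLANTED_MOTIF = "PARBZIP_MOTIF"

DETECTION_FLOOR = 10.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the index-patient study design: 28 treatment visits over
    12 four-week cycles with flow-cytometry observations at 9 visits, a
    pre-treatment malignant fraction of 0.93 decaying along a Gaussian to a
    small residual remission fraction, one relapse sample at one third of the
    pre-treatment burden, and 4 + 5 healthy donors (training / validation).
    """

    n_genes: int = 8000
    n_signature_genes: int = 300
    fold_range: tuple = (1.2, 20.0)
    n_zero_in_normal: int = 20
    n_visits: int = 28
    n_cycles: int = 12
    n_observed_visits: int = 9
    pre_treatment_fraction: float = 0.93
    archetype: str = "complete_responder"
    n_healthy_train: int = 4
    n_healthy_valid: int = 5
    batch_count: int = 2
    batch_sd: float = 0.02
    noise_sd: float = 0.02
    residual_fraction: float = 0.03
    relapse_fraction: Optional[float] = None  # default pre_treatment/3
    sigma_scale: float = 0.22  # Gaussian width as a fraction of n_visits
    meth_noise_sd: float = 0.01
    mirna_noise_sd: float = 0.10
    n_meth_probes: int = 400
    n_mirna_families: int = 100
    n_planted_mirnas: int = 24
    n_triple_regulated: int = 11
    remission_start_cycle: int = 7
    subject_id: str = "case1"
    seed: int = 17

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            n_signature_genes=self.n_signature_genes,
            n_zero_in_normal=self.n_zero_in_normal,
            n_visits=self.n_visits,
            n_cycles=self.n_cycles,
            n_observed_visits=self.n_observed_visits,
            n_healthy_train=self.n_healthy_train,
            n_healthy_valid=self.n_healthy_valid,
            batch_count=self.batch_count,
            n_meth_probes=self.n_meth_probes,
            n_mirna_families=self.n_mirna_families,
            n_planted_mirnas=self.n_planted_mirnas,
        )
        bad = [k for k, v in counts.items() if v < 0 or (k in (
            "n_genes", "n_visits", "n_cycles", "batch_count") and v < 1)]
        if bad:
            raise ValueError(f"counts must be positive: {bad}")
        if not 0.0 <= self.pre_treatment_fraction <= 1.0:
            raise ValueError("pre_treatment_fraction must lie in [0, 1]")
        if self.fold_range[0] <= 1.0:
            raise ValueError("fold_range lower bound must exceed 1")
        if self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range must be increasing")
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; valid: {ARCHETYPES}"
            )
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        # n_zero_in_normal is clamped to n_signature_genes during generation
        if self.n_planted_mirnas > self.n_mirna_families:
            raise ValueError("n_planted_mirnas exceeds n_mirna_families")
        if self.n_observed_visits > self.n_visits:
            raise ValueError("n_observed_visits exceeds n_visits")

    @property
    def relapse_fraction_value(self) -> float:
        if self.relapse_fraction is not None:
            return float(self.relapse_fraction)
        return self.pre_treatment_fraction / 3.0


@dataclass
class TruthTables:
    """Ground truth for every planted entity in a generated cohort."""

    true_fraction: dict  # sample_id -> fraction in [0, 1]
    signature_genes: pd.DataFrame  # index gene_id; columns fold, zero_in_normal
    planted_motif_genes: set
    planted_mirna_families: set
    mirna_targets: dict  # family -> set of target genes (designated families)
    planted_hypomethylated_probes: dict  # probe -> (beta_malignant, beta_normal)
    probe_to_gene: dict
    tf_pair: tuple  # (activator, repressor)
    triple_regulated: list

    def to_json(self) -> str:
        payload = {
            "true_fraction": self.true_fraction,
            "signature_genes": {
                g: {"fold": float(r["fold"]), "zero_in_normal": bool(r["zero_in_normal"])}
                for g, r in self.signature_genes.iterrows()
            },
            "planted_motif_genes": sorted(self.planted_motif_genes),
            "planted_mirna_families": sorted(self.planted_mirna_families),
            "mirna_targets": {f: sorted(g) for f, g in self.mirna_targets.items()},
            "planted_hypomethylated_probes": {
                p: list(map(float, pair))
                for p, pair in self.planted_hypomethylated_probes.items()
            },
            "probe_to_gene": dict(self.probe_to_gene),
            "tf_pair": list(self.tf_pair),
            "triple_regulated": list(self.triple_regulated),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTables":
        d = json.loads(text)
        sig = pd.DataFrame(
            {
                "fold": {g: v["fold"] for g, v in d["signature_genes"].items()},
                "zero_in_normal": {
                    g: v["zero_in_normal"] for g, v in d["signature_genes"].items()
                },
            }
        )
        return cls(
            true_fraction=d["true_fraction"],
            signature_genes=sig,
            planted_motif_genes=set(d["planted_motif_genes"]),
            planted_mirna_families=set(d["planted_mirna_families"]),
            mirna_targets={f: set(g) for f, g in d["mirna_targets"].items()},
            planted_hypomethylated_probes={
                p: tuple(v) for p, v in d["planted_hypomethylated_probes"].items()
            },
            probe_to_gene=d["probe_to_gene"],
            tf_pair=tuple(d["tf_pair"]),
            triple_regulated=list(d["triple_regulated"]),
        )


@dataclass
class CohortBundle:
    """Everything one synthetic study produces."""

    config: CohortConfig
    expression: ExpressionMatrix
    samples: pd.DataFrame
    beta: BetaMatrix
    mirna: MirnaMatrix
    annotations: AnnotationTable
    targets: dict  # family -> set of target genes
    truth: TruthTables


# ---------------------------------------------------------------------------
# burden trajectories
# ---------------------------------------------------------------------------

def generate_burden_trajectory(
    archetype: str,
    n_visits: int,
    pre_treatment_fraction: float,
    seed: int = 0,
    *,
    floor: float = 0.03,
    sigma_scale: float = 0.22,
) -> np.ndarray:
    """True malignant-cell fractions at each visit for one patient archetype.

    ``complete_responder`` decays as floor + (p0−floor)·exp(−t²/(2σ²)) with
    σ = sigma_scale·n_visits, dropping below 5% around visit 19 of 28 (cycle
    7 of 12).  ``non_responder`` loses 18% of the burden linearly over the
    first treatment cycle (3 visits) and stays flat.  The rebounding partial
    responder decays to mid-course and climbs back to ≥ 0.95·p0.  ``stable``
    is constant.  Deterministic; ``seed`` is accepted for interface symmetry.
    """
    if n_visits < 2:
        raise ValueError("n_visits must be at least 2")
    if not 0.0 <= pre_treatment_fraction <= 1.0:
        raise ValueError("pre_treatment_fraction must lie in [0, 1]")
    p0 = float(pre_treatment_fraction)
    t = np.arange(n_visits, dtype=float)
    if archetype == "complete_responder":
        fl = min(floor, p0)
        sigma = sigma_scale * n_visits
        traj = fl + (p0 - fl) * np.exp(-(t**2) / (2.0 * sigma**2))
    elif archetype == "non_responder":
        drop_end = min(3.0, n_visits - 1.0)
        frac = np.minimum(t, drop_end) / drop_end
        traj = p0 * (1.0 - 0.18 * frac)
    elif archetype == "partial_responder_rebound":
        sigma = max(n_visits / 6.0, 1.0)
        trough_t = n_visits / 2.0
        decay = np.exp(-(np.minimum(t, trough_t) ** 2) / (2.0 * sigma**2))
        g_trough = float(np.exp(-(trough_t**2) / (2.0 * sigma**2)))
        rise = np.zeros_like(t)
        late = t > trough_t
        if late.any():
            rise[late] = (t[late] - trough_t) / (n_visits - 1 - trough_t)
        traj = p0 * np.where(late, g_trough + (0.95 - g_trough) * rise, decay)
    elif archetype == "stable":
        traj = np.full(n_visits, p0)
    else:
        raise ValueError(f"unknown archetype {archetype!r}; valid: {ARCHETYPES}")
    return np.clip(traj, 0.0, 1.0)


def _visit_slots(n_visits: int, n_cycles: int) -> list:
    """Map visits onto (cycle, week) labels, spreading them over the course."""
    n_slots = n_cycles * 3
    if n_visits > n_slots:
        raise ValueError("more visits than cycle/week slots")
    slots = np.unique(np.round(np.linspace(0, n_slots - 1, n_visits)).astype(int))
    # rounding collisions are resolved by shifting later duplicates forward
    while len(slots) < n_visits:
        missing = sorted(set(range(n_slots)) - set(slots))
        slots = np.sort(np.append(slots, missing[: n_visits - len(slots)]))
    return [(int(s) // 3 + 1, int(s) % 3 + 1) for s in slots]


def _build_sample_table(config: CohortConfig, traj: np.ndarray) -> pd.DataFrame:
    subj = config.subject_id
    slots = _visit_slots(config.n_visits, config.n_cycles)
    rows = []
    for i, ((cyc, wk), frac) in enumerate(zip(slots, traj)):
        if i == 0:
            phase = "pretreatment"
        elif cyc >= config.remission_start_cycle:
            phase = "remission"
        else:
            phase = "on_treatment"
        rows.append(
            dict(
                sample_id=f"{subj}_c{cyc:02d}w{wk}",
                subject_id=subj,
                group="patient",
                cycle=cyc,
                week=wk,
                observed_fraction=np.nan,
                phase=phase,
                true_fraction=frac,
            )
        )
    rows.append(
        dict(
            sample_id=f"{subj}_relapse",
            subject_id=subj,
            group="patient",
            cycle=np.nan,
            week=np.nan,
            observed_fraction=np.nan,
            phase="relapse",
            true_fraction=config.relapse_fraction_value,
        )
    )
    n_healthy = config.n_healthy_train + config.n_healthy_valid
    for h in range(n_healthy):
        role = "train" if h < config.n_healthy_train else "valid"
        rows.append(
            dict(
                sample_id=f"hd{h + 1:02d}_{role}",
                subject_id=f"hd{h + 1:02d}",
                group="healthy",
                cycle=np.nan,
                week=np.nan,
                observed_fraction=np.nan,
                phase="donor",
                true_fraction=0.0,
            )
        )
    table = pd.DataFrame(rows)
    table["batch"] = [f"b{i % config.batch_count}" for i in range(len(table))]
    # flow-cytometry observations at evenly spread patient visits
    obs_idx = np.round(
        np.linspace(0, config.n_visits - 1, config.n_observed_visits)
    ).astype(int)
    obs_idx = np.unique(obs_idx)
    table.loc[obs_idx, "observed_fraction"] = table.loc[obs_idx, "true_fraction"]
    # the relapse sample burden is also measured
    relapse_row = table.index[table["phase"] == "relapse"]
    table.loc[relapse_row, "observed_fraction"] = table.loc[
        relapse_row, "true_fraction"
    ]
    cols = [
        "sample_id",
        "subject_id",
        "group",
        "cycle",
        "week",
        "batch",
        "observed_fraction",
        "phase",
        "true_fraction",
    ]
    return table[cols]


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _deepest_remission_fraction(config: CohortConfig, traj: np.ndarray) -> float:
    return float(np.min(traj)) if len(traj) else config.residual_fraction


def _build_truth(config: CohortConfig, rng: np.random.Generator) -> TruthTables:
    traj = generate_burden_trajectory(
        config.archetype,
        config.n_visits,
        config.pre_treatment_fraction,
        floor=config.residual_fraction,
        sigma_scale=config.sigma_scale,
    )
    table = _build_sample_table(config, traj)
    true_fraction = dict(zip(table["sample_id"], table["true_fraction"].astype(float)))

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_sig = config.n_signature_genes
    sig_genes = list(genes[:n_sig])

    lo, hi = config.fold_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_sig))
    zero_flags = np.zeros(n_sig, dtype=bool)
    if n_sig:
        # genes absent from normal lymphocytes double as the guaranteed strong
        # (>10-fold) tail: the residual-disease cascade needs them detectable
        # at a 3% remission burden.
        n_zero = min(config.n_zero_in_normal, n_sig)
        zero_idx = np.arange(n_zero)
        folds[zero_idx] = np.exp(rng.uniform(np.log(10.0), np.log(hi), size=n_zero))
        zero_flags[zero_idx] = True
        # the first zero-in-normal gene is the plastin-like marker whose fold
        # is calibrated so the pre-treatment / deepest-remission expression
        # ratio equals the reported 18.7
        f_pre = config.pre_treatment_fraction
        f_min = _deepest_remission_fraction(config, traj)
        target_ratio = 18.7
        denom = f_pre - target_ratio * f_min
        if denom > 0:
            folds[0] = 1.0 + (target_ratio - 1.0) / denom

    signature = pd.DataFrame(
        {"fold": folds, "zero_in_normal": zero_flags}, index=pd.Index(sig_genes)
    )

    # regulatory layers ----------------------------------------------------
    # the plastin-like gene (index 0) carries the weak methylation probe, so
    # the triple-regulated set starts at index 1: its members must all be
    # detectable on every layer at default thresholds
    triple = sig_genes[1: 1 + min(config.n_triple_regulated, max(n_sig - 1, 0))]
    planted_regulatory = sig_genes[:1] + triple
    motif_extra = [
        g for g in sig_genes if rng.random() < 0.6 and g not in planted_regulatory
    ]
    null_genes = genes[n_sig:]
    motif_background = [g for g in null_genes if rng.random() < 0.08]
    motif_genes = set(planted_regulatory) | set(motif_extra) | set(motif_background)

    families = [f"fam{i:03d}" for i in range(config.n_mirna_families)]
    planted_fams = set(families[: config.n_planted_mirnas])
    designated = families[: min(6, config.n_planted_mirnas)]
    pool = sig_genes[: min(150, n_sig)]
    targets: dict = {}
    for fam in designated:
        if not pool:
            targets[fam] = set()
            continue
        k = min(60, len(pool))
        chosen = set(rng.choice(pool, size=k, replace=False).tolist())
        # planted regulatory genes are hit by every designated family
        chosen |= set(planted_regulatory)
        targets[fam] = chosen

    # methylation probes: strong hypomethylated probes on the triple-regulated
    # genes and a further block of signature genes; one weak plastin-like probe
    # (0.09 malignant / 0.24 normal) planted deliberately below the 0.20
    # delta-beta detection threshold.
    probes = [f"cg{i:05d}" for i in range(config.n_meth_probes)]
    planted_probes: dict = {}
    probe_to_gene: dict = {}
    p_idx = 0
    if sig_genes:
        # weak plastin-like probe: 9% methylated in malignant cells vs 24% in
        # normal cells — a real planted change whose delta stays below the
        # 0.20 detection threshold
        planted_probes[probes[p_idx]] = (0.09, 0.24)
        probe_to_gene[probes[p_idx]] = sig_genes[0]
        p_idx += 1
    hypo_genes = list(dict.fromkeys(list(triple) + sig_genes[max(n_sig - 10, 0):]))
    for j, g in enumerate(hypo_genes):
        if p_idx >= len(probes):
            break
        probe = probes[p_idx]
        if j == 0:
            pair = (0.23, 0.61)  # canonical strong treatment-course change
        else:
            b_norm = float(rng.uniform(0.45, 0.75))
            gap = float(rng.uniform(0.32, min(0.5, b_norm - 0.05)))
            pair = (b_norm - gap, b_norm)
        planted_probes[probe] = pair
        probe_to_gene[probe] = g
        p_idx += 1
    for j in range(p_idx, len(probes)):
        gi = int(rng.integers(0, len(genes)))
        probe_to_gene[probes[j]] = genes[gi]

    activator, repressor = "TF_ACT", "TF_REP"
    return TruthTables(
        true_fraction=true_fraction,
        signature_genes=signature,
        planted_motif_genes=motif_genes,
        planted_mirna_families=planted_fams,
        mirna_targets=targets,
        planted_hypomethylated_probes=planted_probes,
        probe_to_gene=probe_to_gene,
        tf_pair=(activator, repressor),
        triple_regulated=list(triple),
    )


# ---------------------------------------------------------------------------
# matrix generation
# ---------------------------------------------------------------------------

def _sample_frame(truth: TruthTables) -> tuple:
    samples = list(truth.true_fraction.keys())
    fracs = np.array([truth.true_fraction[s] for s in samples], dtype=float)
    return samples, fracs


def _batch_factors(
    config: CohortConfig,
    genes: list,
    samples: list,
    batches: pd.Series,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene multiplicative log-scale batch shifts, shape (genes, samples)."""
    labels = sorted(batches.unique())
    delta = rng.normal(0.0, config.batch_sd, size=(len(genes), len(labels)))
    col = np.array([labels.index(batches[s]) for s in samples])
    return np.exp(delta[:, col])


def generate_expression(
    truth: TruthTables,
    config: CohortConfig,
    seed: int,
    *,
    batches: Optional[pd.Series] = None,
    noise_sd: Optional[float] = None,
    batch_sd: Optional[float] = None,
) -> ExpressionMatrix:
    """Mixture expression matrix with detection p-values.

    For a signature gene with linear fold φ the noiseless abundance at
    malignant fraction f is base·(1 + (φ−1)·f); genes silent in normal cells
    sit at the detection floor in healthy samples.  The planted activator TF
    follows the same mixture law; the repressor follows base·((1−f)/(1−f_min))^γ
    with γ chosen so its span between pre-treatment and deepest remission is
    ~60-fold.  Noise and batch effects are multiplicative log-normal.
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    if batch_sd is None:
        batch_sd = config.batch_sd
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    samples, fracs = _sample_frame(truth)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    base = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), size=config.n_genes))
    phi = np.ones(config.n_genes)
    sig = truth.signature_genes
    for i, g in enumerate(genes):
        if g in sig.index:
            phi[i] = sig.at[g, "fold"]
            if sig.at[g, "zero_in_normal"]:
                base[i] = DETECTION_FLOOR

    values = base[:, None] * (1.0 + (phi[:, None] - 1.0) * fracs[None, :])

    # planted transcription-factor pair
    act, rep = truth.tf_pair
    f_pre = float(np.max(fracs)) if len(fracs) else config.pre_treatment_fraction
    patient_fracs = fracs[fracs > 0]
    f_min = float(np.min(patient_fracs)) if len(patient_fracs) else 0.0
    act_base, rep_base = 80.0, 400.0
    act_vals = act_base * (1.0 + 7.0 * fracs)  # activator scales with burden
    span = (1.0 - f_min) / max(1.0 - f_pre, 1e-9)
    gamma = np.log(60.0) / np.log(span) if span > 1.0 else 1.0
    rep_vals = rep_base * ((1.0 - fracs) / max(1.0 - f_min, 1e-9)) ** gamma
    all_genes = genes + [act, rep]
    values = np.vstack([values, act_vals[None, :], rep_vals[None, :]])

    if batches is not None and batch_sd > 0:
        cfg = CohortConfig(**{**asdict(config), "batch_sd": batch_sd})
        values = values * _batch_factors(cfg, all_genes, samples, batches, rng)
    if noise_sd > 0:
        values = values * np.exp(
            rng.normal(0.0, noise_sd, size=values.shape)
        )

    det = np.exp(-np.maximum(values / DETECTION_FLOOR - 1.0, 0.0))
    det = np.clip(det, 1e-16, 1.0)
    vals_df = pd.DataFrame(values, index=all_genes, columns=samples)
    det_df = pd.DataFrame(det, index=all_genes, columns=samples)
    return ExpressionMatrix(vals_df, det_df)


def generate_methylation(
    truth: TruthTables, config: CohortConfig, seed: int
) -> BetaMatrix:
    """Beta-value matrix: planted probes mix the malignant and normal betas
    by the malignant fraction; all other probes are constant up to noise."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    samples, fracs = _sample_frame(truth)
    probes = sorted(truth.probe_to_gene.keys())
    base = rng.uniform(0.1, 0.9, size=len(probes))
    beta = np.tile(base[:, None], (1, len(samples)))
    for i, p in enumerate(probes):
        if p in truth.planted_hypomethylated_probes:
            b_mal, b_norm = truth.planted_hypomethylated_probes[p]
            beta[i] = fracs * b_mal + (1.0 - fracs) * b_norm
    if config.meth_noise_sd > 0:
        beta = beta + rng.normal(0.0, config.meth_noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    df = pd.DataFrame(beta, index=probes, columns=samples)
    return BetaMatrix(df, dict(truth.probe_to_gene))


def generate_mirna(
    truth: TruthTables, config: CohortConfig, seed: int
) -> MirnaMatrix:
    """miRNA matrix: planted families scale with (1−f), the rest are flat."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    samples, fracs = _sample_frame(truth)
    families = [f"fam{i:03d}" for i in range(config.n_mirna_families)]
    members_per_family = 2
    rows, names, fam_map = [], [], {}
    for fam in families:
        fam_base = float(np.exp(rng.uniform(np.log(20.0), np.log(500.0))))
        planted = fam in truth.planted_mirna_families
        for m in range(members_per_family):
            name = f"{fam}.m{m + 1}"
            names.append(name)
            fam_map[name] = fam
            scale = float(np.exp(rng.normal(0.0, 0.1)))
            if planted:
                rows.append(fam_base * scale * (0.1 + 0.9 * (1.0 - fracs)))
            else:
                rows.append(np.full(len(samples), fam_base * scale))
    values = np.array(rows)
    if config.mirna_noise_sd > 0:
        values = values * np.exp(
            rng.normal(0.0, config.mirna_noise_sd, size=values.shape)
        )
    df = pd.DataFrame(values, index=names, columns=samples)
    return MirnaMatrix(df, fam_map)


def _build_annotations(
    truth: TruthTables, config: CohortConfig, rng: np.random.Generator
) -> AnnotationTable:
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    universe = set(genes) | set(truth.tf_pair)
    sets = {PLANTED_MOTIF: set(truth.planted_motif_genes)}
    for d in range(10):
        mask = rng.random(len(genes)) < 0.08
        sets[f"DECOY_MOTIF_{d:02d}"] = {g for g, m in zip(genes, mask) if m}
    mask = rng.random(len(genes)) < 0.10
    sets[GO_PLASMA_MEMBRANE] = {g for g, m in zip(genes, mask) if m}
    mask = rng.random(len(genes)) < 0.05
    sets[GO_RECEPTOR_ACTIVITY] = {g for g, m in zip(genes, mask) if m}
    return AnnotationTable(sets, universe)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full study bundle for one patient plus healthy donors."""
    root = np.random.SeedSequence([int(config.seed), 7])
    rng_truth = np.random.default_rng(root.spawn(1)[0])
    truth = _build_truth(config, rng_truth)

    traj = generate_burden_trajectory(
        config.archetype,
        config.n_visits,
        config.pre_treatment_fraction,
        floor=config.residual_fraction,
        sigma_scale=config.sigma_scale,
    )
    samples = _build_sample_table(config, traj)
    batches = samples.set_index("sample_id")["batch"]

    expr = generate_expression(truth, config, config.seed, batches=batches)
    beta = generate_methylation(truth, config, config.seed)
    mirna = generate_mirna(truth, config, config.seed)
    rng_anno = np.random.default_rng(np.random.SeedSequence([int(config.seed), 404]))
    annotations = _build_annotations(truth, config, rng_anno)
    return CohortBundle(
        config=config,
        expression=expr,
        samples=samples,
        beta=beta,
        mirna=mirna,
        annotations=annotations,
        targets=dict(truth.mirna_targets),
        truth=truth,
    )


def generate_validation_cohort(
    bundle: CohortBundle,
    archetype: str,
    seed: int,
    *,
    pre_treatment_fraction: Optional[float] = None,
    n_visits: Optional[int] = None,
    subject_id: Optional[str] = None,
    platform_scale: Optional[float] = None,
    platform_scale_sd: float = 0.0,
    n_healthy: int = 0,
) -> tuple:
    """A held-out patient sharing the training cohort's gene truth.

    Reuses base expression parameters implicitly (same truth tables, new
    trajectory and noise draws) so a predictor trained on the original bundle
    can be scored against this patient's true fractions.  ``platform_scale``
    applies a per-gene multiplicative distortion (log-normal around the given
    scale) emulating a different array platform.

    Returns ``(ExpressionMatrix, sample_table)`` where the sample table
    carries ``true_fraction`` per sample.
    """
    config = bundle.config
    p0 = (
        pre_treatment_fraction
        if pre_treatment_fraction is not None
        else config.pre_treatment_fraction
    )
    nv = n_visits if n_visits is not None else config.n_visits
    subj = subject_id or f"val_{archetype}"
    traj = generate_burden_trajectory(
        archetype, nv, p0, floor=config.residual_fraction,
        sigma_scale=config.sigma_scale,
    )
    slots = _visit_slots(nv, config.n_cycles)
    sample_ids = [f"{subj}_c{c:02d}w{w}" for c, w in slots]
    fractions = dict(zip(sample_ids, traj.astype(float)))
    for h in range(n_healthy):
        fractions[f"{subj}_hd{h + 1:02d}"] = 0.0

    truth2 = TruthTables(
        true_fraction=fractions,
        signature_genes=bundle.truth.signature_genes,
        planted_motif_genes=bundle.truth.planted_motif_genes,
        planted_mirna_families=bundle.truth.planted_mirna_families,
        mirna_targets=bundle.truth.mirna_targets,
        planted_hypomethylated_probes=bundle.truth.planted_hypomethylated_probes,
        probe_to_gene=bundle.truth.probe_to_gene,
        tf_pair=bundle.truth.tf_pair,
        triple_regulated=bundle.truth.triple_regulated,
    )
    # identical base/fold draws: generate_expression reseeds gene parameters
    # from (seed, 101), so base expression must come from the SAME seed as the
    # training bundle, while noise must differ.  Regenerate noiselessly with
    # the training seed, then add fresh noise.
    expr0 = generate_expression(
        truth2, config, config.seed, batches=None, noise_sd=0.0, batch_sd=0.0
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    values = expr0.values.to_numpy().copy()
    if platform_scale is not None:
        scale = platform_scale * np.exp(
            rng.normal(0.0, platform_scale_sd, size=values.shape[0])
        )
        values = values * scale[:, None]
    if config.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, config.noise_sd, size=values.shape))
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=expr0.values.index, columns=expr0.values.columns)
    )
    table = pd.DataFrame(
        {
            "sample_id": list(fractions.keys()),
            "subject_id": subj,
            "group": ["patient"] * len(sample_ids)
            + ["healthy"] * (len(fractions) - len(sample_ids)),
            "true_fraction": list(fractions.values()),
        }
    )
    return expr, table
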