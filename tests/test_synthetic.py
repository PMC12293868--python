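"""Ground-truth structure of the synthetic cohort generator."""
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mcpkit import io as io_mod
from mcpkit.synthetic import (
    ARCHETYPES,
    CohortConfig,
    generate_burden_trajectory,
    generate_cohort,
)


class TestBurdenTrajectory:
    def test_complete_responder_decays_below_clinical_threshold(self):
        traj = generate_burden_trajectory("complete_responder", 28, 0.93)
        assert traj[0] == pytest.approx(0.93)
        assert traj[-1] < 0.05
        assert np.all(np.diff(traj) <= 1e-12)  # monotone non-increasing
        # normal levels reached by visit 19 (treatment cycle 7 of 12)
        assert traj[18] < 0.05
        assert np.all((traj >= 0) & (traj <= 1))

    def test_stable_archetype_is_flat(self):
        traj = generate_burden_trajectory("stable", 6, 0.5)
        assert np.allclose(traj, 0.5)

    def test_non_responder_18pct_drop_after_first_cycle(self):
        traj = generate_burden_trajectory("non_responder", 4, 0.90)
        assert traj[0] == pytest.approx(0.90)
        assert traj[-1] == pytest.approx(0.90 * 0.82)

    def test_rebound_returns_to_near_baseline(self):
        traj = generate_burden_trajectory("partial_responder_rebound", 28, 0.85)
        trough = traj.min()
        assert trough < 0.5 * 0.85
        assert traj[-1] >= 0.9 * 0.85

    def test_unknown_archetype_lists_valid_ones(self):
        with pytest.raises(ValueError) as exc:
            generate_burden_trajectory("miracle", 10, 0.9)
        for name in ARCHETYPES:
            assert name in str(exc.value)

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValueError):
            generate_burden_trajectory("stable", 1, 0.5)


@pytest.fixture(scope="module")
def noiseless():
    cfg = CohortConfig(n_genes=400, n_signature_genes=40, seed=5,
                       noise_sd=0.0, batch_sd=0.0)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="module")
def noiseless_mirna_bundle():
    cfg = CohortConfig(n_genes=300, n_signature_genes=40, seed=9,
                       mirna_noise_sd=0.0)
    return generate_cohort(cfg)


class TestExpressionMixture:
    def test_mixture_slope_recovery(self, noiseless):
        """Noiseless abundance is base·(1+(φ−1)f): regression on the true
        fraction recovers slope base·(φ−1) to 1e−9 relative error."""
        _, bundle = noiseless
        fracs = np.array([bundle.truth.true_fraction[s]
                          for s in bundle.expression.sample_ids])
        X = np.column_stack([np.ones_like(fracs), fracs])
        for gene, row in bundle.truth.signature_genes.iterrows():
            y = bundle.expression.values.loc[gene].to_numpy()
            (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
            phi = row["fold"]
            assert b == pytest.approx(a * (phi - 1.0), rel=1e-9)

    def test_plastin_like_ratio_matches_treatment_course(self, noiseless):
        """The calibrated marker spans an 18.7-fold change between the
        pre-treatment and deepest-remission samples."""
        _, bundle = noiseless
        gene = bundle.truth.signature_genes.index[0]
        vals = bundle.expression.values.loc[gene]
        visits = bundle.samples[(bundle.samples.group == "patient")
                                & (bundle.samples.phase != "relapse")]
        v = vals[visits.sample_id]
        assert v.iloc[0] / v.min() == pytest.approx(18.7, rel=1e-6)

    def test_repressor_spans_sixty_fold(self, noiseless):
        _, bundle = noiseless
        _, rep = bundle.truth.tf_pair
        vals = bundle.expression.values.loc[rep]
        visits = bundle.samples[(bundle.samples.group == "patient")
                                & (bundle.samples.phase != "relapse")]
        v = vals[visits.sample_id]
        assert v.max() / v.iloc[0] == pytest.approx(60.0, rel=1e-6)

    def test_zero_in_normal_genes_undetected_in_healthy(self, noiseless):
        _, bundle = noiseless
        truth = bundle.truth
        zgenes = truth.signature_genes.index[
            truth.signature_genes.zero_in_normal
        ]
        healthy = bundle.samples.loc[
            bundle.samples.group == "healthy", "sample_id"
        ]
        det = bundle.expression.detection_pvals.loc[zgenes, healthy]
        assert (det > 0.05).all().all()


class TestMethylation:
    def test_planted_probe_mixture_endpoints(self):
        cfg = CohortConfig(n_genes=200, n_signature_genes=30, seed=3,
                           meth_noise_sd=0.0)
        bundle = generate_cohort(cfg)
        beta = bundle.beta.beta
        fr = bundle.truth.true_fraction
        for probe, (b_mal, b_norm) in \
                bundle.truth.planted_hypomethylated_probes.items():
            for s in beta.columns:
                expect = fr[s] * b_mal + (1 - fr[s]) * b_norm
                assert beta.loc[probe, s] == pytest.approx(expect, abs=1e-12)

    def test_betas_always_clipped_to_unit_interval(self):
        cfg = CohortConfig(n_genes=100, n_signature_genes=10, seed=3,
                           meth_noise_sd=0.5)  # noise large enough to overshoot
        bundle = generate_cohort(cfg)
        arr = bundle.beta.beta.to_numpy()
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestMirna:
    def test_planted_families_rise_at_least_twofold(self, noiseless_mirna_bundle):
        bundle = noiseless_mirna_bundle
        visits = bundle.samples[(bundle.samples.group == "patient")
                                & (bundle.samples.phase != "relapse")]
        early, late = visits.sample_id.iloc[0], visits.sample_id.iloc[-1]
        fams = bundle.mirna.family_members()
        for fam in bundle.truth.planted_mirna_families:
            for m in fams[fam]:
                row = bundle.mirna.values.loc[m]
                assert row[late] / row[early] >= 2.0

    def test_unplanted_families_flat_in_noiseless_limit(self, noiseless_mirna_bundle):
        bundle = noiseless_mirna_bundle
        fams = bundle.mirna.family_members()
        flat = set(fams) - bundle.truth.planted_mirna_families
        for fam in sorted(flat)[:10]:
            for m in fams[fam]:
                row = bundle.mirna.values.loc[m]
                assert row.max() / row.min() == pytest.approx(1.0, abs=1e-9)

    def test_target_tables_reference_signature_genes(self, noiseless_mirna_bundle):
        bundle = noiseless_mirna_bundle
        sig = set(bundle.truth.signature_genes.index)
        for fam, targets in bundle.targets.items():
            assert set(targets) <= sig


class TestCohortBundle:
    def test_sample_counts_match_study_design(self, default_bundle):
        s = default_bundle.samples
        visits = s[(s.group == "patient") & (s.phase != "relapse")]
        assert len(visits) == 28
        assert (s.phase == "relapse").sum() == 1
        assert (s.group == "healthy").sum() == 9
        assert visits["observed_fraction"].notna().sum() == 9

    def test_relapse_burden_is_one_third_of_pretreatment(self, default_bundle):
        s = default_bundle.samples.set_index("sample_id")
        relapse = s[s.phase == "relapse"].iloc[0]
        assert relapse.true_fraction == pytest.approx(0.93 / 3)

    def test_healthy_samples_have_zero_true_fraction(self, default_bundle):
        s = default_bundle.samples
        assert (s.loc[s.group == "healthy", "true_fraction"] == 0).all()

    def test_truth_closure(self, default_bundle):
        """Every planted entity resolves to a row of a generated matrix."""
        b = default_bundle
        genes = set(b.expression.values.index)
        assert set(b.truth.signature_genes.index) <= genes
        assert b.truth.planted_motif_genes <= genes
        assert set(b.truth.tf_pair) <= genes
        assert set(b.truth.triple_regulated) <= genes
        probes = set(b.beta.beta.index)
        assert set(b.truth.planted_hypomethylated_probes) <= probes
        fams = set(b.mirna.family_map.values())
        assert b.truth.planted_mirna_families <= fams
        for targets in b.truth.mirna_targets.values():
            assert set(targets) <= genes
        samples = set(b.expression.values.columns)
        assert set(b.truth.true_fraction) == samples

    def test_determinism_byte_identical(self, tmp_path):
        cfg = dict(n_genes=300, n_signature_genes=30, seed=17)
        digests = []
        for run in ("a", "b"):
            bundle = generate_cohort(CohortConfig(**cfg))
            out = tmp_path / run
            io_mod.write_bundle(bundle, out)
            h = hashlib.sha256()
            for p in sorted(Path(out).iterdir()):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(pre_treatment_fraction=1.5)
        with pytest.raises(ValueError):
            CohortConfig(fold_range=(0.9, 20))
        with pytest.raises(ValueError):
            CohortConfig(archetype="unknown")
        with pytest.raises(ValueError):
            CohortConfig(n_planted_mirnas=200, n_mirna_families=100)
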