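"""Multiplicity adjustment and regulatory-layer statistics."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mcpkit.regulation import (
    bh_adjust,
    bonferroni_adjust,
    detect_methylation_changes,
    fisher_exact_2x2,
    hypergeom_overlap,
    mirna_target_coverage,
    motif_enrichment,
    regulatory_overlap_matrix,
    select_treatment_mirnas,
)


def hypergeom_tail_oracle(A, B, C, k):
    """Exact rational upper-tail P(X >= k) by direct enumeration."""
    denom = math.comb(C, B)
    total = Fraction(0)
    for kk in range(k, min(A, B) + 1):
        total += Fraction(math.comb(A, kk) * math.comb(C - A, B - kk), denom)
    return float(total)


def fisher_two_sided_oracle(table):
    """Minimum-likelihood two-sided p by rational enumeration."""
    (a, b), (c, d) = table
    r1, c1, N = a + b, a + c, a + b + c + d
    denom = math.comb(N, c1)
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(N - r1, c1 - k), denom)
           for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestAdjustments:
    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_input_order_preserved(self):
        p = [0.04, 0.001, 0.2]
        q = bh_adjust(p)
        assert q[1] == min(q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_independent_step_up_oracle(self, p):
        """BH output equals a from-scratch step-up computation."""
        p = np.asarray(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expect, atol=1e-12)

    @pytest.mark.parametrize("p,m,expect", [(0.01, 10, 0.1), (0.5, 10, 1.0)])
    def test_bonferroni(self, p, m, expect):
        adj = bonferroni_adjust([p] + [1.0] * (m - 1))
        assert adj[0] == pytest.approx(expect)

    def test_bonferroni_identity_for_single_test(self):
        assert bonferroni_adjust([0.2]) == pytest.approx([0.2])


class TestHypergeomOverlap:
    def test_expected_and_fold_formula(self):
        res = hypergeom_overlap(10, 20, 100, 2)
        assert res.expected == pytest.approx(2.0)
        assert res.fold == pytest.approx(1.0)

    def test_degenerate_full_draw(self):
        res = hypergeom_overlap(5, 20, 20, 5)
        assert res.p_value == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        res = hypergeom_overlap(5, 5, 20, 4)
        assert res.p_value == pytest.approx(
            hypergeom_tail_oracle(5, 5, 20, 4), abs=1e-12)

    @given(st.data())
    def test_oracle_agreement_property(self, data):
        C = data.draw(st.integers(1, 30))
        A = data.draw(st.integers(0, C))
        B = data.draw(st.integers(0, C))
        k = data.draw(st.integers(max(0, A + B - C), min(A, B)))
        res = hypergeom_overlap(A, B, C, k)
        assert res.p_value == pytest.approx(
            hypergeom_tail_oracle(A, B, C, k), abs=1e-10)
        if C:
            assert res.expected == A * B / C  # exact identity

    def test_precondition_violations_name_inequality(self):
        with pytest.raises(ValueError, match="A"):
            hypergeom_overlap(40, 5, 30, 2)
        with pytest.raises(ValueError, match="k"):
            hypergeom_overlap(5, 5, 30, 6)


class TestFisher:
    def test_diagonal_table(self):
        p, _ = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_uniform_table(self):
        p, odds = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_empty_margin(self):
        p, odds = fisher_exact_2x2([[0, 0], [3, 5]])
        assert p == 1.0 and np.isnan(odds)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_transpose_symmetry(self, cells):
        a, b, c, d = cells
        p1, _ = fisher_exact_2x2([[a, b], [c, d]])
        p2, _ = fisher_exact_2x2([[a, c], [b, d]])
        assert p1 == pytest.approx(p2, abs=1e-12)

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p, _ = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(
            fisher_two_sided_oracle([[a, b], [c, d]]), abs=1e-10)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestMotifEnrichment:
    def test_fold_arithmetic(self):
        universe = {f"u{i}" for i in range(1000)}
        gene_set = {f"u{i}" for i in range(100)}
        motif = {f"u{i}" for i in range(50)} | {
            f"u{i}" for i in range(100, 300)}  # 50% of set, 25% of universe
        df = motif_enrichment(gene_set, {"M": motif}, universe)
        assert df.loc["M", "fold"] == pytest.approx(2.0)

    def test_absent_motif_fold_zero(self):
        universe = {f"u{i}" for i in range(100)}
        df = motif_enrichment({"u1", "u2"}, {"M": {"u50", "u60"}}, universe)
        assert df.loc["M", "fold"] == 0.0
        assert not df.loc["M", "significant"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            motif_enrichment(set(), {"M": set()}, set())

    def test_planted_motif_is_top_hit(self, default_bundle,
                                      regulatory_results):
        motif = regulatory_results["motif"]
        assert motif.index[0] == "PARBZIP_MOTIF"
        assert bool(motif.iloc[0]["significant"])


class TestMirnaSelection:
    def _matrix(self, folds, n_early=6, n_late=8, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows, index = [], []
        for i, fold in enumerate(folds):
            early = 100.0 * np.exp(rng.normal(0, noise, n_early))
            late = 100.0 * fold * np.exp(rng.normal(0, noise, n_late))
            rows.append(np.concatenate([early, late]))
            index.append(f"fam{i}.m1")
        cols = [f"e{j}" for j in range(n_early)] + [
            f"l{j}" for j in range(n_late)]
        df = pd.DataFrame(rows, index=index, columns=cols)
        fam_map = {f"fam{i}.m1": f"fam{i}" for i in range(len(folds))}
        return df, fam_map, cols[:n_early], cols[n_early:]

    def test_induced_family_selected_and_flat_not(self):
        df, fam_map, early, late = self._matrix([5.0, 1.0])
        out = select_treatment_mirnas(df, early, late, family_map=fam_map)
        assert bool(out.loc["fam0", "selected"])
        assert not bool(out.loc["fam1", "selected"])

    def test_fold_boundary_excludes_1_8(self):
        df, fam_map, early, late = self._matrix([1.8], noise=0.001)
        out = select_treatment_mirnas(df, early, late, family_map=fam_map)
        assert out.loc["fam0", "q_value"] < 0.001  # significant ...
        assert not bool(out.loc["fam0", "selected"])  # ... but below 2-fold

    def test_planted_families_recovered_on_cohort(self, default_bundle,
                                                  regulatory_results):
        selected = set(regulatory_results["selected_families"])
        planted = default_bundle.truth.planted_mirna_families
        assert selected == planted
        assert len(selected) == 24

    def test_needs_two_samples_per_group(self):
        df, fam_map, early, late = self._matrix([2.0])
        with pytest.raises(ValueError):
            select_treatment_mirnas(df, early[:1], late, family_map=fam_map)


class TestTargetCoverage:
    def test_disjoint_blocks(self):
        gene_set = {f"g{i}" for i in range(30)}
        universe = {f"g{i}" for i in range(100)}
        targets = {
            "f1": {f"g{i}" for i in range(10)},
            "f2": {f"g{i}" for i in range(10, 20)},
            "f3": {f"g{i}" for i in range(20, 30)},
        }
        out = mirna_target_coverage(list(targets), targets, gene_set, universe)
        assert out["coverage"]["ge1"] == 30
        assert out["coverage"]["ge3"] == 0

    def test_gene_hit_by_five_families(self):
        gene_set = {"hub", "other"}
        universe = gene_set | {f"u{i}" for i in range(50)}
        targets = {f"f{i}": {"hub"} for i in range(5)}
        targets["f5"] = {"other"}
        out = mirna_target_coverage(list(targets), targets, gene_set, universe)
        assert out["coverage"]["ge5"] == 1

    def test_per_family_p_matches_oracle(self):
        gene_set = {f"g{i}" for i in range(8)}
        universe = {f"g{i}" for i in range(25)}
        targets = {"f1": {f"g{i}" for i in range(5, 15)}}
        out = mirna_target_coverage(["f1"], targets, gene_set, universe)
        res = out["per_family"]["f1"]
        assert res.p_value == pytest.approx(
            hypergeom_tail_oracle(8, 10, 25, res.observed), abs=1e-10)

    def test_family_without_targets_is_zero_coverage(self):
        out = mirna_target_coverage(["f1"], {}, {"g1"}, {"g1", "g2"})
        assert out["coverage"]["ge1"] == 0


class TestMethylationChanges:
    def test_planted_probes_on_cohort(self, default_bundle,
                                      regulatory_results):
        meth = regulatory_results["methylation"]
        truth = default_bundle.truth.planted_hypomethylated_probes
        strong = [p for p, (bm, bn) in truth.items() if bn - bm >= 0.3]
        weak = [p for p, (bm, bn) in truth.items()
                if abs((bn - bm) - 0.15) < 1e-9]
        assert meth.loc[strong, "significant"].all()
        assert (meth.loc[strong, "direction"]
                == "hypomethylated_in_malignant").all()
        # the 0.15-delta probe is real but below the 0.20 threshold
        assert weak and not meth.loc[weak, "significant"].any()

    def test_constant_probe_excluded(self):
        samples = [f"s{j}" for j in range(12)]
        fr = pd.Series(np.linspace(0.9, 0.05, 12), index=samples)
        beta = pd.DataFrame(
            [np.full(12, 0.5), 0.2 + 0.5 * fr.to_numpy()],
            index=["flat", "tracks"], columns=samples,
        )
        out = detect_methylation_changes(beta, fr)
        assert bool(out.loc["flat", "excluded_constant"])
        assert not bool(out.loc["flat", "significant"])
        assert bool(out.loc["tracks", "significant"])

    def test_shuffled_labels_break_significance(self):
        rng = np.random.default_rng(5)
        samples = [f"s{j}" for j in range(24)]
        fr = pd.Series(np.linspace(0.93, 0.03, 24), index=samples)
        beta_vals = 0.2 + 0.5 * (1 - fr.to_numpy())
        hits = 0
        reps = 20
        for _ in range(reps):
            shuffled = rng.permutation(beta_vals)
            noise = rng.normal(0, 0.01, (30, 24))
            rows = np.clip(shuffled + noise, 0, 1)
            beta = pd.DataFrame(rows, index=[f"p{i}" for i in range(30)],
                                columns=samples)
            out = detect_methylation_changes(beta, fr)
            hits += int(out["significant"].any())
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestOverlapMatrix:
    def test_identical_sets(self):
        s = {f"g{i}" for i in range(10)}
        universe = {f"g{i}" for i in range(40)}
        out = regulatory_overlap_matrix(s, s, s, universe)
        for res in out["pairwise"].values():
            assert res.fold == pytest.approx(40 / 10)
        assert set(out["triple_members"]) == s

    def test_disjoint_sets(self):
        universe = {f"g{i}" for i in range(30)}
        out = regulatory_overlap_matrix(
            {f"g{i}" for i in range(5)},
            {f"g{i}" for i in range(5, 10)},
            {f"g{i}" for i in range(10, 15)},
            universe,
        )
        for res in out["pairwise"].values():
            assert res.observed == 0 and res.fold == 0.0
        assert out["triple_size"] == 0

    def test_eleven_gene_triple_fixture(self):
        """Eleven genes planted in all three regulatory layers are returned
        exactly as the triple intersection."""
        eleven = {f"triple{i}" for i in range(11)}
        universe = eleven | {f"bg{i}" for i in range(280)}
        motif = eleven | {f"bg{i}" for i in range(100)}
        mirna = eleven | {f"bg{i}" for i in range(100, 180)}
        meth = eleven | {f"bg{i}" for i in range(180, 230)}
        out = regulatory_overlap_matrix(motif, mirna, meth, universe)
        assert out["triple_size"] == 11
        assert set(out["triple_members"]) == eleven

    def test_cohort_triple_contains_planted_genes(self, default_bundle,
                                                  regulatory_results):
        planted = set(default_bundle.truth.triple_regulated)
        assert planted <= set(regulatory_results["overlap"]["triple_members"])

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            regulatory_overlap_matrix({"x"}, set(), set(), {"y"})
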