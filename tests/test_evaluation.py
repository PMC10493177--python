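from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mosaicsim as ms
from mosaicsim.evaluation import (
    EvalReport,
    adversarial_accuracy,
    build_report,
    diversity_pct,
    generalizability_pct,
    kinship,
    kinship_matrix,
    ld_decay,
    ld_divergence,
    maf_divergence,
    pc_alignment,
    relatedness_counts,
)

from conftest import binomial_cohort, make_genotype_matrix


class TestMafDivergence:
    def test_identity_hand_value_and_symmetry(self):
        a = make_genotype_matrix([[0, 0], [0, 2], [2, 2], [0, 0]])
        assert maf_divergence(a, a) == 0.0
        # MAF pairs (0.1, 0.2) and (0.3, 0.3) -> mean |diff| = 0.05
        rng = np.random.default_rng(0)
        x = make_genotype_matrix(np.column_stack([
            rng.permutation([1] * 2 + [0] * 8),   # f = 0.1
            rng.permutation([1] * 6 + [0] * 4),   # f = 0.3
        ]))
        y = make_genotype_matrix(np.column_stack([
            rng.permutation([1] * 4 + [0] * 6),   # f = 0.2
            rng.permutation([1] * 6 + [0] * 4),   # f = 0.3
        ]))
        assert maf_divergence(x, y) == pytest.approx(0.05)
        assert maf_divergence(x, y) == maf_divergence(y, x)

    def test_variant_mismatch_rejected(self):
        a = make_genotype_matrix([[0, 1]])
        b = make_genotype_matrix([[0, 1]], positions=[5, 6])
        with pytest.raises(ValueError):
            maf_divergence(a, b)


class TestLdDecay:
    def test_duplicated_column_gives_r2_one_in_its_bin(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, 50).astype(np.uint8)
        other = rng.integers(0, 3, 50).astype(np.uint8)
        # duplicate pair at 0.1 Mb distance, unrelated SNP far away
        gm = make_genotype_matrix(np.column_stack([col, col, other]),
                                  positions=[100_000, 200_000, 900_000])
        bins = np.linspace(0, 1, 11)
        _, curve = ld_decay(gm, bins=bins, maf_min=0.0)
        assert curve[1] == pytest.approx(1.0)  # the pair at 0.1 Mb

    def test_bruteforce_oracle_small_instance(self):
        rng = np.random.default_rng(2)
        n, k = 20, 40
        gm = binomial_cohort(rng, n, k)
        bins = np.linspace(0, 1, 21)
        _, curve = ld_decay(gm, bins=bins, maf_min=0.0)
        X = gm.dosages.astype(float)
        pos = gm.variants["pos"].to_numpy() / 1e6
        sums = np.zeros(20)
        counts = np.zeros(20)
        for i in range(k):
            for j in range(i + 1, k):
                d = pos[j] - pos[i]
                if d >= 1.0 or np.std(X[:, i]) == 0 or np.std(X[:, j]) == 0:
                    continue
                b = int(np.digitize(d, bins)) - 1  # same edge convention
                sums[b] += np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
                counts[b] += 1
        expected = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(curve, expected, atol=1e-12)

    def test_independent_snps_hit_small_sample_floor(self):
        rng = np.random.default_rng(3)
        n = 200
        gm = binomial_cohort(rng, n, 150)
        _, curve = ld_decay(gm, maf_min=0.0)
        mean_r2 = np.nanmean(curve)
        assert mean_r2 == pytest.approx(1 / (n - 1), rel=0.2)

    def test_empty_bins_are_nan_not_zero(self):
        gm = make_genotype_matrix([[0, 1], [1, 2], [2, 0], [1, 1]],
                                  positions=[100, 200])
        _, curve = ld_decay(gm, maf_min=0.0)
        assert np.isnan(curve[10:]).all()

    def test_maf_filter_errors_when_nothing_passes(self):
        gm = make_genotype_matrix([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            ld_decay(gm)


class TestLdDivergence:
    def test_hand_values_and_missing_bins(self):
        assert ld_divergence([0.5, 0.2], [0.5, 0.2]) == 0.0
        assert ld_divergence([0.5, 0.2], [0.5, 0.1]) == pytest.approx(0.1)
        assert ld_divergence([0.5, np.nan, 0.2],
                             [0.5, 0.9, 0.1]) == pytest.approx(0.1)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.random((3, 8))
        assert ld_divergence(a, c) <= ld_divergence(a, b) + ld_divergence(b, c) + 1e-12


class TestPcAlignment:
    def test_identical_datasets_score_one(self, small_fixture):
        panel, _, _ = small_fixture
        gm = panel.as_genotypes()
        assert pc_alignment(gm, gm) == pytest.approx(1.0, abs=1e-6)

    def test_permuted_columns_score_near_random_baseline(self, small_fixture):
        panel, _, _ = small_fixture
        gm = panel.as_genotypes()
        rng = np.random.default_rng(4)
        shuffled = gm.dosages.copy()
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        other = make_genotype_matrix(shuffled,
                                     positions=gm.variants["pos"].to_numpy())
        score = pc_alignment(gm, other)
        assert 0.0 <= score < 0.25

    def test_too_few_samples_rejected(self):
        gm = binomial_cohort(np.random.default_rng(0), 10, 30)
        with pytest.raises(ValueError):
            pc_alignment(gm, gm, n_pcs=20)


class TestKinship:
    def test_self_kinship_is_half(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        assert kinship(g, g) == pytest.approx(0.5)

    def test_hand_worked_eight_snp_pair(self):
        # 2 shared hets, 1 opposite homozygote, 4 hets each -> (2-2)/8 = 0
        gi = np.array([1, 1, 1, 1, 0, 2, 0, 0])
        gj = np.array([1, 1, 0, 2, 2, 2, 1, 1])
        assert kinship(gi, gj) == pytest.approx(0.0)

    def test_unrelated_pairs_mean_near_zero(self):
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.1, 0.5, 400)
        a = binomial_cohort(rng, 1000, 400, freqs=freqs)
        b = binomial_cohort(rng, 1000, 400, freqs=freqs)
        phi = np.array([kinship(a.dosages[i], b.dosages[i]) for i in range(1000)])
        assert abs(phi.mean()) < 0.01

    def test_no_heterozygotes_rejected(self):
        with pytest.raises(ValueError):
            kinship(np.array([0, 2, 0]), np.array([2, 0, 2]))

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(6)
        a = binomial_cohort(rng, 8, 100)
        b = binomial_cohort(rng, 5, 100)
        mat = kinship_matrix(a, b)
        for i in range(8):
            for j in range(5):
                assert mat[i, j] == pytest.approx(
                    kinship(a.dosages[i], b.dosages[j]), abs=1e-12)


class TestRelatednessCounts:
    def test_copy_cohort_all_duplicates(self):
        rng = np.random.default_rng(7)
        ref = binomial_cohort(rng, 20, 300)
        n_dup, n_first, n_second = relatedness_counts(ref, ref)
        assert n_dup >= 20  # every sample matches its own copy

    def test_disjoint_panels_have_no_relatives(self):
        rng = np.random.default_rng(8)
        a = binomial_cohort(rng, 30, 500)
        b = binomial_cohort(rng, 30, 500)
        assert relatedness_counts(a, b) == (0, 0, 0)

    def test_within_set_pair_enumeration(self):
        rng = np.random.default_rng(9)
        a = binomial_cohort(rng, 3, 200)
        counts = relatedness_counts(a)
        assert all(c >= 0 for c in counts)
        # 3 unordered pairs exist; unrelated i.i.d. samples -> no duplicates
        assert counts[0] == 0


class TestFormulas:
    def test_generalizability_hand_values(self):
        assert generalizability_pct(0, 10, 10) == 100.0
        assert generalizability_pct(100, 10, 10) == 0.0
        assert generalizability_pct(31, 1000, 775) == pytest.approx(
            (1 - 31 / 775_000) * 100)

    def test_diversity_hand_values(self):
        assert diversity_pct(0, 100) == 100.0
        assert diversity_pct(9900, 100) == 0.0
        # 5 unordered related pairs among 100 samples -> 10 ordered
        assert diversity_pct(2 * 5, 100) == pytest.approx(
            (1 - 10 / 9900) * 100)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(2, 10_000), st.integers(1, 10_000), st.integers(0, 100))
    def test_exact_rational_arithmetic(self, n_syn, n_ref, n_close):
        n_cross = min(n_close, n_syn * n_ref)
        expected = float((1 - Fraction(n_cross, n_syn * n_ref)) * 100)
        assert generalizability_pct(n_cross, n_syn, n_ref) == pytest.approx(
            expected, rel=1e-12)
        n_pairs = min(2 * n_close, n_syn**2 - n_syn)
        expected = float((1 - Fraction(n_pairs, n_syn**2 - n_syn)) * 100)
        assert diversity_pct(n_pairs, n_syn) == pytest.approx(expected, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            generalizability_pct(-1, 10, 10)
        with pytest.raises(ValueError):
            diversity_pct(0, 1)


class TestAdversarialAccuracy:
    def test_exact_copy_scores_zero(self):
        rng = np.random.default_rng(10)
        ref = binomial_cohort(rng, 50, 200)
        syn = make_genotype_matrix(ref.dosages.copy())
        assert adversarial_accuracy(ref, syn) == 0.0

    def test_iid_split_is_near_chance(self):
        rng = np.random.default_rng(11)
        freqs = rng.uniform(0.05, 0.5, 300)
        a = binomial_cohort(rng, 500, 300, freqs=freqs)
        b = binomial_cohort(rng, 500, 300, freqs=freqs)
        assert adversarial_accuracy(a, b) == pytest.approx(0.5, abs=0.05)

    def test_separated_distributions_score_high(self):
        rng = np.random.default_rng(12)
        a = binomial_cohort(rng, 40, 300, freqs=np.full(300, 0.1))
        b = binomial_cohort(rng, 40, 300, freqs=np.full(300, 0.9))
        assert adversarial_accuracy(a, b) > 0.95

    def test_minimum_sizes(self):
        a = binomial_cohort(np.random.default_rng(0), 1, 10)
        with pytest.raises(ValueError):
            adversarial_accuracy(a, a)


class TestBuildReport:
    def test_identity_bundle(self, small_fixture):
        panel, gmap, _ = small_fixture
        gm = panel.as_genotypes()
        rep = build_report(gm, gm, gmap)
        assert rep.maf_divergence == 0.0
        assert rep.ld_divergence == 0.0
        assert rep.pc_alignment == pytest.approx(1.0, abs=1e-6)
        assert rep.adversarial_accuracy == 0.0

    def test_report_roundtrip_and_map_fallback(self, small_fixture, tmp_path):
        panel, _, _ = small_fixture
        gm = panel.as_genotypes()
        other = binomial_cohort(np.random.default_rng(13), 50, panel.n_variants)
        other.variants["pos"] = gm.variants["pos"].to_numpy()
        rep = build_report(gm, other, gmap=None, out_path=tmp_path / "r.tsv")
        assert any("map" in w for w in rep.warnings)
        back = EvalReport.from_file(tmp_path / "r.tsv")
        assert back.maf_divergence == pytest.approx(rep.maf_divergence)
        assert back.relatedness_cross == tuple(rep.relatedness_cross)
        assert (tmp_path / "r.tsv.ld.tsv").exists()
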