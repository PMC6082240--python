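"""Dosage r², two-locus EM, and the windowed pairwise scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldecay import (
    MISSING,
    PairCounts,
    em_haplotype_freqs,
    genotype_r2,
    ld_pair_frame,
    pairwise_ld,
    simulate_block_ld,
)

from conftest import make_dataset, random_dosages


def pearson_r2_oracle(a, b):
    """Brute-force oracle: mask, then np.corrcoef on the complete subset."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    x, y = a[ok], b[ok]
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


dosage_vectors = st.lists(
    st.sampled_from([0, 1, 2, MISSING]), min_size=4, max_size=40
)


class TestGenotypeR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        r2, n = genotype_r2(a, a)
        assert r2 == pytest.approx(1.0) and n == 6

    def test_hand_value(self):
        # verified against an independent from-scratch Pearson computation
        r2, n = genotype_r2([0, 0, 1, 1, 2, 2], [0, 1, 0, 2, 1, 2])
        assert r2 == pytest.approx(0.25, abs=1e-15) and n == 6

    def test_matches_corrcoef_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            a = random_dosages(rng, 50, 1, missing_rate=0.15)[:, 0]
            b = random_dosages(rng, 50, 1, missing_rate=0.15)[:, 0]
            got, _ = genotype_r2(a, b)
            want = pearson_r2_oracle(a, b)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=dosage_vectors, b=dosage_vectors)
    def test_symmetry_and_relabel_invariance(self, a, b):
        m = min(len(a), len(b))
        a = np.array(a[:m], dtype=np.int8)
        b = np.array(b[:m], dtype=np.int8)
        r_ab, _ = genotype_r2(a, b)
        r_ba, _ = genotype_r2(b, a)
        flip = np.where(b == MISSING, MISSING, 2 - b).astype(np.int8)
        r_aflip, _ = genotype_r2(a, flip)
        if np.isnan(r_ab):
            assert np.isnan(r_ba) and np.isnan(r_aflip)
        else:
            assert r_ab == pytest.approx(r_ba, abs=1e-12)
            assert r_ab == pytest.approx(r_aflip, abs=1e-12)

    def test_perfect_ld_after_relabel(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        r2, _ = genotype_r2(a, 2 - a)
        assert r2 == pytest.approx(1.0)

    def test_appending_missing_samples_is_a_noop(self, rng):
        a = random_dosages(rng, 30, 1, 0.0)[:, 0]
        b = random_dosages(rng, 30, 1, 0.0)[:, 0]
        r_base, n_base = genotype_r2(a, b)
        a2 = np.concatenate([a, [MISSING, 0, MISSING]])
        b2 = np.concatenate([b, [1, MISSING, MISSING]])
        r_ext, n_ext = genotype_r2(a2, b2)
        assert n_ext == n_base
        assert r_ext == pytest.approx(r_base, abs=1e-15)

    def test_zero_variance_undefined(self):
        r2, _ = genotype_r2([1, 1, 1, 1], [0, 1, 2, 1])
        assert np.isnan(r2)

    def test_too_few_complete_pairs_undefined(self):
        r2, n = genotype_r2([0, MISSING, MISSING], [1, 0, 2])
        assert np.isnan(r2) and n == 1

    def test_affine_dependence_gives_one(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
        r2, _ = genotype_r2(a, a)  # identity is affine
        assert r2 == pytest.approx(1.0)


class TestEmHaplotypes:
    def test_no_double_hets_is_exact_at_first_pass(self):
        # genotypes built from phased haplotypes AB,AB,ab,ab,Ab,aB (no 1/1 pair)
        a = np.array([2, 0, 2, 0])  # individuals: AB/AB, ab/ab, AB/Ab? keep simple
        b = np.array([2, 0, 0, 2])
        est = em_haplotype_freqs(a, b)
        # hand count: ind1 2xAB, ind2 2xab, ind3 2xAb, ind4 2xaB over 8 haplotypes
        assert est.freqs == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-12)
        assert est.converged

    def test_recovers_simulated_haplotype_freqs(self):
        truth = (0.35, 0.15, 0.15, 0.35)
        ds = simulate_block_ld(truth, n_sample=10_000, seed=11)
        a, b = ds.dosages[:, 0], ds.dosages[:, 1]
        est = em_haplotype_freqs(a, b)
        assert est.converged
        np.testing.assert_allclose(est.freqs, truth, atol=0.01)
        # truth: D = 0.35 - 0.25 = 0.1, r2 = 0.01/0.0625 = 0.16
        assert est.D == pytest.approx(0.1, abs=0.01)
        assert est.r_squared_hap == pytest.approx(0.16, abs=0.02)

    def test_independent_loci_near_zero(self):
        ds = simulate_block_ld((0.25, 0.25, 0.25, 0.25), n_sample=10_000, seed=5)
        est = em_haplotype_freqs(ds.dosages[:, 0], ds.dosages[:, 1])
        assert abs(est.D) < 0.01
        assert est.r_squared_hap < 0.005

    def test_frequencies_sum_to_one(self, rng):
        for seed in range(5):
            ds = simulate_block_ld((0.4, 0.2, 0.1, 0.3), n_sample=500, seed=seed)
            est = em_haplotype_freqs(ds.dosages[:, 0], ds.dosages[:, 1])
            assert est.freqs.sum() == pytest.approx(1.0, abs=1e-10)
            assert est.D == pytest.approx(est.freq_AB - (est.freq_AB + est.freq_Ab) * (est.freq_AB + est.freq_aB), abs=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            em_haplotype_freqs([0, 0, 0], [0, 1, 2])


class TestPairwiseLd:
    def test_three_snps_give_three_pairs(self, rng):
        d = random_dosages(rng, 30, 3, 0.0)
        ds = make_dataset(d, positions=[1000, 2000, 3000])
        pairs = list(pairwise_ld(ds, max_distance_bp=1_000_000))
        assert len(pairs) == 3

    def test_cross_chromosome_pairs_excluded(self, rng):
        d = random_dosages(rng, 30, 2, 0.0)
        ds = make_dataset(d, chromosomes=["1", "2"], positions=[1000, 2000])
        assert list(pairwise_ld(ds, max_distance_bp=1_000_000)) == []

    def test_matches_brute_force_double_loop(self, rng):
        d = random_dosages(rng, 40, 50, missing_rate=0.1)
        chroms = ["1"] * 25 + ["2"] * 25
        positions = sorted(rng.integers(1, 500_000, size=25)) + sorted(
            rng.integers(1, 500_000, size=25)
        )
        ds = make_dataset(d, chromosomes=chroms, positions=positions)
        max_d = 200_000

        got = {(p.snp_i, p.snp_j): p for p in pairwise_ld(ds, max_d)}

        want = {}
        for i in range(50):
            for j in range(i + 1, 50):
                if chroms[i] != chroms[j]:
                    continue
                dist = abs(positions[j] - positions[i])
                if dist == 0 or dist > max_d:
                    continue
                r2 = pearson_r2_oracle(d[:, i], d[:, j])
                if np.isnan(r2):
                    continue
                key = (f"snp{i + 1}", f"snp{j + 1}")
                want[key] = (dist, r2)

        assert set(got) == set(want)
        for key, (dist, r2) in want.items():
            assert got[key].distance_bp == dist
            assert got[key].r_squared == pytest.approx(r2, abs=1e-12)

    def test_frame_equals_generator(self, rng):
        d = random_dosages(rng, 25, 30, missing_rate=0.15)
        positions = np.sort(rng.integers(1, 300_000, size=30))
        ds = make_dataset(d, positions=positions)
        gen_counts = PairCounts()
        gen_pairs = list(pairwise_ld(ds, 100_000, r2_min=0.1, counts=gen_counts))
        frame, frame_counts = ld_pair_frame(ds, 100_000, r2_min=0.1)
        assert frame_counts.as_dict() == gen_counts.as_dict()
        assert len(frame) == len(gen_pairs)
        for row, p in zip(frame.itertuples(), gen_pairs):
            assert (row.snp_i, row.snp_j) == (p.snp_i, p.snp_j)
            assert row.r_squared == pytest.approx(p.r_squared, abs=1e-12)

    def test_zero_distance_pairs_counted_not_emitted(self, rng):
        d = random_dosages(rng, 20, 2, 0.0)
        ds = make_dataset(d, positions=[5000, 5000])
        counts = PairCounts()
        pairs = list(pairwise_ld(ds, 100_000, counts=counts))
        assert pairs == [] and counts.n_zero_distance == 1

    def test_unsorted_dataset_rejected(self, rng):
        d = random_dosages(rng, 10, 2, 0.0)
        ds = make_dataset(d, positions=[2000, 1000])
        with pytest.raises(ValueError, match="sort"):
            list(pairwise_ld(ds, 100_000))

    def test_r2_min_filter_tallies(self, rng):
        d = random_dosages(rng, 40, 10, 0.0)
        ds = make_dataset(d, positions=np.arange(1, 11) * 1000)
        all_counts = PairCounts()
        all_pairs = list(pairwise_ld(ds, 100_000, counts=all_counts))
        filt_counts = PairCounts()
        filt_pairs = list(pairwise_ld(ds, 100_000, r2_min=0.1, counts=filt_counts))
        assert filt_counts.n_emitted + filt_counts.n_filtered == all_counts.n_emitted
        assert all(p.r_squared >= 0.1 for p in filt_pairs)
        assert len(all_pairs) == all_counts.n_emitted
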