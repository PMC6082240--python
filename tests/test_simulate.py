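"""Wright-Fisher simulator, exact-LD block fixtures, Sved curve and Ne fit."""

import numpy as np
import pytest

from ldecay import (
    MISSING,
    SimConfig,
    bin_decay,
    expected_r2_sved,
    fit_ne_from_decay,
    genotype_r2,
    ld_pair_frame,
    simulate_block_ld,
    simulate_wright_fisher,
)
from ldecay.simulate import _evolve_chromosome


class TestSimConfig:
    def test_sample_larger_than_population_rejected(self):
        with pytest.raises(ValueError, match="n_sample"):
            SimConfig(effective_size_ne=10, n_sample=11)

    def test_equally_spaced_positions(self):
        cfg = SimConfig(n_snps=4, chromosome_length_bp=4000)
        assert list(cfg.snp_positions()) == [1000, 2000, 3000, 4000]

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text(
            "effective_size_ne: 20\ngenerations: 5\nn_sample: 10\nn_snps: 8\n"
            "chromosome_length_bp: 100000\nseed: 7\ninit_maf_law: [uniform, 0.1, 0.4]\n"
        )
        cfg = SimConfig.from_yaml(p)
        assert cfg.effective_size_ne == 20
        assert cfg.init_maf_law == ("uniform", 0.1, 0.4)


class TestWrightFisher:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(effective_size_ne=20, generations=10, n_sample=15, n_snps=30,
                        chromosome_length_bp=1_000_000, missing_rate=0.05, seed=42)
        a = simulate_wright_fisher(cfg)
        b = simulate_wright_fisher(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps == b.snps and a.samples == b.samples

    def test_different_seed_differs(self):
        base = dict(effective_size_ne=20, generations=10, n_sample=15, n_snps=30,
                    chromosome_length_bp=1_000_000)
        a = simulate_wright_fisher(SimConfig(**base, seed=1))
        b = simulate_wright_fisher(SimConfig(**base, seed=2))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_no_recombination_copies_founder_haplotypes(self):
        # with map length 0 every gamete is a verbatim parental haplotype,
        # so after any number of generations each haplotype equals a founder
        rng = np.random.default_rng(3)
        founders = (rng.random((20, 15)) < 0.4).astype(np.uint8)
        pos_m = np.zeros(15)
        final = _evolve_chromosome(founders.copy(), pos_m, generations=30, rng=rng)
        founder_rows = {f.tobytes() for f in founders}
        assert all(h.tobytes() in founder_rows for h in final)

    def test_zero_generations_matches_init_law(self):
        # allele frequencies at generation 0 are the founder draws; their
        # mean over many SNPs estimates the mean of uniform(0.05, 0.5)
        cfg = SimConfig(effective_size_ne=200, generations=0, n_sample=200,
                        n_snps=400, chromosome_length_bp=10_000_000, seed=9)
        ds = simulate_wright_fisher(cfg)
        freqs = ds.dosages.mean(axis=0) / 2
        want = (0.05 + 0.5) / 2
        se = np.sqrt(np.var(freqs) / freqs.size)
        assert abs(freqs.mean() - want) < 4 * se + 0.01

    def test_dosage_codes_conserved(self):
        cfg = SimConfig(effective_size_ne=30, generations=20, n_sample=25, n_snps=40,
                        chromosome_length_bp=2_000_000, missing_rate=0.1, seed=4)
        ds = simulate_wright_fisher(cfg)
        assert set(np.unique(ds.dosages)) <= {0, 1, 2, MISSING}

    def test_multi_chromosome_layout(self):
        cfg = SimConfig(effective_size_ne=20, generations=5, n_sample=10, n_snps=6,
                        n_chromosomes=3, chromosome_length_bp=600_000, seed=1)
        ds = simulate_wright_fisher(cfg)
        assert ds.n_snps == 18
        assert sorted(set(ds.chromosomes)) == ["1", "2", "3"]
        assert ds.is_sorted()

    def test_returned_haplotypes_sum_to_dosages(self):
        cfg = SimConfig(effective_size_ne=20, generations=5, n_sample=12, n_snps=10,
                        chromosome_length_bp=500_000, seed=8)
        ds, haps = simulate_wright_fisher(cfg, return_haplotypes=True)
        assert np.array_equal(haps[0::2] + haps[1::2], ds.dosages)


class TestBlockLd:
    def test_no_ld_haplotypes_give_near_zero_r2(self):
        ds = simulate_block_ld((0.25, 0.25, 0.25, 0.25), n_sample=10_000, seed=1)
        r2, _ = genotype_r2(ds.dosages[:, 0], ds.dosages[:, 1])
        assert r2 < 0.002

    def test_coupling_only_haplotypes_give_perfect_ld(self):
        ds = simulate_block_ld((0.5, 0.0, 0.0, 0.5), n_sample=10_000, seed=2)
        r2, _ = genotype_r2(ds.dosages[:, 0], ds.dosages[:, 1])
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_known_population_r2_recovered(self):
        # D = 0.35 - 0.5*0.5 = 0.1 -> r2 = 0.01 / 0.0625 = 0.16
        ds = simulate_block_ld((0.35, 0.15, 0.15, 0.35), n_sample=10_000, seed=3)
        r2, _ = genotype_r2(ds.dosages[:, 0], ds.dosages[:, 1])
        assert r2 == pytest.approx(0.16, abs=0.03)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            simulate_block_ld((0.5, 0.5, 0.5, 0.5), n_sample=10, seed=0)

    def test_monomorphic_flagged_not_raised(self):
        ds = simulate_block_ld((0.5, 0.5, 0.0, 0.0), n_sample=100, seed=0)
        assert ds.monomorphic_warning


class TestSved:
    def test_zero_recombination_limit(self):
        assert expected_r2_sved(100, 0.0) == 1.0

    def test_closed_form_value(self):
        assert expected_r2_sved(50, 0.005) == pytest.approx(0.5)

    def test_sample_size_correction_additive(self):
        assert expected_r2_sved(50, 0.005, sample_n=100) == pytest.approx(0.51)

    def test_capped_at_one(self):
        assert expected_r2_sved(1, 1e-9, sample_n=2) == 1.0


class TestNeFit:
    def _noiseless_curve(self, ne, sample_n=None, width=50_000, max_dist=1_000_000):
        mids = np.arange(width // 2, max_dist, width)
        pairs = []
        from ldecay import LdPair

        for m in mids:
            r2 = expected_r2_sved(ne, m / 1e8, sample_n)
            pairs.append(LdPair("a", "b", "1", int(m), r2, 100))
        return bin_decay(pairs, width, max_dist)

    def test_noiseless_self_consistency(self):
        curve = self._noiseless_curve(100)
        fit = fit_ne_from_decay(curve, bp_per_morgan=1e8)
        assert fit.converged
        assert fit.ne_hat == pytest.approx(100, abs=1e-6)
        assert fit.residual_sse < 1e-20

    def test_noiseless_with_sample_correction(self):
        curve = self._noiseless_curve(250, sample_n=80)
        fit = fit_ne_from_decay(curve, bp_per_morgan=1e8, sample_n=80)
        assert fit.ne_hat == pytest.approx(250, abs=1e-4)

    def test_two_bins_rejected(self):
        curve = bin_decay(
            [],
            500_000,
            1_000_000,
        )
        with pytest.raises(ValueError, match="3 non-empty"):
            fit_ne_from_decay(curve)

    def test_filtered_curve_refused(self):
        curve = self._noiseless_curve(100)
        curve.r2_min_applied = 0.1
        with pytest.raises(ValueError, match="prefilter"):
            fit_ne_from_decay(curve)
        fit = fit_ne_from_decay(curve, allow_filtered=True)
        assert fit.ne_hat > 0

    def test_wright_fisher_recovery_single_seed(self):
        # one seed of the recovery experiment; the full 10-seed median check
        # lives in the acceptance suite
        cfg = SimConfig(effective_size_ne=100, generations=300, n_sample=100,
                        n_snps=120, n_chromosomes=4, chromosome_length_bp=3_000_000,
                        recomb_rate_per_bp=1e-8, seed=0)
        ds = simulate_wright_fisher(cfg)
        pairs, _ = ld_pair_frame(ds, 1_000_000)
        curve = bin_decay(pairs, 50_000, 1_000_000)
        fit = fit_ne_from_decay(curve, bp_per_morgan=1e8, sample_n=100)
        assert 30 < fit.ne_hat < 300
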