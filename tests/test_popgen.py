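"""Diversity estimators, neutrality statistics and mismatch fitting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylosdm import popgen, seqio
from phylosdm.errors import DegenerateDataError, ParameterError


def _aln(*seqs):
    return seqio.Alignment(
        tuple(f"s{i}" for i in range(len(seqs))), tuple(seqs)
    )


class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        assert popgen.haplotype_diversity(np.array([7]))[0] == 0.0

    def test_two_distinct_is_one(self):
        hd, _ = popgen.haplotype_diversity(np.array([1, 1]))
        assert hd == pytest.approx(1.0)

    def test_three_one_one(self):
        # n=5, counts (3,1,1): Hd = 5/4 * (1 - (9+1+1)/25) = 0.7000
        hd, sd = popgen.haplotype_diversity(np.array([3, 1, 1]))
        assert hd == pytest.approx(0.7, abs=1e-12)
        assert sd > 0

    def test_needs_two_samples(self):
        with pytest.raises(DegenerateDataError):
            popgen.haplotype_diversity(np.array([1]))

    @given(
        st.lists(st.integers(min_value=1, max_value=20), min_size=2, max_size=8)
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_relabeling_invariance(self, counts):
        hd, _ = popgen.haplotype_diversity(np.array(counts))
        assert 0.0 <= hd <= 1.0
        hd2, _ = popgen.haplotype_diversity(np.array(counts[::-1]))
        assert hd == pytest.approx(hd2)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = _aln("ACGT", "ACGT")
        mask = seqio.build_site_mask(aln)
        assert popgen.nucleotide_diversity(aln, mask)[0] == 0.0

    def test_one_site_in_hundred(self):
        a = "A" * 100
        b = "T" + "A" * 99
        aln = _aln(a, b)
        pi, _ = popgen.nucleotide_diversity(aln, seqio.build_site_mask(aln))
        assert pi == pytest.approx(0.01)

    def test_matches_brute_force_pair_mean(self):
        seqs = ["AAA", "AAT", "ATT", "TTT"]
        aln = _aln(*seqs)
        mask = seqio.build_site_mask(aln)
        pairs = [
            sum(x != y for x, y in zip(a, b)) / 3
            for a, b in itertools.combinations(seqs, 2)
        ]
        pi, _ = popgen.nucleotide_diversity(aln, mask)
        assert pi == pytest.approx(np.mean(pairs))

    def test_column_permutation_invariance(self):
        seqs = ["ACGTA", "ACGAT", "TCGTA", "ACATA"]
        aln = _aln(*seqs)
        perm = [3, 1, 4, 0, 2]
        aln2 = _aln(*["".join(s[i] for i in perm) for s in seqs])
        pi1, _ = popgen.nucleotide_diversity(aln, seqio.build_site_mask(aln))
        pi2, _ = popgen.nucleotide_diversity(aln2, seqio.build_site_mask(aln2))
        assert pi1 == pytest.approx(pi2)


class TestAllelicRichness:
    def test_monomorphic(self):
        assert popgen.allelic_richness(np.array([9]), 3) == pytest.approx(1.0)
        assert popgen.allelic_richness(
            np.array([9]), 3, "minus_one"
        ) == pytest.approx(0.0)

    def test_hand_computed_g4(self):
        # counts (3,1,1), g=4: 1 + 2*(1 - C(4,4)/C(5,4)) = 2.6
        assert popgen.allelic_richness(np.array([3, 1, 1]), 4) == pytest.approx(2.6)

    def test_full_sample_equals_nh(self):
        counts = np.array([4, 3, 2, 1])
        assert popgen.allelic_richness(counts, 10) == pytest.approx(4.0)

    def test_monotone_in_g(self):
        counts = np.array([5, 3, 2, 1, 1])
        ars = [popgen.allelic_richness(counts, g) for g in range(1, 13)]
        assert ars[0] == pytest.approx(1.0)
        assert all(a <= b + 1e-12 for a, b in zip(ars, ars[1:]))

    def test_g_out_of_range(self):
        with pytest.raises(ParameterError):
            popgen.allelic_richness(np.array([2, 1]), 4)


class TestTajimasD:
    def test_a1_constant(self):
        assert popgen._tajima_constants(5)["a1"] == pytest.approx(25 / 12)

    def test_zero_when_estimators_agree(self):
        c = popgen._tajima_constants(10)
        S = 12
        assert popgen.tajimas_d(S, S / c["a1"], 10) == pytest.approx(0.0)

    def test_undefined_when_no_polymorphism(self):
        assert math.isnan(popgen.tajimas_d(0, 0.0, 10))

    def test_sign_reflects_frequency_spectrum(self):
        c = popgen._tajima_constants(20)
        assert popgen.tajimas_d(10, 10 / c["a1"] - 1.0, 20) < 0
        assert popgen.tajimas_d(10, 10 / c["a1"] + 1.0, 20) > 0


class TestFuFs:
    def test_hand_enumeration_n3(self):
        # |s(3,k)| = (2,3,1); rising factorial theta=1 is 6
        assert popgen.fu_fs(2, 3, 1.0) == pytest.approx(math.log(2))
        assert popgen.fu_fs(3, 3, 1.0) == pytest.approx(math.log(1 / 5))

    def test_k1_degenerate(self):
        assert math.isinf(popgen.fu_fs(1, 10, 2.0))

    def test_many_haplotypes_small_theta_is_negative(self):
        assert popgen.fu_fs(18, 20, 1.0) < -5

    @pytest.mark.parametrize("n", [10, 50, 150, 300])
    def test_ewens_pmf_normalised(self, n):
        lp = popgen.ewens_log_pmf(n, 3.7)
        assert abs(np.exp(lp).sum() - 1.0) < 1e-10


class TestNeutralityNull:
    def test_self_consistent_p_near_half(self):
        # an observation at the simulated null's centre gives p about 0.5
        rng = np.random.default_rng(0)
        sims = [
            popgen.simulate_coalescent_summary(15, 4.0, rng)
            for _ in range(300)
        ]
        ds = [
            popgen.tajimas_d(S, kbar, 15)
            for S, kbar, _, _ in sims
            if S > 0
        ]
        med = float(np.median(ds))
        c = popgen._tajima_constants(15)
        # construct an observation whose D equals the simulated median
        S_obs = 8
        kbar_obs = S_obs / c["a1"] + med * math.sqrt(
            c["e1"] * S_obs + c["e2"] * S_obs * (S_obs - 1)
        )
        res = popgen.neutrality_null(S_obs, kbar_obs, 5, 15, n_sim=400, seed=1)
        assert 0.35 < res.D_p < 0.65

    def test_requires_minimum_sims(self):
        with pytest.raises(ParameterError):
            popgen.neutrality_null(5, 2.0, 3, 10, n_sim=10)


class TestMismatch:
    def test_monomorphic_all_pairs_zero(self):
        aln = _aln(*["ACGT"] * 4)
        obs = popgen.mismatch_observed(aln, seqio.build_site_mask(aln))
        assert obs.tolist() == [6]

    def test_matches_brute_force(self):
        seqs = ["AAAA", "AAAT", "AATT", "TTTT"]
        aln = _aln(*seqs)
        obs = popgen.mismatch_observed(aln, seqio.build_site_mask(aln))
        diffs = [
            sum(x != y for x, y in zip(a, b))
            for a, b in itertools.combinations(seqs, 2)
        ]
        expect = np.bincount(diffs)
        assert obs.tolist() == expect.tolist()

    def test_two_clusters_bimodal(self, two_cluster):
        aln = two_cluster["alignment"]
        obs = popgen.mismatch_observed(aln, seqio.build_site_mask(aln))
        assert obs[0] == 6 and obs[5] == 9  # within- and between-cluster pairs

    @pytest.mark.parametrize("theta", [0.3, 1.0, 7.5])
    def test_equilibrium_distribution_normalised(self, theta):
        F = popgen.mismatch_expected(0.0, theta, theta, 400)
        assert F.sum() == pytest.approx(1.0, abs=1e-9)

    def test_raggedness_hand_sum(self):
        r = popgen.raggedness(np.array([0.5, 0.3, 0.2]))
        assert r == pytest.approx(0.04 + 0.01 + 0.04)

    def test_fit_optimum_beats_grid(self):
        rng = np.random.default_rng(3)
        truth = popgen.mismatch_expected(4.0, 0.5, 30.0, 25)
        obs = rng.multinomial(190, truth)
        res = popgen.mismatch_fit(obs, n_boot=10, seed=0)
        freq = obs / obs.sum()
        for tau in (0.0, 2.0, 6.0, 10.0):
            for th0 in (0.1, 1.0):
                grid_ssd = float(
                    np.sum(
                        (freq - popgen.mismatch_expected(tau, th0, 30.0, 25)) ** 2
                    )
                )
                assert res.SSD <= grid_ssd + 1e-12

    def test_parameter_recovery_from_fitted_model(self):
        rng = np.random.default_rng(5)
        truth = popgen.mismatch_expected(5.0, 0.2, 40.0, 30)
        obs = rng.multinomial(5000, truth)
        res = popgen.mismatch_fit(obs, n_boot=20, seed=1)
        assert res.tau == pytest.approx(5.0, abs=1.5)
        assert res.SSD < 1e-3
        assert 0.0 <= res.SSD_p <= 1.0 and 0.0 <= res.raggedness_p <= 1.0
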