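"""Transition/emission probabilities and the forward likelihood.

The forward recursion is checked against an independent brute-force
oracle that enumerates all 4^M inheritance paths and sums their joint
probabilities directly.
"""

import itertools

import numpy as np
import pytest

import sibmap as sm
from sibmap import (
    GenotypeCallData,
    InconsistentDataError,
    ReadCountData,
    RecombinationParams,
    forward_loglik_individual,
    genotype_emission,
    read_count_prob,
    sequencing_emission,
    total_loglik,
    transition_matrix,
)
from sibmap.hmm import (
    G_AA,
    G_AB,
    G_BB,
    G_MISSING,
    OPGP_STATE_GENOTYPE,
    forward_logliks,
    sequencing_emissions,
)


def brute_force_loglik(y, d, opgps, r_pat, r_mat, epsilon):
    """Sum over all 4^M inheritance paths of prior x emission products."""
    m = len(y)
    total = 0.0
    for path in itertools.product(range(4), repeat=m):
        p = 0.25
        for j in range(1, m):
            s1p, s1m = divmod(path[j - 1], 2)
            s2p, s2m = divmod(path[j], 2)
            p *= (r_pat[j - 1] if s1p != s2p else 1 - r_pat[j - 1])
            p *= (r_mat[j - 1] if s1m != s2m else 1 - r_mat[j - 1])
        for j in range(m):
            p *= sequencing_emission(y[j], d[j], path[j], opgps[j], epsilon)
        total += p
    return np.log(total)


class TestTransition:
    def test_no_recombination_is_identity(self):
        assert np.array_equal(transition_matrix(0.0, 0.0), np.eye(4))

    def test_half_half_is_uniform(self):
        assert np.allclose(transition_matrix(0.5, 0.5), np.full((4, 4), 0.25))

    def test_diagonal_is_product_of_retention_probs(self):
        T = transition_matrix(0.01, 0.02)
        assert np.allclose(np.diag(T), 0.99 * 0.98)

    def test_rows_sum_to_one_and_bitflip_symmetry(self, rng):
        for _ in range(20):
            rp, rm = rng.random(2)
            T = transition_matrix(rp, rm)
            assert np.allclose(T.sum(axis=1), 1.0)
            # simultaneous flip of both bits: state s -> 3 - s
            assert np.allclose(T, T[::-1, ::-1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.5, 0.1)


class TestEmissions:
    def test_genotype_emission_table_lookup(self):
        # OPGP 1 = (A,B,A,B); state (1,1) selects (Z11, Z01) = A,A -> AA
        assert genotype_emission(G_AB, 3, 1) == 0.0
        assert genotype_emission(G_AA, 3, 1) == 1.0
        assert genotype_emission("missing", 3, 1) == 1.0
        assert genotype_emission(G_MISSING, 0, 7) == 1.0

    @pytest.mark.parametrize(
        "a,d,g,eps,expected",
        [
            (1, 2, "AB", 0.37, 0.5),
            (3, 3, "AA", 0.0, 1.0),
            (3, 4, "AA", 0.01, 4 * 0.99**3 * 0.01),
        ],
    )
    def test_read_count_prob_values(self, a, d, g, eps, expected):
        assert read_count_prob(a, d, g, eps) == pytest.approx(expected, rel=1e-12)

    def test_read_count_prob_invalid(self):
        with pytest.raises(ValueError):
            read_count_prob(5, 3, "AA", 0.0)

    def test_read_count_prob_normalizes(self):
        """Summing over all read counts gives 1 for every genotype/depth/error."""
        for eps in (0.0, 0.002, 0.01, 0.3):
            for d in range(0, 31):
                for g in (G_AA, G_AB, G_BB):
                    tot = sum(read_count_prob(a, d, g, eps) for a in range(d + 1))
                    assert tot == pytest.approx(1.0, rel=1e-10)

    def test_sequencing_emission_values(self):
        assert sequencing_emission(0, 0, 2, 9, 0.3) == 1.0  # missing
        # OPGP 4 = (B,A,B,A); state (0,0) -> A+A = AA; no error, all-ref reads
        assert sequencing_emission(5, 5, 0, 4, 0.0) == 1.0
        # OPGP 5 = (A,B,A,A); state (1,0) -> A+A = AA
        assert sequencing_emission(2, 3, 2, 5, 0.01) == pytest.approx(
            3 * 0.99**2 * 0.01, rel=1e-12
        )

    def test_state_genotype_consistency_with_read_model(self):
        """Eq-style factorization: the emission equals the read-count
        probability at the state-implied genotype, for every OPGP/state."""
        for code in range(1, 17):
            for s in range(4):
                g = int(OPGP_STATE_GENOTYPE[code, s])
                assert sequencing_emission(2, 6, s, code, 0.05) == pytest.approx(
                    read_count_prob(2, 6, g, 0.05)
                )


class TestForward:
    def test_all_missing_likelihood_is_one(self):
        params = RecombinationParams(r_paternal=[0.3], r_maternal=[0.1])
        ll = forward_loglik_individual(
            np.zeros(2, int), params, np.array([1, 9]), obs_depth=np.zeros(2, int)
        )
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        """100 random small cases, every OPGP represented, rtol 1e-10."""
        for case in range(100):
            m = int(rng.integers(1, 5))
            codes = rng.integers(1, 17, size=m)
            r_pat = rng.random(max(m - 1, 1)) * 0.5
            r_mat = rng.random(max(m - 1, 1)) * 0.5
            eps = float(rng.choice([0.0, 0.002, 0.05]))
            d = rng.integers(0, 8, size=m)
            # sample reads from genotypes reachable under the OPGPs so the
            # likelihood is positive even at eps = 0
            g = np.array(
                [OPGP_STATE_GENOTYPE[c, rng.integers(0, 4)] for c in codes]
            )
            p_ref = np.where(g == G_AA, 1.0 - eps, np.where(g == G_BB, eps, 0.5))
            y = rng.binomial(d, p_ref)
            params = RecombinationParams(
                r_paternal=r_pat[: m - 1], r_maternal=r_mat[: m - 1], epsilon=eps
            )
            got = forward_loglik_individual(y, params, codes, obs_depth=d)
            want = brute_force_loglik(y, d, codes, r_pat, r_mat, eps)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_phase_flip_invariance(self, rng):
        """Globally flipping one parent's chromosomes leaves the likelihood
        unchanged (phase symmetry)."""
        from sibmap.phasing import apply_global_flips

        cfg = sm.study_config(5.0, 0.01, n_progeny=20, seed=3)
        data, _ = sm.simulate_dataset(cfg)
        params = RecombinationParams(
            r_paternal=np.full(11, 0.05), r_maternal=np.full(11, 0.02), epsilon=0.01
        )
        base = total_loglik(data, params, cfg.opgps)
        for fp, fm in [(True, False), (False, True), (True, True)]:
            flipped = [apply_global_flips(cfg.opgps[0], fp, fm)]
            assert total_loglik(data, params, flipped) == pytest.approx(base, rel=1e-12)

    def test_individuals_and_families_factorize(self):
        cfg = sm.study_config(10.0, 0.0, n_progeny=10, seed=9)
        data, _ = sm.simulate_dataset(cfg)
        params = RecombinationParams(
            r_paternal=np.full(11, 0.01), r_maternal=np.full(11, 0.01), epsilon=0.001
        )
        single = total_loglik(data, params, cfg.opgps)
        doubled = ReadCountData(
            Y=np.vstack([data.Y, data.Y]),
            D=np.vstack([data.D, data.D]),
            family_of=np.concatenate([np.zeros(10, int), np.ones(10, int)]),
        )
        two_fam = total_loglik(doubled, params, [cfg.opgps[0], cfg.opgps[0]])
        assert two_fam == pytest.approx(2 * single, rel=1e-12)

    def test_sequencing_converges_to_genotype_model_at_high_depth(self):
        """With deep error-free coverage, read counts pin the genotypes and
        the two models' likelihoods agree."""
        cfg = sm.study_config(10.0, 0.0, n_progeny=15, seed=4)
        data, truth = sm.simulate_dataset(cfg)
        G = truth["genotypes"]
        depth = np.full_like(G, 500)
        reads = ReadCountData(Y=np.where(G == G_AA, 500, np.where(G == G_BB, 0, 250)), D=depth)
        params = RecombinationParams(
            r_paternal=np.full(11, 0.02), r_maternal=np.full(11, 0.02), epsilon=0.0
        )
        ll_seq = total_loglik(reads, params, cfg.opgps)
        ll_gen = total_loglik(GenotypeCallData(G=G), params, cfg.opgps, model="genotype")
        # read-count likelihood includes the binomial ordering factor at AB;
        # compare after removing the depth-only C(d,a)(1/2)^d term
        n_het = int((G == G_AB).sum())
        from sibmap.hmm import read_count_prob as rcp

        offset = n_het * np.log(rcp(250, 500, G_AB, 0.0))
        assert ll_seq - offset == pytest.approx(ll_gen, abs=1e-6)

    def test_impossible_genotype_raises_under_error_free_model(self):
        # alternate homozygote at an MI_A locus cannot occur without error
        G = np.array([[G_BB]])
        params = RecombinationParams([0.0], [0.0])
        with pytest.raises(InconsistentDataError):
            total_loglik(GenotypeCallData(G=G), params, [np.array([9])], model="genotype")
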