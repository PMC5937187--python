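"""EM map estimation, estimable intervals, Haldane distances, two-point fits."""

import numpy as np
import pytest

import sibmap as sm
from sibmap import (
    GenotypeCallData,
    NoSharedMeiosisError,
    ReadCountData,
    SegregationType,
    estimable_intervals,
    fit_map,
    fit_twopoint,
    haldane_cM,
    twopoint_matrix,
)
from sibmap.hmm import G_AA, G_AB, G_BB


class TestEstimableIntervals:
    def test_homozygous_father_everywhere(self):
        pat, mat = estimable_intervals([[SegregationType.MI_A] * 3])
        assert not pat.any()
        assert mat.all()

    def test_interval_spanning_an_uninformative_locus(self):
        sts = [[SegregationType.BI, SegregationType.PI_A, SegregationType.BI]]
        pat, mat = estimable_intervals(sts)
        assert pat.tolist() == [True, True]
        # locus 2 is maternally homozygous: maternal r_1 excluded, r_2 spans 1->3
        assert mat.tolist() == [False, True]

    def test_every_family_rule(self):
        sts = [
            [SegregationType.MI_A, SegregationType.MI_A],
            [SegregationType.BI, SegregationType.BI],
        ]
        pat, mat = estimable_intervals(sts)
        assert pat.tolist() == [True] and mat.tolist() == [True]

    def test_none_treated_as_uninformative(self):
        pat, mat = estimable_intervals([[None, SegregationType.BI]])
        assert pat.tolist() == [False] and mat.tolist() == [False]


class TestHaldane:
    def test_values(self):
        assert haldane_cM(0.0) == 0.0
        assert haldane_cM(0.01) == pytest.approx(-50 * np.log(0.98), rel=1e-12)
        assert haldane_cM(0.01) == pytest.approx(1.0101, abs=1e-4)
        assert 11 * haldane_cM(0.01) == pytest.approx(11.111, abs=1e-3)

    def test_infinite_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_cM(0.5)


class TestFitMap:
    def test_classical_estimator_on_complete_bi_data(self):
        """With complete error-free BI genotype calls, EM reproduces the
        fully-informative count estimate r = recombinants / meioses."""
        # 2-locus BI family, OPGP 1 at both loci.  Homozygous progeny
        # genotypes pin the inheritance state exactly (AA <-> state (1,1),
        # BB <-> (0,0)), so each meiosis is fully informative: 15 concordant
        # progeny and 5 AA->BB double recombinants give r = 5/20 = 0.25 in
        # each parent by direct counting.
        G = np.array([[G_AA, G_AA]] * 8 + [[G_BB, G_BB]] * 7 + [[G_AA, G_BB]] * 5)
        est = fit_map(
            GenotypeCallData(G=G), [np.array([1, 1])], model="genotype", tol=1e-12
        )
        assert est.params.r_paternal[0] == pytest.approx(0.25, abs=1e-6)
        assert est.params.r_maternal[0] == pytest.approx(0.25, abs=1e-6)

    def test_em_ascent_and_convergence(self, small_dataset):
        cfg, data, _ = small_dataset
        est = fit_map(data, cfg.opgps, sex_specific=False)
        assert est.converged
        assert np.all(np.diff(est.loglik_trace) > -1e-8)

    def test_zero_recombination_recovered(self):
        cfg = sm.SimConfig(
            n_progeny=[80],
            opgps=[np.array([1, 1, 1, 1])],
            r_paternal=np.zeros(3),
            r_maternal=np.zeros(3),
            mean_depth=30.0,
            epsilon=0.0,
            seed=5,
        )
        data, _ = sm.simulate_dataset(cfg)
        est = fit_map(data, cfg.opgps, sex_specific=False, estimate_epsilon=False,
                      epsilon_init=0.0)
        assert np.all(est.params.r_paternal < 1e-3)
        assert est.total_cM == pytest.approx(0.0, abs=0.1)

    def test_sex_specific_false_ties_parents(self, small_dataset):
        cfg, data, _ = small_dataset
        est = fit_map(data, cfg.opgps, sex_specific=False)
        assert np.array_equal(est.params.r_paternal, est.params.r_maternal)

    def test_non_estimable_intervals_fixed_at_zero(self):
        cfg = sm.SimConfig(
            n_progeny=[40],
            opgps=[np.array([9, 9, 9])],  # MI_A everywhere: father homozygous
            r_paternal=np.full(2, 0.1),
            r_maternal=np.full(2, 0.1),
            mean_depth=15.0,
            seed=6,
        )
        data, _ = sm.simulate_dataset(cfg)
        est = fit_map(data, cfg.opgps, sex_specific=True)
        assert np.all(est.params.r_paternal == 0.0)
        assert np.all(~est.params.estimable_paternal)
        assert np.all(est.params.estimable_maternal)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_map(
                ReadCountData(Y=np.empty((0, 2), int), D=np.empty((0, 2), int)),
                [np.array([1, 1])],
            )


class TestTwoPoint:
    @staticmethod
    def _pair_data(r, n=200, depth=20.0, seed=11, opgps=(1, 1)):
        cfg = sm.SimConfig(
            n_progeny=[n],
            opgps=[np.array(opgps)],
            r_paternal=np.array([r]),
            r_maternal=np.array([r]),
            mean_depth=depth,
            epsilon=0.0,
            seed=seed,
        )
        data, _ = sm.simulate_dataset(cfg)
        data.sts = cfg.sts
        return data

    def test_duplicated_locus_cosegregates(self):
        cfg = sm.SimConfig(
            n_progeny=[100], opgps=[np.array([1])], r_paternal=np.empty(0),
            r_maternal=np.empty(0), mean_depth=25.0, seed=7,
        )
        data, _ = sm.simulate_dataset(cfg)
        dup = ReadCountData(
            Y=np.hstack([data.Y, data.Y]), D=np.hstack([data.D, data.D]),
            sts=[[SegregationType.BI, SegregationType.BI]],
        )
        res = fit_twopoint(dup, epsilon=0.0)
        assert res.r_hat == pytest.approx(0.0, abs=1e-4)
        assert res.phase == {"paternal": "coupling", "maternal": "coupling"}

    def test_unlinked_loci(self):
        data = self._pair_data(0.5, seed=13)
        res = fit_twopoint(data)
        assert res.r_hat == pytest.approx(0.5, abs=0.06)

    def test_recovers_intermediate_r(self):
        data = self._pair_data(0.1, seed=17)
        res = fit_twopoint(data)
        assert res.r_hat == pytest.approx(0.1, abs=0.035)

    def test_repulsion_phase_detected(self):
        # PI_A pair with the second locus's paternal chromosomes swapped
        # (OPGP 6): only the paternal meiosis segregates, so the flip is
        # identifiable and must be assigned to the father
        data = self._pair_data(0.05, seed=19, opgps=(5, 6))
        res = fit_twopoint(data)
        assert res.phase == {"paternal": "repulsion"}
        assert res.r_hat == pytest.approx(0.05, abs=0.035)

    def test_bi_pair_r_invariant_to_unidentifiable_flip_parent(self):
        """For a BI pair under a tied r, which parent carries a single flip is
        not identifiable: both assignments give the same maximized likelihood
        and the same r estimate."""
        from sibmap.estimation import _flip_code

        data = self._pair_data(0.05, seed=19, opgps=(1, 2))
        fits = {}
        for fp, fm in [(True, False), (False, True)]:
            opgps = [np.array([1, _flip_code(1, fp, fm)])]
            fits[(fp, fm)] = fit_map(
                data, opgps, sex_specific=False, estimate_epsilon=False, epsilon_init=0.0
            )
        a, b = fits.values()
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)
        assert a.params.r_paternal[0] == pytest.approx(b.params.r_paternal[0], abs=1e-8)
        res = fit_twopoint(data)
        assert res.r_hat == pytest.approx(0.05, abs=0.035)

    def test_disjoint_parents_rejected(self):
        data = self._pair_data(0.1, seed=23, opgps=(9, 5))  # MI then PI
        with pytest.raises(NoSharedMeiosisError):
            fit_twopoint(data)

    def test_matches_full_fit_at_m2(self):
        data = self._pair_data(0.1, seed=29)
        res = fit_twopoint(data)
        full = fit_map(
            data, [np.array([1, 1])], sex_specific=False,
            estimate_epsilon=False, epsilon_init=0.0,
        )
        assert res.loglik == pytest.approx(full.loglik, abs=1e-6)
        assert res.r_hat == pytest.approx(full.params.r_paternal[0], abs=1e-6)

    def test_matrix_symmetric_with_zero_diagonal(self):
        cfg = sm.SimConfig(
            n_progeny=[80],
            opgps=[np.array([1, 9, 1])],
            r_paternal=np.full(2, 0.1),
            r_maternal=np.full(2, 0.1),
            mean_depth=15.0,
            seed=31,
        )
        data, _ = sm.simulate_dataset(cfg)
        data.sts = cfg.sts
        mat = twopoint_matrix(data, parent="maternal")
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.all(np.diag(mat) == 0.0)
        assert np.isfinite(mat[0, 1])

    def test_matrix_increases_away_from_diagonal(self):
        cfg = sm.SimConfig(
            n_progeny=[150],
            opgps=[np.array([1, 1, 1, 1])],
            r_paternal=np.full(3, 0.15),
            r_maternal=np.full(3, 0.15),
            mean_depth=20.0,
            seed=37,
        )
        data, _ = sm.simulate_dataset(cfg)
        data.sts = cfg.sts
        mat = twopoint_matrix(data, parent="paternal")
        assert mat[0, 1] < mat[0, 2] < mat[0, 3]
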