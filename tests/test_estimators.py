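import numpy as np
import pandas as pd
import pytest

import damline as dl
from damline.datatypes import ORIGIN_A, ORIGIN_B, ORIGIN_C, ORIGIN_UNASSIGNED
from damline.estimators import (GrandparentRelationship, LinearRegressionAncestry,
                                SupervisedAdmixture, boa_proportions, grm_cross,
                                lr_estimate, rel_gp_estimate)

from conftest import make_panel


def freqs_from(p):
    return dl.LineFrequencies(np.asarray(p, float))


class TestLinearRegression:
    def test_square_full_rank_solve(self):
        # x_B=(2,0), x_C=(0,2), x_A=(1,1): g=(1,1) -> g*=(0.5,0.5) -> (0.25,0.25)
        f = freqs_from([[0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        est = LinearRegressionAncestry.from_frequencies(f)
        b = est.predict([[1, 1]])
        np.testing.assert_allclose(b, [[0.25, 0.25]], atol=1e-12)

    def test_raw_estimates_can_leave_parameter_space(self):
        f = freqs_from([[0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        b = LinearRegressionAncestry.from_frequencies(f).predict([[2, 0]])
        np.testing.assert_allclose(b, [[0.75, -0.25]], atol=1e-12)

    def test_matches_normal_equations_on_simulated_panel(self, small_sim):
        panel = small_sim.panel
        f = dl.purebred_line_freqs(panel)
        est = lr_estimate(panel, f)
        X = np.column_stack([f.x[:, 1], f.x[:, 2]])
        G = panel.genotypes_of(dl.CROSSBRED).astype(float) - 0.5 * f.x[:, 0]
        expect = np.linalg.pinv(X) @ G.T
        np.testing.assert_allclose(np.column_stack([est.b_b, est.b_c]),
                                   expect.T, atol=1e-10)

    def test_correlates_with_truth(self, unrelated_run):
        _, estimates, truth = unrelated_run
        r = dl.evaluate(estimates["LR"], truth)
        assert r.accuracy > 0.9

    def test_collinear_regressors_rejected(self):
        f = freqs_from([[0.5, 0.4, 0.4], [0.2, 0.3, 0.3]])
        with pytest.raises(dl.DamlineError, match="collinear"):
            LinearRegressionAncestry.from_frequencies(f).predict([[1, 1]])

    def test_label_swap_symmetry(self, rng):
        p = rng.random((40, 3))
        g = rng.integers(0, 3, size=(6, 40))
        b = LinearRegressionAncestry.from_frequencies(freqs_from(p)).predict(g)
        swapped = LinearRegressionAncestry.from_frequencies(
            freqs_from(p[:, [0, 2, 1]])).predict(g)
        np.testing.assert_allclose(swapped, b[:, ::-1], atol=1e-10)


class TestSupervisedAdmixture:
    def test_unidentifiable_frequencies_keep_initial_q(self):
        p = np.full((30, 3), 0.4)
        est = SupervisedAdmixture.from_frequencies(freqs_from(p))
        q = est.predict_q(np.ones((2, 30)))
        np.testing.assert_allclose(q, [[0.5, 0.25, 0.25]] * 2, atol=1e-9)

    def test_degenerate_likelihood_pushes_q_to_vertex(self):
        p = np.tile([0.0, 1.0, 0.0], (50, 1))
        est = SupervisedAdmixture.from_frequencies(freqs_from(p))
        q = est.predict_q(np.full((1, 50), 2))
        assert q[0, 1] > 0.999

    def test_loglik_monotone_and_q_on_simplex(self, small_sim):
        panel = small_sim.panel
        f = dl.purebred_line_freqs(panel)
        est = SupervisedAdmixture.from_frequencies(f)
        q = est.predict_q(panel.genotypes_of(dl.CROSSBRED)[:10])
        path = np.stack(est.loglik_path_)
        assert (np.diff(path, axis=0) > -1e-8).all()
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)
        assert (q >= -1e-12).all()

    def test_em_beats_random_simplex_restarts(self, small_sim, rng):
        panel = small_sim.panel
        f = dl.purebred_line_freqs(panel)
        m = min(500, panel.n_snps)
        sub = panel.subset_snps(np.arange(m))
        fsub = f.subset_snps(np.arange(m))
        g = sub.genotypes_of(dl.CROSSBRED)[:1].astype(float)
        est = SupervisedAdmixture.from_frequencies(fsub)
        q = est.predict_q(g)
        p = np.clip(fsub.p, 1e-6, 1 - 1e-6)
        best_em = SupervisedAdmixture._loglik(g, p, q)[0]
        candidates = rng.dirichlet(np.ones(3), size=200)
        ll = SupervisedAdmixture._loglik(np.repeat(g, 200, axis=0), p, candidates)
        assert best_em >= ll.max() - 1e-6


class TestGenomicRelationship:
    def test_hand_computed_example(self):
        g_ij, g_jj = grm_cross([2, 1], [2, 0], [0.5, 0.5], [0.5, 0.5])
        assert g_ij == pytest.approx(1.0, abs=1e-12)
        assert g_jj == pytest.approx(2.0, abs=1e-12)

    def test_genotype_at_twice_frequency_centres_to_zero(self, rng):
        p_i = rng.uniform(0.25, 0.75, 20)
        g_i = 2 * p_i  # exactly the population mean at every SNP
        g_j = rng.integers(0, 3, 20)
        p_j = rng.uniform(0.2, 0.8, 20)
        s_i = np.sum(2 * p_i * (1 - p_i))
        s_j = np.sum(2 * p_j * (1 - p_j))
        num = ((g_i - 2 * p_i) * (g_j - 2 * p_j)).sum()
        assert num / np.sqrt(s_i * s_j) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_when_frequencies_shared(self, rng):
        g1 = rng.integers(0, 3, 30)
        g2 = rng.integers(0, 3, 30)
        p = rng.uniform(0.1, 0.9, 30)
        a, _ = grm_cross(g1, g2, p, p)
        b, _ = grm_cross(g2, g1, p, p)
        assert a == pytest.approx(b, abs=1e-12)


class TestRelGp:
    def test_self_relationship_ratio(self):
        # G_jj = 2, G_ij = 1: REL_GP 1.0, REL_GP_noF 0.5
        g_ij, g_jj = grm_cross([2, 1], [2, 0], [0.5, 0.5], [0.5, 0.5])
        assert g_ij / g_jj == pytest.approx(0.5, abs=1e-12)

    def test_crossbreds_without_grandparents_excluded(self, small_sim):
        panel, ped = small_sim.panel, small_sim.pedigree
        f = dl.regression_line_freqs(panel)
        tab = ped.crossbreds.copy()
        tab.loc[tab.index[:5], "mgs"] = "0"
        est, rel_b, rel_c, n_excl = rel_gp_estimate(panel, dl.Pedigree(tab), f)
        assert n_excl == 5
        assert len(est) == len(tab) - 5
        assert set(rel_b["j"]).issubset(set(panel.ids_of("B")))
        assert (rel_b["G_jj"] > 0).all()

    def test_variants_correlate_with_truth(self, unrelated_run):
        _, estimates, truth = unrelated_run
        acc = dl.evaluate(estimates["REL_GP_noF"], truth).accuracy
        assert acc > 0.9

    def test_label_swap_symmetry(self, small_sim):
        panel, ped = small_sim.panel, small_sim.pedigree
        f = dl.regression_line_freqs(panel)
        est, *_ = rel_gp_estimate(panel, ped, f, adjust_inbreeding=True)
        swapped_lines = np.where(panel.lines == "B", "C",
                                 np.where(panel.lines == "C", "B", panel.lines))
        panel2 = dl.GenotypePanel(panel.ids, swapped_lines, panel.genotypes,
                                  panel.markers)
        tab = ped.crossbreds.rename(columns={"mgs": "mgd", "mgd": "mgs"})
        f2 = dl.regression_line_freqs(panel2)
        est2, *_ = rel_gp_estimate(panel2, dl.Pedigree(tab), f2,
                                   adjust_inbreeding=True)
        est2 = est2.restrict(est.ids)
        np.testing.assert_allclose(est2.b_b, est.b_c, atol=1e-10)
        np.testing.assert_allclose(est2.b_c, est.b_b, atol=1e-10)


class TestBoa:
    def test_complete_origins_equal_true_proportions(self, small_sim):
        boa = boa_proportions(small_sim.origins)
        np.testing.assert_array_equal(boa.b_b, small_sim.truth.b_b)
        np.testing.assert_array_equal(boa.b_c, small_sim.truth.b_c)

    def test_half_b_half_c_maternal_gamete(self):
        codes = np.empty((1, 10, 2), np.int8)
        codes[:, :, 0] = ORIGIN_A
        codes[0, :5, 1] = ORIGIN_B
        codes[0, 5:, 1] = ORIGIN_C
        est = boa_proportions(dl.OriginMatrix(np.array(["x"], object), codes))
        assert (est.b_b[0], est.b_c[0]) == (0.25, 0.25)

    def test_unbiased_under_random_unassignment(self):
        rng = np.random.default_rng(99)
        n, m = 1000, 500
        codes = np.empty((n, m, 2), np.int8)
        codes[:, :, 0] = ORIGIN_A
        codes[:, :, 1] = rng.choice([ORIGIN_B, ORIGIN_C], size=(n, m))
        ids = np.array([f"x{i}" for i in range(n)], object)
        truth = dl.true_proportions(dl.OriginMatrix(ids, codes))
        masked = codes.copy()
        masked[rng.random((n, m, 2)) < 0.10] = ORIGIN_UNASSIGNED
        est = boa_proportions(dl.OriginMatrix(ids, masked))
        bias = (est.b_b - truth.b_b).mean()
        se = (est.b_b - truth.b_b).std() / np.sqrt(n)
        assert abs(bias) < 4 * se + 1e-4

    def test_fully_unassigned_animal_rejected(self):
        codes = np.full((1, 5, 2), ORIGIN_UNASSIGNED, np.int8)
        with pytest.raises(dl.DamlineError, match="no assigned"):
            boa_proportions(dl.OriginMatrix(np.array(["x"], object), codes))
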