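import numpy as np
import pytest

import damline as dl
from damline.evaluation import _wc_theta, theoretical_variance

from conftest import make_panel


def est_of(values, method="LR"):
    v = np.asarray(values, float)
    ids = np.array([f"x{i}" for i in range(len(v))], object)
    return dl.ProportionEstimates(ids, v, 0.5 - v, method=method)


class TestEvaluate:
    def test_perfect_estimates(self):
        ref = est_of([0.2, 0.25, 0.3, 0.22], "TRUE")
        r = dl.evaluate(est_of([0.2, 0.25, 0.3, 0.22]), ref)
        assert r.accuracy == pytest.approx(1.0, abs=1e-12)
        assert r.slope == pytest.approx(1.0, abs=1e-12)
        assert r.max_abs_error == 0.0
        assert r.rmse == 0.0

    def test_constant_offset(self):
        ref = est_of([0.2, 0.25, 0.3, 0.22], "TRUE")
        r = dl.evaluate(est_of([0.21, 0.26, 0.31, 0.23]), ref)
        assert r.accuracy == pytest.approx(1.0, abs=1e-12)
        assert r.slope == pytest.approx(1.0, abs=1e-12)
        assert r.max_abs_error == pytest.approx(0.01, abs=1e-12)
        assert r.rmse == pytest.approx(0.01, abs=1e-12)

    def test_inflated_estimates_halve_the_slope(self):
        ref_v = np.array([0.2, 0.25, 0.3, 0.35, 0.15])
        est_v = 2 * (ref_v - 0.25) + 0.25
        r = dl.evaluate(est_of(est_v), est_of(ref_v, "TRUE"))
        assert r.slope == pytest.approx(0.5, abs=1e-12)

    def test_slope_accuracy_sd_identity(self, rng):
        e = rng.random(60) / 2
        f = rng.random(60) / 2
        r = dl.evaluate(est_of(e), est_of(f, "TRUE"))
        assert r.slope == pytest.approx(r.accuracy * f.std(ddof=1) / e.std(ddof=1),
                                        abs=1e-12)

    def test_zero_variance_estimates_rejected(self):
        with pytest.raises(dl.DamlineError, match="zero variance"):
            dl.evaluate(est_of([0.25, 0.25]), est_of([0.2, 0.3], "TRUE"))


class TestTheoreticalVariance:
    def test_zero_length_limit_is_single_locus_variance(self):
        assert theoretical_variance([1e-9]).variance == pytest.approx(1 / 16, rel=1e-6)

    def test_matches_numerical_covariance_integral(self):
        # independent oracle: Var = (1/(4 l^2)) Int_0^l Int_0^l exp(-2|x-y|) dx dy,
        # evaluated on a fine grid, then / 4 for the line proportion
        for l in (0.25, 0.61, 1.0, 3.2):
            x = np.linspace(0, l, 1500)
            cov = np.exp(-2.0 * np.abs(x[:, None] - x[None, :])) / 4.0
            gamete_var = np.trapezoid(np.trapezoid(cov, x, axis=1), x) / l ** 2
            assert theoretical_variance([l]).variance == pytest.approx(
                gamete_var / 4.0, rel=1e-3)

    def test_reference_values(self):
        assert theoretical_variance([1.0]).variance == pytest.approx(0.03548, abs=5e-5)
        d = theoretical_variance([3.20, 0.61])
        assert d.variance == pytest.approx(0.01274, abs=5e-5)
        assert d.sd == pytest.approx(0.113, abs=5e-4)
        assert d.mean == 0.25

    def test_multi_chromosome_weighting(self):
        # identical chromosomes: genome variance is half a single chromosome's
        single = theoretical_variance([1.0]).variance
        double = theoretical_variance([1.0, 1.0]).variance
        assert double == pytest.approx(single / 2, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(dl.DamlineError):
            theoretical_variance([1.0, 0.0])


class TestFst:
    def test_hand_computed_two_population_fixture(self):
        # 2 populations (n1=4, n2=6), 3 SNPs; WC components worked out explicitly
        g1 = np.array([[0, 2, 1], [1, 2, 1], [2, 1, 0], [1, 2, 1]], np.int8)
        g2 = np.array([[0, 1, 2], [0, 0, 2], [1, 1, 2], [0, 1, 1], [1, 0, 2], [0, 1, 2]],
                      np.int8)
        n1, n2, r = 4, 6, 2
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        thetas = []
        for j in range(3):
            p1 = g1[:, j].sum() / (2 * n1)
            p2 = g2[:, j].sum() / (2 * n2)
            h1 = (g1[:, j] == 1).mean()
            h2 = (g2[:, j] == 1).mean()
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                       - h_bar / 4) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                         - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2
            thetas.append(a / (a + b + c))
        expected = float(np.mean(thetas))
        panel = make_panel(np.vstack([g1, g2]), ["A"] * 4 + ["B"] * 6)
        got = dl.fst_wc(panel, lines=("A", "B"))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_pool_split_in_two_is_near_zero(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 2000), size=(1000, 2000)).astype(np.int8)
        panel = make_panel(g, ["A"] * 500 + ["B"] * 500)
        assert abs(dl.fst_wc(panel, lines=("A", "B"))) < 0.01

    def test_fixed_opposite_alleles_give_one(self):
        g = np.vstack([np.full((5, 4), 2), np.zeros((5, 4))]).astype(np.int8)
        panel = make_panel(g, ["A"] * 5 + ["B"] * 5)
        assert dl.fst_wc(panel, lines=("A", "B")) == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_mode_matches_direct_computation(self, small_sim):
        pure = small_sim.panel.subset_animals(small_sim.panel.lines != dl.CROSSBRED)
        pw = dl.fst_wc(pure, pairwise=True)
        for (x, y), theta in pw.items():
            direct = _wc_theta([pure.genotypes_of(x), pure.genotypes_of(y)])
            assert theta == pytest.approx(direct, abs=1e-12)

    def test_monomorphic_panel_rejected(self):
        panel = make_panel(np.full((6, 3), 2), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(dl.DamlineError, match="monomorphic"):
            dl.fst_wc(panel, lines=("A", "B"))


class TestCorrelationTable:
    def test_matches_pairwise_evaluate(self, rng):
        ests = [est_of(rng.random(30) / 2, m) for m in ("LR", "ADM", "REL_GP")]
        table = dl.method_correlation_table(ests)
        assert np.allclose(np.diag(table.to_numpy()), 1.0)
        for i, a in enumerate(ests):
            for j, b in enumerate(ests):
                expect = np.corrcoef(a.b_b, b.b_b)[0, 1]
                assert table.iloc[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(table.to_numpy(), table.to_numpy().T)


def test_histogram_figure_renders(tmp_path, small_sim):
    import matplotlib
    from damline.evaluation import proportion_histogram_figure
    fig = proportion_histogram_figure(small_sim.truth, (3.20, 0.61),
                                      path=tmp_path / "hist.png")
    assert (tmp_path / "hist.png").stat().st_size > 0
    matplotlib.pyplot.close(fig)
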