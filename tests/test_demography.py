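"""Coalescent SFS machinery, composite likelihood, AIC selection, bootstrap."""

import numpy as np
import pytest
from scipy import stats

from invapop import demography as dm


@pytest.fixture(scope="module")
def model_a():
    return dm.DemographicModel("A", n_cur=1000.0)


class TestSizeTrajectory:
    def test_model_a_constant(self, model_a):
        n = dm.size_trajectory(model_a, {})
        assert n(0.0) == n(123.0) == n(1e6) == 1000.0

    def test_model_b_step_at_published_point_estimates(self):
        model = dm.DemographicModel("B", n_cur=206_750)
        n = dm.size_trajectory(model, {"N_ANC": 1_044_983, "T_BOT": 114})
        assert n(100.0) == 206_750
        assert n(200.0) == 1_044_983

    def test_model_c_with_zero_rate_reduces_to_b(self):
        mb = dm.DemographicModel("B", n_cur=5e4)
        mc = dm.DemographicModel("C", n_cur=5e4)
        pb = {"N_ANC": 2e5, "T_BOT": 300.0}
        pc = {**pb, "G_R": 0.0}
        tb = dm.size_trajectory(mb, pb)
        tc = dm.size_trajectory(mc, pc)
        for t in (0.0, 150.0, 299.9, 300.0, 1e4):
            assert tb(t) == pytest.approx(tc(t))

    def test_model_d_three_epochs(self):
        md = dm.DemographicModel("D", n_cur=1e4)
        n = dm.size_trajectory(
            md, {"N_ANC": 1e5, "N_BOT": 100.0, "T_BOT": 300.0, "T_ENDBOT": 50.0}
        )
        assert n(10.0) == 1e4
        assert n(100.0) == 100.0
        assert n(500.0) == 1e5

    def test_model_d_requires_ordered_times(self):
        md = dm.DemographicModel("D", n_cur=1e4)
        with pytest.raises(ValueError):
            dm.build_epochs(
                md, {"N_ANC": 1e5, "N_BOT": 100.0, "T_BOT": 50.0, "T_ENDBOT": 60.0}
            )


class TestCoalescentTimes:
    def test_pairwise_coalescence_time_is_2n(self, model_a):
        epochs = dm.build_epochs(model_a, {})
        exps = np.random.default_rng(0).standard_exponential((1, 20_000))
        t = dm._simulate_level_times(epochs, 2, exps)
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 2_000.0) < 3 * se

    def test_exponential_epoch_matches_numeric_integration(self):
        # waiting-time inversion agrees with numerically integrating 1/(2N(t))
        mc = dm.DemographicModel("C", n_cur=5e3, bounds={"G_R": (-0.02, 0.01)})
        params = {"N_ANC": 2.5e4, "T_BOT": 800.0, "G_R": -0.004}
        epochs = dm.build_epochs(mc, params)
        from scipy.integrate import quad

        n_of_t = dm.size_trajectory(mc, params)
        for x in (1e-5, 5e-5, 2e-4):
            t_hit = dm._advance(epochs, np.zeros(1), np.array([x]))[0]
            integral, _ = quad(lambda s: 1.0 / (2.0 * n_of_t(s)), 0.0, t_hit)
            assert integral == pytest.approx(x, rel=1e-6)


class TestSimulatedSfs:
    def test_sfs_sums_to_n_snps(self, model_a):
        sfs = dm.simulate_sfs(model_a, {}, n_individuals=8, n_snps=500, seed=3)
        assert sfs.n_snps == 500

    def test_constant_size_matches_folded_neutral_closed_form(self, model_a):
        sfs = dm.simulate_sfs(model_a, {}, n_individuals=10, n_snps=10_000, seed=1)
        expected = dm.neutral_folded_proportions(10) * sfs.n_snps
        chi2 = float(((sfs.counts[1:] - expected) ** 2 / expected).sum())
        p = stats.chi2.sf(chi2, df=9)
        assert p > 0.01

    def test_constant_size_matches_msprime_branch_oracle(self, model_a):
        import msprime

        n = 10
        reps = msprime.sim_ancestry(
            samples=n, population_size=1000, ploidy=2,
            num_replicates=4000, random_seed=7,
        )
        afs = np.zeros(2 * n + 1)
        for ts in reps:
            afs += ts.allele_frequency_spectrum(mode="branch", polarised=False)
        expected = afs[1 : n + 1] / afs[1 : n + 1].sum()
        sfs = dm.simulate_sfs(model_a, {}, n_individuals=n, n_snps=10_000, seed=2)
        exp_counts = expected * sfs.n_snps
        chi2 = float(((sfs.counts[1:] - exp_counts) ** 2 / exp_counts).sum())
        assert stats.chi2.sf(chi2, df=n - 1) > 0.01

    def test_founder_expansion_has_excess_rare_variants(self):
        mc = dm.DemographicModel("C", n_cur=5e3, bounds={"G_R": (-0.02, 0.01)})
        p_c = dm.expected_folded_sfs(
            mc, {"N_ANC": 2.5e4, "T_BOT": 1000.0, "G_R": -0.005},
            n_individuals=15, n_sims=20_000, seed=4,
        )
        p_a = dm.neutral_folded_proportions(15)
        # expansion genealogies are star-like: excess singletons
        assert p_c[0] > p_a[0]


class TestCompositeLikelihood:
    def test_maximum_at_empirical_proportions(self):
        counts = np.array([0, 50, 30, 20])
        obs = dm.FoldedSFS(counts=counts, n_individuals=3)
        p_hat = counts[1:] / counts[1:].sum()
        max_lnl = dm.composite_lnl(obs, p_hat)
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            assert dm.composite_lnl(obs, p) <= max_lnl + 1e-9

    def test_matches_multinomial_oracle_up_to_constant(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate([[0], rng.integers(1, 100, size=6)])
        obs = dm.FoldedSFS(counts=counts, n_individuals=6)
        p = rng.dirichlet(np.ones(6) * 2)
        # independent oracle: scipy multinomial pmf minus the log coefficient
        from scipy.special import gammaln

        pf = np.maximum(p, dm.PROB_FLOOR)
        pf = pf / pf.sum()
        m = counts[1:]
        oracle = stats.multinomial.logpmf(m, n=m.sum(), p=pf)
        log_coeff = gammaln(m.sum() + 1) - gammaln(m + 1).sum()
        assert dm.composite_lnl(obs, p) == pytest.approx(oracle - log_coeff)

    def test_all_zero_obs_rejected(self):
        obs = dm.FoldedSFS(counts=np.zeros(5, dtype=int), n_individuals=4)
        with pytest.raises(ValueError):
            dm.composite_lnl(obs, np.full(4, 0.25))


class TestModelSelection:
    def _fit_stub(self, model_id, aic, rep_lnls):
        model = dm.DemographicModel(model_id, n_cur=1e4)
        lnl = (2 * model.k - aic) / 2
        return dm.ModelFitResult(model=model, params_hat={}, lnl=lnl, aic=aic,
                                 rep_lnls=rep_lnls)

    def test_formula_on_worked_example(self):
        fits = {
            "A": self._fit_stub("A", 100.0, [-50.0]),
            "B": self._fit_stub("B", 101.5, [-48.75]),
            "C": self._fit_stub("C", 110.0, [-52.0]),
        }
        table = dm.model_selection(fits).set_index("model")
        assert table.loc["A", "delta_AIC"] == 0.0
        assert table.loc["B", "delta_AIC"] == pytest.approx(1.5)
        assert table.loc["C", "delta_AIC"] == pytest.approx(10.0)
        assert table.loc["A", "weight"] == pytest.approx(0.676, abs=1e-3)
        assert table.loc["B", "weight"] == pytest.approx(0.319, abs=1e-3)
        assert table.loc["C", "weight"] == pytest.approx(0.005, abs=1e-3)

    def test_identical_aics_share_weight_and_joint_support(self):
        fits = {
            "A": self._fit_stub("A", 100.0, [-50.0]),
            "B": self._fit_stub("B", 100.0, [-48.0]),
        }
        table = dm.model_selection(fits)
        np.testing.assert_allclose(table["weight"], 0.5)
        assert table["joint_support"].all()

    def test_joint_support_threshold_at_three_units(self):
        fits = {
            "A": self._fit_stub("A", 100.0, [-50.0]),
            "B": self._fit_stub("B", 102.9, [-49.45]),
            "C": self._fit_stub("C", 103.1, [-48.55]),
        }
        table = dm.model_selection(fits).set_index("model")
        assert bool(table.loc["B", "joint_support"]) is True
        assert bool(table.loc["C", "joint_support"]) is False

    def test_selection_freq_counts_replicate_wins(self):
        # model A wins replicate 0, model B wins replicate 1 (AIC = -2 lnl + 2k)
        fits = {
            "A": self._fit_stub("A", 100.0, [-50.0, -60.0]),
            "B": self._fit_stub("B", 99.0, [-52.0, -47.5]),
        }
        table = dm.model_selection(fits).set_index("model")
        assert table.loc["A", "selection_freq"] == 0.5
        assert table.loc["B", "selection_freq"] == 0.5

    def test_ranking_invariant_to_lnl_shift(self):
        fits1 = {
            "A": self._fit_stub("A", 100.0, [-50.0]),
            "B": self._fit_stub("B", 104.0, [-50.0]),
        }
        shift = 37.0
        fits2 = {
            "A": self._fit_stub("A", 100.0 - 2 * shift, [-50.0 + shift]),
            "B": self._fit_stub("B", 104.0 - 2 * shift, [-50.0 + shift]),
        }
        t1 = dm.model_selection(fits1)
        t2 = dm.model_selection(fits2)
        np.testing.assert_allclose(t1["delta_AIC"], t2["delta_AIC"])
        np.testing.assert_allclose(t1["weight"], t2["weight"])


class TestFitting:
    def test_model_a_fit_is_deterministic_likelihood_evaluation(self):
        model = dm.DemographicModel("A", n_cur=5e3)
        obs = dm.simulate_sfs(model, {}, 12, 2000, seed=9)
        fit = dm.fit_model(obs, model, n_sims=2000, n_reps=2, seed=1)
        assert fit.params_hat == {}
        assert fit.aic == pytest.approx(-2 * fit.lnl)

    def test_nested_model_never_fits_worse(self):
        # model C nests model B (G_R = 0): with the bottleneck truth, the
        # extra parameter cannot lower the attainable likelihood
        nc = 5e3
        mb = dm.DemographicModel("B", n_cur=nc)
        mc = dm.DemographicModel("C", n_cur=nc)
        obs = dm.simulate_sfs(mb, {"N_ANC": 2.5e4, "T_BOT": 200.0}, 15, 3000,
                              seed=5)
        fb = dm.fit_model(obs, mb, n_cycles=4, n_sims=1500, n_reps=3, seed=2)
        fc = dm.fit_model(obs, mc, n_cycles=4, n_sims=1500, n_reps=3, seed=2,
                          start={**fb.params_hat, "G_R": 0.0})
        assert fc.lnl >= fb.lnl - 0.5  # same CRN streams, optimizer noise only

    def test_bootstrap_collapses_for_degenerate_simulator(self, monkeypatch):
        model = dm.DemographicModel("B", n_cur=5e3)
        params = {"N_ANC": 2.5e4, "T_BOT": 200.0}
        frozen = dm.simulate_sfs(model, params, 12, 2000, seed=1)

        monkeypatch.setattr(dm, "simulate_sfs",
                            lambda *a, **k: frozen)
        ci = dm.parametric_bootstrap(model, params, 12, 2000, n_boot=5, seed=0,
                                     n_sims=1000, n_cycles=0)
        for name, (lo, hi) in ci.intervals.items():
            assert lo == pytest.approx(hi)
            assert lo == pytest.approx(params[name])


class TestConversions:
    @pytest.mark.parametrize(
        "gens, years, rounded",
        [(114, 20.727, 21), (217, 39.455, 39), (55, 10.0, 10)],
    )
    def test_generations_to_years(self, gens, years, rounded):
        raw, r = dm.generations_to_years(gens)
        assert raw == pytest.approx(years, abs=1e-3)
        assert r == rounded

    def test_reduction_fraction_published_values(self):
        assert dm.reduction_fraction(206_750, 1_044_983) == pytest.approx(
            0.8022, abs=1e-4
        )
        assert dm.reduction_fraction(48_600, 1_044_710) == pytest.approx(
            0.9535, abs=1e-4
        )
        assert dm.reduction_fraction(1e4, 1e4) == 0.0


def test_sfs_text_round_trip(tmp_path, model_a):
    sfs = dm.simulate_sfs(model_a, {}, 8, 300, seed=11)
    path = tmp_path / "spectrum.sfs"
    dm.write_sfs(sfs, path)
    back = dm.read_sfs(path)
    assert back.n_individuals == 8
    np.testing.assert_array_equal(back.counts, sfs.counts)
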