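"""Adaptive Metropolis correctness, convergence diagnostics, and posterior
predictive summaries."""

import warnings

import numpy as np
import pytest

from mekfit.amcmc import (
    Chain,
    constraint_satisfaction_fractions,
    ess,
    posterior_predictive_bands,
    run_adaptive_chain,
    split_rhat,
)

BOX = np.array([[-20.0, 20.0], [-20.0, 20.0]])


def gaussian_logpost(cov):
    prec = np.linalg.inv(cov)

    def lp(x):
        return float(-0.5 * x @ prec @ x)

    return lp


def ar1(rng, n_chains, n_draws, rho):
    e = rng.standard_normal((n_chains, n_draws))
    out = np.empty_like(e)
    out[:, 0] = e[:, 0]
    for t in range(1, n_draws):
        out[:, t] = rho * out[:, t - 1] + np.sqrt(1 - rho ** 2) * e[:, t]
    return out


class TestSampler:
    def test_standard_normal_means_within_mc_error(self):
        lp = gaussian_logpost(np.eye(2))
        chain = run_adaptive_chain(lp, BOX, np.array([0.3, -0.2]), seed=8,
                                   phases=(1000, 2000, 10000))
        for i in range(2):
            n_eff = ess(chain.samples[None, :, i], "bulk")
            mcse = 1.0 / np.sqrt(n_eff)
            assert abs(chain.samples[:, i].mean()) < 3 * mcse

    def test_bookkeeping_of_phases(self):
        lp = gaussian_logpost(np.eye(2))
        chain = run_adaptive_chain(lp, BOX, np.array([0.0, 0.0]), seed=9,
                                   phases=(0, 0, 100))
        assert chain.samples.shape == (100, 2)
        assert chain.log_post.shape == (100,)
        assert 0.0 <= chain.acceptance_rate <= 1.0

    def test_boundary_init_rejected(self):
        lp = gaussian_logpost(np.eye(2))
        with pytest.raises(ValueError, match="strictly inside"):
            run_adaptive_chain(lp, BOX, np.array([-20.0, 0.0]), seed=1,
                               phases=(10, 10, 10))
        with pytest.raises(ValueError, match="not finite"):
            run_adaptive_chain(lambda x: -np.inf, BOX, np.array([0.0, 0.0]),
                               seed=1, phases=(10, 10, 10))

    def test_same_seed_bit_identical(self):
        lp = gaussian_logpost(np.eye(2))
        a = run_adaptive_chain(lp, BOX, np.array([0.1, 0.1]), seed=3,
                               phases=(200, 300, 500))
        b = run_adaptive_chain(lp, BOX, np.array([0.1, 0.1]), seed=3,
                               phases=(200, 300, 500))
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_draws_stay_inside_box(self):
        tight = np.array([[-0.5, 0.5], [-0.5, 0.5]])
        lp = gaussian_logpost(np.eye(2))
        chain = run_adaptive_chain(lp, tight, np.array([0.0, 0.0]), seed=4,
                                   phases=(200, 400, 2000))
        assert np.all(chain.samples >= -0.5) and np.all(chain.samples <= 0.5)


class TestDiagnostics:
    def test_iid_chains_converge(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((4, 2000))
        assert split_rhat(x) - 1.0 < 0.01
        # 4 x 1000 i.i.d. draws: bulk ESS on the order of the 4000 total
        assert 2000 <= ess(x[:, :1000], "bulk") <= 6000

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1000))
        x[1] += 10.0
        assert split_rhat(x) > 1.5

    def test_rank_rhat_invariant_under_monotone_transform(self):
        # the location (unfolded) statistic is purely rank-based
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 500))
        assert split_rhat(np.exp(x), fold=False) == pytest.approx(
            split_rhat(x, fold=False), rel=1e-12)

    def test_ar1_bulk_ess_near_closed_form(self):
        rho, n = 0.9, 20000
        rng = np.random.default_rng(11)
        x = ar1(rng, 1, n, rho)
        expected = n * (1 - rho) / (1 + rho)  # ~1053
        measured = ess(x, "bulk")
        assert expected / 2 <= measured <= expected * 2

    def test_constant_chains_are_undefined_not_crashing(self):
        x = np.ones((2, 100))
        assert np.isnan(split_rhat(x))
        assert np.isnan(ess(x, "bulk"))
        assert np.isnan(ess(x, "tail"))

    def test_input_validation(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="2 chains"):
            split_rhat(rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="4 draws"):
            split_rhat(rng.standard_normal((2, 3)))
        with pytest.raises(ValueError, match="bulk.*tail|'bulk' or 'tail'"):
            ess(rng.standard_normal((2, 100)), "median")

    def test_agreement_with_reference_implementation(self):
        """Bulk/tail ESS and rank R-hat vs arviz on shared fixture chains."""
        az = pytest.importorskip("arviz")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rng = np.random.default_rng(21)
            fixtures = {
                "iid": rng.standard_normal((4, 1500)),
                "ar1": ar1(rng, 4, 1500, 0.8),
                "offset": rng.standard_normal((4, 1500)) + np.arange(4)[:, None] * 0.3,
            }
            for name, x in fixtures.items():
                data = az.from_dict(posterior={"x": x})
                assert split_rhat(x) == pytest.approx(
                    float(az.rhat(data, method="rank")["x"]), rel=0.01), name
                assert ess(x, "bulk") == pytest.approx(
                    float(az.ess(data, method="bulk")["x"]), rel=0.01), name
                assert ess(x, "tail") == pytest.approx(
                    float(az.ess(data, method="tail")["x"]), rel=0.01), name


class TestPosteriorSummaries:
    def test_degenerate_posterior_collapses_bands(self):
        draws = np.tile(np.array([0.5, -1.0]), (200, 1))
        times = np.linspace(0, 1, 5)

        def series(x):
            return x[0] * times + x[1]

        bands = posterior_predictive_bands(draws, series, "obs", times, seed=0)
        for lo, hi in bands.intervals.values():
            assert np.allclose(lo, bands.median)
            assert np.allclose(hi, bands.median)

    def test_bands_are_nested(self):
        rng = np.random.default_rng(3)
        draws = rng.standard_normal((400, 2))
        times = np.linspace(0, 1, 7)

        def series(x):
            return x[0] * times + x[1]

        bands = posterior_predictive_bands(draws, series, "obs", times,
                                           levels=(0.1, 0.5, 0.95), seed=0)
        lo10, hi10 = bands.intervals[0.1]
        lo50, hi50 = bands.intervals[0.5]
        lo95, hi95 = bands.intervals[0.95]
        assert np.all(lo95 <= lo50) and np.all(lo50 <= lo10)
        assert np.all(hi10 <= hi50) and np.all(hi50 <= hi95)

    def test_subsample_sizes_agree_within_mc_error(self):
        rng = np.random.default_rng(4)
        draws = rng.standard_normal((5000, 1))
        times = np.zeros(1)

        def series(x):
            return np.array([x[0]])

        a = posterior_predictive_bands(draws, series, "obs", times,
                                       levels=(0.5,), max_draws=500, seed=1)
        b = posterior_predictive_bands(draws, series, "obs", times,
                                       levels=(0.5,), max_draws=1000, seed=2)
        # half-width of a 50% band of a standard normal is ~0.67; MC error
        # at 500 draws is ~0.07
        assert a.intervals[0.5][1][0] == pytest.approx(b.intervals[0.5][1][0],
                                                       abs=0.2)

    def test_failed_draws_are_dropped(self):
        draws = np.array([[0.0], [1.0], [2.0]] * 40, dtype=float)
        times = np.zeros(1)

        def series(x):
            if x[0] == 1.0:
                raise RuntimeError("integrator blew up")
            return np.array([x[0]])

        bands = posterior_predictive_bands(draws, series, "obs", times,
                                           levels=(0.5,), seed=0)
        assert np.isfinite(bands.median).all()


@pytest.fixture(scope="module")
def tiny_problem():
    from mekfit.objective import CalibrationProblem, ParamSpec, ThetaVector
    from mekfit.synthetic_data import (
        SyntheticDesign, TRUE_RATES, generate_qual, wt_comparison_pairs)

    design = SyntheticDesign(statement_scale=0.0, seed=13)
    statements = generate_qual(TRUE_RATES, design,
                               pairs=wt_comparison_pairs(design))
    theta = ThetaVector([ParamSpec("d3", 1e-5, 1e-1),
                         ParamSpec("u3", 1e-5, 1e-1)])
    return CalibrationProblem(theta, statements=statements)


class TestSatisfactionFractions:
    def test_posterior_at_truth_satisfies_everything(self, tiny_problem):
        x = tiny_problem.theta.to_array({"d3": 1e-3, "u3": 1e-3})
        draws = np.tile(x, (50, 1))
        fracs = constraint_satisfaction_fractions(draws, tiny_problem, seed=0)
        assert np.allclose(fracs, 1.0)

    def test_two_point_posterior_and_brute_force_recount(self, tiny_problem):
        from mekfit.qualdata import delta, heaviside_prediction

        good = tiny_problem.theta.to_array({"d3": 1e-3, "u3": 1e-3})
        other = tiny_problem.theta.to_array({"d3": 9e-2, "u3": 9e-2})
        draws = np.vstack([np.tile(good, (25, 1)), np.tile(other, (25, 1))])
        fracs = constraint_satisfaction_fractions(draws, tiny_problem, seed=0)

        # exhaustive recount over the two distinct draws
        expected = np.zeros(len(tiny_problem.statements))
        for x, w in [(good, 0.5), (other, 0.5)]:
            bank = tiny_problem.simulate_bank(tiny_problem.theta.from_array(x))
            for j, s in enumerate(tiny_problem.statements):
                if heaviside_prediction(delta(s, bank)) == s.z:
                    expected[j] += w
        assert np.array_equal(fracs, expected)
        assert set(np.round(np.unique(fracs), 6)) <= {0.0, 0.5, 1.0}
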