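import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from risefall.connectome import Connectome, make_transport
from risefall.dynamics import ModelParameters
from risefall.inference import (ObservationSet, ParameterSpace, Prior,
                                default_priors, empirical_prior, fit,
                                gelman_rubin, log_likelihood, map_estimate,
                                posterior_updated)


def _isolated_obs(values, times=None, sigma_region="solo"):
    times = times if times is not None else [1.0] * len(values)
    df = pd.DataFrame({
        "region": [sigma_region] * len(values),
        "time_months": times,
        "replicate": range(len(values)),
        "value": values,
    })
    return ObservationSet.from_dataframe(df, [sigma_region])


def _isolated_transport():
    return make_transport(Connectome(["solo"], np.zeros((1, 1))), "retrograde")


class TestPrior:
    def test_truncnorm_matches_scipy(self):
        p = Prior("truncnorm", 0.0, 0.5)
        ref = stats.truncnorm(0, np.inf, loc=0, scale=0.5)
        x = np.linspace(0.01, 2, 25)
        assert np.allclose(p.logpdf(x), ref.logpdf(x), atol=1e-10)
        assert np.allclose(p.cdf(x), ref.cdf(x), atol=1e-12)
        assert p.logpdf(-0.1) == -np.inf

    def test_draws_respect_support(self, rng):
        p = Prior("truncnorm", -1.0, 0.5)
        assert (p.rvs(size=500, rng=rng) > 0).all()

    def test_diff_initial_condition_prior_is_widest(self):
        wide = default_priors("diff")["u0"].sigma
        assert wide > default_priors("diff_r")["u0"].sigma
        assert wide > default_priors("diff_rf")["u0"].sigma


class TestEmpiricalPrior:
    def test_moment_match_roundtrip(self, rng):
        src = Prior("truncnorm", 0.4, 0.3)
        draws = src.rvs(size=20_000, rng=rng)
        fitted = fitted_prior = empirical_prior(draws)
        samples = fitted_prior.rvs(size=20_000, rng=rng)
        assert samples.mean() == pytest.approx(draws.mean(), abs=0.02)
        assert samples.std() == pytest.approx(draws.std(), abs=0.02)
        assert fitted.positive


class TestLogLikelihood:
    def test_zero_residual_single_record(self):
        # DIFF on an isolated node holds u == u0, so one matching record
        # contributes exactly -log(2 pi)/2 at sigma = 1
        obs = _isolated_obs([0.7])
        params = ModelParameters(model="diff", rho=1.0, u0=0.7, sigma=1.0,
                                 seeds=[0])
        total, pw = log_likelihood(params, _isolated_transport(), obs)
        assert total == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-8)
        assert pw.size == 1

    def test_doubling_sigma_costs_log2_per_record(self):
        obs = _isolated_obs([0.7, 0.7, 0.7])
        base = ModelParameters(model="diff", rho=1.0, u0=0.7, sigma=1.0,
                               seeds=[0])
        wide = ModelParameters(model="diff", rho=1.0, u0=0.7, sigma=2.0,
                               seeds=[0])
        ll0, _ = log_likelihood(base, _isolated_transport(), obs)
        ll1, _ = log_likelihood(wide, _isolated_transport(), obs)
        assert ll0 - ll1 == pytest.approx(3 * math.log(2), abs=1e-8)

    def test_hand_set_residuals(self):
        # residuals (0, 1, -2) at sigma 1: total = -3 log(2pi)/2 - 2.5
        obs = _isolated_obs([1.0, 2.0, -1.0])
        params = ModelParameters(model="diff", rho=1.0, u0=1.0, sigma=1.0,
                                 seeds=[0])
        total, pw = log_likelihood(params, _isolated_transport(), obs)
        assert total == pytest.approx(-1.5 * math.log(2 * math.pi) - 2.5,
                                      abs=1e-8)

    def test_missing_values_skipped(self):
        df = pd.DataFrame({
            "region": ["solo"] * 3,
            "time_months": [1.0, 2.0, 3.0],
            "replicate": [0, 0, 0],
            "value": [0.5, np.nan, 0.5],
        })
        obs = ObservationSet.from_dataframe(df, ["solo"])
        assert obs.n_obs == 2 and obs.n_dropped == 1


class TestObservationSet:
    def test_unknown_region_label_rejected(self):
        df = pd.DataFrame({"region": ["nope"], "time_months": [1.0],
                           "replicate": [0], "value": [0.1]})
        with pytest.raises(ValueError, match="nope"):
            ObservationSet.from_dataframe(df, ["solo"])

    def test_drop_timepoint_splits_records(self, small_study):
        obs = small_study.observations
        kept, held = obs.drop_timepoint(obs.times.size - 1)
        assert kept.n_obs + held.n_obs == obs.n_obs
        assert np.all(held.time_idx == obs.times.size - 1)
        with pytest.raises(IndexError):
            obs.drop_timepoint(99)

    def test_roundtrip_via_dataframe(self, small_study):
        obs = small_study.observations
        df = obs.to_dataframe()
        back = ObservationSet.from_dataframe(df, obs.region_ids)
        assert np.allclose(np.sort(back.value), np.sort(obs.value))


class TestParameterSpace:
    def test_pack_unpack_roundtrip(self):
        priors = default_priors("diff_rf")
        sp = ParameterSpace("diff_rf", 3, [1], priors)
        params = ModelParameters(model="diff_rf", rho=0.5, alpha=1.2,
                                 beta=np.array([0.1, 0.5, 0.9]),
                                 gamma=np.array([0.2, 0.3, 0.4]), u0=0.4,
                                 sigma=0.05, seeds=[1])
        x = sp.pack(params)
        back = sp.unpack(x)
        assert back.rho == params.rho and back.alpha == params.alpha
        assert np.allclose(back.beta, params.beta)
        assert np.allclose(back.gamma, params.gamma)

    def test_transform_roundtrip_and_jacobian(self, rng):
        priors = default_priors("diff_r")
        sp = ParameterSpace("diff_r", 2, [0], priors)
        x = np.abs(rng.normal(size=sp.ndim)) + 0.1
        x[~sp.positive] = rng.normal(size=(~sp.positive).sum())
        z = sp.to_unconstrained(x)
        assert np.allclose(sp.to_natural(z), x)
        assert sp.log_jacobian(z) == pytest.approx(
            np.sum(np.log(x[sp.positive])))


class TestPriorPredictive:
    def test_default_prior_draws_simulate_finitely(self, small_study):
        # forward-simulating parameter sets drawn from the default priors
        # must almost always produce finite trajectories
        from risefall.connectome import make_transport
        from risefall.dynamics import simulate
        from risefall.inference import ParameterSpace

        conn = small_study.connectome
        transport = make_transport(conn, "retrograde")
        priors = default_priors("diff_rf")
        space = ParameterSpace("diff_rf", conn.n_regions, [0], priors)
        rng = np.random.default_rng(17)
        ok = 0
        n_draws = 100
        for _ in range(n_draws):
            params = space.unpack(space.prior_draw(rng))
            try:
                traj = simulate(params, transport, [0.5, 3.0, 9.0])
                ok += np.all(np.isfinite(traj.u))
            except RuntimeError:
                pass
        assert ok >= 0.99 * n_draws


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=200), (4, 1))
        assert gelman_rubin(x) == pytest.approx(1.0, abs=1e-6)

    def test_same_distribution_converges(self, rng):
        x = rng.normal(size=(4, 5000))
        assert gelman_rubin(x) < 1.01

    def test_disjoint_chains_flagged(self, rng):
        x = np.vstack([rng.normal(0, 0.01, 100), rng.normal(1, 0.01, 100)])
        assert gelman_rubin(x) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestPosteriorUpdated:
    def test_prior_draws_rarely_flag(self):
        prior = Prior("truncnorm", 0.0, 0.1)
        false_alarms = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            draws = prior.rvs(size=1000, rng=rng)
            updated, _ = posterior_updated(draws, prior, alpha=0.001)
            false_alarms += updated
        assert false_alarms <= 1  # >= 99% of repeats stay unflagged

    def test_point_mass_at_median_flags(self):
        prior = Prior("normal", 0.0, 1.0)
        draws = np.zeros(4000)
        updated, p = posterior_updated(draws, prior)
        assert updated and p < 1e-10

    def test_gross_shift_flags(self, rng):
        prior = Prior("normal", 0.0, 1.0)
        draws = rng.normal(5.0, 1.0, size=500)
        updated, _ = posterior_updated(draws, prior)
        assert updated


@pytest.fixture(scope="module")
def toy_fit():
    rng = np.random.default_rng(5)
    y = rng.normal(0.8, 0.1, size=60)
    obs = _isolated_obs(list(y), times=list(np.tile([1.0, 2.0, 3.0], 20)))
    post = fit("diff", _isolated_transport(), obs, seeds=[0], chains=4,
               warmup=400, samples=400, rng_seed=3)
    return post, y


class TestFitConjugateToy:
    """DIFF on an isolated node: u(t) == u0 for any rho.

    The posterior of u0 is then (nearly) the conjugate Normal-mean
    posterior, and rho is untouched by the data so its posterior must
    reproduce the prior.
    """

    def test_posterior_mean_matches_conjugate_solution(self, toy_fit):
        post, y = toy_fit
        draws = post.marginal("u0")
        sigma = post.marginal("sigma").mean()
        prior = post.priors["u0"]
        precision = y.size / sigma**2 + 1 / prior.sigma**2
        conj_mean = (y.sum() / sigma**2) / precision
        mc_se = draws.std(ddof=1) / math.sqrt(200)  # conservative ESS
        assert abs(draws.mean() - conj_mean) < 3 * mc_se + 1e-3

    def test_map_near_analytic_mode(self, toy_fit):
        post, y = toy_fit
        params = map_estimate(post)
        assert abs(params.u0 - y.mean()) < 0.05

    def test_data_free_parameter_reproduces_prior(self, toy_fit):
        # rho never enters the likelihood here: the ESS-corrected KS filter
        # must NOT flag an update, while the strongly-informed u0 must be
        from risefall.inference import updated_flags
        post, _ = toy_fit
        flags = updated_flags(post).set_index("parameter")
        assert not flags.loc["rho", "updated"]
        assert flags.loc["u0", "updated"]

    def test_truncated_draws_strictly_positive(self, toy_fit):
        post, _ = toy_fit
        for name in ("rho", "u0", "sigma"):
            assert (post.marginal(name) > 0).all()

    def test_empty_observations_rejected(self):
        obs = _isolated_obs([1.0])
        obs = obs._subset(np.zeros(1, dtype=bool))
        with pytest.raises(ValueError):
            fit("diff", _isolated_transport(), obs, seeds=[0])
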