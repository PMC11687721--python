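import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from occucam import model as mod
from occucam.covariates import CovariateTable
from tests.conftest import make_matrix


def brute_force_loglik(beta, p, values, X):
    """Independent oracle: sum the joint likelihood over every latent
    occupancy configuration in {0,1}^n_sites."""
    import itertools

    n = values.shape[0]
    psi = expit(X @ np.asarray(beta, dtype=float))
    total = 0.0
    for zs in itertools.product([0, 1], repeat=n):
        lik = 1.0
        for i, z in enumerate(zs):
            yi = values[i][~np.isnan(values[i])]
            lik *= psi[i] if z else (1 - psi[i])
            if z:
                lik *= np.prod(p**yi * (1 - p) ** (1 - yi))
            elif yi.sum() > 0:
                lik = 0.0
                break
        total += lik
    return np.log(total)


def _table(Z, names):
    n = Z.shape[0]
    return CovariateTable(
        data=pd.DataFrame(Z, columns=names, index=pd.Index([f"s{i + 1}" for i in range(n)], name="site_id")),
        raw_means=pd.Series(0.0, index=names),
        raw_sds=pd.Series(1.0, index=names),
    )


class TestLogLikelihood:
    def test_certain_occupancy_limit(self):
        m = make_matrix([[1.0]])
        spec = mod.ModelSpec(covariate_names=())
        assert mod.log_likelihood([30.0], 0.5, m, spec=spec) == pytest.approx(np.log(0.5), abs=1e-9)

    def test_hand_marginal_all_zero_history(self):
        m = make_matrix([[0.0, 0.0, 0.0]])
        spec = mod.ModelSpec(covariate_names=())
        ll = mod.log_likelihood([0.0], 0.5, m, spec=spec)
        assert ll == pytest.approx(np.log(0.5 * 0.125 + 0.5), abs=1e-12)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 9))
        values = rng.choice([0.0, 1.0, np.nan], size=(n, 3), p=[0.5, 0.3, 0.2])
        names = ["c1", "c2"]
        Z = rng.normal(size=(n, 2))
        beta = rng.normal(scale=1.5, size=3)
        p = float(rng.uniform(0.1, 0.9))
        m = make_matrix(values)
        spec = mod.ModelSpec(covariate_names=tuple(names))
        ll = mod.log_likelihood(beta, p, m, _table(Z, names), spec)
        X = np.column_stack([np.ones(n), Z])
        assert ll == pytest.approx(brute_force_loglik(beta, p, values, X), abs=1e-10)

    def test_site_permutation_invariance(self):
        rng = np.random.default_rng(5)
        n = 30
        values = rng.choice([0.0, 1.0], size=(n, 3))
        Z = rng.normal(size=(n, 2))
        beta, p = np.array([0.3, -0.5, 1.0]), 0.4
        spec = mod.ModelSpec(covariate_names=("c1", "c2"))
        perm = rng.permutation(n)
        ll1 = mod.log_likelihood(beta, p, make_matrix(values), _table(Z, ["c1", "c2"]), spec)
        ll2 = mod.log_likelihood(beta, p, make_matrix(values[perm]), _table(Z[perm], ["c1", "c2"]), spec)
        assert abs(ll1 - ll2) < 1e-12

    def test_site_count_mismatch_rejected(self):
        spec = mod.ModelSpec(covariate_names=("c1",))
        with pytest.raises(ValueError, match="sites"):
            mod.log_likelihood(
                [0.0, 0.0], 0.5, make_matrix(np.zeros((3, 2))), _table(np.zeros((4, 1)), ["c1"]), spec
            )

    def test_rejects_p_outside_unit_interval(self):
        spec = mod.ModelSpec(covariate_names=())
        with pytest.raises(ValueError, match="p must"):
            mod.log_likelihood([0.0], 1.5, make_matrix(np.zeros((2, 2))), spec=spec)


class TestLogPosterior:
    def test_empty_matrix_reduces_to_prior(self):
        m = make_matrix(np.zeros((3, 0)))
        spec = mod.ModelSpec(covariate_names=(), prior_sd_beta=10.0)
        lp = mod.log_posterior([1.2], 0.5, m, spec=spec)
        assert lp == pytest.approx(norm.logpdf(1.2, 0, 10), abs=1e-12)

    def test_prior_mode_is_maximal_with_empty_matrix(self):
        m = make_matrix(np.zeros((2, 0)))
        spec = mod.ModelSpec(covariate_names=())
        at_mode = mod.log_posterior([0.0], 0.5, m, spec=spec)
        for b in (-3.0, -0.5, 0.7, 4.0):
            assert mod.log_posterior([b], 0.5, m, spec=spec) < at_mode

    def test_closed_form_normal_prior(self):
        rng = np.random.default_rng(7)
        values = rng.choice([0.0, 1.0], size=(6, 3))
        Z = rng.normal(size=(6, 1))
        m = make_matrix(values)
        table = _table(Z, ["c1"])
        spec = mod.ModelSpec(covariate_names=("c1",), prior_sd_beta=10.0)
        beta = np.array([1.0, 0.0])
        expected = mod.log_likelihood(beta, 0.4, m, table, spec) + norm.logpdf(
            beta, 0.0, 10.0
        ).sum()
        assert mod.log_posterior(beta, 0.4, m, table, spec) == pytest.approx(expected, abs=1e-12)


class TestRunMcmc:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = make_matrix((rng.random((40, 3)) < 0.3).astype(float))
        spec = mod.ModelSpec(covariate_names=())
        cfg = mod.MCMCConfig(seed=3, n_adapt=100, n_burnin=100, n_iter=200)
        a = mod.run_mcmc(m, None, spec, cfg)
        b = mod.run_mcmc(m, None, spec, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(9)
        n = 500
        z = rng.binomial(1, 0.5, n)
        y = ((rng.random((n, 3)) < 0.5) * z[:, None]).astype(float)
        m = make_matrix(y)
        spec = mod.ModelSpec(covariate_names=())
        cfg = mod.MCMCConfig(seed=4, n_adapt=300, n_burnin=300, n_iter=1500)
        chains = mod.run_mcmc(m, None, spec, cfg)
        psi_draws = expit(chains.flat("beta0"))
        assert abs(psi_draws.mean() - 0.5) < 3 * psi_draws.std()
        p_draws = chains.flat("p")
        assert abs(p_draws.mean() - 0.5) < 3 * p_draws.std()

    def test_acceptance_rates_in_tuned_band(self):
        rng = np.random.default_rng(10)
        m = make_matrix((rng.random((100, 3)) < 0.4).astype(float))
        spec = mod.ModelSpec(covariate_names=())
        cfg = mod.MCMCConfig(seed=5, n_adapt=600, n_burnin=200, n_iter=1000)
        chains = mod.run_mcmc(m, None, spec, cfg)
        assert (chains.accept_rates > 0.1).all()
        assert (chains.accept_rates < 0.6).all()

    def test_rejects_too_few_chains(self):
        with pytest.raises(ValueError, match="2 chains"):
            mod.MCMCConfig(n_chains=1)


def gibbs_occupancy_oracle(values, X, prior_sd, seed, n_iter=15000, burn=3000):
    """Independent sampler for the same posterior: latent-state data
    augmentation (conjugate Beta update for p, Bernoulli update for z,
    random-walk logistic update for beta). Shares no code path with the
    marginalized sampler."""
    rng = np.random.default_rng(seed)
    obs = ~np.isnan(values)
    d = np.where(obs, values, 0.0).sum(axis=1)
    J = obs.sum(axis=1).astype(float)
    detected = d > 0
    k = X.shape[1]
    beta = np.zeros(k)
    z = detected.astype(float)
    keep = np.empty((n_iter - burn, k + 1))
    for it in range(n_iter):
        occ = z == 1
        p = rng.beta(1 + d[occ].sum(), 1 + (J[occ] - d[occ]).sum())
        psi = expit(X @ beta)
        num = psi * (1 - p) ** J
        with np.errstate(invalid="ignore"):
            prob = num / (num + 1 - psi)
        prob = np.where(np.isnan(prob), 1.0, np.clip(prob, 0, 1))
        und = ~detected
        z[und] = rng.binomial(1, prob[und])

        def lp(b):
            eta = X @ b
            return float(np.sum(z * eta - np.logaddexp(0, eta)) - 0.5 * np.sum((b / prior_sd) ** 2))

        cur = lp(beta)
        for _ in range(3):
            for j in range(k):
                prop = beta.copy()
                prop[j] += 0.3 * rng.standard_normal()
                lpp = lp(prop)
                if np.log(rng.random()) < lpp - cur:
                    beta, cur = prop, lpp
        if it >= burn:
            keep[it - burn, :k] = beta
            keep[it - burn, k] = p
    return keep


def test_marginalized_sampler_agrees_with_gibbs_oracle():
    rng = np.random.default_rng(321)
    n = 150
    Z = rng.normal(size=(n, 2))
    Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
    X = np.column_stack([np.ones(n), Z])
    psi = expit(-0.5 + 1.2 * Z[:, 0])
    zlat = rng.binomial(1, psi)
    y = ((rng.random((n, 3)) < 0.45) * zlat[:, None]).astype(float)
    m = make_matrix(y)
    table = _table(Z, ["c1", "c2"])
    spec = mod.ModelSpec(covariate_names=("c1", "c2"), prior_sd_beta=2.5)
    cfg = mod.MCMCConfig(seed=6, n_adapt=500, n_burnin=500, n_iter=4000)
    chains = mod.run_mcmc(m, table, spec, cfg)
    oracle = gibbs_occupancy_oracle(y, X, prior_sd=2.5, seed=7)
    for idx, name in enumerate(["beta0", "beta_c1", "beta_c2", "p"]):
        ours = chains.flat(name)
        theirs = oracle[:, idx]
        pooled_sd = np.sqrt((ours.var() + theirs.var()) / 2)
        assert abs(ours.mean() - theirs.mean()) < 0.25 * pooled_sd, name
        assert ours.std() == pytest.approx(theirs.std(), rel=0.25), name


class TestRhat:
    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(11)
        chains = rng.normal(size=(4, 4000))
        assert mod.rhat(chains) < 1.05

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(12)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert mod.rhat(chains) > 5.0

    def test_constant_chains_sentinel(self):
        assert mod.rhat(np.full((3, 100), 2.0)) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            mod.rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(13)
        chains = np.cumsum(rng.normal(size=(3, 2000)), axis=1) * 0.01 + rng.normal(
            size=(3, 2000)
        )
        ours = mod.rhat(chains)
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.05)


class TestEss:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(14)
        chains = rng.normal(size=(3, 3000))
        assert mod.ess(chains) == pytest.approx(9000, rel=0.2)

    def test_correlated_draws_shrink(self):
        rng = np.random.default_rng(15)
        ar = np.empty((2, 5000))
        for c in range(2):
            e = rng.normal(size=5000)
            x = np.zeros(5000)
            for t in range(1, 5000):
                x[t] = 0.9 * x[t - 1] + e[t]
            ar[c] = x
        assert mod.ess(ar) < 2500

    def test_same_order_as_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(16)
        ar = np.empty((3, 2000))
        for c in range(3):
            e = rng.normal(size=2000)
            x = np.zeros(2000)
            for t in range(1, 2000):
                x[t] = 0.7 * x[t - 1] + e[t]
            ar[c] = x
        ours = mod.ess(ar)
        theirs = float(arviz.ess(arviz.convert_to_dataset(ar))["x"].values)
        assert 0.5 < ours / theirs < 2.0


class TestSummarize:
    def _chains_from(self, arr):
        arr = np.asarray(arr, dtype=float)
        return mod.Chains(param_names=["theta"], draws=arr[:, :, None])

    def test_constant_draws(self):
        s = mod.summarize(self._chains_from(np.full((2, 100), 2.0)))
        row = s.iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == 0.0
        assert not row["overlap0"]
        assert row["f"] == 1.0

    def test_symmetric_draws(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(2, 5000))
        x = np.concatenate([x, -x], axis=1)  # exactly symmetric
        s = mod.summarize(self._chains_from(x))
        row = s.iloc[0]
        assert row["overlap0"]
        assert row["f"] == pytest.approx(0.5, abs=0.02)

    def test_normal_quantiles(self):
        rng = np.random.default_rng(18)
        s = mod.summarize(self._chains_from(rng.normal(size=(2, 50000))))
        row = s.iloc[0]
        assert row["LCI"] == pytest.approx(-1.959964, abs=0.05)
        assert row["UCI"] == pytest.approx(1.959964, abs=0.05)

    def test_overlap0_iff_interval_contains_zero(self):
        rng = np.random.default_rng(19)
        for shift in (-3.0, -0.5, 0.0, 0.5, 3.0):
            s = mod.summarize(self._chains_from(rng.normal(shift, 1, size=(2, 2000))))
            row = s.iloc[0]
            assert row["overlap0"] == (row["LCI"] <= 0.0 <= row["UCI"])
            assert row["LCI"] <= row["UCI"]
            assert 0.45 <= row["f"] <= 1.0


class TestDerivedOccupancy:
    def _const_chains(self, beta0, p, n=200):
        draws = np.zeros((2, n, 2))
        draws[:, :, 0] = beta0
        draws[:, :, 1] = p
        return mod.Chains(param_names=["beta0", "p"], draws=draws)

    def test_zero_intercept_gives_half(self):
        chains = self._const_chains(0.0, 0.5)
        m = make_matrix(np.zeros((4, 3)))
        d = mod.derived_occupancy(chains, None, mod.ModelSpec(covariate_names=()), matrix=m)
        assert d.mean_occupancy == pytest.approx(0.5)
        assert d.sd_occupancy == 0.0

    def test_detected_site_conditional_is_one(self):
        chains = self._const_chains(0.0, 0.5)
        vals = np.zeros((3, 3))
        vals[1, 2] = 1.0
        m = make_matrix(vals)
        d = mod.derived_occupancy(chains, None, mod.ModelSpec(covariate_names=()), matrix=m)
        assert d.conditional_site_mean.iloc[1] == 1.0

    def test_undetected_conditional_hand_value(self):
        chains = self._const_chains(0.0, 0.5)  # psi = 0.5, p = 0.5
        m = make_matrix(np.zeros((1, 3)))  # J = 3, no detections
        d = mod.derived_occupancy(chains, None, mod.ModelSpec(covariate_names=()), matrix=m)
        assert d.conditional_site_mean.iloc[0] == pytest.approx(1 / 9, abs=1e-12)

    def test_covariate_mismatch_rejected(self):
        chains = self._const_chains(0.0, 0.5)
        m = make_matrix(np.zeros((3, 2)))
        table = _table(np.zeros((5, 1)), ["c1"])
        with pytest.raises(ValueError):
            mod.derived_occupancy(chains, table, mod.ModelSpec(covariate_names=("c1",)), matrix=m)
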