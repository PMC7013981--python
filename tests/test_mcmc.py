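"""MCMC sampler: conjugate-limit exactness, DIC arithmetic, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from stcar import (
    MCMCConfig,
    PriorSpec,
    convergence_report,
    dic,
    fit,
    generate_panel,
    lcar_precision,
    make_lattice,
)
from conftest import exact_joint_posterior, manual_samples


@pytest.fixture(scope="module")
def small_fit():
    """One reduced fit on a 4 x 4 lattice shared by several checks."""
    _, adj = make_lattice(4, 4)
    panel, truth = generate_panel(adj, T=3, seed=5)
    config = MCMCConfig(n_chains=2, n_iter=1500, burn_in=500, thin=2, seed=7)
    return fit(panel, adj, config=config), config, truth


class TestFitContracts:
    def test_draw_counts_and_ranges(self, small_fit):
        samples, config, _ = small_fit
        assert samples.n_chains == 2
        assert samples.n_draws == 2 * (config.n_iter - config.burn_in) // config.thin
        for nm in ("rho", "lam"):
            d = samples.pooled(nm)
            assert np.all((d > 0) & (d < 1))
        assert np.all(samples.pooled("sigma2") > 0)
        assert np.all(samples.pooled("tau2") > 0)
        assert len(samples.acceptance) == 2

    def test_singular_design_rejected(self):
        _, adj = make_lattice(2, 2)
        panel, _ = generate_panel(adj, T=2, seed=0)
        with pytest.raises(ValueError, match="singular"):
            fit(panel, adj, terms=["uldi", "uldi"])

    def test_mismatched_adjacency_rejected(self):
        _, adj = make_lattice(2, 2)
        _, adj_big = make_lattice(2, 3)
        panel, _ = generate_panel(adj, T=2, seed=0)
        with pytest.raises(ValueError, match="disagree"):
            fit(panel, adj_big)

    @pytest.mark.filterwarnings("ignore:rho acceptance rate")
    def test_single_period_fixes_lambda(self):
        _, adj = make_lattice(2, 3)
        panel, _ = generate_panel(adj, T=1, seed=1)
        samples = fit(
            panel, adj, terms=["uldi", "green"],
            config=MCMCConfig(n_chains=1, n_iter=400, burn_in=100, thin=1, seed=2),
        )
        assert np.all(samples.pooled("lam") == 0.0)


class TestConjugateLimit:
    @pytest.mark.parametrize("T", [1, 2])
    def test_gibbs_matches_exact_gaussian_posterior(self, T):
        # with (rho, lambda, tau2, sigma2) pinned the posterior of the
        # coefficients is Gaussian in closed form; the Gibbs mean must
        # agree within Monte-Carlo error
        _, adj = make_lattice(2, 2)
        panel, _ = generate_panel(adj, T=T, seed=3, tau2=0.3, sigma2=0.01)
        rho, lam, tau2, sigma2 = 0.7, (0.5 if T > 1 else 0.0), 0.3, 0.01
        priors = PriorSpec(coef_precision=1e-4)
        config = MCMCConfig(n_chains=2, n_iter=6000, burn_in=1000, thin=1, seed=11)
        samples = fit(
            panel, adj, terms=["uldi", "green"], priors=priors, config=config,
            fixed={"rho": rho, "lam": lam, "tau2": tau2, "sigma2": sigma2},
        )
        p = len(samples.coef_names)
        m0, P0 = priors.coef_prior(p)
        Q = lcar_precision(adj, rho).Q
        mean, cov = exact_joint_posterior(
            panel.y, samples.Z, Q, lam, tau2, sigma2, m0, P0
        )
        gibbs_mean = samples.pooled("coef").mean(axis=0)
        post_sd = np.sqrt(np.diag(cov)[:p])
        # Monte-Carlo standard errors from the measured effective sample size
        import arviz as az

        ess = np.array(
            [
                float(
                    az.ess(
                        az.from_dict(
                            posterior={
                                "b": np.stack([c["coef"][:, j] for c in samples.chains])
                            }
                        )
                    )["b"].values
                )
                for j in range(p)
            ]
        )
        mcse = post_sd / np.sqrt(np.maximum(ess, 10.0))
        assert np.all(np.abs(gibbs_mean - mean[:p]) < 5 * mcse)


def _single_site_fit(y, Z, L, n_iter, burn_in, seed, a=0.001, b=0.001):
    """Independent oracle: dense single-site Gibbs with griddy-Gibbs rho.

    Shares no code with the package sampler — conditionals are written from
    the joint density directly, psi is updated one site at a time, and rho
    is drawn from a discretised grid using dense log-determinants.
    """
    rng = np.random.default_rng(seed)
    K, T, p = Z.shape
    n = K * T
    Zm = Z.reshape(n, p)
    yv = y.reshape(n)
    W_ = np.diag(np.diag(L)) - L
    theta = np.linalg.lstsq(Zm, yv, rcond=None)[0]
    psi = np.zeros((K, T))
    rv = max(float(np.var(yv - Zm @ theta)), 1e-8)
    sigma2 = tau2 = rv / 2
    rho, lam = 0.5, 0.5
    grid = np.linspace(0.001, 0.999, 199)
    Qs = [np.diag(1 - r + r * np.diag(L)) - r * W_ for r in grid]
    lds = [np.linalg.slogdet(Qg)[1] for Qg in Qs]
    keep = {k: [] for k in ("sigma2", "tau2", "rho", "lam")}
    for it in range(n_iter):
        Q = np.diag(1 - rho + rho * np.diag(L)) - rho * W_
        r = yv - psi.reshape(n)
        prec = Zm.T @ Zm / sigma2 + 1e-6 * np.eye(p)
        mean = np.linalg.solve(prec, Zm.T @ r / sigma2)
        theta = mean + np.linalg.solve(
            np.linalg.cholesky(prec).T, rng.standard_normal(p)
        )
        mu = Z @ theta
        for t in range(T):
            c_t = 1 + (lam * lam if t < T - 1 else 0.0)
            for k in range(K):
                pr = 1 / sigma2 + c_t * Q[k, k] / tau2
                lin = -c_t * (Q[k] @ psi[:, t] - Q[k, k] * psi[k, t])
                if t > 0:
                    lin += lam * (Q[k] @ psi[:, t - 1])
                if t < T - 1:
                    lin += lam * (Q[k] @ psi[:, t + 1])
                m = ((y[k, t] - mu[k, t]) / sigma2 + lin / tau2) / pr
                psi[k, t] = m + rng.standard_normal() / np.sqrt(pr)
        rss = float(np.sum((y - mu - psi) ** 2))
        sigma2 = (b + rss / 2) / rng.gamma(a + n / 2)
        innov = psi.copy()
        innov[:, 1:] -= lam * psi[:, :-1]
        quad = float(np.sum(innov * (Q @ innov)))
        tau2 = (b + quad / 2) / rng.gamma(a + n / 2)
        prev = psi[:, :-1]
        Qp = Q @ prev
        A = float(np.sum(prev * Qp))
        B = float(np.sum(psi[:, 1:] * Qp))
        if A > 0:
            m_l, s_l = B / A, np.sqrt(tau2 / A)
            lam = float(
                stats.truncnorm.rvs(
                    -m_l / s_l, (1 - m_l) / s_l, loc=m_l, scale=s_l,
                    random_state=rng,
                )
            )
        innov = psi.copy()
        innov[:, 1:] -= lam * psi[:, :-1]
        sI = float(np.sum(innov * innov))
        sL = float(np.sum(innov * (L @ innov)))
        logp = np.array(
            [T / 2 * ld - ((1 - g) * sI + g * sL) / (2 * tau2) for g, ld in zip(grid, lds)]
        )
        w = np.exp(logp - logp.max())
        rho = float(rng.choice(grid, p=w / w.sum()))
        if it >= burn_in:
            for key, val in (("sigma2", sigma2), ("tau2", tau2), ("rho", rho), ("lam", lam)):
                keep[key].append(val)
    return {k: np.array(v) for k, v in keep.items()}


class TestSingleSiteEquivalence:
    def test_block_and_single_site_posteriors_agree(self):
        # the package's per-period block updates and a from-scratch
        # single-site sampler must target the same posterior
        _, adj = make_lattice(3, 3)
        panel, _ = generate_panel(adj, T=2, seed=42)
        samples = fit(
            panel, adj, terms=["uldi", "green"],
            config=MCMCConfig(n_chains=2, n_iter=4000, burn_in=1000, thin=1, seed=2),
        )
        from stcar.design import build_design

        Z, _ = build_design(panel, ["uldi", "green"])
        oracle = _single_site_fit(panel.y, Z, adj.laplacian(), 4000, 1000, seed=9)
        for name in ("sigma2", "tau2", "rho", "lam"):
            block = samples.pooled(name)
            ss = oracle[name]
            scale = max(np.std(block), np.std(ss))
            assert abs(np.median(block) - np.median(ss)) < 0.5 * scale
            # matching spread, not just location
            assert 0.5 < np.std(block) / np.std(ss) < 2.0


class TestDIC:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        K, T, p = 4, 2, 2
        y = rng.normal(size=(K, T))
        Z = np.stack([np.ones((K, T)), rng.normal(size=(K, T))], axis=2)
        return y, Z, ["intercept", "x"], rng

    def test_degenerate_chain_has_zero_pd(self):
        y, Z, names, rng = self._fixture()
        coef = np.tile([0.3, -0.2], (12, 1))
        psi = np.tile(rng.normal(size=(4, 2)), (12, 1, 1))
        sigma2 = np.full(12, 0.5)
        samples = manual_samples(coef, psi, sigma2, y, Z, names)
        res = dic(samples)
        assert res.p_d == pytest.approx(0.0, abs=1e-10)
        assert res.dic == pytest.approx(res.deviance_at_means)

    def test_two_draw_chain_matches_hand_computation(self):
        y, Z, names, rng = self._fixture(1)
        coef = np.array([[0.5, 0.1], [0.1, -0.3]])
        psi = rng.normal(size=(2, 4, 2)) * 0.3
        sigma2 = np.array([0.4, 0.9])
        samples = manual_samples(coef, psi, sigma2, y, Z, names)
        res = dic(samples, min_draws=2)

        # independent recomputation with scipy's normal density
        devs = []
        for c, p_, s in zip(coef, psi, sigma2):
            mu = Z @ c + p_
            devs.append(-2 * stats.norm.logpdf(y, mu, np.sqrt(s)).sum())
        mean_dev = np.mean(devs)
        mu_bar = Z @ coef.mean(axis=0) + psi.mean(axis=0)
        dev_bar = -2 * stats.norm.logpdf(y, mu_bar, np.sqrt(sigma2.mean())).sum()
        assert res.mean_deviance == pytest.approx(mean_dev, rel=1e-12)
        assert res.p_d == pytest.approx(mean_dev - dev_bar, rel=1e-9)
        assert res.dic == pytest.approx(2 * mean_dev - dev_bar, rel=1e-9)

    def test_small_noise_gives_negative_deviance(self):
        # a Gaussian likelihood with tiny sigma2 yields negative deviance,
        # hence negative DIC values are legitimate
        y, Z, names, rng = self._fixture(2)
        coef = np.tile([0.0, 0.0], (12, 1))
        psi = np.tile(y[None], (12, 1, 1)) - Z @ np.array([0.0, 0.0])
        sigma2 = np.full(12, 1e-4)
        res = dic(manual_samples(coef, psi, sigma2, y, Z, names))
        assert res.dic < 0

    def test_too_few_draws_rejected(self):
        y, Z, names, rng = self._fixture(3)
        coef = np.zeros((2, 2))
        psi = np.zeros((2, 4, 2))
        sigma2 = np.ones(2)
        with pytest.raises(ValueError, match="at least"):
            dic(manual_samples(coef, psi, sigma2, y, Z, names))


class TestConvergenceReport:
    def _samples_from_chains(self, chain_values: list[np.ndarray]):
        n = len(chain_values[0]) * len(chain_values)
        rng = np.random.default_rng(0)
        K, T = 3, 2
        y = rng.normal(size=(K, T))
        Z = np.ones((K, T, 1))
        coef = np.concatenate(chain_values)[:, None]
        psi = np.zeros((n, K, T))
        sigma2 = np.ones(n)
        return manual_samples(
            coef, psi, sigma2, y, Z, ["intercept"], n_chains=len(chain_values)
        )

    def test_identical_chains_rhat_one(self):
        draws = np.random.default_rng(1).normal(size=1000)
        rep = convergence_report(self._samples_from_chains([draws, draws.copy()]))
        assert rep.loc["intercept", "rhat"] == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=500)
        b = rng.normal(8.0, 1.0, size=500)  # stuck at a different mode
        rep = convergence_report(self._samples_from_chains([a, b]))
        assert rep.loc["intercept", "rhat"] > 1.1

    def test_iid_chains_ess_near_total_draws(self):
        rng = np.random.default_rng(3)
        chains = [rng.normal(size=5000), rng.normal(size=5000)]
        rep = convergence_report(self._samples_from_chains(chains))
        assert rep.loc["intercept", "ess"] == pytest.approx(10_000, rel=0.10)

    def test_single_chain_warns(self):
        draws = np.random.default_rng(4).normal(size=200)
        with pytest.warns(UserWarning, match="single chain"):
            convergence_report(self._samples_from_chains([draws]))
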