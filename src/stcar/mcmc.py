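"""MCMC fitting of the Gaussian spatio-temporal LCAR-AR(1) panel model.

Model, for county k = 1..K and period t = 1..T:

    y_kt ~ N(z_kt' theta + psi_kt, sigma2)
    psi_1 ~ N(0, tau2 Q(rho, W)^{-1})
    psi_t | psi_{t-1} ~ N(lambda psi_{t-1}, tau2 Q(rho, W)^{-1})

with Q(rho, W) = diag(1 - rho + rho w+) - rho W (Leroux CAR) and priors
theta ~ N(m0, P0^{-1}) (diffuse), sigma2, tau2 ~ Inverse-Gamma(a, b),
rho, lambda ~ Uniform(0, 1).

The sampler is a Gibbs cycle with one Metropolis step:

  (i)   theta   — conjugate Gaussian update given psi, sigma2;
  (ii)  psi_t   — block Gaussian updates per period, solved in the
                  eigenbasis of the graph Laplacian, with conditional
                  precision (1/sigma2) I + c_t (1/tau2) Q and
                  c_t = 1 + lambda^2 * 1[t < T];
  (iii) sigma2  — Inverse-Gamma(a + KT/2, b + RSS/2);
  (iv)  tau2    — Inverse-Gamma(a + KT/2, b + S/2) where S is the sum of
                  LCAR quadratic forms of the AR(1) innovations;
  (v)   lambda  — its Gaussian full conditional truncated to (0, 1);
  (vi)  rho     — random-walk Metropolis on the logit scale with the
                  eigenvalue-cached log-determinant, proposal scale
                  adapted toward ~0.4 acceptance during burn-in then frozen.

Deviance is conditional on the latent field,
D = -2 log N(y | Z theta + psi, sigma2 I), which with small sigma2 can be
negative — and so can the DIC built from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design
from .spatial import AdjacencyMatrix
from .synthetic import PanelData

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "DICResult",
    "fit",
    "dic",
    "convergence_report",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Diffuse conjugate priors.

    ``coef_precision`` may be a scalar (isotropic) or a full matrix; the
    inverse-gamma (a, b) applies to both sigma2 and tau2; rho and lambda
    priors are fixed Uniform(0, 1).

    The default IG(0.001, 0.001) approximates a flat prior on log variance
    and is deliberately scale-free: any fixed-scale choice such as
    IG(1, 0.01) carries almost no mass below its scale parameter (prior
    median ~0.014) and visibly biases a weakly identified observation
    variance upward when the true value is of order 1e-3.
    """

    coef_mean: float | np.ndarray = 0.0
    coef_precision: float | np.ndarray = 1e-6
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def __post_init__(self) -> None:
        if self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")

    def coef_prior(self, p: int) -> tuple[np.ndarray, np.ndarray]:
        m = np.broadcast_to(np.asarray(self.coef_mean, dtype=float), (p,)).copy()
        P = np.asarray(self.coef_precision, dtype=float)
        P = P * np.eye(p) if P.ndim == 0 else P
        if P.shape != (p, p):
            raise ValueError("coef_precision shape mismatch")
        return m, P


@dataclass
class MCMCConfig:
    """Chain layout; defaults follow the study protocol (2 x 70k / 20k / 10)."""

    n_chains: int = 2
    n_iter: int = 70_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    rho_proposal_sd: float = 1.0  # logit scale, adapted during burn-in
    store_psi: bool = True

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws per chain, plus the data needed to evaluate deviance."""

    chains: list[dict[str, np.ndarray]]  # keys: coef, sigma2, tau2, rho, lam, loglik, psi
    coef_names: list[str]
    unit_ids: list[str]
    years: list[int]
    y: np.ndarray  # (K, T)
    Z: np.ndarray  # (K, T, p)
    acceptance: list[float] = field(default_factory=list)  # rho, per chain
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_draws(self) -> int:
        return sum(c["coef"].shape[0] for c in self.chains)

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one block concatenated across chains."""
        return np.concatenate([c[name] for c in self.chains], axis=0)

    def scalar_parameters(self) -> dict[str, np.ndarray]:
        """Named scalar draws pooled across chains (coefs + variances + dependence)."""
        out = {}
        coef = self.pooled("coef")
        for j, nm in enumerate(self.coef_names):
            out[nm] = coef[:, j]
        out["tau2"] = self.pooled("tau2")
        out["sigma2"] = self.pooled("sigma2")
        out["rho"] = self.pooled("rho")
        out["lambda"] = self.pooled("lam")
        return out

    def psi_median(self) -> np.ndarray:
        """(K, T) per-cell posterior median of the latent field."""
        if "psi" not in self.chains[0]:
            raise ValueError("psi draws were not stored (store_psi=False)")
        return np.median(self.pooled("psi"), axis=0)


def _gaussian_loglik(y: np.ndarray, mean: np.ndarray, sigma2: float) -> float:
    n = y.size
    rss = float(np.sum((y - mean) ** 2))
    return -0.5 * n * (_LOG2PI + np.log(sigma2)) - 0.5 * rss / sigma2


def _lcar_quadforms(
    psi: np.ndarray, lam: float, L: np.ndarray
) -> tuple[float, float]:
    """(s_I, s_L): identity- and Laplacian-weighted sums of AR(1) innovation
    quadratic forms, so that psi'Q psi terms total (1-rho) s_I + rho s_L."""
    innov = psi.copy()
    innov[:, 1:] -= lam * psi[:, :-1]
    s_I = float(np.sum(innov * innov))
    s_L = float(np.sum(innov * (L @ innov)))
    return s_I, s_L


def _run_chain(
    y: np.ndarray,
    Z: np.ndarray,
    L: np.ndarray,
    eigs: np.ndarray,
    V: np.ndarray,
    priors: PriorSpec,
    config: MCMCConfig,
    fixed: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float]:
    K, T, p = Z.shape
    n = K * T
    Zm = Z.reshape(n, p)
    yv = y.reshape(n)
    m0, P0 = priors.coef_prior(p)
    ZtZ = Zm.T @ Zm
    a, b = priors.ig_shape, priors.ig_scale

    # initialisation: least squares for theta, psi = 0, residual variance
    # split evenly between observation and latent levels
    theta = np.linalg.lstsq(Zm, yv, rcond=None)[0]
    psi = np.zeros((K, T))
    resid_var = max(float(np.var(yv - Zm @ theta)), 1e-8)
    sigma2 = fixed.get("sigma2", resid_var / 2.0)
    tau2 = fixed.get("tau2", resid_var / 2.0)
    rho = fixed.get("rho", 0.5)
    lam = fixed.get("lam", 0.5 if T > 1 else 0.0)

    q_eig = 1.0 - rho + rho * eigs
    logdet = float(np.sum(np.log(q_eig)))

    log_sd = float(np.log(config.rho_proposal_sd))
    window_acc = window_n = 0
    post_acc = post_n = 0

    n_ret = config.n_retained
    out = {
        "coef": np.empty((n_ret, p)),
        "sigma2": np.empty(n_ret),
        "tau2": np.empty(n_ret),
        "rho": np.empty(n_ret),
        "lam": np.empty(n_ret),
        "loglik": np.empty(n_ret),
    }
    if config.store_psi:
        out["psi"] = np.empty((n_ret, K, T))

    def Qv(M: np.ndarray) -> np.ndarray:
        return V @ (q_eig[:, None] * (V.T @ M)) if M.ndim == 2 else V @ (
            q_eig * (V.T @ M)
        )

    kept = 0
    for it in range(config.n_iter):
        # (i) regression coefficients: conjugate Gaussian
        r = yv - psi.reshape(n)
        prec = ZtZ / sigma2 + P0
        cf = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Zm.T @ r / sigma2 + P0 @ m0)
        theta = mean + np.linalg.solve(cf.T, rng.standard_normal(p))
        mu_fixed = (Z @ theta)  # (K, T)

        # (ii) latent field, one Gaussian block per period
        for t in range(T):
            c_t = 1.0 + (lam * lam if t < T - 1 else 0.0)
            d = 1.0 / sigma2 + c_t * q_eig / tau2
            nb = np.zeros(K)
            if t > 0:
                nb += psi[:, t - 1]
            if t < T - 1:
                nb += psi[:, t + 1]
            rhs = (y[:, t] - mu_fixed[:, t]) / sigma2 + (lam / tau2) * Qv(nb)
            zt = rng.standard_normal(K)
            psi[:, t] = V @ ((V.T @ rhs) / d + zt / np.sqrt(d))

        # (iii) observation variance
        rss = float(np.sum((y - mu_fixed - psi) ** 2))
        if "sigma2" not in fixed:
            sigma2 = b + 0.5 * rss
            sigma2 /= rng.gamma(a + 0.5 * n)
        # (iv) latent variance
        s_I, s_L = _lcar_quadforms(psi, lam, L)
        quad = (1.0 - rho) * s_I + rho * s_L
        if "tau2" not in fixed:
            tau2 = (b + 0.5 * quad) / rng.gamma(a + 0.5 * n)

        # (v) temporal dependence: truncated-Gaussian full conditional
        if T > 1 and "lam" not in fixed:
            prev = psi[:, :-1]
            Qprev = Qv(prev)
            A = float(np.sum(prev * Qprev))
            B = float(np.sum(psi[:, 1:] * Qprev))
            if A > 0:
                m_l = B / A
                s_l = np.sqrt(tau2 / A)
                lam = float(
                    stats.truncnorm.rvs(
                        (0.0 - m_l) / s_l, (1.0 - m_l) / s_l,
                        loc=m_l, scale=s_l, random_state=rng,
                    )
                )
            else:
                lam = float(rng.uniform())
            s_I, s_L = _lcar_quadforms(psi, lam, L)

        # (vi) spatial dependence: logit random-walk Metropolis
        if "rho" not in fixed:
            x = np.log(rho) - np.log1p(-rho)
            x_new = x + np.exp(log_sd) * rng.standard_normal()
            rho_new = 1.0 / (1.0 + np.exp(-x_new))
            q_new = 1.0 - rho_new + rho_new * eigs
            if np.all(q_new > 0):
                logdet_new = float(np.sum(np.log(q_new)))
                def logtarget(r_, ld_):
                    quad_ = (1.0 - r_) * s_I + r_ * s_L
                    return (
                        0.5 * T * ld_
                        - 0.5 * quad_ / tau2
                        + np.log(r_) + np.log1p(-r_)  # logit Jacobian
                    )
                if np.log(rng.uniform()) < logtarget(rho_new, logdet_new) - logtarget(
                    rho, logdet
                ):
                    rho, q_eig, logdet = rho_new, q_new, logdet_new
                    window_acc += 1
                    if it >= config.burn_in:
                        post_acc += 1
            window_n += 1
            if it >= config.burn_in:
                post_n += 1
            if it < config.burn_in and window_n == 50:
                rate = window_acc / 50.0
                log_sd += 0.5 * (rate - 0.4)
                window_acc = window_n = 0

        assert 0.0 < rho < 1.0 or "rho" in fixed
        assert (0.0 <= lam < 1.0) or "lam" in fixed or T == 1
        assert sigma2 > 0.0 and tau2 > 0.0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_ret:
            out["coef"][kept] = theta
            out["sigma2"][kept] = sigma2
            out["tau2"][kept] = tau2
            out["rho"][kept] = rho
            out["lam"][kept] = lam
            out["loglik"][kept] = -0.5 * n * (_LOG2PI + np.log(sigma2)) - 0.5 * rss / sigma2
            if config.store_psi:
                out["psi"][kept] = psi
            kept += 1

    acc_rate = post_acc / post_n if post_n else float("nan")
    return out, acc_rate


def fit(
    panel: PanelData,
    W: AdjacencyMatrix,
    terms: list[str] | None = None,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Fit the model by MCMC and return retained, thinned draws.

    ``terms`` selects covariates and interactions (see
    :func:`stcar.design.build_design`); ``fixed`` pins any of
    {"rho", "lam", "tau2", "sigma2"} at a value (no update), which is how
    conjugate-limit checks are run.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    fixed = dict(fixed or {})
    if W.K != panel.K:
        raise ValueError("adjacency and panel disagree on K")
    if panel.K < 2:
        raise ValueError("model fitting needs at least 2 areal units")
    if panel.T == 1 and "lam" not in fixed:
        fixed["lam"] = 0.0  # lambda unidentifiable with one period

    Z, names = build_design(panel, terms)
    n, p = panel.K * panel.T, Z.shape[2]
    if np.linalg.matrix_rank(Z.reshape(n, p)) < p:
        raise ValueError("singular design matrix (collinear terms)")

    L = W.laplacian()
    eigs, V = np.linalg.eigh(L)

    chains, acc = [], []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for ss in seeds:
        draws, a_rate = _run_chain(
            panel.y, Z, L, eigs, V, priors, config, fixed,
            np.random.default_rng(ss),
        )
        chains.append(draws)
        acc.append(a_rate)

    for a_rate in acc:
        if "rho" not in fixed and np.isfinite(a_rate) and not 0.1 <= a_rate <= 0.6:
            warnings.warn(
                f"rho acceptance rate {a_rate:.2f} outside [0.1, 0.6] after "
                "adaptation; inspect mixing",
                stacklevel=2,
            )
    return PosteriorSamples(
        chains=chains,
        coef_names=names,
        unit_ids=list(panel.unit_ids),
        years=list(panel.years),
        y=panel.y,
        Z=Z,
        acceptance=acc,
        fixed=fixed,
    )


@dataclass
class DICResult:
    dic: float
    p_d: float
    mean_deviance: float
    deviance_at_means: float
    loglik_at_means: float


def dic(samples: PosteriorSamples, min_draws: int = 10) -> DICResult:
    """Deviance information criterion, conditional on the latent field.

    D = -2 log N(y | Z theta + psi, sigma2 I); DIC = mean(D) + p_D with
    p_D = mean(D) - D at the posterior means of (theta, psi, sigma2).
    With a Gaussian likelihood and small sigma2, D and hence DIC can be
    negative.
    """
    if samples.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws")
    ll = samples.pooled("loglik")
    mean_dev = float(np.mean(-2.0 * ll))
    theta_bar = samples.pooled("coef").mean(axis=0)
    psi_bar = samples.pooled("psi").mean(axis=0)
    sigma2_bar = float(samples.pooled("sigma2").mean())
    ll_at_means = _gaussian_loglik(
        samples.y, samples.Z @ theta_bar + psi_bar, sigma2_bar
    )
    dev_at_means = -2.0 * ll_at_means
    p_d = mean_dev - dev_at_means
    return DICResult(
        dic=mean_dev + p_d,
        p_d=p_d,
        mean_deviance=mean_dev,
        deviance_at_means=dev_at_means,
        loglik_at_means=ll_at_means,
    )


def convergence_report(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and effective sample size per scalar parameter (via arviz)."""
    import arviz as az

    if samples.n_chains < 2:
        warnings.warn(
            "convergence diagnostics from a single chain are unreliable",
            stacklevel=2,
        )
    per_chain = {}
    for nm in samples.scalar_parameters():
        key = {"lambda": "lam", "tau2": "tau2", "sigma2": "sigma2", "rho": "rho"}.get(nm)
        if key in ("lam", "tau2", "sigma2", "rho"):
            arr = np.stack([c[key] for c in samples.chains])
        else:
            j = samples.coef_names.index(nm)
            arr = np.stack([c["coef"][:, j] for c in samples.chains])
        per_chain[nm] = arr
    idata = az.from_dict(posterior=per_chain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = [
        {
            "parameter": nm,
            "rhat": float(rhat[nm].values),
            "ess": float(ess[nm].values),
        }
        for nm in per_chain
    ]
    return pd.DataFrame(rows).set_index("parameter")
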