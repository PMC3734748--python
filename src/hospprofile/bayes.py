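"""Bayesian Poisson models for hospital effects.

Observed deaths O_i are Poisson with mean E_i * exp(theta_i), so the
log mean is the log expected-death offset plus a hospital effect
theta_i (the log standardised mortality ratio).  Two priors are
offered:

* fixed:        theta_i ~ Normal(0, fixed_prior_variance), independent
* hierarchical: theta_i ~ Normal(mu0, sigma0^2) with hyper-priors
                mu0 ~ Normal(0, 1000) and either a Gamma(0.001, 0.001)
                prior on the precision sigma0^-2 (rate parameterisation,
                prior mean 1 and variance 1000) or a Uniform(0, 100)
                prior on the standard deviation sigma0.

Sampling is Metropolis-within-Gibbs: each theta_i gets an adaptive
Gaussian random-walk update (target acceptance ~0.44, adaptation frozen
after burn-in); mu0 and the precision are conjugate Gibbs draws; the
uniform-SD prior is handled by a Metropolis step on log sigma0.  Chains
start over-dispersed and run in lock-step, so a run is a pure function
of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_TARGET_ACCEPT = 0.44
_ADAPT_BLOCK = 50


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "fixed"  # "fixed" | "hierarchical"
    fixed_prior_variance: float = 1000.0
    hyper_mean_prior_variance: float = 1000.0
    hyper_precision_prior: str = "gamma"  # "gamma" | "uniform_sd"
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001
    uniform_sd_upper: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "hierarchical"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.hyper_precision_prior not in ("gamma", "uniform_sd"):
            raise ValueError(
                f"unknown hyper-precision prior {self.hyper_precision_prior!r}"
            )
        if min(self.fixed_prior_variance, self.hyper_mean_prior_variance) <= 0:
            raise ValueError("prior variances must be positive")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iterations: int = 50_000
    burn_in: int = 15_000
    seed: int = 0
    adapt_window: int | None = None  # defaults to the whole burn-in

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.burn_in

    @property
    def adaptation_end(self) -> int:
        return self.burn_in if self.adapt_window is None else min(
            self.adapt_window, self.burn_in
        )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws; theta has shape (n_chains, n_retained, n_hospitals)."""

    theta: np.ndarray
    hospital_ids: np.ndarray
    kind: str
    mu0: np.ndarray | None = None  # (n_chains, n_retained), hierarchical only
    sigma0_sq: np.ndarray | None = None
    acceptance_rate: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_retained(self) -> int:
        return self.theta.shape[1]

    @property
    def chain_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.n_retained)

    def theta_combined(self) -> np.ndarray:
        """All chains pooled: shape (n_chains * n_retained, n_hospitals)."""
        return self.theta.reshape(-1, self.theta.shape[2])

    def mu0_combined(self) -> np.ndarray:
        if self.mu0 is None:
            raise ValueError("fixed-effects draws carry no hyper-parameters")
        return self.mu0.reshape(-1)

    def sigma0_sq_combined(self) -> np.ndarray:
        if self.sigma0_sq is None:
            raise ValueError("fixed-effects draws carry no hyper-parameters")
        return self.sigma0_sq.reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long columnar layout: parameter, chain, iteration, value."""
        frames = []
        c, n, h = self.theta.shape
        chain = np.repeat(np.arange(c), n)
        iteration = np.tile(np.arange(n), c)
        for j in range(h):
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": f"theta[{self.hospital_ids[j]}]",
                        "chain": chain,
                        "iteration": iteration,
                        "value": self.theta[:, :, j].reshape(-1),
                    }
                )
            )
        if self.mu0 is not None:
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": "mu0",
                        "chain": chain,
                        "iteration": iteration,
                        "value": self.mu0.reshape(-1),
                    }
                )
            )
        if self.sigma0_sq is not None:
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": "sigma0_sq",
                        "chain": chain,
                        "iteration": iteration,
                        "value": self.sigma0_sq.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @staticmethod
    def read(path: str | Path) -> "PosteriorDraws":
        """Inverse of :meth:`write` (kind is inferred from the columns)."""
        frame = pd.read_csv(path)
        chains = np.sort(frame["chain"].unique())
        iters = np.sort(frame["iteration"].unique())
        c, n = len(chains), len(iters)
        theta_params = sorted(
            (p for p in frame["parameter"].unique() if p.startswith("theta[")),
            key=lambda p: int(p[6:-1]),
        )
        ids = np.array([int(p[6:-1]) for p in theta_params])
        wide = frame.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value", sort=True
        )
        theta = np.stack(
            [wide[p].to_numpy().reshape(c, n) for p in theta_params], axis=2
        )
        mu0 = s2 = None
        if "mu0" in wide.columns:
            mu0 = wide["mu0"].to_numpy().reshape(c, n)
        if "sigma0_sq" in wide.columns:
            s2 = wide["sigma0_sq"].to_numpy().reshape(c, n)
        kind = "hierarchical" if mu0 is not None else "fixed"
        return PosteriorDraws(
            theta=theta, hospital_ids=ids, kind=kind, mu0=mu0, sigma0_sq=s2
        )


@dataclass(frozen=True)
class ConvergenceReport:
    r_hat: dict[str, float]
    monitored: tuple[str, ...] = field(default_factory=tuple)

    def max_r_hat(self) -> float:
        return max(self.r_hat.values())

    def lines(self) -> list[str]:
        out = [f"r_hat[{k}] = {v:.4f}" for k, v in self.r_hat.items()]
        out.append(f"max r_hat = {self.max_r_hat():.4f}")
        return out


def _validate_summaries(summaries: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = summaries["hospital_id"].to_numpy()
    O = summaries["observed_deaths"].to_numpy(dtype=float)
    E = summaries["expected_deaths"].to_numpy(dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected deaths must be positive for every hospital")
    return ids, O, E


def _initial_theta(O: np.ndarray, E: np.ndarray, n_chains: int) -> np.ndarray:
    """Over-dispersed starts around the crude log O/E."""
    base = np.log(O + 0.5) - np.log(E)
    offsets = np.array([(-1.0, 0.0, 1.0)[c % 3] for c in range(n_chains)])
    return base[None, :] + offsets[:, None]


def _adapt(scale: np.ndarray, accepted: np.ndarray) -> None:
    rate = accepted / _ADAPT_BLOCK
    scale *= np.exp(rate - _TARGET_ACCEPT)
    np.clip(scale, 1e-3, 10.0, out=scale)
    accepted[:] = 0.0


def fit_fixed_model(
    summaries: pd.DataFrame, spec: ModelSpec, mcmc: McmcConfig
) -> PosteriorDraws:
    """Sample each hospital's effect under the independent Normal(0, v)
    prior.  Hospitals are conditionally independent, so all chains and
    hospitals update in a single vectorised Metropolis sweep."""
    ids, O, E = _validate_summaries(summaries)
    v = spec.fixed_prior_variance
    rng = np.random.default_rng(mcmc.seed)
    C, H = mcmc.n_chains, len(ids)

    theta = _initial_theta(O, E, C)

    def logp(th: np.ndarray) -> np.ndarray:
        return O * th - E * np.exp(th) - th**2 / (2.0 * v)

    lp = logp(theta)
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError("non-finite log-posterior at the initial state")

    scale = np.full((C, H), 1.0)
    accepted = np.zeros((C, H))
    total_accepted = np.zeros((C, H))
    kept = np.empty((C, mcmc.n_retained, H))

    for it in range(mcmc.n_iterations):
        prop = theta + scale * rng.standard_normal((C, H))
        lp_prop = logp(prop)
        accept = np.log(rng.random((C, H))) < lp_prop - lp
        theta = np.where(accept, prop, theta)
        lp = np.where(accept, lp_prop, lp)
        accepted += accept
        if it >= mcmc.burn_in:
            kept[:, it - mcmc.burn_in, :] = theta
            total_accepted += accept
        elif (it + 1) % _ADAPT_BLOCK == 0 and it < mcmc.adaptation_end:
            _adapt(scale, accepted)

    return PosteriorDraws(
        theta=kept,
        hospital_ids=ids,
        kind="fixed",
        acceptance_rate=total_accepted / mcmc.n_retained,
    )


def fit_hierarchical_model(
    summaries: pd.DataFrame, spec: ModelSpec, mcmc: McmcConfig
) -> PosteriorDraws:
    """Sample hospital effects and hyper-parameters under the exchangeable
    Normal(mu0, sigma0^2) prior.

    mu0 and (under the gamma prior) sigma0^-2 are conjugate Gibbs
    updates; theta_i and (under the uniform-SD prior) log sigma0 are
    adaptive Metropolis steps.
    """
    ids, O, E = _validate_summaries(summaries)
    if len(ids) < 3:
        raise ValueError("hierarchical model requires >= 3 hospitals")
    rng = np.random.default_rng(mcmc.seed)
    C, H = mcmc.n_chains, len(ids)
    v_mu = spec.hyper_mean_prior_variance

    theta = _initial_theta(O, E, C)
    mu0 = np.zeros(C)
    sigma0_sq = np.array([(0.01, 0.1, 1.0)[c % 3] for c in range(C)])

    def loglik(th: np.ndarray) -> np.ndarray:
        return O * th - E * np.exp(th)

    ll = loglik(theta)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-posterior at the initial state")

    scale = np.full((C, H), 1.0)
    accepted = np.zeros((C, H))
    log_sd_scale = np.full(C, 0.5)  # for the uniform-SD Metropolis step
    log_sd_accepted = np.zeros(C)

    kept_theta = np.empty((C, mcmc.n_retained, H))
    kept_mu0 = np.empty((C, mcmc.n_retained))
    kept_s2 = np.empty((C, mcmc.n_retained))

    for it in range(mcmc.n_iterations):
        # theta | mu0, sigma0 — vectorised Metropolis
        prop = theta + scale * rng.standard_normal((C, H))
        ll_prop = loglik(prop)
        d_prior = ((theta - mu0[:, None]) ** 2 - (prop - mu0[:, None]) ** 2) / (
            2.0 * sigma0_sq[:, None]
        )
        accept = np.log(rng.random((C, H))) < ll_prop - ll + d_prior
        theta = np.where(accept, prop, theta)
        ll = np.where(accept, ll_prop, ll)
        accepted += accept

        # mu0 | theta, sigma0 — normal conjugate with Normal(0, v_mu) prior
        post_var = 1.0 / (H / sigma0_sq + 1.0 / v_mu)
        post_mean = post_var * theta.sum(axis=1) / sigma0_sq
        mu0 = post_mean + np.sqrt(post_var) * rng.standard_normal(C)

        resid_ss = ((theta - mu0[:, None]) ** 2).sum(axis=1)
        if spec.hyper_precision_prior == "gamma":
            shape = spec.gamma_shape + H / 2.0
            rate = spec.gamma_rate + resid_ss / 2.0
            sigma0_sq = 1.0 / rng.gamma(shape, 1.0 / rate, size=C)
        else:
            # Metropolis on u = log sigma0 with Uniform(0, upper) prior
            # on sigma0; the Jacobian contributes +u.
            u = 0.5 * np.log(sigma0_sq)
            u_prop = u + log_sd_scale * rng.standard_normal(C)

            def log_target(uu: np.ndarray) -> np.ndarray:
                s2 = np.exp(2.0 * uu)
                out = -H * uu - resid_ss / (2.0 * s2) + uu
                return np.where(np.exp(uu) < spec.uniform_sd_upper, out, -np.inf)

            acc_u = np.log(rng.random(C)) < log_target(u_prop) - log_target(u)
            u = np.where(acc_u, u_prop, u)
            sigma0_sq = np.exp(2.0 * u)
            log_sd_accepted += acc_u

        if it >= mcmc.burn_in:
            j = it - mcmc.burn_in
            kept_theta[:, j, :] = theta
            kept_mu0[:, j] = mu0
            kept_s2[:, j] = sigma0_sq
        elif (it + 1) % _ADAPT_BLOCK == 0 and it < mcmc.adaptation_end:
            _adapt(scale, accepted)
            rate_u = log_sd_accepted / _ADAPT_BLOCK
            log_sd_scale *= np.exp(rate_u - _TARGET_ACCEPT)
            np.clip(log_sd_scale, 1e-3, 10.0, out=log_sd_scale)
            log_sd_accepted[:] = 0.0

    if float(np.median(kept_s2)) < 1e-12:
        warnings.warn(
            "sigma0 chain appears absorbed at 0; the hierarchical variance "
            "is not identified for these data",
            RuntimeWarning,
            stacklevel=2,
        )

    return PosteriorDraws(
        theta=kept_theta,
        hospital_ids=ids,
        kind="hierarchical",
        mu0=kept_mu0,
        sigma0_sq=kept_s2,
    )


def psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_iterations).  Classic
    between/within decomposition: sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("need >= 2 chains")
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray]) -> ConvergenceReport:
    """PSRF for every monitored parameter (all hospital effects, plus
    hyper-parameters for hierarchical draws)."""
    if isinstance(draws, PosteriorDraws):
        monitored: dict[str, np.ndarray] = {
            f"theta[{draws.hospital_ids[j]}]": draws.theta[:, :, j]
            for j in range(draws.theta.shape[2])
        }
        if draws.mu0 is not None:
            monitored["mu0"] = draws.mu0
        if draws.sigma0_sq is not None:
            monitored["sigma0_sq"] = draws.sigma0_sq
    else:
        monitored = dict(draws)
    r_hat = {name: psrf(ch) for name, ch in monitored.items()}
    return ConvergenceReport(r_hat=r_hat, monitored=tuple(monitored))


def posterior_summary(
    draws: np.ndarray, level: float = 0.95
) -> dict[str, np.ndarray | float]:
    """Mean, median and equal-tailed interval along the draw axis (axis 0)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return {
        "mean": draws.mean(axis=0),
        "median": np.quantile(draws, 0.5, axis=0),
        "lower": np.quantile(draws, lo, axis=0),
        "upper": np.quantile(draws, hi, axis=0),
    }
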