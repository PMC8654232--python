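"""Bayesian hierarchical logit model for the case-crossover table.

The outcome indicator of each case/referent window is Bernoulli with

    logit(pi) = alpha + d_c + beta_p' X + beta_w' W

where ``d_c`` is a random effect for the window's year-month-day-of-week
stratum.  Priors (shape/rate convention for the Gamma):

* beta_j  | tau_j   ~ Normal(0, 1/tau_j),   tau_j ~ Gamma(2, 1)
* alpha   | tau_a   ~ Normal(0, 1/tau_a),   tau_a = 1/sd_alpha^2,
                                            sd_alpha ~ Uniform(0, 4)
* d_c     | tau_d   ~ Normal(0, 1/tau_d),   tau_d ~ Gamma(2, 0.5)

Sampling is blockwise MCMC: conditionally conjugate Gibbs draws for the
precisions, adaptive random-walk Metropolis for the intercept, each
coefficient and ``sd_alpha``, and a vectorized per-stratum Metropolis sweep
for the random effects (stratum likelihood terms are conditionally
independent, so all strata are proposed and accepted in parallel).  Only
occupied strata carry a parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelData",
    "ParameterState",
    "Posterior",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "tau_d_full_conditional",
    "tau_beta_full_conditional",
    "fit_mcmc",
    "diagnostics",
    "dic",
    "fit_conditional_logistic",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the linear predictor and how priors are set."""

    covariates: tuple[str, ...]
    include_strata: bool = True
    shared_tau_beta: bool = False
    #: fix hyperparameters instead of sampling them (reduced-model testing)
    fixed_tau_beta: float | None = None
    fixed_sd_alpha: float | None = None
    tau_beta_prior: tuple[float, float] = (2.0, 1.0)   # shape, rate
    tau_d_prior: tuple[float, float] = (2.0, 0.5)      # shape, rate
    sd_alpha_bound: float = 4.0

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class ModelData:
    """Design arrays extracted from a centred case-crossover table."""

    y: np.ndarray
    X: np.ndarray
    covariates: tuple[str, ...]
    stratum_codes: np.ndarray | None  # 0..C-1 over occupied strata
    stratum_labels: np.ndarray | None

    @classmethod
    def from_rows(cls, rows: pd.DataFrame, spec: ModelSpec) -> "ModelData":
        missing = [c for c in spec.covariates if c not in rows.columns]
        if missing:
            raise KeyError(f"covariates missing from rows: {missing}")
        y = rows["y"].to_numpy(dtype=float)
        X = rows[list(spec.covariates)].to_numpy(dtype=float)
        if spec.include_strata:
            labels, codes = np.unique(rows["stratum"].to_numpy(), return_inverse=True)
        else:
            labels, codes = None, None
        return cls(y, X, spec.covariates, codes, labels)

    @property
    def n_strata(self) -> int:
        return 0 if self.stratum_labels is None else len(self.stratum_labels)


@dataclass
class ParameterState:
    """One point in parameter space."""

    alpha: float
    betas: np.ndarray
    d: np.ndarray          # one effect per occupied stratum (may be empty)
    tau_beta: np.ndarray   # one precision per coefficient (or length 1, shared)
    tau_d: float
    sd_alpha: float

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.alpha, self.betas.copy(), self.d.copy(),
            self.tau_beta.copy(), self.tau_d, self.sd_alpha,
        )


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _eta(state: ParameterState, data: ModelData) -> np.ndarray:
    eta = state.alpha + data.X @ state.betas
    if data.stratum_codes is not None and len(state.d):
        eta = eta + state.d[data.stratum_codes]
    return eta


def log_likelihood(state: ParameterState, data: ModelData) -> float:
    """Bernoulli log likelihood, computed with a stable log-sigmoid."""
    if len(state.betas) != data.X.shape[1]:
        raise ValueError("state/covariate dimension mismatch")
    if data.stratum_codes is not None and len(state.d) != data.n_strata:
        raise ValueError("state/stratum dimension mismatch")
    eta = _eta(state, data)
    # sum_i [ y eta - log(1 + e^eta) ]
    return float(data.y @ eta - _softplus(eta).sum())


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior density; -inf outside the support."""
    if state.tau_d <= 0 or np.any(state.tau_beta <= 0):
        return -np.inf
    if not (0.0 < state.sd_alpha < spec.sd_alpha_bound):
        return -np.inf
    lp = -np.log(spec.sd_alpha_bound)  # Uniform(0, bound) for sd_alpha
    tau_alpha = state.sd_alpha**-2
    lp += stats.norm.logpdf(state.alpha, scale=np.sqrt(1.0 / tau_alpha))
    tb = np.broadcast_to(state.tau_beta, state.betas.shape)
    lp += float(stats.norm.logpdf(state.betas, scale=np.sqrt(1.0 / tb)).sum())
    a, b = spec.tau_beta_prior
    if spec.fixed_tau_beta is None:
        lp += float(stats.gamma.logpdf(state.tau_beta, a, scale=1.0 / b).sum())
    if len(state.d):
        lp += float(
            stats.norm.logpdf(state.d, scale=np.sqrt(1.0 / state.tau_d)).sum()
        )
    ad, bd = spec.tau_d_prior
    lp += float(stats.gamma.logpdf(state.tau_d, ad, scale=1.0 / bd))
    return float(lp)


def tau_d_full_conditional(
    d: np.ndarray, prior: tuple[float, float] = (2.0, 0.5)
) -> tuple[float, float]:
    """(shape, rate) of the stratum-precision Gibbs conditional.

    Normal likelihood for the ``C`` stratum effects with a Gamma(shape, rate)
    prior is conjugate: ``Gamma(shape + C/2, rate + sum(d^2)/2)``.
    """
    a, b = prior
    d = np.asarray(d, dtype=float)
    return a + 0.5 * len(d), b + 0.5 * float(d @ d)


def tau_beta_full_conditional(
    beta: float | np.ndarray, prior: tuple[float, float] = (2.0, 1.0)
) -> tuple[float, float]:
    """(shape, rate) of one coefficient precision's Gibbs conditional."""
    a, b = prior
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    return a + 0.5 * beta.size, b + 0.5 * float(beta @ beta)


def log_posterior(state: ParameterState, data: ModelData, spec: ModelSpec) -> float:
    lp = log_prior(state, spec)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(state, data)


@dataclass
class Posterior:
    """Retained MCMC draws plus run metadata.

    ``draws`` maps parameter names to arrays of shape ``(n_chains, n_draws)``
    (scalars), ``(n_chains, n_draws, p)`` (betas and their precisions) or
    ``(n_chains, n_draws, C)`` (stratum effects).
    """

    draws: dict[str, np.ndarray]
    loglik: np.ndarray  # (n_chains, n_draws)
    covariates: tuple[str, ...]
    stratum_labels: np.ndarray | None
    spec: ModelSpec
    n_chains: int
    n_iter: int
    n_burnin: int
    thin: int
    seed: int
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings_log: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[1]

    def beta(self, name: str) -> np.ndarray:
        """Flattened draws (all chains pooled) for one coefficient."""
        j = self.covariates.index(name)
        return self.draws["beta"][:, :, j].ravel()

    def scalar(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    def mean_state(self) -> ParameterState:
        """Posterior-mean parameter point (plug-in point for DIC)."""
        d = (
            self.draws["d"].mean(axis=(0, 1))
            if "d" in self.draws
            else np.empty(0)
        )
        return ParameterState(
            alpha=float(self.draws["alpha"].mean()),
            betas=self.draws["beta"].mean(axis=(0, 1)),
            d=d,
            tau_beta=self.draws["tau_beta"].mean(axis=(0, 1)),
            tau_d=float(self.draws["tau_d"].mean()),
            sd_alpha=float(self.draws["sd_alpha"].mean()),
        )

    def to_arviz(self):
        import arviz as az

        data = {
            "alpha": self.draws["alpha"],
            "sd_alpha": self.draws["sd_alpha"],
            "tau_d": self.draws["tau_d"],
        }
        for j, name in enumerate(self.covariates):
            data[f"beta_{name}"] = self.draws["beta"][:, :, j]
        return az.from_dict(posterior=data)

    def to_frame(self) -> pd.DataFrame:
        """One column per scalar parameter, all chains stacked."""
        cols = {
            "chain": np.repeat(np.arange(self.n_chains), self.n_draws),
            "alpha": self.draws["alpha"].ravel(),
            "sd_alpha": self.draws["sd_alpha"].ravel(),
            "tau_d": self.draws["tau_d"].ravel(),
            "loglik": self.loglik.ravel(),
        }
        for j, name in enumerate(self.covariates):
            cols[f"beta_{name}"] = self.draws["beta"][:, :, j].ravel()
            tb = self.draws["tau_beta"]
            cols[f"tau_beta_{name}"] = tb[:, :, min(j, tb.shape[2] - 1)].ravel()
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_burnin": self.n_burnin,
            "thin": self.thin,
            "covariates": list(self.covariates),
            "include_strata": self.spec.include_strata,
            "acceptance": self.acceptance,
            "warnings": self.warnings_log,
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def fit_mcmc(
    data: ModelData | pd.DataFrame,
    spec: ModelSpec,
    n_iter: int = 10_000,
    n_burnin: int = 5_000,
    n_chains: int = 4,
    thin: int = 1,
    seed: int = 0,
    target_accept: float = 0.35,
    store_strata: bool = True,
    max_init_retries: int = 20,
) -> Posterior:
    """Run the blockwise MCMC sampler and return retained draws.

    Chains start from overdispersed points; step sizes adapt during burn-in
    toward the target acceptance rate and are frozen afterwards.  Fully
    reproducible for a fixed ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        data = ModelData.from_rows(data, spec)
    if n_iter < n_burnin:
        raise ValueError("n_iter must be >= n_burnin")
    n_keep = (n_iter - n_burnin) // thin
    p = data.X.shape[1]
    C = data.n_strata
    n_tau = 1 if spec.shared_tau_beta else p

    chain_draws = []
    acc_totals: dict[str, list[float]] = {}
    warn_log: list[str] = []
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chain]))
        out = _run_chain(
            data, spec, rng, n_iter, n_burnin, thin, n_keep,
            target_accept, store_strata, max_init_retries, warn_log,
        )
        chain_draws.append(out)

    draws = {
        key: np.stack([c[0][key] for c in chain_draws])
        for key in chain_draws[0][0]
    }
    loglik = np.stack([c[1] for c in chain_draws])
    acceptance = {
        key: float(np.mean([c[2][key] for c in chain_draws]))
        for key in chain_draws[0][2]
    }
    return Posterior(
        draws=draws, loglik=loglik, covariates=data.covariates,
        stratum_labels=data.stratum_labels, spec=spec,
        n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin, thin=thin,
        seed=seed, acceptance=acceptance, warnings_log=warn_log,
    )


def _init_state(data, spec, rng, p, C, n_tau) -> ParameterState:
    sd_alpha = (
        spec.fixed_sd_alpha
        if spec.fixed_sd_alpha is not None
        else rng.uniform(0.5, spec.sd_alpha_bound - 0.5)
    )
    tau_beta = (
        np.full(n_tau, spec.fixed_tau_beta)
        if spec.fixed_tau_beta is not None
        else rng.gamma(2.0, 1.0, size=n_tau)
    )
    return ParameterState(
        alpha=float(rng.normal(0.0, 1.0)),
        betas=rng.normal(0.0, 0.1, size=p),
        d=rng.normal(0.0, 0.1, size=C) if C else np.empty(0),
        tau_beta=tau_beta,
        tau_d=float(rng.gamma(2.0, 1.0 / 0.5)),
        sd_alpha=float(sd_alpha),
    )


def _run_chain(
    data, spec, rng, n_iter, n_burnin, thin, n_keep,
    target_accept, store_strata, max_init_retries, warn_log,
):
    y, X = data.y, data.X
    codes = data.stratum_codes
    p = X.shape[1]
    C = data.n_strata
    n_tau = 1 if spec.shared_tau_beta else p
    ysum = float(y.sum())
    yX = y @ X  # per-coefficient sufficient statistic for the y'eta term

    state = None
    for _ in range(max_init_retries):
        cand = _init_state(data, spec, rng, p, C, n_tau)
        if np.isfinite(log_posterior(cand, data, spec)):
            state = cand
            break
    if state is None:
        raise RuntimeError("could not find a finite-posterior starting point")

    eta = _eta(state, data)
    sp_sum = float(_softplus(eta).sum())

    # adaptive log step sizes
    ls_alpha, ls_sd = np.log(0.1), np.log(0.2)
    ls_beta = np.full(p, np.log(0.05))
    ls_d = np.full(C, np.log(0.5)) if C else None
    n_acc = {"alpha": 0.0, "beta": 0.0, "sd_alpha": 0.0, "d": 0.0}
    n_try = {"alpha": 0, "beta": 0, "sd_alpha": 0, "d": 0}

    kept: dict[str, np.ndarray] = {
        "alpha": np.empty(n_keep),
        "beta": np.empty((n_keep, p)),
        "tau_beta": np.empty((n_keep, n_tau)),
        "tau_d": np.empty(n_keep),
        "sd_alpha": np.empty(n_keep),
    }
    if C and store_strata:
        kept["d"] = np.empty((n_keep, C))
    loglik = np.empty(n_keep)

    a_tb, b_tb = spec.tau_beta_prior
    a_td, b_td = spec.tau_d_prior
    k = 0
    for it in range(n_iter):
        adapting = it < n_burnin
        gamma = (it + 1) ** -0.6 if adapting else 0.0

        # --- Gibbs: coefficient precisions -------------------------------
        if spec.fixed_tau_beta is None:
            if spec.shared_tau_beta:
                shape, rate = tau_beta_full_conditional(
                    state.betas, spec.tau_beta_prior
                )
                state.tau_beta = np.array([rng.gamma(shape, 1.0 / rate)])
            else:
                shape = a_tb + 0.5
                rate = b_tb + 0.5 * state.betas**2
                state.tau_beta = rng.gamma(shape, 1.0 / rate)

        # --- Gibbs: stratum precision ------------------------------------
        if C:
            shape, rate = tau_d_full_conditional(state.d, spec.tau_d_prior)
            state.tau_d = float(rng.gamma(shape, 1.0 / rate))

        # --- MH: intercept ------------------------------------------------
        da = np.exp(ls_alpha) * rng.standard_normal()
        eta_p = eta + da
        sp_p = float(_softplus(eta_p).sum())
        a_new = state.alpha + da
        tau_a = state.sd_alpha**-2
        delta = (
            ysum * da - (sp_p - sp_sum)
            - 0.5 * tau_a * (a_new**2 - state.alpha**2)
        )
        accept = np.log(rng.uniform()) < delta
        if accept:
            state.alpha, eta, sp_sum = a_new, eta_p, sp_p
        n_try["alpha"] += 1
        n_acc["alpha"] += accept
        ls_alpha += gamma * (np.exp(min(delta, 0.0)) - target_accept)

        # --- MH: coefficients --------------------------------------------
        tb = np.broadcast_to(state.tau_beta, (p,))
        acc_b = 0.0
        for j in range(p):
            db = np.exp(ls_beta[j]) * rng.standard_normal()
            eta_p = eta + db * X[:, j]
            sp_p = float(_softplus(eta_p).sum())
            b_new = state.betas[j] + db
            delta = (
                yX[j] * db - (sp_p - sp_sum)
                - 0.5 * tb[j] * (b_new**2 - state.betas[j] ** 2)
            )
            accept = np.log(rng.uniform()) < delta
            if accept:
                state.betas[j], eta, sp_sum = b_new, eta_p, sp_p
                acc_b += 1
            ls_beta[j] += gamma * (np.exp(min(delta, 0.0)) - target_accept)
        n_try["beta"] += p
        n_acc["beta"] += acc_b

        # --- MH: sd_alpha (Uniform(0, bound) prior) -----------------------
        if spec.fixed_sd_alpha is None:
            ds = np.exp(ls_sd) * rng.standard_normal()
            s_new = state.sd_alpha + ds
            if 0.0 < s_new < spec.sd_alpha_bound:
                delta = (
                    -np.log(s_new) - 0.5 * state.alpha**2 / s_new**2
                    + np.log(state.sd_alpha)
                    + 0.5 * state.alpha**2 / state.sd_alpha**2
                )
                accept = np.log(rng.uniform()) < delta
                if accept:
                    state.sd_alpha = float(s_new)
                ls_sd += gamma * (np.exp(min(delta, 0.0)) - target_accept)
                n_acc["sd_alpha"] += accept
            else:
                ls_sd += gamma * (0.0 - target_accept)
            n_try["sd_alpha"] += 1

        # --- MH: stratum effects, all strata in parallel ------------------
        if C:
            dd = np.exp(ls_d) * rng.standard_normal(C)
            d_new = state.d + dd
            eta_p = eta + dd[codes]
            cur = np.bincount(codes, weights=y * eta - _softplus(eta), minlength=C)
            prop = np.bincount(
                codes, weights=y * eta_p - _softplus(eta_p), minlength=C
            )
            delta_c = (
                prop - cur - 0.5 * state.tau_d * (d_new**2 - state.d**2)
            )
            accept_c = np.log(rng.uniform(size=C)) < delta_c
            if accept_c.any():
                state.d = np.where(accept_c, d_new, state.d)
                eta = eta + np.where(accept_c[codes], dd[codes], 0.0)
                sp_sum = float(_softplus(eta).sum())
            ls_d += gamma * (np.exp(np.minimum(delta_c, 0.0)) - target_accept)
            n_try["d"] += C
            n_acc["d"] += int(accept_c.sum())

        # --- retain -------------------------------------------------------
        if it >= n_burnin and (it - n_burnin) % thin == 0 and k < n_keep:
            kept["alpha"][k] = state.alpha
            kept["beta"][k] = state.betas
            kept["tau_beta"][k] = state.tau_beta
            kept["tau_d"][k] = state.tau_d
            kept["sd_alpha"][k] = state.sd_alpha
            if C and store_strata:
                kept["d"][k] = state.d
            loglik[k] = float(y @ eta - sp_sum)
            k += 1

    acc_rates = {
        key: (n_acc[key] / n_try[key]) if n_try[key] else np.nan for key in n_acc
    }
    return kept, loglik, acc_rates


def diagnostics(posterior: Posterior, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split R-hat and effective sample size per scalar parameter.

    Single-chain posteriors get ESS only, with a warning that R-hat needs at
    least two chains.
    """
    import arviz as az

    idata = posterior.to_arviz()
    names = list(idata.posterior.data_vars)
    ess = az.ess(idata)
    if posterior.n_chains >= 2:
        rhat = az.rhat(idata)
        rhat_vals = {n: float(rhat[n].values) for n in names}
    else:
        warnings.warn("R-hat requires >= 2 chains; omitted")
        rhat_vals = {n: np.nan for n in names}
    rows = []
    for n in names:
        r = rhat_vals[n]
        rows.append(
            {
                "parameter": n,
                "rhat": r,
                "ess": float(ess[n].values),
                "flagged": bool(np.isfinite(r) and r > rhat_threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def dic(posterior: Posterior, data: ModelData) -> DicResult:
    """Deviance information criterion: DIC = Dbar + pD.

    ``Dbar`` is the posterior mean of the deviance -2*loglik over retained
    draws; ``pD = Dbar - D(theta_bar)`` evaluates the deviance at the
    posterior mean of the parameters.
    """
    if "d" not in posterior.draws and data.n_strata:
        raise ValueError("posterior lacks stored stratum draws needed for DIC")
    dbar = float((-2.0 * posterior.loglik).mean())
    dhat = -2.0 * log_likelihood(posterior.mean_state(), data)
    p_d = dbar - dhat
    return DicResult(dic=dbar + p_d, p_d=p_d, mean_deviance=dbar)


def fit_conditional_logistic(rows: pd.DataFrame, covariates) -> pd.Series:
    """Classical conditional-logistic cross-check on the same rows.

    Groups are individual visits (1 case vs its referents) — the standard
    frequentist estimator for the case-crossover design.  Used as an
    independent oracle for the Bayesian fit, never as the implementation.
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    groups, _ = pd.factorize(rows["visit_id"])
    model = ConditionalLogit(
        rows["y"].to_numpy(), rows[list(covariates)].to_numpy(), groups=groups
    )
    res = model.fit(disp=False)
    return pd.Series(res.params, index=list(covariates))
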