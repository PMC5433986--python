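"""Candidate models for breeding trajectories and their maximum-likelihood fits.

Four nested Bernoulli-logit models are fitted to the same response vector
(every occasion from the second onward; the first occasion only seeds the
lagged covariate):

* ``Mnil``   : intercept only,
* ``MNTLH``  : intercept + lagged own state (state dependence, coefficient
  gamma on the log-odds-ratio scale),
* ``MHPDH``  : intercept + univariate individual random intercept
  (heterogeneity, SD sigma_repro),
* ``Mfull``  : both.

The fixed-effects models are ordinary logistic regressions (statsmodels).
The random-intercept models maximise the marginal likelihood

    L(mu, gamma, sigma) = prod_i int prod_t Bern(y_it | expit(mu + gamma x_it
                          + sigma u)) N(u; 0, 1) du,

each individual's integral approximated by adaptive Gauss-Hermite quadrature:
the nodes are recentred at the individual's conditional mode and rescaled by
the curvature there, which keeps 5 nodes accurate even for long trajectories.
A dense-grid integrator (`loglik_brute`) is provided as an independent check.

Model comparison uses information-criterion weights; the random intercept
counts as one extra (variance) parameter, so the models have 1-3 parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .simulate import LifeHistoryPanel

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "DesignData",
    "build_design",
    "BreedingTrajectoryModel",
    "BreedingTrajectoryResults",
    "fit_glm",
    "fit_glmm_aghq",
    "loglik_brute",
    "information_weights",
]

#: exp(log sigma) below this bound is reported as an exact zero
_LOG_SIGMA_FLOOR = -8.0


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: which of the two mechanisms it includes."""

    name: str
    has_lag: bool
    has_frailty: bool

    @property
    def n_params(self) -> int:
        """Parameter count: intercept, plus gamma and/or the frailty SD."""
        return 1 + int(self.has_lag) + int(self.has_frailty)


MODEL_SPECS: dict[str, ModelSpec] = {
    "Mnil": ModelSpec("Mnil", has_lag=False, has_frailty=False),
    "MNTLH": ModelSpec("MNTLH", has_lag=True, has_frailty=False),
    "MHPDH": ModelSpec("MHPDH", has_lag=False, has_frailty=True),
    "Mfull": ModelSpec("Mfull", has_lag=True, has_frailty=True),
}


@dataclass
class DesignData:
    """Analysis arrays shared by all four models.

    responses and lag_covariate are 0/1 vectors over all breeding occasions;
    the lag covariate is the same individual's outcome one occasion earlier
    and is 0 at recruitment, where no previous state exists.
    individual_index maps each row to a 0-based individual id.
    """

    responses: np.ndarray
    lag_covariate: np.ndarray
    individual_index: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.lag_covariate = np.asarray(self.lag_covariate, dtype=float)
        self.individual_index = np.asarray(self.individual_index, dtype=np.int64)
        if not (
            len(self.responses)
            == len(self.lag_covariate)
            == len(self.individual_index)
        ):
            raise ValueError("design vectors must have equal length")

    @property
    def n_obs(self) -> int:
        return len(self.responses)

    @property
    def n_individuals(self) -> int:
        return int(self.individual_index.max()) + 1 if self.n_obs else 0


def build_design(panel: LifeHistoryPanel) -> DesignData:
    """Extract the shared design from a panel.

    One row per breeding occasion per individual.  The lag covariate is the
    same individual's outcome at the previous occasion and is coded 0 at the
    first occasion, where no previous state exists — exactly the generating
    mechanism's convention, so for a correctly specified model the marginal
    likelihood is that of the complete trajectory.  Dropping the first
    response instead would condition the lag on an outcome that is informative
    about the individual's random effect while still integrating that effect
    over its unconditional distribution (the initial-conditions problem),
    which biases the lag coefficient upward on short trajectories.  All four
    candidate models see the identical response vector, so their information
    criteria are comparable.

    Panels containing an individual with fewer than two occasions are
    malformed and rejected.
    """
    resp, lag, idx = [], [], []
    for j, rec in enumerate(panel.records):
        if rec.lifespan < 2:
            raise ValueError(
                f"individual {rec.id} has lifespan {rec.lifespan} < 2; "
                "trajectories must span at least two occasions"
            )
        s = np.asarray(rec.successes)
        resp.append(s)
        lag.append(np.concatenate(([0], s[:-1])))
        idx.append(np.full(rec.lifespan, j, dtype=np.int64))
    return DesignData(
        np.concatenate(resp), np.concatenate(lag), np.concatenate(idx)
    )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise log Bernoulli(y | expit(eta)), stable for large |eta|."""
    # y*eta - log(1 + e^eta)
    return y * eta - np.logaddexp(0.0, eta)


class BreedingTrajectoryModel:
    """Bernoulli-logit model of a breeding record, statsmodels-style.

    Parameters
    ----------
    design : DesignData
        Shared response/lag/grouping arrays (see :func:`build_design`).
    spec : ModelSpec or str
        Which candidate model to fit.
    n_quad : int
        Adaptive Gauss-Hermite nodes for frailty models (default 5).
    """

    def __init__(self, design: DesignData, spec: ModelSpec | str, n_quad: int = 5):
        if isinstance(spec, str):
            spec = MODEL_SPECS[spec]
        if design.n_obs == 0:
            raise ValueError("empty design")
        if spec.has_frailty and design.n_individuals < 2:
            raise ValueError("frailty models need at least two individuals")
        self.design = design
        self.spec = spec
        self.n_quad = int(n_quad)
        nodes, weights = hermgauss(self.n_quad)
        self._gh_nodes = nodes
        # log(w_k) + x_k^2 so the Gaussian kernel can be folded into the
        # integrand exactly once
        self._gh_logw = np.log(weights) + nodes**2

    @classmethod
    def from_panel(
        cls, panel: LifeHistoryPanel, spec: ModelSpec | str, n_quad: int = 5
    ) -> "BreedingTrajectoryModel":
        return cls(build_design(panel), spec, n_quad=n_quad)

    # ------------------------------------------------------------------ #
    # likelihood machinery
    # ------------------------------------------------------------------ #

    def _linpred(self, mu: float, gamma: float) -> np.ndarray:
        return mu + gamma * self.design.lag_covariate

    def loglike(self, mu: float, gamma: float = 0.0, sigma: float = 0.0) -> float:
        """Marginal log-likelihood at (mu, gamma, sigma).

        sigma = 0 gives the plain fixed-effects Bernoulli log-likelihood; for
        sigma > 0 each individual's random-effect integral is evaluated by
        adaptive Gauss-Hermite quadrature.
        """
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        eta0 = self._linpred(mu, gamma)
        if sigma == 0.0:
            return float(_bernoulli_loglik(self.design.responses, eta0).sum())
        return float(self._loglike_aghq(eta0, sigma).sum())

    def _conditional_modes(
        self, eta0: np.ndarray, sigma: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-individual mode and curvature of the conditional log-density.

        Newton iterations on f(u) = sum_t log Bern(y | expit(eta0 + sigma u))
        - u^2/2, which is strictly concave in u, so convergence is global.
        Returns (mode, h) with h = -f''(mode) >= 1.
        """
        y = self.design.responses
        g = self.design.individual_index
        n_ind = self.design.n_individuals
        u = np.zeros(n_ind)
        for _ in range(50):
            p = expit(eta0 + sigma * u[g])
            score = sigma * np.bincount(g, weights=y - p, minlength=n_ind) - u
            curv = sigma**2 * np.bincount(
                g, weights=p * (1.0 - p), minlength=n_ind
            ) + 1.0
            step = score / curv
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = expit(eta0 + sigma * u[g])
        h = sigma**2 * np.bincount(g, weights=p * (1.0 - p), minlength=n_ind) + 1.0
        return u, h

    def _loglike_aghq(self, eta0: np.ndarray, sigma: float) -> np.ndarray:
        """Vector of per-individual AGHQ marginal log-likelihood contributions."""
        y = self.design.responses
        g = self.design.individual_index
        n_ind = self.design.n_individuals
        mode, h = self._conditional_modes(eta0, sigma)
        if not np.all(np.isfinite(h)):
            # fall back to non-adaptive nodes for individuals with bad curvature
            bad = ~np.isfinite(h)
            mode = np.where(bad, 0.0, mode)
            h = np.where(bad, 1.0, h)
        scale = np.sqrt(2.0 / h)
        # integrand at each shifted/scaled node, accumulated per individual
        contrib = np.empty((self.n_quad, n_ind))
        for k, (x, logw) in enumerate(zip(self._gh_nodes, self._gh_logw)):
            u_k = mode + scale * x
            eta = eta0 + sigma * u_k[g]
            ll_obs = _bernoulli_loglik(y, eta)
            log_prior = -0.5 * u_k**2 - 0.5 * np.log(2.0 * np.pi)
            contrib[k] = (
                logw + np.bincount(g, weights=ll_obs, minlength=n_ind) + log_prior
            )
        return np.log(scale) + logsumexp(contrib, axis=0)

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #

    def fit(
        self,
        start_params: Sequence[float] | None = None,
        gtol: float = 1e-8,
    ) -> "BreedingTrajectoryResults":
        """Maximise the (marginal) likelihood and return a results object."""
        if self.spec.has_frailty:
            return self._fit_glmm(start_params, gtol)
        return self._fit_glm()

    def _glm_exog(self) -> np.ndarray:
        if self.spec.has_lag:
            return np.column_stack(
                [np.ones(self.design.n_obs), self.design.lag_covariate]
            )
        return np.ones((self.design.n_obs, 1))

    def _fit_glm(self) -> "BreedingTrajectoryResults":
        y = self.design.responses
        exog = self._glm_exog()
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog).fit(disp=0, method="newton", tol=1e-10)
            params = res.params
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True)) and bool(
                np.all(np.isfinite(params))
            )
        except Exception:
            params = np.full(exog.shape[1], np.nan)
            llf = np.nan
            converged = False
        mu = float(params[0])
        gamma = float(params[1]) if self.spec.has_lag else 0.0
        return BreedingTrajectoryResults(
            model=self,
            mu_hat=mu,
            gamma_hat=gamma,
            sigma_repro_hat=0.0,
            loglik=llf,
            converged=converged,
        )

    def _fit_glmm(
        self, start_params: Sequence[float] | None, gtol: float
    ) -> "BreedingTrajectoryResults":
        # nested sigma = 0 fit provides both the starting fixed effects and
        # the boundary solution to compare against
        glm_spec = MODEL_SPECS["MNTLH" if self.spec.has_lag else "Mnil"]
        glm_fit = BreedingTrajectoryModel(self.design, glm_spec).fit()
        if not glm_fit.converged:
            return BreedingTrajectoryResults(
                model=self,
                mu_hat=np.nan,
                gamma_hat=np.nan,
                sigma_repro_hat=np.nan,
                loglik=np.nan,
                converged=False,
            )

        if start_params is not None:
            z0 = np.asarray(start_params, dtype=float)
        elif self.spec.has_lag:
            z0 = np.array([glm_fit.mu_hat, glm_fit.gamma_hat, np.log(0.5)])
        else:
            z0 = np.array([glm_fit.mu_hat, np.log(0.5)])

        def unpack(z: np.ndarray) -> tuple[float, float, float]:
            if self.spec.has_lag:
                return z[0], z[1], np.exp(z[2])
            return z[0], 0.0, np.exp(z[1])

        def negll(z: np.ndarray) -> float:
            mu, gamma, sigma = unpack(z)
            val = self.loglike(mu, gamma, sigma)
            return -val if np.isfinite(val) else 1e12

        bounds = [(-15.0, 15.0)] * (len(z0) - 1) + [(-10.0, 3.0)]
        opt = minimize(
            negll,
            z0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": gtol, "maxiter": 500},
        )
        mu, gamma, sigma = unpack(opt.x)
        loglik = -float(opt.fun)
        log_sigma = opt.x[-1]
        converged = bool(opt.success)

        # boundary comparison: the sigma = 0 MLE is the nested GLM; take it if
        # it is at least as good, which also keeps the likelihood nesting exact
        if glm_fit.loglik >= loglik or log_sigma <= _LOG_SIGMA_FLOOR:
            if glm_fit.loglik >= loglik:
                mu, gamma = glm_fit.mu_hat, glm_fit.gamma_hat
                loglik = glm_fit.loglik
            sigma = 0.0
            converged = converged or bool(glm_fit.converged)
        return BreedingTrajectoryResults(
            model=self,
            mu_hat=float(mu),
            gamma_hat=float(gamma),
            sigma_repro_hat=float(sigma),
            loglik=loglik,
            converged=converged,
        )


@dataclass
class BreedingTrajectoryResults:
    """Maximum-likelihood fit of one candidate model.

    gamma_hat is exactly 0 for models without the lag term and
    sigma_repro_hat exactly 0 for models without the random intercept — those
    parameters are excluded by definition, not estimated at zero.
    """

    model: BreedingTrajectoryModel
    mu_hat: float
    gamma_hat: float
    sigma_repro_hat: float
    loglik: float
    converged: bool

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def n_obs(self) -> int:
        return self.model.design.n_obs

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def params(self) -> dict[str, float]:
        return {
            "mu_hat": self.mu_hat,
            "gamma_hat": self.gamma_hat,
            "sigma_repro_hat": self.sigma_repro_hat,
        }

    def summary(self) -> str:
        spec = self.spec
        lines = [
            f"Breeding trajectory model: {spec.name}",
            f"  observations: {self.n_obs}   individuals: "
            f"{self.model.design.n_individuals}",
            f"  converged: {self.converged}",
            f"  log-likelihood: {self.loglik:.4f}",
            f"  BIC: {self.bic:.4f}   AIC: {self.aic:.4f}",
            f"  mu (intercept, logit):      {self.mu_hat: .4f}",
        ]
        if spec.has_lag:
            lines.append(f"  gamma (lagged state, logOR): {self.gamma_hat: .4f}")
        if spec.has_frailty:
            lines.append(
                f"  sigma_repro (frailty SD):    {self.sigma_repro_hat: .4f}"
            )
        return "\n".join(lines)


def fit_glm(
    spec: ModelSpec | str, design: DesignData
) -> BreedingTrajectoryResults:
    """Fit a fixed-effects candidate (Mnil or MNTLH) by maximum likelihood."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if spec.has_frailty:
        raise ValueError("fit_glm handles fixed-effects models only")
    return BreedingTrajectoryModel(design, spec).fit()


def fit_glmm_aghq(
    spec: ModelSpec | str, design: DesignData, n_quad: int = 5
) -> BreedingTrajectoryResults:
    """Fit a random-intercept candidate (MHPDH or Mfull) via adaptive GHQ."""
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if not spec.has_frailty:
        raise ValueError("fit_glmm_aghq handles frailty models only")
    return BreedingTrajectoryModel(design, spec, n_quad=n_quad).fit()


def loglik_brute(
    spec: ModelSpec | str,
    design: DesignData,
    mu: float,
    gamma: float = 0.0,
    sigma: float = 0.0,
    n_grid: int = 4001,
    width: float = 8.0,
) -> float:
    """Marginal log-likelihood by dense fixed-grid integration (test oracle).

    Integrates each individual's likelihood over the standard-normal random
    effect on an equally spaced grid u in [-width, width] with the
    trapezoidal rule evaluated in log space.  Slow but independent of the
    adaptive quadrature code path.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    y = design.responses
    g = design.individual_index
    eta0 = mu + gamma * design.lag_covariate
    if sigma == 0.0 or not spec.has_frailty:
        return float(_bernoulli_loglik(y, eta0).sum())
    n_ind = design.n_individuals
    u = np.linspace(-width, width, n_grid)
    du = u[1] - u[0]
    log_trap = np.full(n_grid, 0.0)
    log_trap[0] = log_trap[-1] = np.log(0.5)
    log_prior = -0.5 * u**2 - 0.5 * np.log(2.0 * np.pi)
    logint = np.empty((n_grid, n_ind))
    for j in range(n_grid):
        ll_obs = _bernoulli_loglik(y, eta0 + sigma * u[j])
        logint[j] = (
            np.bincount(g, weights=ll_obs, minlength=n_ind)
            + log_prior[j]
            + log_trap[j]
        )
    return float(np.sum(logsumexp(logint, axis=0) + np.log(du)))


def information_weights(
    fits: Sequence[BreedingTrajectoryResults], criterion: str = "BIC"
) -> np.ndarray:
    """Information-criterion weights across candidate fits of the same data.

    weight_m proportional to exp(-Delta_m / 2) with Delta the criterion
    difference to the best model.  All fits must share the response vector
    (checked through n_obs), otherwise the likelihoods are not comparable.
    """
    if criterion not in ("BIC", "AIC"):
        raise ValueError("criterion must be 'BIC' or 'AIC'")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits computed on different data (n_obs differ)")
    ic = np.array([f.bic if criterion == "BIC" else f.aic for f in fits])
    delta = ic - ic.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()
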