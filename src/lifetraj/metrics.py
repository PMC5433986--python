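"""Summaries used to compare fitted models of breeding trajectories.

All analytic quantities are evaluated for the average individual (random
effect 0), using only the fitted (mu, gamma):

* the 2x2 success/failure transition matrix of the implied Markov chain,
* its stationary distribution and scaled entropy (transition entropy in nats
  divided by log 2, the two-state maximum, so 1 means coin-flip transitions
  and 0 a deterministic chain),
* the within-individual (sampling) variance of a failure-then-success step,
  i.e. the sum of Bernoulli variances at previous-state 0 and 1,
* relative bias of estimates against truth, in percent, capped at +/-100 and
  with the denominator floored at 0.01 so "no heterogeneity" scenarios stay
  finite.

Distributional comparison of lifetime reproductive success (LRS) uses the
one-dimensional Earth Mover Distance between integer-valued histograms with
unit ground distance, which reduces to the sum of absolute cumulative-count
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .model import BreedingTrajectoryResults

__all__ = [
    "TransitionMatrix",
    "EntropySummary",
    "LRSHistogram",
    "BiasReport",
    "transition_matrix",
    "stationary_distribution",
    "scaled_entropy",
    "within_individual_variance",
    "predict_lrs",
    "lrs_histogram",
    "earth_mover_distance",
    "relative_bias",
]

#: denominator floor in relative bias, mirroring the 0.01 "no heterogeneity" SD
BIAS_DENOMINATOR_FLOOR = 0.01


@dataclass(frozen=True)
class TransitionMatrix:
    """Success/failure transition probabilities of the breeding Markov chain.

    p_star = P(success | previous failure), p = P(success | previous success);
    rows (from-failure, from-success) each sum to 1.
    """

    p_star: float
    p: float

    def __post_init__(self) -> None:
        for name, v in (("p_star", self.p_star), ("p", self.p)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def psi11(self) -> float:
        return 1.0 - self.p_star

    @property
    def psi12(self) -> float:
        return self.p_star

    @property
    def psi21(self) -> float:
        return 1.0 - self.p

    @property
    def psi22(self) -> float:
        return self.p

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.psi11, self.psi12], [self.psi21, self.psi22]], dtype=float
        )


@dataclass(frozen=True)
class EntropySummary:
    """Stationary proportions and (scaled) transition entropy of the chain."""

    pi1: float
    pi2: float
    entropy_nats: float
    scaled_entropy: float


@dataclass(frozen=True)
class LRSHistogram:
    """Counts of individuals by lifetime reproductive success 0..max."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64)
        )
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BiasReport:
    """Relative bias of a set of estimates against the true value."""

    parameter: str
    truth: float
    mean_estimate: float
    relative_bias_pct: float
    n_replicates_used: int


def transition_matrix(
    mu: float, gamma: float, alpha: float = 0.0
) -> TransitionMatrix:
    """Transition matrix implied by (mu, gamma) for an individual with effect alpha."""
    return TransitionMatrix(
        p_star=float(expit(mu + alpha)), p=float(expit(mu + alpha + gamma))
    )


def stationary_distribution(tm: TransitionMatrix) -> tuple[float, float]:
    """Stationary proportions (pi1, pi2) of failures and successes.

    pi1 = psi21 / (psi21 + psi12).  Undefined when both off-diagonal entries
    vanish (two absorbing states).
    """
    denom = tm.psi21 + tm.psi12
    if denom == 0.0:
        raise ValueError(
            "stationary distribution undefined: both states are absorbing"
        )
    pi1 = tm.psi21 / denom
    return pi1, 1.0 - pi1


def _xlogx(x: float) -> float:
    # 0 log 0 == 0 convention for entropy terms
    return 0.0 if x == 0.0 else x * np.log(x)


def scaled_entropy(tm: TransitionMatrix) -> EntropySummary:
    """Average transition entropy of the chain, scaled to [0, 1] by log 2."""
    if tm.psi12 + tm.psi21 == 0.0:
        # two absorbing states: both row entropies are 0, so the average is 0
        # for any weighting even though the stationary proportions are undefined
        return EntropySummary(pi1=0.5, pi2=0.5, entropy_nats=0.0, scaled_entropy=0.0)
    pi1, pi2 = stationary_distribution(tm)
    h_from_fail = -(_xlogx(tm.psi11) + _xlogx(tm.psi12))
    h_from_succ = -(_xlogx(tm.psi21) + _xlogx(tm.psi22))
    h = pi1 * h_from_fail + pi2 * h_from_succ
    return EntropySummary(
        pi1=pi1,
        pi2=pi2,
        entropy_nats=float(h),
        scaled_entropy=float(h / np.log(2.0)),
    )


def within_individual_variance(mu: float, gamma: float) -> float:
    """Sampling variance of a "01" breeding step for the average individual.

    Sum of the Bernoulli variances p(1-p) at previous state 1 (success
    probability expit(mu + gamma)) and previous state 0 (expit(mu)); variances
    of successive steps add along a trajectory.
    """
    v_prev1 = 1.0 / (2.0 + np.exp(mu + gamma) + np.exp(-(mu + gamma)))
    v_prev0 = 1.0 / (2.0 + np.exp(mu) + np.exp(-mu))
    return float(v_prev1 + v_prev0)


def lrs_histogram(
    lrs_values: Sequence[int] | np.ndarray, max_occasions: int
) -> LRSHistogram:
    """Histogram of LRS values on the common support 0..max_occasions."""
    counts = np.bincount(
        np.asarray(lrs_values, dtype=np.int64), minlength=max_occasions + 1
    )
    return LRSHistogram(counts)


def predict_lrs(
    fit: BreedingTrajectoryResults,
    lifespans: Sequence[int] | np.ndarray,
    rng: np.random.Generator,
    max_occasions: int | None = None,
) -> LRSHistogram:
    """Predicted LRS distribution conditional on the observed lifespans.

    For each observed individual one breeding trajectory of the same length is
    simulated under the fitted model: a fresh individual effect ~ N(0,
    sigma_hat^2) when the model has a random intercept, the lagged-state term
    gamma_hat when it has one, and no lag at the first occasion.  Averaging
    over draws is the caller's job (one draw per individual per call).
    """
    if not fit.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    lifespans = np.asarray(lifespans, dtype=np.int64)
    if np.any(lifespans < 2):
        raise ValueError("observed lifespans must be >= 2")
    if max_occasions is None:
        max_occasions = int(lifespans.max())
    n = len(lifespans)
    spec = fit.spec
    alpha = (
        rng.normal(0.0, fit.sigma_repro_hat, size=n)
        if spec.has_frailty and fit.sigma_repro_hat > 0
        else np.zeros(n)
    )
    gamma = fit.gamma_hat if spec.has_lag else 0.0
    base = fit.mu_hat + alpha
    t_max = int(lifespans.max())
    u = rng.random((n, t_max))
    state = (u[:, 0] < expit(base)).astype(np.int64)
    lrs = state.copy()
    for t in range(1, t_max):
        p = expit(base + gamma * state)
        nxt = (u[:, t] < p).astype(np.int64)
        alive = lifespans > t
        lrs += np.where(alive, nxt, 0)
        state = np.where(alive, nxt, state)
    return lrs_histogram(lrs, max_occasions)


def earth_mover_distance(h1: LRSHistogram, h2: LRSHistogram) -> float:
    """1-D Earth Mover Distance between equal-mass count histograms.

    With unit distance between adjacent integer LRS values the minimum-cost
    transport equals the sum of absolute differences of cumulative counts;
    units are individuals x LRS.
    """
    c1, c2 = h1.counts, h2.counts
    if h1.total != h2.total:
        raise ValueError("histograms must have equal totals")
    m = max(len(c1), len(c2))
    c1 = np.pad(c1, (0, m - len(c1)))
    c2 = np.pad(c2, (0, m - len(c2)))
    return float(np.abs(np.cumsum(c1 - c2)).sum())


def relative_bias(
    truth: float, estimates: Sequence[float] | np.ndarray, parameter: str = ""
) -> BiasReport:
    """Percent relative bias of the mean estimate, capped at +/-100.

    The denominator is max(|truth|, 0.01), the same floor the simulation grid
    uses for "no heterogeneity", so scenarios with a zero-valued truth report
    a finite (and typically capped) bias.
    """
    estimates = np.asarray(estimates, dtype=float)
    estimates = estimates[np.isfinite(estimates)]
    if estimates.size == 0:
        raise ValueError("no finite estimates supplied")
    mean_est = float(estimates.mean())
    denom = max(abs(truth), BIAS_DENOMINATOR_FLOOR)
    pct = 100.0 * (mean_est - truth) / denom
    pct = float(np.clip(pct, -100.0, 100.0))
    return BiasReport(
        parameter=parameter,
        truth=float(truth),
        mean_estimate=mean_est,
        relative_bias_pct=pct,
        n_replicates_used=int(estimates.size),
    )
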