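"""Simulation of individual life-history panels.

The data-generating mechanism couples two Bernoulli processes on the logit
scale.  Each individual i carries a pair of permanent random effects

    (alpha_i1, alpha_i2) ~ N2(0, Sigma),

with SDs (sigma_phi, sigma_repro) and correlation ``cor``.  Survival between
breeding occasions is Bernoulli(expit(mu_phi + alpha_i1)) with mu_phi =
logit(phi); breeding success at occasion t is Bernoulli(expit(mu + alpha_i2 +
gamma * success_{t-1})), the lagged own state entering from the second
occasion onward.  Every simulated individual has recruited and survived to a
second breeding occasion, so lifespans (numbers of breeding occasions) lie in
[2, max_occasions]; with phi = 0.75 and a cap of 42 the expected number of
occasions per individual is 1 + sum_{k=0}^{40} phi^k, about 5 — hence about
5,000 observations per 1,000 individuals.

Only the breeding record is ever analysed downstream; survival matters
through the realised lifespans and, when ``cor`` is nonzero, through the
induced covariance between lifespan and breeding propensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .scenarios import ScenarioParams

__all__ = [
    "SimulationSettings",
    "IndividualRecord",
    "LifeHistoryPanel",
    "draw_individual_effects",
    "simulate_lifespan",
    "simulate_breeding",
    "simulate_panel",
    "expected_total_occasions",
]

# survival probabilities are clipped away from 1 so the geometric draw for
# time-to-death stays well defined; expit never reaches 1 exactly but can
# round to it in float64 for |eta| > ~37
_P_MAX = 1.0 - 1e-12


@dataclass(frozen=True)
class SimulationSettings:
    """Bookkeeping for a simulated panel.

    n_individuals : number of life histories per panel (study default 1,000).
    max_occasions : cap on breeding occasions per individual (default 42).
    n_replicates  : panels per scenario in a study (default 500).
    """

    n_individuals: int = 1000
    max_occasions: int = 42
    n_replicates: int = 500

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.max_occasions < 2:
            raise ValueError("max_occasions must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class IndividualRecord:
    """One simulated life history."""

    id: int
    alpha1: float
    alpha2: float
    lifespan: int
    successes: np.ndarray  # 0/1, length == lifespan

    @property
    def lrs(self) -> int:
        """Lifetime reproductive success: total successes over the lifespan."""
        return int(self.successes.sum())


@dataclass
class LifeHistoryPanel:
    """A panel of simulated individuals plus the parameters that produced it."""

    records: list[IndividualRecord]
    params: ScenarioParams
    settings: SimulationSettings
    scenario_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if not self.scenario_id:
            self.scenario_id = self.params.scenario_id

    @property
    def n_individuals(self) -> int:
        return len(self.records)

    @property
    def lifespans(self) -> np.ndarray:
        return np.array([r.lifespan for r in self.records], dtype=np.int64)

    @property
    def lrs(self) -> np.ndarray:
        return np.array([r.lrs for r in self.records], dtype=np.int64)

    @property
    def total_occasions(self) -> int:
        return int(self.lifespans.sum())

    def long_view(self) -> pd.DataFrame:
        """Rows (individual, occasion, prev_state, response) for occasions >= 2.

        This is the analysis view: the first occasion of each individual only
        seeds the lag and contributes no response row, so the frame has
        sum_i (lifespan_i - 1) rows.
        """
        ids, occs, prev, resp, spans = [], [], [], [], []
        for r in self.records:
            s = r.successes
            ids.append(np.full(r.lifespan - 1, r.id, dtype=np.int64))
            occs.append(np.arange(2, r.lifespan + 1, dtype=np.int64))
            prev.append(s[:-1])
            resp.append(s[1:])
            spans.append(np.full(r.lifespan - 1, r.lifespan, dtype=np.int64))
        return pd.DataFrame(
            {
                "scenario_id": self.scenario_id,
                "replicate": self.replicate,
                "individual": np.concatenate(ids),
                "occasion": np.concatenate(occs),
                "prev_state": np.concatenate(prev).astype(np.int64),
                "response": np.concatenate(resp).astype(np.int64),
                "lifespan": np.concatenate(spans),
            }
        )

    def to_csv(self, path) -> None:
        """Serialize the analysis view as long-format CSV."""
        self.long_view().to_csv(path, index=False)

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        params: ScenarioParams | None = None,
        settings: SimulationSettings | None = None,
    ) -> "LifeHistoryPanel":
        """Rebuild a panel from its long view.

        The first-occasion response is recovered from the prev_state column of
        each individual's first row; random effects are not serialized and
        come back as NaN.
        """
        records = []
        for ind, g in frame.groupby("individual", sort=True):
            g = g.sort_values("occasion")
            successes = np.concatenate(
                ([g["prev_state"].iloc[0]], g["response"].to_numpy())
            ).astype(np.int8)
            records.append(
                IndividualRecord(
                    id=int(ind),
                    alpha1=float("nan"),
                    alpha2=float("nan"),
                    lifespan=len(successes),
                    successes=successes,
                )
            )
        if settings is None:
            settings = SimulationSettings(
                n_individuals=len(records),
                max_occasions=max(r.lifespan for r in records),
                n_replicates=1,
            )
        if params is None:
            params = ScenarioParams(gamma=0.0)
        scenario_id = (
            str(frame["scenario_id"].iloc[0]) if "scenario_id" in frame else ""
        )
        replicate = int(frame["replicate"].iloc[0]) if "replicate" in frame else 0
        return cls(records, params, settings, scenario_id, replicate)


def draw_individual_effects(
    params: ScenarioParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n pairs (alpha_i1, alpha_i2) from the bivariate normal of effects.

    Returns an (n, 2) array; column 0 is the survival effect, column 1 the
    breeding effect.
    """
    cov = params.covariance()
    # |cor| < 1 is enforced at construction, so cov is positive definite
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2))
    return z @ chol.T


def simulate_lifespan(
    alpha1,
    params: ScenarioParams,
    settings: SimulationSettings,
    rng: np.random.Generator,
):
    """Simulate the number of breeding occasions for one or more individuals.

    The first two occasions are guaranteed (recruitment plus forced survival
    to a second occasion); from the second occasion onward each further
    occasion requires surviving a Bernoulli(expit(mu_phi + alpha1)) trial, and
    the count is capped at ``settings.max_occasions``.  Scalar in, scalar out.
    """
    alpha1 = np.asarray(alpha1, dtype=float)
    scalar = alpha1.ndim == 0
    p_surv = np.clip(expit(params.mu_phi + np.atleast_1d(alpha1)), 0.0, _P_MAX)
    # number of consecutive survivals K before the first death is geometric:
    # rng.geometric gives trials-to-first-death T >= 1, so K = T - 1 and the
    # lifespan is 2 + K, capped
    t_death = rng.geometric(1.0 - p_surv)
    lifespan = np.minimum(1 + t_death, settings.max_occasions)
    return int(lifespan[0]) if scalar else lifespan.astype(np.int64)


def _simulate_success_matrix(
    alpha2: np.ndarray,
    lifespans: np.ndarray,
    params: ScenarioParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised breeding sequences; entries beyond the lifespan are -1."""
    n = len(alpha2)
    t_max = int(lifespans.max())
    u = rng.random((n, t_max))
    out = np.full((n, t_max), -1, dtype=np.int8)
    base = params.mu + alpha2
    state = (u[:, 0] < expit(base)).astype(np.int8)  # no lag at occasion 1
    out[:, 0] = state
    for t in range(1, t_max):
        p = expit(base + params.gamma * state)
        nxt = (u[:, t] < p).astype(np.int8)
        alive = lifespans > t
        out[alive, t] = nxt[alive]
        state = np.where(alive, nxt, state).astype(np.int8)
    return out


def simulate_breeding(
    alpha2: float,
    params: ScenarioParams,
    lifespan: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one individual's 0/1 breeding sequence of length ``lifespan``.

    The first occasion has no lagged state and uses success probability
    expit(mu + alpha2); later occasions add gamma times the previous outcome.
    """
    if lifespan < 2:
        raise ValueError("lifespan must be >= 2")
    mat = _simulate_success_matrix(
        np.array([alpha2], dtype=float),
        np.array([lifespan], dtype=np.int64),
        params,
        rng,
    )
    return mat[0, :lifespan].copy()


def simulate_panel(
    params: ScenarioParams,
    settings: SimulationSettings,
    rng: np.random.Generator,
    scenario_id: str = "",
    replicate: int = 0,
) -> LifeHistoryPanel:
    """Simulate a full panel: effects, lifespans, then breeding sequences."""
    n = settings.n_individuals
    effects = draw_individual_effects(params, n, rng)
    lifespans = simulate_lifespan(effects[:, 0], params, settings, rng)
    successes = _simulate_success_matrix(effects[:, 1], lifespans, params, rng)
    records = [
        IndividualRecord(
            id=i,
            alpha1=float(effects[i, 0]),
            alpha2=float(effects[i, 1]),
            lifespan=int(lifespans[i]),
            successes=successes[i, : lifespans[i]].copy(),
        )
        for i in range(n)
    ]
    return LifeHistoryPanel(records, params, settings, scenario_id, replicate)


def expected_total_occasions(
    phi: float, n_individuals: int, max_occasions: int
) -> float:
    """Analytic expected total breeding occasions in a homogeneous panel.

    Each individual contributes 1 + sum_{k=0}^{max-2} phi^k occasions in
    expectation (the k = 0 term is the guaranteed second occasion).
    """
    k = np.arange(0, max_occasions - 1)
    return n_individuals * (1.0 + np.sum(phi**k))
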