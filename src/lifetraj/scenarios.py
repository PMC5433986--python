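"""Scenario parameterisation and the factorial simulation grid.

A scenario is a point in the data-generating mechanism's parameter space:
state dependence ``gamma`` (a log odds ratio), the two heterogeneity SDs
``sigma_phi`` (survival) and ``sigma_repro`` (breeding) on the logit scale,
their correlation ``cor``, the breeding intercept ``mu`` and the mean
survival probability ``phi``.  The full factorial grid crosses seven odds
ratio levels, four levels of each SD and five correlations: 7 x 4 x 4 x 5 =
560 scenarios, with mu = 0 (average breeding success 0.5) and phi = 0.75
throughout.  "No heterogeneity" is encoded as SD 0.01 rather than 0 to keep
the bivariate normal non-degenerate and the relative-bias denominator finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ODDS_RATIO_LEVELS",
    "SIGMA_LEVELS",
    "COR_LEVELS",
    "ScenarioParams",
    "build_scenario_grid",
    "grid_to_frame",
]

#: State-dependence levels on the odds-ratio scale: none, small (+/-),
#: moderate (+/-), large (+/-).  gamma = log(OR).
ODDS_RATIO_LEVELS: tuple[float, ...] = (1.0, 3 / 4, 4 / 3, 3 / 5, 5 / 3, 1 / 2, 2.0)

#: Heterogeneity SD levels (logit scale); 0.01 stands in for "none".
SIGMA_LEVELS: tuple[float, ...] = (0.01, 0.33, 0.66, 1.0)

#: Correlation levels between the survival and breeding random effects.
COR_LEVELS: tuple[float, ...] = (0.0, -0.3, 0.3, -0.6, 0.6)

#: Floor used for "no heterogeneity" SDs and for relative-bias denominators.
SIGMA_FLOOR: float = 0.01


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of the joint survival/breeding data-generating mechanism.

    Attributes
    ----------
    gamma : float
        State-dependence coefficient: log odds ratio of breeding successfully
        again after a success versus after a failure.
    sigma_phi : float
        SD of the individual survival random effect (logit scale), > 0.
    sigma_repro : float
        SD of the individual breeding random effect (logit scale), > 0.
    cor : float
        Correlation of the two random effects, in (-1, 1).  Negative values
        encode a survival/breeding trade-off, positive values "quality".
    mu : float
        Breeding intercept on the logit scale (0 gives mean success 0.5).
    phi : float
        Mean survival probability between breeding occasions, in (0, 1).
    """

    gamma: float
    sigma_phi: float = SIGMA_FLOOR
    sigma_repro: float = SIGMA_FLOOR
    cor: float = 0.0
    mu: float = 0.0
    phi: float = 0.75
    scenario_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.sigma_phi > 0:
            raise ValueError(f"sigma_phi must be > 0, got {self.sigma_phi}")
        if not self.sigma_repro > 0:
            raise ValueError(f"sigma_repro must be > 0, got {self.sigma_repro}")
        if not abs(self.cor) < 1:
            raise ValueError(f"|cor| must be < 1, got {self.cor}")
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if not self.scenario_id:
            object.__setattr__(self, "scenario_id", self._default_id())

    def _default_id(self) -> str:
        return (
            f"or{math.exp(self.gamma):.3g}_sp{self.sigma_phi:g}"
            f"_sr{self.sigma_repro:g}_c{self.cor:g}"
        )

    @property
    def mu_phi(self) -> float:
        """Survival intercept logit(phi)."""
        return _logit(self.phi)

    @property
    def odds_ratio(self) -> float:
        """State dependence on the odds-ratio scale, exp(gamma)."""
        return math.exp(self.gamma)

    def covariance(self) -> np.ndarray:
        """2x2 covariance matrix of the (survival, breeding) random effects."""
        off = self.cor * self.sigma_phi * self.sigma_repro
        return np.array(
            [[self.sigma_phi**2, off], [off, self.sigma_repro**2]], dtype=float
        )

    def with_id(self, scenario_id: str) -> "ScenarioParams":
        return replace(self, scenario_id=scenario_id)


def _iter_grid() -> Iterator[ScenarioParams]:
    for odds_ratio in ODDS_RATIO_LEVELS:
        for sigma_phi in SIGMA_LEVELS:
            for sigma_repro in SIGMA_LEVELS:
                for cor in COR_LEVELS:
                    yield ScenarioParams(
                        gamma=math.log(odds_ratio),
                        sigma_phi=sigma_phi,
                        sigma_repro=sigma_repro,
                        cor=cor,
                    )


def build_scenario_grid() -> list[ScenarioParams]:
    """Return the full factorial grid of 560 scenarios.

    Order is row-major over (odds ratio, sigma_phi, sigma_repro, cor) with the
    level orders of :data:`ODDS_RATIO_LEVELS`, :data:`SIGMA_LEVELS` and
    :data:`COR_LEVELS`; scenario ids are stable across runs.
    """
    return [
        params.with_id(f"s{i:03d}_{params.scenario_id}")
        for i, params in enumerate(_iter_grid())
    ]


def grid_to_frame(grid: list[ScenarioParams]) -> pd.DataFrame:
    """Tabulate a scenario list (one row per scenario, keyed by scenario_id)."""
    return pd.DataFrame(
        {
            "scenario_id": [p.scenario_id for p in grid],
            "odds_ratio": [p.odds_ratio for p in grid],
            "gamma": [p.gamma for p in grid],
            "sigma_phi": [p.sigma_phi for p in grid],
            "sigma_repro": [p.sigma_repro for p in grid],
            "cor": [p.cor for p in grid],
            "mu": [p.mu for p in grid],
            "phi": [p.phi for p in grid],
        }
    )
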