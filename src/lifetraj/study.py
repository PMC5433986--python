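"""Factorial simulation study: simulate, fit all four models, summarise.

One *replicate* is: simulate a panel under a scenario, build the shared
design, fit Mnil / MNTLH / MHPDH / Mfull to the identical response vector,
and record per model the estimates, log-likelihood, information-criterion
weight, Earth Mover Distance between observed and predicted LRS, scaled
entropy and plug-in within-individual variance.  A *study* runs a scenario
grid x replicates and aggregates scenario-level tile tables (means, Monte
Carlo standard errors and capped relative biases over converged replicates).

Replicate r of scenario index s uses a child seed derived deterministically
from (master_seed, s, r), so any single replicate is reproducible in
isolation and results do not depend on execution order or worker count.

The full-scale design (560 scenarios x 500 replicates x 1,000 individuals)
is supported but long-running; the desk-scale default is the 8-scenario
corner grid at 100 replicates x 500 individuals, which runs in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import (
    earth_mover_distance,
    lrs_histogram,
    predict_lrs,
    relative_bias,
    scaled_entropy,
    transition_matrix,
    within_individual_variance,
)
from .model import (
    MODEL_SPECS,
    BreedingTrajectoryModel,
    build_design,
    information_weights,
)
from .scenarios import ScenarioParams, build_scenario_grid
from .simulate import SimulationSettings, simulate_panel

__all__ = [
    "MODEL_ORDER",
    "StudyConfig",
    "replicate_seed",
    "run_replicate",
    "run_study",
    "aggregate",
    "corner_grid",
    "regime_corners",
    "named_grid",
]

logger = logging.getLogger(__name__)

#: fitting order; also the row order within each replicate
MODEL_ORDER: tuple[str, ...] = ("Mnil", "MNTLH", "MHPDH", "Mfull")

_SIGMA_NONE = 0.01
_SIGMA_LARGE = 1.0


def regime_corners() -> dict[str, ScenarioParams]:
    """The four generating regimes at their corner values (cor = 0).

    Keys name the model that is the true data-generating mechanism there:
    Mnil (no mechanism), MNTLH (odds ratio 2 only), MHPDH (heterogeneity SD 1
    only), Mfull (both).
    """
    return {
        "Mnil": ScenarioParams(
            gamma=0.0, sigma_phi=_SIGMA_NONE, sigma_repro=_SIGMA_NONE
        ).with_id("regime_Mnil"),
        "MNTLH": ScenarioParams(
            gamma=log(2.0), sigma_phi=_SIGMA_NONE, sigma_repro=_SIGMA_NONE
        ).with_id("regime_MNTLH"),
        "MHPDH": ScenarioParams(
            gamma=0.0, sigma_phi=_SIGMA_LARGE, sigma_repro=_SIGMA_LARGE
        ).with_id("regime_MHPDH"),
        "Mfull": ScenarioParams(
            gamma=log(2.0), sigma_phi=_SIGMA_LARGE, sigma_repro=_SIGMA_LARGE
        ).with_id("regime_Mfull"),
    }


def corner_grid() -> list[ScenarioParams]:
    """Eight corner scenarios: OR in {1, 2} x each SD in {0.01, 1}, cor = 0."""
    grid = []
    for odds_ratio in (1.0, 2.0):
        for sigma_phi in (_SIGMA_NONE, _SIGMA_LARGE):
            for sigma_repro in (_SIGMA_NONE, _SIGMA_LARGE):
                p = ScenarioParams(
                    gamma=log(odds_ratio),
                    sigma_phi=sigma_phi,
                    sigma_repro=sigma_repro,
                )
                grid.append(p.with_id(f"corner_{p.scenario_id}"))
    return grid


def named_grid(name: str) -> list[ScenarioParams]:
    """Named scenario subsets: regimes (4), corner (8), cor0 (112), full (560)."""
    if name == "regimes":
        return list(regime_corners().values())
    if name == "corner":
        return corner_grid()
    if name == "cor0":
        return [p for p in build_scenario_grid() if p.cor == 0.0]
    if name == "full":
        return build_scenario_grid()
    raise ValueError(f"unknown grid name {name!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Everything that determines a study's output."""

    grid: tuple[ScenarioParams, ...] = field(
        default_factory=lambda: tuple(corner_grid())
    )
    settings: SimulationSettings = field(
        default_factory=lambda: SimulationSettings(
            n_individuals=500, max_occasions=42, n_replicates=100
        )
    )
    master_seed: int = 0
    criterion: str = "BIC"
    n_quad: int = 5

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.criterion not in ("BIC", "AIC"):
            raise ValueError("criterion must be 'BIC' or 'AIC'")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "StudyConfig":
        grid = cfg.get("grid", "corner")
        if isinstance(grid, str):
            grid = named_grid(grid)
        settings = SimulationSettings(
            n_individuals=int(cfg.get("n_individuals", 500)),
            max_occasions=int(cfg.get("max_occasions", 42)),
            n_replicates=int(cfg.get("n_replicates", 100)),
        )
        return cls(
            grid=tuple(grid),
            settings=settings,
            master_seed=int(cfg.get("master_seed", 0)),
            criterion=str(cfg.get("criterion", "BIC")),
            n_quad=int(cfg.get("n_quad", 5)),
        )


def replicate_seed(
    master_seed: int, scenario_index: int, replicate: int
) -> np.random.SeedSequence:
    """Deterministic child seed for one replicate of one scenario."""
    return np.random.SeedSequence((int(master_seed), int(scenario_index), int(replicate)))


def run_replicate(
    params: ScenarioParams,
    settings: SimulationSettings,
    seed,
    n_quad: int = 5,
    criterion: str = "BIC",
    replicate: int = 0,
) -> list[dict]:
    """Simulate one panel, fit all four models, compute all per-model metrics.

    Returns one dict per model (in :data:`MODEL_ORDER`).  Non-converged fits
    yield rows with converged=False and NaN metrics; information weights are
    only defined when all four fits converged.
    """
    rng = np.random.default_rng(seed)
    panel = simulate_panel(
        params, settings, rng, scenario_id=params.scenario_id, replicate=replicate
    )
    design = build_design(panel)
    observed = lrs_histogram(panel.lrs, settings.max_occasions)

    fits = [
        BreedingTrajectoryModel(design, MODEL_SPECS[name], n_quad=n_quad).fit()
        for name in MODEL_ORDER
    ]
    if all(f.converged for f in fits):
        weights = information_weights(fits, criterion)
    else:
        weights = np.full(len(fits), np.nan)

    rows = []
    for f, w in zip(fits, weights):
        if f.converged:
            pred = predict_lrs(f, panel.lifespans, rng, settings.max_occasions)
            emd = earth_mover_distance(observed, pred)
            ent = scaled_entropy(
                transition_matrix(f.mu_hat, f.gamma_hat)
            ).scaled_entropy
            wv = within_individual_variance(f.mu_hat, f.gamma_hat)
        else:
            emd = ent = wv = np.nan
        rows.append(
            {
                "scenario_id": params.scenario_id,
                "replicate": replicate,
                "model": f.spec.name,
                "mu_hat": f.mu_hat,
                "gamma_hat": f.gamma_hat,
                "sigma_repro_hat": f.sigma_repro_hat,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "n_obs": f.n_obs,
                "converged": bool(f.converged),
                "emd": emd,
                "scaled_entropy": ent,
                "within_var_hat": wv,
                "criterion": criterion,
                "criterion_value": f.bic if criterion == "BIC" else f.aic,
                "weight": float(w),
            }
        )
    return rows


def run_study(config: StudyConfig, n_jobs: int = 1) -> pd.DataFrame:
    """Run the full grid x replicates experiment.

    Replicates are independent work units with pre-assigned child seeds, so
    the output is a pure function of the config whatever the worker count.
    """
    tasks = [
        (s_idx, params, r)
        for s_idx, params in enumerate(config.grid)
        for r in range(config.settings.n_replicates)
    ]

    def one(s_idx: int, params: ScenarioParams, r: int) -> list[dict]:
        return run_replicate(
            params,
            config.settings,
            replicate_seed(config.master_seed, s_idx, r),
            n_quad=config.n_quad,
            criterion=config.criterion,
            replicate=r,
        )

    if n_jobs == 1:
        chunks = []
        for i, (s_idx, params, r) in enumerate(tasks):
            chunks.append(one(s_idx, params, r))
            if (i + 1) % 50 == 0:
                logger.info("completed %d/%d replicates", i + 1, len(tasks))
    else:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(
            delayed(one)(s_idx, params, r) for s_idx, params, r in tasks
        )

    rows = pd.DataFrame([row for chunk in chunks for row in chunk])
    n_dropped = int((~rows["converged"]).sum())
    if n_dropped:
        logger.warning(
            "%d of %d model fits did not converge and will be excluded from "
            "scenario means",
            n_dropped,
            len(rows),
        )
    return rows


def _mc_se(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def aggregate(
    rows: pd.DataFrame, grid: Sequence[ScenarioParams]
) -> pd.DataFrame:
    """Scenario x model tile table: means, Monte Carlo SEs and capped biases.

    Means are over converged replicates only; each cell carries the replicate
    count actually used.  Biases are percent relative to the scenario's true
    (gamma, sigma_repro, within-individual variance), floored/capped as in
    :func:`lifetraj.metrics.relative_bias`; cells with no converged replicate
    are flagged via n_used = 0 and NaN means.
    """
    if rows.empty:
        raise ValueError("no rows to aggregate")
    by_id = {p.scenario_id: p for p in grid}
    out = []
    for (scenario_id, model), sub in rows.groupby(
        ["scenario_id", "model"], sort=False
    ):
        params = by_id[scenario_id]
        conv = sub[sub["converged"]]
        n_used = len(conv)
        cell: dict = {
            "scenario_id": scenario_id,
            "model": model,
            "odds_ratio": params.odds_ratio,
            "gamma_true": params.gamma,
            "sigma_repro_true": params.sigma_repro,
            "sigma_phi_true": params.sigma_phi,
            "cor_true": params.cor,
            "n_replicates": len(sub),
            "n_used": n_used,
        }
        wv_true = within_individual_variance(params.mu, params.gamma)
        cell["within_var_true"] = wv_true
        if n_used == 0:
            for c in (
                "emd_mean", "emd_se", "scaled_entropy_mean", "scaled_entropy_se",
                "weight_mean", "weight_se", "gamma_hat_mean", "gamma_hat_se",
                "sigma_repro_hat_mean", "sigma_repro_hat_se",
                "within_var_mean", "within_var_se",
                "gamma_bias_pct", "sigma_repro_bias_pct", "within_var_bias_pct",
            ):
                cell[c] = np.nan
        else:
            for col, stem in (
                ("emd", "emd"),
                ("scaled_entropy", "scaled_entropy"),
                ("weight", "weight"),
                ("gamma_hat", "gamma_hat"),
                ("sigma_repro_hat", "sigma_repro_hat"),
                ("within_var_hat", "within_var"),
            ):
                x = conv[col].to_numpy(dtype=float)
                finite = x[np.isfinite(x)]
                cell[f"{stem}_mean"] = (
                    float(finite.mean()) if finite.size else np.nan
                )
                cell[f"{stem}_se"] = _mc_se(x)
            cell["gamma_bias_pct"] = relative_bias(
                params.gamma, conv["gamma_hat"], "gamma"
            ).relative_bias_pct
            cell["sigma_repro_bias_pct"] = relative_bias(
                params.sigma_repro, conv["sigma_repro_hat"], "sigma_repro"
            ).relative_bias_pct
            cell["within_var_bias_pct"] = relative_bias(
                wv_true, conv["within_var_hat"], "within_var"
            ).relative_bias_pct
        out.append(cell)
    return pd.DataFrame(out)
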