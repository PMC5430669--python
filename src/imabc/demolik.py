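"""Rejection-sampling approximate likelihood over a demographic parameter grid.

The likelihood of a parameter combination is approximated by ln(a / n)
where a of n multi-locus coalescent simulations produce the four
Wakeley–Hey across-locus sums within ±epsilon % of the observed ones.
When no simulation is accepted only the upper bound ln(1/n) can be
reported.  Profile-likelihood confidence intervals use the 1.92 lnL-unit
(chi-square, 1 df, 95%) drop rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .coalsim import (
    ISOLATION,
    MODELS,
    ONGOING_MIGRATION,
    SECONDARY_CONTACT,
    LocusSpec,
    ModelParams,
    _migration_window,
    coalescent_scaling,
)
from .seqio import MutationRate
from .sumstats import WHStats

__all__ = [
    "RejectionConfig",
    "GridSpec",
    "LikelihoodSurface",
    "accept",
    "zero_acceptance_bound",
    "approx_lnL",
    "grid_search",
    "profile_ci",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def _paper_theta_axis() -> tuple[float, ...]:
    fine = [round(0.001 * i, 3) for i in range(1, 11)]  # 0.001 .. 0.010
    coarse = [round(0.01 * i, 2) for i in range(1, 11)]  # 0.01 .. 0.10
    return tuple(sorted(set(fine) | set(coarse)))


def _paper_m_axis() -> tuple[float, ...]:
    fine = [round(0.1 * i, 1) for i in range(0, 11)]  # 0.0 .. 1.0
    coarse = [float(i) for i in range(1, 11)]  # 1 .. 10
    return tuple(sorted(set(fine) | set(coarse)))


@dataclass(frozen=True)
class RejectionConfig:
    """Tolerance and effort of the rejection sampler.

    Defaults follow the study settings: epsilon = 25%, 40,000 simulations
    per grid point.  ``per_component`` acceptance requires each of the four
    across-locus sums to match within the tolerance; ``total_sum`` tests
    only the grand total.
    """

    epsilon_pct: float = 25.0
    n_sims: int = 40_000
    acceptance_mode: Literal["per_component", "total_sum"] = "per_component"
    rng_seed: int = 0
    migration_convention: Literal["wright", "scaled"] = "wright"

    def __post_init__(self) -> None:
        if self.epsilon_pct <= 0:
            raise ValueError("epsilon_pct must be positive")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")


@dataclass(frozen=True)
class GridSpec:
    """Axes of the likelihood grid; defaults are the study's grid."""

    T_gen: tuple[float, ...] = tuple(1e6 * i for i in range(21))
    theta: tuple[float, ...] = field(default_factory=_paper_theta_axis)
    m: tuple[float, ...] = field(default_factory=_paper_m_axis)
    tau: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))

    def points(self, model: str) -> list[ModelParams]:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        if not (self.T_gen and self.theta):
            raise ValueError("empty grid")
        points = []
        if model == ISOLATION:
            for T in self.T_gen:
                for th in self.theta:
                    points.append(ModelParams(model, th, T))
        elif model == ONGOING_MIGRATION:
            if not self.m:
                raise ValueError("empty m axis")
            for T in self.T_gen:
                for th in self.theta:
                    for m in self.m:
                        points.append(ModelParams(model, th, T, m=m))
        else:
            if not (self.m and self.tau):
                raise ValueError("empty m or tau axis")
            for T in self.T_gen:
                for th in self.theta:
                    for m in self.m:
                        for tau in self.tau:
                            points.append(ModelParams(model, th, T, m=m, tau=tau))
        return points


@dataclass
class LikelihoodSurface:
    """Grid of (parameters, acceptances, simulations, approximate lnL).

    Backed by a tidy DataFrame with columns model, theta, T_gen, m, tau,
    n_accepted, n_sims, lnL, is_bound; rows where n_accepted = 0 carry the
    ln(1/n) upper bound and is_bound = True.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["lnL"] > 0).any():
            raise ValueError("lnL must be non-positive")

    @property
    def max_lnL(self) -> float:
        return float(self.table["lnL"].max())

    @property
    def max_is_bound(self) -> bool:
        return bool(self.table.loc[self.table["lnL"].idxmax(), "is_bound"])

    def mle(self) -> ModelParams:
        """Argmax row; ties resolved by first-in-grid order."""
        row = self.table.loc[self.table["lnL"].idxmax()]
        return ModelParams(
            row["model"],
            float(row["theta"]),
            float(row["T_gen"]),
            m=float(row["m"]),
            tau=float(row["tau"]),
        )

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "LikelihoodSurface":
        return cls(pd.read_csv(path, sep="\t"))


def accept(sim_stats: WHStats, obs_stats: WHStats, cfg: RejectionConfig) -> bool:
    """Tolerance test for one simulated dataset against the observation."""
    eps = cfg.epsilon_pct / 100.0
    sim = sim_stats.as_array()
    obs = obs_stats.as_array()
    if cfg.acceptance_mode == "per_component":
        return bool(np.all(np.abs(sim - obs) <= eps * obs))
    return bool(abs(sim.sum() - obs.sum()) <= eps * obs.sum())


def zero_acceptance_bound(n_sims: int) -> float:
    """Upper bound ln(1/n) for the lnL when no simulation is accepted."""
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    return float(np.log(1.0 / n_sims))


def _point_seeds(params: ModelParams, cfg: RejectionConfig) -> np.ndarray:
    """Per-replicate child seeds, keyed by the parameter values themselves.

    Keying on values (not grid position) gives shared simulation streams
    wherever two model grids contain the same parameter combination, which
    makes the nested-model lnL ordering exact at shared points.
    """
    entropy = (
        int(cfg.rng_seed),
        int(round(params.theta * 1e9)),
        int(round(params.T_gen)),
        int(round(params.m * 1000)),
        int(round(params.tau * 1000)),
    )
    ss = np.random.SeedSequence(entropy)
    return (ss.generate_state(cfg.n_sims, dtype=np.uint32) % _SEED_MOD).astype(
        np.int64
    )


def approx_lnL(
    obs: WHStats,
    params: ModelParams,
    specs: Sequence[LocusSpec],
    mu: MutationRate,
    cfg: RejectionConfig,
    warn_zero_obs: bool = True,
) -> tuple[int, float, bool]:
    """(n_accepted, lnL, is_bound) at one parameter combination."""
    if (
        warn_zero_obs
        and cfg.acceptance_mode == "per_component"
        and (obs.as_array() == 0).any()
    ):
        logger.warning(
            "observed component is zero; acceptance degenerates to requiring "
            "the simulated component to be zero"
        )
    _, t_coal, m_coal = coalescent_scaling(params, mu, cfg.migration_convention)
    _, tau = _migration_window(params)
    nw = np.array([s.n_west for s in specs], dtype=np.int64)
    ne = np.array([s.n_east for s in specs], dtype=np.int64)
    th = np.array([s.theta_locus(params.theta) for s in specs], dtype=np.float64)
    seeds = _point_seeds(params, cfg)
    n_accepted = int(
        _kernels.rejection_count(
            nw,
            ne,
            th,
            t_coal,
            m_coal,
            tau,
            obs.as_array(),
            cfg.epsilon_pct / 100.0,
            cfg.acceptance_mode == "per_component",
            seeds,
        )
    )
    if n_accepted == 0:
        return 0, zero_acceptance_bound(cfg.n_sims), True
    return n_accepted, float(np.log(n_accepted / cfg.n_sims)), False


def grid_search(
    obs: WHStats,
    model: str,
    grid: GridSpec,
    specs: Sequence[LocusSpec],
    mu: MutationRate,
    cfg: RejectionConfig,
) -> LikelihoodSurface:
    """Approximate-likelihood surface over all grid points of one model."""
    points = grid.points(model)
    if cfg.acceptance_mode == "per_component" and (obs.as_array() == 0).any():
        logger.warning(
            "observed component is zero; acceptance degenerates to requiring "
            "the simulated component to be zero at every grid point"
        )
    rows = []
    for params in points:
        n_accepted, lnL, is_bound = approx_lnL(
            obs, params, specs, mu, cfg, warn_zero_obs=False
        )
        rows.append(
            {
                "model": params.model,
                "theta": params.theta,
                "T_gen": params.T_gen,
                "m": params.m,
                "tau": params.tau,
                "n_accepted": n_accepted,
                "n_sims": cfg.n_sims,
                "lnL": lnL,
                "is_bound": is_bound,
            }
        )
    return LikelihoodSurface(pd.DataFrame(rows))


def profile_ci(
    surface: LikelihoodSurface, axis: str, drop: float = 1.92
) -> tuple[float, float, bool, bool]:
    """Profile-likelihood confidence interval along one parameter axis.

    Profiles the surface (max lnL over the other axes at each value of
    ``axis``), then takes the outermost axis values whose profile lies
    within ``drop`` lnL units of the maximum.  Returns (low, high,
    censored_low, censored_high); a censored flag marks an interval end
    that reaches the grid boundary, where the true CI may extend beyond
    the values tested.
    """
    if axis not in ("theta", "T_gen", "m", "tau"):
        raise ValueError(f"unknown axis {axis!r}")
    table = surface.table
    if table.empty:
        raise ValueError("empty surface")
    profile = table.groupby(axis)["lnL"].max().sort_index()
    cutoff = profile.max() - drop
    inside = profile[profile >= cutoff]
    low, high = float(inside.index.min()), float(inside.index.max())
    censored_low = low == float(profile.index.min())
    censored_high = high == float(profile.index.max())
    return low, high, censored_low, censored_high
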