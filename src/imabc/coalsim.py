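"""Structured-coalescent simulation of two-population demographic models.

Three nested histories for a pair of populations that split T generations
ago are supported: strict isolation, ongoing symmetric migration, and
secondary contact where migration operates only during the most recent
fraction tau of the time since the split.  Genealogies are simulated
backwards in time under the structured coalescent and polymorphism is added
under the infinite-sites model.

Scaling conventions (used consistently by generation and inference):
N_e = theta / (4 mu); split depth T_coal = T_gen / (4 N_e); within-deme
pairs coalesce at rate 1 per coalescent time unit; lineages migrate at rate
M_coal / 2 each; mutations fall at rate theta_locus / 2 per unit branch
length with theta_locus = theta * scalar * length.  The migration parameter
m is read as Wright's Nm (migrant individuals per generation), giving
M_coal = 4 m; ``migration_convention="scaled"`` instead uses M_coal = m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from . import _kernels
from .seqio import MutationRate

__all__ = [
    "ISOLATION",
    "ONGOING_MIGRATION",
    "SECONDARY_CONTACT",
    "MODELS",
    "ModelParams",
    "LocusSpec",
    "Genealogy",
    "SimLocus",
    "coalescent_scaling",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_locus",
    "simulate_wh_dataset",
    "to_ms_text",
]

ISOLATION = "isolation"
ONGOING_MIGRATION = "ongoing_migration"
SECONDARY_CONTACT = "secondary_contact"
MODELS = (ISOLATION, ONGOING_MIGRATION, SECONDARY_CONTACT)


@dataclass(frozen=True)
class ModelParams:
    """One demographic hypothesis.

    theta is the per-site polymorphism parameter 4*N_e*mu (constant in the
    ancestral and both descendant populations), T_gen the split time in
    generations, m the symmetric migration rate in migrant individuals per
    generation, and tau the fraction of T (measured back from the present)
    during which migration occurs.
    """

    model: str
    theta: float
    T_gen: float
    m: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.T_gen < 0:
            raise ValueError("T_gen must be non-negative")
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.model == ISOLATION and self.m != 0:
            raise ValueError("isolation model requires m = 0")
        if self.model == ONGOING_MIGRATION and self.tau != 1.0:
            raise ValueError("ongoing migration model requires tau = 1")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")


@dataclass(frozen=True)
class LocusSpec:
    """Sampling design and relative mutation rate for one locus."""

    locus_name: str
    length: int  # number of (synonymous) sites the mutation rate applies to
    scalar: float = 1.0
    n_west: int = 2
    n_east: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.scalar <= 0:
            raise ValueError("scalar must be positive")
        if self.n_west + self.n_east < 2:
            raise ValueError("need at least 2 sampled alleles")

    def theta_locus(self, theta: float) -> float:
        return theta * self.scalar * self.length


@dataclass
class Genealogy:
    """Ultrametric genealogy in coalescent time units.

    Leaves 0..n_west-1 are west alleles, the next n_east east; internal
    nodes are numbered in coalescence order so parents have larger ids than
    children.  ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    n_west: int
    n_east: int

    @property
    def n_leaves(self) -> int:
        return self.n_west + self.n_east

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros_like(self.node_time)
        has_parent = self.parent >= 0
        bl[has_parent] = self.node_time[self.parent[has_parent]] - self.node_time[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self, node: int) -> np.ndarray:
        """Sorted leaf ids below (or equal to) ``node``."""
        n_nodes = len(self.parent)
        below = np.zeros(n_nodes, dtype=bool)
        below[node] = True
        for v in range(n_nodes - 2, -1, -1):
            if below[self.parent[v]]:
                below[v] = True
        below[node] = True
        return np.flatnonzero(below[: self.n_leaves])


@dataclass
class SimLocus:
    """Infinite-sites polymorphism for one simulated locus.

    Each segregating site is (position in [0,1), boolean derived-carrier
    vector over the n_west + n_east sampled alleles).  Derived state is
    defined relative to the simulated root, which under infinite sites is
    also the outgroup state.
    """

    locus_name: str
    n_west: int
    n_east: int
    positions: np.ndarray
    carriers: np.ndarray  # shape (S, n_leaves), bool

    @property
    def num_sites(self) -> int:
        return len(self.positions)

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        w = self.carriers[:, : self.n_west].sum(axis=1)
        e = self.carriers[:, self.n_west :].sum(axis=1)
        return w, e


def _migration_window(params: ModelParams) -> tuple[float, float]:
    """(M_coal per 4m convention handled by caller, tau fraction)."""
    if params.model == ISOLATION:
        return 0.0, 1.0
    if params.model == ONGOING_MIGRATION:
        return params.m, 1.0
    return params.m, params.tau


def coalescent_scaling(
    params: ModelParams,
    mu: MutationRate,
    migration_convention: Literal["wright", "scaled"] = "wright",
) -> tuple[float, float, float]:
    """(N_e, T_coal, M_coal) for a parameter combination.

    N_e = theta/(4 mu); T_coal = T_gen/(4 N_e); M_coal = 4 m under the
    default Wright's-Nm reading of m, or m directly under the "scaled"
    convention.  The degenerate theta = 0 maps to (0, 0, M): no mutations
    can arise, so the genealogy's time scale is immaterial.
    """
    if params.theta == 0.0:
        m_eff, _ = _migration_window(params)
        m_coal = 4.0 * m_eff if migration_convention == "wright" else m_eff
        return 0.0, 0.0, m_coal
    n_e = params.theta / (4.0 * mu.mu)
    t_coal = params.T_gen / (4.0 * n_e)
    m_eff, _ = _migration_window(params)
    m_coal = 4.0 * m_eff if migration_convention == "wright" else m_eff
    return n_e, t_coal, m_coal


def _scaled_rates(
    params: ModelParams, mu: MutationRate, migration_convention: str
) -> tuple[float, float, float]:
    _, t_coal, m_coal = coalescent_scaling(params, mu, migration_convention)
    _, tau = _migration_window(params)
    return t_coal, m_coal, tau


def simulate_genealogy(
    params: ModelParams,
    spec: LocusSpec,
    mu: MutationRate,
    rng_seed: int,
    migration_convention: Literal["wright", "scaled"] = "wright",
) -> Genealogy:
    """One structured-coalescent genealogy for a locus."""
    if rng_seed < 0:
        raise ValueError("rng_seed must be non-negative")
    t_coal, m_coal, tau = _scaled_rates(params, mu, migration_convention)
    _kernels.set_seed(rng_seed)
    parent, node_time = _kernels.sim_genealogy(
        spec.n_west, spec.n_east, t_coal, m_coal, tau * t_coal
    )
    return Genealogy(parent, node_time, spec.n_west, spec.n_east)


def drop_mutations(
    genealogy: Genealogy,
    spec: LocusSpec,
    params: ModelParams,
    rng_seed: int,
) -> SimLocus:
    """Infinite-sites mutations at rate theta_locus/2 per branch-length unit."""
    _kernels.set_seed(rng_seed)
    return _mutate(genealogy, spec, params)


def _mutate(genealogy: Genealogy, spec: LocusSpec, params: ModelParams) -> SimLocus:
    branch_nodes, positions = _kernels.drop_mutations(
        genealogy.parent, genealogy.node_time, spec.theta_locus(params.theta) / 2.0
    )
    n = genealogy.n_leaves
    carriers = np.zeros((len(branch_nodes), n), dtype=bool)
    for i, v in enumerate(branch_nodes):
        carriers[i, genealogy.leaves_below(int(v))] = True
    return SimLocus(
        locus_name=spec.locus_name,
        n_west=spec.n_west,
        n_east=spec.n_east,
        positions=positions,
        carriers=carriers,
    )


def simulate_locus(
    params: ModelParams,
    spec: LocusSpec,
    mu: MutationRate,
    rng_seed: int,
    migration_convention: Literal["wright", "scaled"] = "wright",
) -> tuple[Genealogy, SimLocus]:
    """Genealogy plus mutations from a single seeded stream.

    This is the per-locus unit replayed by the fused multi-locus kernel, so
    a dataset simulated locus-by-locus with the per-locus seeds matches the
    fused path exactly.
    """
    t_coal, m_coal, tau = _scaled_rates(params, mu, migration_convention)
    _kernels.set_seed(rng_seed)
    parent, node_time = _kernels.sim_genealogy(
        spec.n_west, spec.n_east, t_coal, m_coal, tau * t_coal
    )
    genealogy = Genealogy(parent, node_time, spec.n_west, spec.n_east)
    return genealogy, _mutate(genealogy, spec, params)


def simulate_wh_dataset(
    params: ModelParams,
    specs: Sequence[LocusSpec],
    mu: MutationRate,
    rng_seed: int,
    migration_convention: Literal["wright", "scaled"] = "wright",
) -> np.ndarray:
    """Across-locus (private W, private E, shared, fixed) sums, fused path."""
    t_coal, m_coal, tau = _scaled_rates(params, mu, migration_convention)
    nw = np.array([s.n_west for s in specs], dtype=np.int64)
    ne = np.array([s.n_east for s in specs], dtype=np.int64)
    th = np.array([s.theta_locus(params.theta) for s in specs], dtype=np.float64)
    _kernels.set_seed(rng_seed)
    return np.asarray(_kernels.wh_dataset(nw, ne, th, t_coal, m_coal, tau))


def to_ms_text(loci: Iterable[SimLocus]) -> str:
    """ms-style text block (``//``, segsites, positions, 0/1 rows)."""
    lines = []
    for locus in loci:
        order = np.argsort(locus.positions)
        lines.append("//")
        lines.append(f"segsites: {locus.num_sites}")
        if locus.num_sites:
            pos = " ".join(f"{p:.5f}" for p in locus.positions[order])
            lines.append(f"positions: {pos}")
            hap = locus.carriers[order].T.astype(int)
            for row in hap:
                lines.append("".join(str(b) for b in row))
        lines.append("")
    return "\n".join(lines)
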