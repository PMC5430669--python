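"""Study-like synthetic datasets with known truth.

Emulates the multi-locus phased-exon design: 13 nuclear exon loci of
333-770 bp, two diverged populations (west/east) of phased diploids, an
outgroup sequence per locus diverged 65 My, per-locus mutation-rate
scalars, and polymorphism generated by the structured-coalescent simulator
under a chosen demographic model.

Derived alleles are embedded only at third positions of codons chosen to
be 4-fold degenerate (and with no other synonymous position), so the
synonymous-site filter recovers exactly the simulated polymorphism: the
number of potentially synonymous sites per locus is length/3 by
construction, and every simulated mutation is a synonymous variable site.
The outgroup carries Poisson divergence at synonymous positions disjoint
from the polymorphic ones, so polarization is unambiguous (no
back-mutation, matching the infinite-sites assumption).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .coalsim import (
    ISOLATION,
    ONGOING_MIGRATION,
    LocusSpec,
    ModelParams,
    simulate_locus,
)
from .seqio import LocusAlignment, MutationRate, write_locus_fasta
from .sumstats import WHStats, wh_from_sim

__all__ = ["StudyDesign", "SyntheticDataset", "generate_dataset", "generate_null_pair"]

# Codons whose third position is 4-fold degenerate and whose first and
# second positions admit no synonymous change: each contributes exactly one
# synonymous site.
_BACKBONE_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC", "CG", "CT")
_BASES = ("A", "C", "G", "T")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class StudyDesign:
    """Shape and truth of a synthetic study.

    Defaults emulate the study: 13 exon loci of 333-770 bp, 22 phased west
    alleles (11 diploids) and 26 east alleles (13 diploids) per locus,
    lognormal rate scalars normalised to mean 1, mu calibrated from a
    65-My outgroup split with a 1-year generation time.
    """

    params: ModelParams = field(
        default_factory=lambda: ModelParams(
            ONGOING_MIGRATION, theta=0.002, T_gen=8.5e6, m=0.7
        )
    )
    n_loci: int = 13
    length_range: tuple[int, int] = (333, 770)
    n_west: int = 22
    n_east: int = 26
    scalar_sigma: float = 0.3  # lognormal sd of per-locus rate scalars
    mu: MutationRate = field(default_factory=lambda: MutationRate(2.69e-9))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if self.n_west < 2 or self.n_east < 2:
            raise ValueError("need at least 2 alleles per population")
        if self.n_west % 2 or self.n_east % 2:
            raise ValueError("allele counts must be even (phased diploids)")
        lo, hi = self.length_range
        if not (3 <= lo <= hi):
            raise ValueError("invalid length range")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus its generating truth."""

    alignments: list[LocusAlignment]
    sample_table: list[tuple[str, str, str, int]]  # sample_id, species, pop, year
    truth: dict

    def truth_wh(self) -> WHStats:
        t = self.truth["wh_total"]
        return WHStats(t[0], t[1], t[2], t[3])

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        loci_dir = out_dir / "loci"
        loci_dir.mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_locus_fasta(aln, loci_dir / f"{aln.locus_name}.fasta")
        lines = ["sample_id\tspecies\tpopulation\tyear"]
        lines += [
            f"{sid}\t{species}\t{pop}\t{year}"
            for sid, species, pop, year in self.sample_table
        ]
        (out_dir / "population_map.tsv").write_text("\n".join(lines) + "\n")
        (out_dir / "truth.json").write_text(json.dumps(self.truth, indent=1) + "\n")
        return out_dir


def _locus_lengths(rng: np.random.Generator, design: StudyDesign) -> list[int]:
    """Codon-multiple lengths uniform over the design range."""
    lo, hi = design.length_range
    lo3 = -(-lo // 3)  # first codon count with 3*lo3 >= lo
    hi3 = hi // 3
    return [3 * int(rng.integers(lo3, hi3 + 1)) for _ in range(design.n_loci)]


def _scalars(rng: np.random.Generator, design: StudyDesign) -> np.ndarray:
    raw = rng.lognormal(mean=0.0, sigma=design.scalar_sigma, size=design.n_loci)
    return raw / raw.mean()


def _backbone(rng: np.random.Generator, n_codons: int) -> str:
    prefixes = rng.integers(0, len(_BACKBONE_PREFIXES), size=n_codons)
    thirds = rng.integers(0, 4, size=n_codons)
    return "".join(
        _BACKBONE_PREFIXES[p] + _BASES[t] for p, t in zip(prefixes, thirds)
    )


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def generate_dataset(design: StudyDesign) -> SyntheticDataset:
    """Simulate one study-like dataset with full truth bookkeeping.

    Per locus, polymorphism is simulated under ``design.params`` with the
    locus's rate scalar and synonymous-site count (length/3), then embedded
    at randomly chosen synonymous third positions of a random codon
    backbone; the outgroup sequence adds Poisson divergence
    d = 2 mu scalar T_outgroup at further synonymous positions.  A locus
    whose simulated segregating sites exceed its synonymous positions is
    re-simulated with a warning (counted in the truth record).
    """
    rng = np.random.default_rng(design.master_seed)
    lengths = _locus_lengths(rng, design)
    scalars = _scalars(rng, design)
    t_outgroup_gen = (
        design.mu.divergence_time_years / design.mu.generation_time_years
    )

    alignments: list[LocusAlignment] = []
    per_locus_truth = []
    wh_total = WHStats()
    n_regenerated = 0

    sample_ids_w = [f"XW{i + 1:02d}" for i in range(design.n_west // 2)]
    sample_ids_e = [f"XE{i + 1:02d}" for i in range(design.n_east // 2)]

    for l in range(design.n_loci):
        length = lengths[l]
        n_codons = length // 3
        n_syn = n_codons
        spec = LocusSpec(
            locus_name=f"locus_{l + 1:02d}",
            length=n_syn,
            scalar=float(scalars[l]),
            n_west=design.n_west,
            n_east=design.n_east,
        )
        # re-simulate on the (rare) event of more mutations than syn sites
        for attempt in range(500):
            locus_seed = int(rng.integers(0, _SEED_MOD))
            _, sim = simulate_locus(design.params, spec, design.mu, locus_seed)
            if sim.num_sites <= n_syn:
                break
            n_regenerated += 1
            warnings.warn(
                f"{spec.locus_name}: {sim.num_sites} segregating sites exceed "
                f"{n_syn} synonymous positions; re-simulating",
                stacklevel=2,
            )
        else:
            raise RuntimeError(
                f"{spec.locus_name}: design infeasible; segregating sites "
                f"exceeded the {n_syn} synonymous positions in 500 attempts"
            )

        ancestral = _backbone(rng, n_codons)
        syn_positions = np.arange(2, length, 3)
        mut_pos = rng.choice(syn_positions, size=sim.num_sites, replace=False)
        derived_bases = [_other_base(rng, ancestral[p]) for p in mut_pos]

        seqs = [list(ancestral) for _ in range(design.n_west + design.n_east)]
        for site, (pos, base) in enumerate(zip(mut_pos, derived_bases)):
            for leaf in np.flatnonzero(sim.carriers[site]):
                seqs[leaf][pos] = base

        free = np.setdiff1d(syn_positions, mut_pos)
        d_locus = 2.0 * design.mu.mu * scalars[l] * t_outgroup_gen
        n_div = min(int(rng.poisson(d_locus * n_syn)), len(free))
        div_pos = rng.choice(free, size=n_div, replace=False)
        outgroup = list(ancestral)
        for pos in div_pos:
            outgroup[pos] = _other_base(rng, ancestral[pos])

        alleles = []
        populations = {}
        for i, sid in enumerate(sample_ids_w + sample_ids_e):
            for a in (1, 2):
                leaf = 2 * i + (a - 1)
                alleles.append((f"{sid}_a{a}", sid, "".join(seqs[leaf])))
            populations[sid] = "west" if sid.startswith("XW") else "east"
        aln = LocusAlignment(
            locus_name=spec.locus_name,
            alleles=alleles,
            populations=populations,
            outgroup_seq="".join(outgroup),
            frame_offset=0,
        )
        alignments.append(aln)

        wh = wh_from_sim(sim)
        wh_total = wh_total + wh
        w_counts, e_counts = sim.derived_counts()
        per_locus_truth.append(
            {
                "locus_name": spec.locus_name,
                "length": length,
                "n_syn_sites": n_syn,
                "scalar": float(scalars[l]),
                "seed": locus_seed,
                "wh": list(wh.as_array().tolist()),
                "segregating_sites": int(sim.num_sites),
                "site_positions": [int(p) for p in mut_pos],
                "site_derived_counts_west": [int(c) for c in w_counts],
                "site_derived_counts_east": [int(c) for c in e_counts],
                "outgroup_divergent_sites": int(n_div),
            }
        )

    sample_table = [
        (sid, "synthetic_frog", "west", 2013) for sid in sample_ids_w
    ] + [(sid, "synthetic_frog", "east", 2013) for sid in sample_ids_e]

    truth = {
        "model": design.params.model,
        "theta": design.params.theta,
        "T_gen": design.params.T_gen,
        "m": design.params.m,
        "tau": design.params.tau,
        "mu": design.mu.mu,
        "divergence_time_years": design.mu.divergence_time_years,
        "generation_time_years": design.mu.generation_time_years,
        "master_seed": design.master_seed,
        "n_regenerated": n_regenerated,
        "wh_total": list(wh_total.as_array().tolist()),
        "loci": per_locus_truth,
    }
    return SyntheticDataset(alignments, sample_table, truth)


def generate_null_pair(design: StudyDesign) -> SyntheticDataset:
    """Two 'populations' sampled from one panmictic deme (T_gen = 0).

    The west/east labels are then arbitrary, which makes the dataset a null
    for F_ST and its permutation test.
    """
    null_params = ModelParams(ISOLATION, theta=design.params.theta, T_gen=0.0)
    null_design = StudyDesign(
        params=null_params,
        n_loci=design.n_loci,
        length_range=design.length_range,
        n_west=design.n_west,
        n_east=design.n_east,
        scalar_sigma=design.scalar_sigma,
        mu=design.mu,
        master_seed=design.master_seed,
    )
    return generate_dataset(null_design)
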