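"""End-to-end workflows tying the modules together.

These are the functions the command-line interface, the analysis drivers
and the acceptance machinery share: load a dataset from disk, reduce it to
the four across-locus summary statistics plus per-locus simulation specs,
fit the demographic models, and tabulate diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import seqio
from .coalsim import ISOLATION, MODELS, LocusSpec, ModelParams
from .demolik import GridSpec, LikelihoodSurface, RejectionConfig, grid_search, profile_ci
from .diversity import (
    allele_counts,
    nucleotide_diversity,
    pairwise_fst,
    rarefied_richness,
    weighted_mean_pi,
)
from .modelcompare import compare_three_models
from .seqio import LocusAlignment, MutationRate, SampleRecord
from .sumstats import WHStats, classify_alignment, wakeley_hey

__all__ = [
    "Dataset",
    "load_dataset",
    "prepare_inference_inputs",
    "fit_models",
    "theta_profile_mle",
    "diversity_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    alignments: list[LocusAlignment]
    samples: list[SampleRecord]


def load_dataset(loci_dir: str | Path, map_path: str | Path) -> Dataset:
    """Read every per-locus FASTA under ``loci_dir`` plus the population map."""
    loci_dir = Path(loci_dir)
    samples = seqio.read_population_map(map_path)
    alignments = []
    for path in sorted(loci_dir.glob("*.fasta")):
        aln = seqio.read_locus_fasta(path, samples)
        aln.frame_offset = seqio.infer_reading_frame(aln.alleles[0][2])
        alignments.append(aln)
    if not alignments:
        raise FileNotFoundError(f"no .fasta files under {loci_dir}")
    return Dataset(alignments, samples)


def prepare_inference_inputs(
    dataset: Dataset,
) -> tuple[WHStats, list[LocusSpec], MutationRate, pd.DataFrame]:
    """Observed statistics, per-locus specs and calibrated mutation rate.

    Per locus: Wakeley-Hey counts at polarized synonymous variable sites,
    the synonymous-site count used as the effective sequence length, the
    sampled allele numbers, and a rate scalar from synonymous outgroup
    divergence; mu is calibrated from the mean divergence assuming the
    65-My outgroup split and a 1-year generation time.
    """
    per_locus_wh = []
    divergences = []
    rows = []
    for aln in dataset.alignments:
        wh = classify_alignment(aln)
        per_locus_wh.append(wh)
        divergences.append(seqio.synonymous_divergence(aln))
        rows.append(
            {
                "locus_name": aln.locus_name,
                "length": aln.length,
                "n_syn_sites": seqio.count_synonymous_sites(aln),
                "n_west": aln.allele_counts().get("west", 0),
                "n_east": aln.allele_counts().get("east", 0),
                "private_west": wh.private_west,
                "private_east": wh.private_east,
                "shared": wh.shared,
                "fixed": wh.fixed,
            }
        )
    table = pd.DataFrame(rows)
    rates = seqio.locus_scalars(divergences, list(table["locus_name"]))
    table["syn_divergence"] = [r.syn_divergence for r in rates]
    table["scalar"] = [r.scalar for r in rates]
    mu = seqio.calibrate_mu(float(np.mean(divergences)))
    obs = wakeley_hey(per_locus_wh)
    if obs.total == 0:
        raise ValueError("no polarizable synonymous variable sites in the dataset")
    specs = [
        LocusSpec(
            locus_name=row.locus_name,
            length=int(row.n_syn_sites),
            scalar=float(row.scalar),
            n_west=int(row.n_west),
            n_east=int(row.n_east),
        )
        for row in table.itertuples(index=False)
    ]
    return obs, specs, mu, table


def fit_models(
    obs: WHStats,
    specs: Sequence[LocusSpec],
    mu: MutationRate,
    cfg: RejectionConfig,
    grid: GridSpec | None = None,
    models: Sequence[str] = MODELS,
) -> tuple[dict[str, LikelihoodSurface], pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Likelihood surfaces, MLE table and profile CIs for the chosen models.

    Returns (surfaces, mle_table, ci_table, comparison_table); the
    comparison table is present only when all three models were fitted.
    """
    grid = grid or GridSpec()
    surfaces: dict[str, LikelihoodSurface] = {}
    mle_rows = []
    ci_rows = []
    for model in models:
        surface = grid_search(obs, model, grid, specs, mu, cfg)
        surfaces[model] = surface
        mle = surface.mle()
        mle_rows.append(
            {
                "model": model,
                "lnL": surface.max_lnL,
                "lnL_is_bound": surface.max_is_bound,
                "theta": mle.theta,
                "T_gen": mle.T_gen,
                "m": mle.m,
                "tau": mle.tau,
            }
        )
        axes = ["theta", "T_gen"]
        if model != ISOLATION:
            axes.append("m")
        if model == "secondary_contact":
            axes.append("tau")
        for axis in axes:
            lo, hi, cens_lo, cens_hi = profile_ci(surface, axis)
            ci_rows.append(
                {
                    "model": model,
                    "parameter": axis,
                    "ci_low": lo,
                    "ci_high": hi,
                    "censored_low": cens_lo,
                    "censored_high": cens_hi,
                }
            )
    comparison = compare_three_models(surfaces) if set(MODELS) <= set(surfaces) else None
    return surfaces, pd.DataFrame(mle_rows), pd.DataFrame(ci_rows), comparison


def theta_profile_mle(
    obs: WHStats,
    specs: Sequence[LocusSpec],
    mu: MutationRate,
    cfg: RejectionConfig,
    model_params: ModelParams,
    theta_axis: Sequence[float] | None = None,
) -> float:
    """Grid MLE of theta with the other parameters held fixed.

    Runs the rejection sampler along the theta axis only (the study's
    theta grid by default), holding T, m and tau at ``model_params``.
    """
    theta_axis = tuple(theta_axis) if theta_axis is not None else GridSpec().theta
    grid = GridSpec(
        T_gen=(model_params.T_gen,),
        theta=theta_axis,
        m=(model_params.m,),
        tau=(model_params.tau,),
    )
    surface = grid_search(obs, model_params.model, grid, specs, mu, cfg)
    return surface.mle().theta


def diversity_tables(
    dataset: Dataset,
    n_boot: int = 5000,
    n_perms: int = 10_000,
    rarefaction_depth: int | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population diversity table and pairwise F_ST table.

    The diversity table carries length-weighted mean pi and mean rarefied
    allelic richness per population with bootstrap CIs; rarefaction depth
    defaults to the smallest sampled-allele count over populations and
    loci (the study's rule).
    """
    populations = sorted({s.population for s in dataset.samples})
    seqs_by_pop = {
        pop: [aln.sequences(pop) for aln in dataset.alignments] for pop in populations
    }
    usable = {
        pop: [s for s in seqs_by_pop[pop] if len(s) >= 2] for pop in populations
    }
    for pop in populations:
        if not usable[pop]:
            logger.warning("population %s has <2 alleles at every locus; skipped", pop)
    if rarefaction_depth is None:
        rarefaction_depth = min(
            len(s)
            for pop in populations
            for s in seqs_by_pop[pop]
            if len(s) >= 2
        )

    div_rows = []
    for pop in populations:
        loci = usable[pop]
        if not loci:
            continue
        pis = [nucleotide_diversity(s) for s in loci]
        lengths = [len(s[0]) for s in loci]
        est = weighted_mean_pi(pis, lengths, pop, n_boot=n_boot, rng_seed=rng_seed)
        div_rows.append(
            {
                "population": pop,
                "statistic": "pi",
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": n_boot,
            }
        )
        richness = [
            rarefied_richness(allele_counts(s), min(rarefaction_depth, len(s)))
            for s in loci
        ]
        boot_rng = np.random.default_rng(rng_seed + 1)
        idx = boot_rng.integers(0, len(richness), size=(n_boot, len(richness)))
        boot = np.asarray(richness)[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        div_rows.append(
            {
                "population": pop,
                "statistic": "allelic_richness",
                "point": float(np.mean(richness)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_boot": n_boot,
            }
        )

    fst_rows = []
    for i, pop_a in enumerate(populations):
        for pop_b in populations[i + 1 :]:
            by_ind_a = []
            by_ind_b = []
            for aln in dataset.alignments:
                a_map: dict[str, list[str]] = {}
                b_map: dict[str, list[str]] = {}
                for _, sid, seq in aln.alleles:
                    if aln.populations.get(sid) == pop_a:
                        a_map.setdefault(sid, []).append(seq)
                    elif aln.populations.get(sid) == pop_b:
                        b_map.setdefault(sid, []).append(seq)
                by_ind_a.append(a_map)
                by_ind_b.append(b_map)
            result = pairwise_fst(
                by_ind_a,
                by_ind_b,
                pair_names=(pop_a, pop_b),
                n_perms=n_perms,
                rng_seed=rng_seed,
            )
            fst_rows.append(
                {
                    "pop_a": pop_a,
                    "pop_b": pop_b,
                    "fst": result.fst,
                    "p_value": result.p_value,
                    "n_perms": n_perms,
                }
            )
    return pd.DataFrame(div_rows), pd.DataFrame(fst_rows)
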