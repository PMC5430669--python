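"""Per-population genetic-diversity statistics.

Nucleotide diversity (pi) per locus with a length-weighted across-locus
mean and percentile-bootstrap confidence intervals; rarefied allelic
richness via the hypergeometric expectation; and pairwise F_ST from
haplotype sequences (Hudson's 1 - Hw/Hb) with an individual-level
permutation test.

Sites are compared with pairwise deletion: only positions where both
alleles carry a plain A/C/G/T base enter a pair's denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.special import comb

__all__ = [
    "DiversityEstimate",
    "FstResult",
    "nucleotide_diversity",
    "weighted_mean_pi",
    "rarefied_richness",
    "allele_counts",
    "hudson_fst",
    "pairwise_fst",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DiversityEstimate:
    population: str
    statistic: str  # "pi" | "allelic_richness"
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    per_locus: tuple[float, ...] = ()


@dataclass(frozen=True)
class FstResult:
    pop_pair: tuple[str, str]
    fst: float
    p_value: float
    n_perms: int


def _encode(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(byte codes, validity mask) for a set of equal-length sequences."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    valid = (
        (arr == ord("A"))
        | (arr == ord("C"))
        | (arr == ord("G"))
        | (arr == ord("T"))
    )
    return arr, valid


def _pair_matrices(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (differences, comparable sites) matrices for one locus."""
    arr, valid = _encode(seqs)
    n = len(seqs)
    diffs = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp_i = both.sum(axis=1)
        diff_i = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        diffs[i, i + 1 :] = diff_i
        diffs[i + 1 :, i] = diff_i
        comp[i, i + 1 :] = comp_i
        comp[i + 1 :, i] = comp_i
    return diffs, comp


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """Mean pairwise difference per comparable site over all allele pairs."""
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs at least 2 alleles")
    diffs, comp = _pair_matrices(seqs)
    iu = np.triu_indices(len(seqs), k=1)
    d, c = diffs[iu], comp[iu]
    usable = c > 0
    if not usable.any():
        raise ValueError("no comparable sites in any allele pair")
    return float(np.mean(d[usable] / c[usable]))


def weighted_mean_pi(
    pis: Sequence[float],
    lengths: Sequence[float],
    population: str = "",
    n_boot: int = 5000,
    rng_seed: int = 0,
) -> DiversityEstimate:
    """Length-weighted mean of per-locus pi with a bootstrap CI over loci.

    The point estimate is sum(pi_i L_i) / sum(L_i); the 95% CI is the
    2.5/97.5 percentile of the same statistic over ``n_boot`` resamples of
    loci with replacement.
    """
    pis = np.asarray(pis, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if pis.size == 0 or pis.size != lengths.size:
        raise ValueError("need matching, non-empty pi and length vectors")
    point = float(np.average(pis, weights=lengths))
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, pis.size, size=(n_boot, pis.size))
    boot = (pis[idx] * lengths[idx]).sum(axis=1) / lengths[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DiversityEstimate(
        population=population,
        statistic="pi",
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        per_locus=tuple(float(p) for p in pis),
    )


def rarefied_richness(counts: Sequence[int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    For an allele present in N_i of N copies, the probability it appears
    in a hypergeometric subsample of size g is 1 - C(N - N_i, g)/C(N, g);
    rarefied richness is the sum of these probabilities over alleles.
    """
    counts = [int(c) for c in counts if c > 0]
    total = sum(counts)
    if not counts:
        raise ValueError("no alleles observed")
    if not 1 <= g <= total:
        raise ValueError(f"rarefaction depth g={g} outside 1..{total}")
    denom = comb(total, g, exact=True)
    return float(
        sum(1.0 - comb(total - n_i, g, exact=True) / denom for n_i in counts)
    )


def allele_counts(seqs: Sequence[str]) -> list[int]:
    """Counts of distinct haplotype sequences (alleles) at a locus."""
    return sorted(Counter(seqs).values(), reverse=True)


def _fst_from_sums(
    dw_a: float, cw_a: float, dw_b: float, cw_b: float, db: float, cb: float
) -> float:
    if cw_a == 0 or cw_b == 0:
        raise ValueError("a population has no within-population pairs")
    if cb == 0:
        raise ValueError("no between-population pairs")
    hw = 0.5 * (dw_a / cw_a + dw_b / cw_b)
    hb = db / cb
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def hudson_fst(
    pop_a: Sequence[Sequence[str]], pop_b: Sequence[Sequence[str]]
) -> float:
    """F_ST = 1 - Hw/Hb from haplotype sequences, pooled across loci.

    ``pop_a``/``pop_b`` are per-locus lists of allele sequences.  Hw is the
    mean over the two populations of the per-site within-population
    pairwise difference, each pooled across loci by summing differences
    and comparable site-pairs; Hb pools all between-population pairs the
    same way.
    """
    if len(pop_a) != len(pop_b):
        raise ValueError("populations must cover the same loci")
    sums = [0.0] * 6  # dw_a, cw_a, dw_b, cw_b, db, cb
    for seqs_a, seqs_b in zip(pop_a, pop_b):
        diffs, comp = _pair_matrices(list(seqs_a) + list(seqs_b))
        na = len(seqs_a)
        iu_a = np.triu_indices(na, k=1)
        sums[0] += diffs[:na, :na][iu_a].sum()
        sums[1] += comp[:na, :na][iu_a].sum()
        iu_b = np.triu_indices(len(seqs_b), k=1)
        sums[2] += diffs[na:, na:][iu_b].sum()
        sums[3] += comp[na:, na:][iu_b].sum()
        cross_d = diffs[:na, na:]
        cross_c = comp[:na, na:]
        if list(seqs_a) == list(seqs_b):
            # a population against itself: drop the self-pairs so that the
            # between comparisons are the same set as the within ones and
            # F_ST is exactly 0
            off = ~np.eye(na, dtype=bool)
            sums[4] += cross_d[off].sum()
            sums[5] += cross_c[off].sum()
        else:
            sums[4] += cross_d.sum()
            sums[5] += cross_c.sum()
    return _fst_from_sums(*sums)


def pairwise_fst(
    pop_a: Sequence[Mapping[str, Sequence[str]]],
    pop_b: Sequence[Mapping[str, Sequence[str]]],
    pair_names: tuple[str, str] = ("west", "east"),
    n_perms: int = 10_000,
    rng_seed: int = 0,
) -> FstResult:
    """Multi-locus Hudson F_ST with an individual-permutation test.

    ``pop_a``/``pop_b`` give, per locus, a mapping individual -> its allele
    sequences.  The permutation unit is the individual (both alleles move
    together); p = (#{F_perm >= F_obs} + 1) / (n_perms + 1).

    Pairwise differences are pre-aggregated into per-individual-pair
    matrices so each permutation costs only mask indexing.
    """
    if len(pop_a) != len(pop_b):
        raise ValueError("populations must cover the same loci")
    individuals_a = sorted({ind for locus in pop_a for ind in locus})
    individuals_b = sorted({ind for locus in pop_b for ind in locus})
    individuals = individuals_a + individuals_b
    index = {ind: i for i, ind in enumerate(individuals)}
    n_ind = len(individuals)

    # D[i, j] / C[i, j]: summed allele-pair differences / comparable
    # site-pairs between individuals i and j (i == j: the within-diploid
    # pair), pooled across loci.
    D = np.zeros((n_ind, n_ind), dtype=np.float64)
    C = np.zeros((n_ind, n_ind), dtype=np.float64)
    for locus_a, locus_b in zip(pop_a, pop_b):
        merged = {**locus_a, **locus_b}
        owners = []
        seqs = []
        for ind, alleles in merged.items():
            for seq in alleles:
                owners.append(index[ind])
                seqs.append(seq)
        if len(seqs) < 2:
            continue
        diffs, comp = _pair_matrices(seqs)
        owners = np.asarray(owners)
        for r in range(len(seqs)):
            for c in range(r + 1, len(seqs)):
                oi, oj = owners[r], owners[c]
                if oi > oj:
                    oi, oj = oj, oi
                D[oi, oj] += diffs[r, c]
                C[oi, oj] += comp[r, c]
    D = D + np.triu(D, k=1).T
    C = C + np.triu(C, k=1).T

    n_a = len(individuals_a)
    labels = np.zeros(n_ind, dtype=bool)
    labels[:n_a] = True

    def fst_for(mask_a: np.ndarray) -> float:
        mask_b = ~mask_a
        within_a = np.outer(mask_a, mask_a)
        within_b = np.outer(mask_b, mask_b)
        between = np.outer(mask_a, mask_b)
        iu = np.triu_indices(n_ind)  # diagonal included: within-diploid pairs
        return _fst_from_sums(
            D[iu][within_a[iu]].sum(),
            C[iu][within_a[iu]].sum(),
            D[iu][within_b[iu]].sum(),
            C[iu][within_b[iu]].sum(),
            D[between].sum(),  # each unordered cross pair appears once
            C[between].sum(),
        )

    fst_obs = fst_for(labels)
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_perms):
        perm_mask = np.zeros(n_ind, dtype=bool)
        perm_mask[rng.choice(n_ind, size=n_a, replace=False)] = True
        if fst_for(perm_mask) >= fst_obs:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return FstResult(pair_names, float(fst_obs), p, n_perms)
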