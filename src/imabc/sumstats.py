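"""Wakeley–Hey polymorphism summaries for two-population sequence data.

The four across-locus statistics count segregating synonymous sites whose
derived polymorphism is private to the west population, private to the
east population, shared between them, or fixed between them.  Sites are
polarized with an outgroup; unpolarizable or tri-allelic sites are
excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coalsim import SimLocus
from .seqio import SYN_VARIABLE, LocusAlignment, classify_synonymous_sites

__all__ = [
    "WHStats",
    "classify_site",
    "classify_alignment",
    "wakeley_hey",
    "wh_from_sim",
    "PRIVATE_WEST",
    "PRIVATE_EAST",
    "SHARED",
    "FIXED",
    "MONOMORPHIC",
    "UNPOLARIZABLE",
]

_BASES = frozenset("ACGT")

PRIVATE_WEST = "private_west"
PRIVATE_EAST = "private_east"
SHARED = "shared"
FIXED = "fixed"
MONOMORPHIC = "monomorphic"
UNPOLARIZABLE = "unpolarizable"


@dataclass(frozen=True)
class WHStats:
    """The four-component summary-statistic vector."""

    private_west: int = 0
    private_east: int = 0
    shared: int = 0
    fixed: int = 0

    def __post_init__(self) -> None:
        if min(self.private_west, self.private_east, self.shared, self.fixed) < 0:
            raise ValueError("WHStats components must be non-negative")

    def __add__(self, other: "WHStats") -> "WHStats":
        return WHStats(
            self.private_west + other.private_west,
            self.private_east + other.private_east,
            self.shared + other.shared,
            self.fixed + other.fixed,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.private_west, self.private_east, self.shared, self.fixed],
            dtype=np.int64,
        )

    @property
    def total(self) -> int:
        return self.private_west + self.private_east + self.shared + self.fixed


def classify_site(
    west_alleles: Sequence[str], east_alleles: Sequence[str], ancestral: str
) -> str:
    """Classify one polarized site.

    A population is polymorphic when it carries both the ancestral and a
    derived base.  Polymorphic in one population only -> private there;
    polymorphic in both -> shared; monomorphic in both for different bases
    -> fixed.  Tri-allelic sites (more than two states among ingroup plus
    ancestral) and sites where polarity cannot be resolved are
    unpolarizable and excluded from the statistics.
    """
    if not west_alleles or not east_alleles:
        raise ValueError("each population needs at least one allele")
    bases = set(west_alleles) | set(east_alleles)
    if not bases <= _BASES or ancestral not in _BASES:
        raise ValueError("bases must be A/C/G/T")
    if len(bases) == 1:
        base = next(iter(bases))
        # monomorphic overall: either truly ancestral or derived fixed in
        # both populations; neither contributes a between-population signal
        return MONOMORPHIC
    if len(bases | {ancestral}) > 2:
        return UNPOLARIZABLE
    derived = next(iter(bases - {ancestral}))
    w = Counter(west_alleles)
    e = Counter(east_alleles)
    poly_w = 0 < w[derived] < len(west_alleles)
    poly_e = 0 < e[derived] < len(east_alleles)
    if poly_w and poly_e:
        return SHARED
    if poly_w:
        return PRIVATE_WEST
    if poly_e:
        return PRIVATE_EAST
    return FIXED


def classify_alignment(aln: LocusAlignment) -> WHStats:
    """Per-locus Wakeley–Hey counts from a phased alignment.

    Only synonymous variable sites are considered; the ancestral state at
    each is the outgroup base.  Sites where the outgroup base is not a
    plain nucleotide are unpolarizable and skipped.
    """
    if aln.outgroup_seq is None:
        raise ValueError(f"{aln.locus_name}: outgroup required for polarization")
    classes = classify_synonymous_sites(aln)
    west = aln.sequences("west")
    east = aln.sequences("east")
    if not west or not east:
        raise ValueError(f"{aln.locus_name}: both populations must be sampled")
    counts = Counter()
    for pos, site_class in enumerate(classes):
        if site_class != SYN_VARIABLE:
            continue
        anc = aln.outgroup_seq[pos]
        if anc not in _BASES:
            counts[UNPOLARIZABLE] += 1
            continue
        counts[classify_site([s[pos] for s in west], [s[pos] for s in east], anc)] += 1
    return WHStats(
        counts[PRIVATE_WEST], counts[PRIVATE_EAST], counts[SHARED], counts[FIXED]
    )


def wakeley_hey(per_locus: Iterable[WHStats]) -> WHStats:
    """Component-wise sum across loci."""
    total = WHStats()
    for stats in per_locus:
        total = total + stats
    return total


def wh_from_sim(locus: SimLocus) -> WHStats:
    """Wakeley–Hey counts from a simulated infinite-sites locus.

    The simulator's derived flags are the truth; every segregating site is
    bi-allelic and polarized by construction.
    """
    w, e = locus.derived_counts()
    nw, ne = locus.n_west, locus.n_east
    poly_w = (w > 0) & (w < nw)
    poly_e = (e > 0) & (e < ne)
    shared = poly_w & poly_e
    private_w = poly_w & ~poly_e
    private_e = poly_e & ~poly_w
    present = (w + e) > 0
    fixed = present & ~poly_w & ~poly_e & ~((w == nw) & (e == ne))
    return WHStats(
        int(private_w.sum()), int(private_e.sum()), int(shared.sum()), int(fixed.sum())
    )
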