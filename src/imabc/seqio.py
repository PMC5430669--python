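"""Phased multi-locus alignment I/O and synonymous-site bookkeeping.

Reads per-locus FASTA alignments of phased alleles together with a
tab-separated population map, infers reading frames by stop-codon
minimisation, classifies alignment columns as synonymous / nonsynonymous /
monomorphic / excluded, and calibrates the per-generation mutation rate and
per-locus relative-rate scalars from synonymous divergence to an outgroup.

FASTA header convention: ``<sample_id>_a1`` and ``<sample_id>_a2`` for the
two phased alleles of a diploid, and ``OUTGROUP`` for the (single) outgroup
sequence.  The population map is tab-separated with the header
``sample_id  species  population  year``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleRecord",
    "LocusAlignment",
    "LocusRates",
    "MutationRate",
    "FormatError",
    "MappingError",
    "read_population_map",
    "read_locus_fasta",
    "write_locus_fasta",
    "infer_reading_frame",
    "classify_synonymous_sites",
    "count_synonymous_sites",
    "synonymous_divergence",
    "calibrate_mu",
    "locus_scalars",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = ("A", "C", "G", "T")

# Site classes emitted by classify_synonymous_sites
SYN_VARIABLE = "synonymous_variable"
NONSYN_VARIABLE = "nonsynonymous_variable"
MONOMORPHIC = "monomorphic"
EXCLUDED = "excluded"


class FormatError(ValueError):
    """Malformed alignment input (ragged records, bad headers...)."""


class MappingError(ValueError):
    """Samples present in a FASTA but absent from the population map."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    population: str  # "east" | "west"
    year: int


@dataclass
class LocusAlignment:
    """One locus: phased allele sequences with population labels.

    ``alleles`` is a list of ``(allele_id, sample_id, sequence)`` tuples;
    every present sample contributes exactly two alleles (phased diploid
    data).  ``frame_offset`` must be set (0/1/2) before synonymous
    classification.
    """

    locus_name: str
    alleles: list[tuple[str, str, str]]
    populations: dict[str, str] = field(default_factory=dict)  # sample_id -> east/west
    outgroup_seq: str | None = None
    frame_offset: int | None = None

    @property
    def length(self) -> int:
        return len(self.alleles[0][2]) if self.alleles else 0

    def sequences(self, population: str | None = None) -> list[str]:
        if population is None:
            return [seq for _, _, seq in self.alleles]
        return [
            seq
            for _, sid, seq in self.alleles
            if self.populations.get(sid) == population
        ]

    def allele_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, sid, _ in self.alleles:
            pop = self.populations.get(sid, "?")
            counts[pop] = counts.get(pop, 0) + 1
        return counts


@dataclass(frozen=True)
class LocusRates:
    locus_name: str
    syn_divergence: float  # substitutions per synonymous site vs outgroup
    scalar: float  # relative rate, mean 1 across loci


@dataclass(frozen=True)
class MutationRate:
    mu: float  # substitutions / site / generation
    divergence_time_years: float = 65e6
    generation_time_years: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def read_population_map(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "species", "population", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"population map {path} lacks columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"duplicate sample ids in map: {dups}")
    records = []
    for row in df.itertuples(index=False):
        if row.population not in ("east", "west"):
            raise FormatError(
                f"population must be east/west, got {row.population!r} "
                f"for sample {row.sample_id}"
            )
        records.append(
            SampleRecord(row.sample_id, row.species, row.population, int(row.year))
        )
    return records


def _parse_header(header: str) -> tuple[str, str]:
    """Split ``<sample>_a1`` into (sample_id, allele suffix)."""
    if "_a" not in header:
        raise FormatError(f"FASTA header {header!r} does not follow <sample>_a1/_a2")
    sample_id, _, suffix = header.rpartition("_a")
    if suffix not in ("1", "2") or not sample_id:
        raise FormatError(f"FASTA header {header!r} does not follow <sample>_a1/_a2")
    return sample_id, suffix


def read_locus_fasta(
    path: str | Path, population_map: Sequence[SampleRecord]
) -> LocusAlignment:
    """Read one locus alignment, joining east/west labels from the map.

    The record named ``OUTGROUP`` (if present) becomes ``outgroup_seq`` and
    is not counted among the alleles.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    by_sample = {r.sample_id: r for r in population_map}
    alleles: list[tuple[str, str, str]] = []
    outgroup = None
    length = None
    for rec in records:
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FormatError(
                f"{path}: record {rec.id} has length {len(seq)}, expected {length}"
            )
        if rec.id == "OUTGROUP":
            outgroup = seq
            continue
        sample_id, _ = _parse_header(rec.id)
        alleles.append((rec.id, sample_id, seq))

    unknown = sorted({sid for _, sid, _ in alleles} - set(by_sample))
    if unknown:
        raise MappingError(f"{path}: samples absent from population map: {unknown}")
    per_sample: dict[str, int] = {}
    for _, sid, _ in alleles:
        per_sample[sid] = per_sample.get(sid, 0) + 1
    bad = {sid: n for sid, n in per_sample.items() if n != 2}
    if bad:
        raise FormatError(f"{path}: samples without exactly 2 alleles: {bad}")

    populations = {sid: by_sample[sid].population for sid in per_sample}
    return LocusAlignment(
        locus_name=path.stem,
        alleles=alleles,
        populations=populations,
        outgroup_seq=outgroup,
    )


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=allele_id, description="")
        for allele_id, _, seq in aln.alleles
    ]
    if aln.outgroup_seq is not None:
        records.append(SeqRecord(Seq(aln.outgroup_seq), id="OUTGROUP", description=""))
    SeqIO.write(records, str(path), "fasta")


def infer_reading_frame(seq: str) -> int:
    """Offset in {0,1,2} minimising stop codons over complete codons.

    Gaps are removed before codon enumeration; ties go to the smallest
    offset.  Raises on an effectively empty sequence.
    """
    ungapped = seq.upper().replace("-", "")
    if len(ungapped) < 3:
        raise ValueError("sequence has fewer than 3 ungapped bases")
    counts = []
    for offset in range(3):
        codons = [
            ungapped[i : i + 3]
            for i in range(offset, len(ungapped) - 2, 3)
        ]
        counts.append(sum(1 for c in codons if c in STOP_CODONS))
    return int(np.argmin(counts))


def _translate(codon: str) -> str | None:
    """Amino acid for a clean codon, '*' for stop, None if ambiguous."""
    if any(b not in _BASES for b in codon):
        return None
    return str(Seq(codon).translate())


def classify_synonymous_sites(aln: LocusAlignment) -> list[str]:
    """Per-site class over the full alignment length.

    A variable site is synonymous iff every observed in-frame codon variant
    (ingroup alleles plus outgroup) encodes the same amino acid.  Codon
    columns containing any N, gap or stop variant are excluded wholesale;
    leading bases before the frame offset are excluded.  The classes over
    all positions always sum to the alignment length.
    """
    if aln.frame_offset is None:
        raise ValueError("frame_offset must be set before classification")
    offset = aln.frame_offset
    length = aln.length
    if (length - offset) % 3 != 0:
        raise ValueError(
            f"alignment length {length} minus offset {offset} is not a codon multiple;"
            " trim to whole codons first"
        )
    seqs = [seq for _, _, seq in aln.alleles]
    if aln.outgroup_seq is not None:
        seqs = seqs + [aln.outgroup_seq]

    classes = [EXCLUDED] * length
    for codon_start in range(offset, length, 3):
        cols = range(codon_start, codon_start + 3)
        codons = {seq[codon_start : codon_start + 3] for seq in seqs}
        aas = {_translate(c) for c in codons}
        if None in aas or "*" in aas:
            continue  # leaves the codon's sites excluded
        # ingroup-only variability decides variable vs monomorphic
        ingroup = [seq for _, _, seq in aln.alleles]
        for col in cols:
            bases = {s[col] for s in ingroup}
            if len(bases) == 1:
                classes[col] = MONOMORPHIC
            elif len(aas) == 1:
                classes[col] = SYN_VARIABLE
            else:
                classes[col] = NONSYN_VARIABLE
    return classes


def _fourfold_positions(reference_codons: Iterable[tuple[int, str]]) -> list[int]:
    positions = []
    for start, codon in reference_codons:
        aa = _translate(codon)
        if aa is None or aa == "*":
            continue
        for i in range(3):
            alts = {
                _translate(codon[:i] + b + codon[i + 1 :])
                for b in _BASES
            }
            if alts == {aa}:
                positions.append(start + i)
    return positions


def _reference_codons(aln: LocusAlignment) -> list[tuple[int, str]]:
    """(start, codon) pairs from the outgroup, else the ingroup majority."""
    if aln.frame_offset is None:
        raise ValueError("frame_offset must be set")
    out = []
    for start in range(aln.frame_offset, aln.length - 2, 3):
        if aln.outgroup_seq is not None:
            codon = aln.outgroup_seq[start : start + 3]
        else:
            variants = [seq[start : start + 3] for _, _, seq in aln.alleles]
            codon = max(set(variants), key=variants.count)
        out.append((start, codon))
    return out


def fourfold_degenerate_positions(aln: LocusAlignment) -> list[int]:
    """Columns whose reference codon is 4-fold degenerate at that position."""
    return _fourfold_positions(_reference_codons(aln))


def count_synonymous_sites(aln: LocusAlignment) -> int:
    """Number of sites at which any mutation would be synonymous.

    Counted as 4-fold degenerate positions of the reference codon (outgroup
    where available).  Used as the effective sequence length when comparing
    synonymous-site polymorphism to coalescent simulations.
    """
    return len(fourfold_degenerate_positions(aln))


def _majority_base(column: list[str]) -> str | None:
    clean = [b for b in column if b in _BASES]
    if not clean:
        return None
    return max(set(clean), key=clean.count)


def synonymous_divergence(aln: LocusAlignment) -> float:
    """Raw p-distance to the outgroup at 4-fold degenerate sites."""
    if aln.outgroup_seq is None:
        raise ValueError(f"{aln.locus_name}: no outgroup sequence")
    positions = fourfold_degenerate_positions(aln)
    if not positions:
        raise ValueError(f"{aln.locus_name}: no synonymous sites")
    diffs = 0
    for pos in positions:
        ingroup = _majority_base([seq[pos] for _, _, seq in aln.alleles])
        out_base = aln.outgroup_seq[pos]
        if ingroup is not None and out_base in _BASES and ingroup != out_base:
            diffs += 1
    return diffs / len(positions)


def calibrate_mu(
    syn_divergence: float,
    divergence_time_years: float = 65e6,
    generation_time_years: float = 1.0,
) -> MutationRate:
    """Per-generation mutation rate from synonymous outgroup divergence.

    Divergence accumulates along both lineages, so
    ``mu = d / (2 * t / g)`` with t the split time in years and g the
    generation time.
    """
    if syn_divergence <= 0 or divergence_time_years <= 0 or generation_time_years <= 0:
        raise ValueError("all calibration inputs must be positive")
    generations = 2.0 * divergence_time_years / generation_time_years
    return MutationRate(
        mu=syn_divergence / generations,
        divergence_time_years=divergence_time_years,
        generation_time_years=generation_time_years,
    )


def locus_scalars(
    divergences: Sequence[float], locus_names: Sequence[str] | None = None
) -> list[LocusRates]:
    """Relative rate scalars d_i / mean(d), normalised to mean exactly 1."""
    d = np.asarray(divergences, dtype=float)
    if d.size == 0:
        raise ValueError("no divergences supplied")
    if np.any(d <= 0):
        raise ValueError("synonymous divergences must all be positive")
    scalars = d / d.mean()
    if locus_names is None:
        locus_names = [f"locus_{i + 1:02d}" for i in range(d.size)]
    return [
        LocusRates(name, float(di), float(si))
        for name, di, si in zip(locus_names, d, scalars)
    ]
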