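"""Shared fixtures: mutation-rate calibration and small alignment builders."""

from __future__ import annotations

import pytest

from imabc.seqio import LocusAlignment, MutationRate


@pytest.fixture(scope="session")
def mu() -> MutationRate:
    """The study's calibrated mutation rate."""
    return MutationRate(2.69e-9, divergence_time_years=65e6, generation_time_years=1.0)


def make_alignment(
    seqs_west: list[str],
    seqs_east: list[str],
    outgroup: str | None = None,
    locus_name: str = "locus_t",
    frame_offset: int | None = 0,
) -> LocusAlignment:
    """Alignment from per-population phased sequences (two per sample)."""
    if len(seqs_west) % 2 or len(seqs_east) % 2:
        raise ValueError("phased data: supply an even number of sequences per pop")
    alleles = []
    populations = {}
    for pop, seqs, prefix in (("west", seqs_west, "W"), ("east", seqs_east, "E")):
        for i in range(0, len(seqs), 2):
            sid = f"{prefix}{i // 2 + 1:02d}"
            populations[sid] = pop
            alleles.append((f"{sid}_a1", sid, seqs[i]))
            alleles.append((f"{sid}_a2", sid, seqs[i + 1]))
    return LocusAlignment(
        locus_name=locus_name,
        alleles=alleles,
        populations=populations,
        outgroup_seq=outgroup,
        frame_offset=frame_offset,
    )
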