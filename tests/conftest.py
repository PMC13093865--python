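"""Shared fixtures: tiny hand-built datasets and simulated genera."""

from __future__ import annotations

import pytest

from antatlas.records import AlignedSeq, GenusAlignment, SpecimenRecord
from antatlas.simulate import SimConfig, simulate_genus


def make_record(specimen_id: str, species: str | None, **kwargs) -> SpecimenRecord:
    defaults = dict(genus="Testus", det_status="identified")
    defaults.update(kwargs)
    return SpecimenRecord(specimen_id=specimen_id, species=species, **defaults)


def seq_with_snps(length: int, snps: dict[int, str], base: str = "A") -> str:
    chars = [base] * length
    for pos, char in snps.items():
        chars[pos] = char
    return "".join(chars)


@pytest.fixture(scope="session")
def sim_genus():
    """One moderately sized simulated genus, reused read-only."""
    config = SimConfig(n_species=6, seqs_per_species=(3, 10), seed=42)
    return simulate_genus(config)


@pytest.fixture
def two_species_alignment():
    """Two well-separated species plus one cf sequence, 658 columns."""
    length = 658
    seqs = [
        AlignedSeq("a1", seq_with_snps(length, {})),
        AlignedSeq("a2", seq_with_snps(length, {10: "T"})),
        AlignedSeq("a3", seq_with_snps(length, {10: "T", 20: "G"})),
        AlignedSeq("b1", seq_with_snps(length, {i: "C" for i in range(0, 60, 2)})),
        AlignedSeq("b2", seq_with_snps(length, {i: "C" for i in range(0, 60, 2)} | {100: "T"})),
        AlignedSeq("b3", seq_with_snps(length, {i: "C" for i in range(0, 60, 2)} | {200: "G"})),
        AlignedSeq("a_cf", seq_with_snps(length, {i: "G" for i in range(300, 420, 2)})),
    ]
    records = [
        make_record("a1", "alpha"),
        make_record("a2", "alpha"),
        make_record("a3", "alpha"),
        make_record("b1", "beta"),
        make_record("b2", "beta"),
        make_record("b3", "beta"),
        make_record("a_cf", "alpha", det_status="cf"),
    ]
    return GenusAlignment("Testus", seqs), records
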